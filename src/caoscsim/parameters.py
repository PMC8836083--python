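"""Parameter containers for the Ca2+ oscillation model and the drug-effect layer.

Kinetic constants live in :class:`ModelParameters`; the Michaelis–Menten
inhibition constants of the two drugs (afatinib, a tyrosine-kinase inhibitor,
and RP4010, a store-operated Ca2+ entry blocker) live in
:class:`DrugParameters`; a treatment is a :class:`DrugDose`.

All concentrations are in µM and all times in seconds throughout the package;
there is no unit-conversion layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "DrugParameters",
    "DrugDose",
    "kyse150_parameters",
    "het1a_parameters",
    "baseline_drug_parameters",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass
class ModelParameters:
    """Kinetic constants of the four-variable Ca2+ oscillation model.

    Defaults are the KYSE-150 (esophageal squamous carcinoma) calibration.
    ``p_s`` (steady-state IP3, µM) and ``k_beta`` (open-probability mode
    constant) are not identifiable from the flux equations alone; ``k_beta``
    keeps its source-model value 0.4 and ``p_s`` is calibrated so that the
    undrugged cell oscillates with a 32.8 s period.

    ``tau_max`` is a time (seconds): dh/dt = (h_inf - h)/tau_h requires
    tau_h to carry units of time.
    """

    delta: float = 1.5          # PM-to-ER flux scale ratio (dimensionless)
    K_tau: float = 0.1          # µM, Ca2+ scale of the h time constant
    K_c: float = 0.2            # µM, half-maximal Ca2+ for IP3R activation
    k_f: float = 3.9            # s^-1, IP3R density / release scale
    V_serca: float = 0.9        # µM/s, maximal SERCA pump rate
    gamma: float = 5.5          # cytosol:ER volume ratio (dimensionless)
    V_pm: float = 0.11          # µM/s, maximal plasma-membrane pump rate
    alpha0: float = 0.0027      # µM/s, constitutive Ca2+ leak into the cell
    K_p: float = 0.2            # µM, half-maximal IP3 for IP3R
    tau_max: float = 1420.0     # s, ceiling of the h relaxation time
    beta_p: float = 0.027       # s^-1, IP3 turnover rate
    K_h: float = 0.08           # µM, half-maximal Ca2+ for IP3R inactivation
    K_bar: float = 1.9e-5       # dimensionless, reverse-mode SERCA weight
    K_e: float = 8.0            # µM, ER Ca2+ scale of SOCE shut-off
    K_pm: float = 0.3           # µM, half-maximal Ca2+ for the PM pump
    alpha1: float = 0.385       # µM/s, maximal SOCE influx rate
    p_s: float = 0.1004         # µM, steady-state IP3 (calibrated)
    k_beta: float = 0.4         # dimensionless, P_O mode constant
    k_serca_half: float = 0.2   # µM, half-saturation of the SERCA flux

    # fixed field order shared with the compiled integrator backend
    _FIELDS = (
        "delta", "K_tau", "K_c", "k_f", "V_serca", "gamma", "V_pm",
        "alpha0", "K_p", "tau_max", "beta_p", "K_h", "K_bar", "K_e",
        "K_pm", "alpha1", "p_s", "k_beta", "k_serca_half",
    )

    def __post_init__(self) -> None:
        self.validate()

    # flux-scale constants may be zeroed (channel/pump knockout); the
    # remaining constants appear in denominators and must stay positive
    _NONNEGATIVE = ("k_f", "V_serca", "V_pm", "alpha0", "alpha1", "p_s", "K_bar")

    def validate(self) -> None:
        for name in self._FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ParameterError(f"{name} must be finite, got {value!r}")
            if name in self._NONNEGATIVE:
                if value < 0.0:
                    raise ParameterError(f"{name} must be >= 0, got {value!r}")
            elif value <= 0.0:
                raise ParameterError(f"{name} must be > 0, got {value!r}")
        if self.gamma < 1.0:
            raise ParameterError("gamma is a cytosol:ER volume ratio and must be >= 1")
        if self.K_bar >= 1.0:
            raise ParameterError("K_bar must be < 1 (reverse SERCA is a small correction)")

    def to_vector(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the integrators."""
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=np.float64)

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {f: float(getattr(self, f)) for f in self._FIELDS}

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParameters":
        unknown = set(mapping) - set(cls._FIELDS)
        if unknown:
            raise ParameterError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if isinstance(payload, dict) and "model" in payload:
            payload = payload["model"]
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"model": self.to_dict()}, fh, sort_keys=False)


@dataclass
class DrugParameters:
    """Michaelis–Menten inhibition constants for the two drugs.

    ``c1``/``k1`` shape afatinib's inhibition of IP3 production (factor D1);
    ``c2``/``k2`` shape RP4010's block of SOCE and ``c3``/``k3`` afatinib's
    crosstalk onto SOCE (both inside factor D2).  Defaults are the fitted
    KYSE-150 values.
    """

    c1: float = 0.51
    c2: float = 1.0
    c3: float = 0.76
    k1: float = 0.34   # µM
    k2: float = 0.6    # µM
    k3: float = 0.8    # µM

    _FIELDS = ("c1", "c2", "c3", "k1", "k2", "k3")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("c1", "c2", "c3"):
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} is a fractional maximal effect; got {value!r}")
        for name in ("k1", "k2", "k3"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ParameterError(f"{name} is a half-effect dose and must be > 0; got {value!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=np.float64)

    def replace(self, **changes: float) -> "DrugParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {f: float(getattr(self, f)) for f in self._FIELDS}

    @classmethod
    def from_dict(cls, mapping: dict) -> "DrugParameters":
        unknown = set(mapping) - set(cls._FIELDS)
        if unknown:
            raise ParameterError(f"unknown drug parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugParameters":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if isinstance(payload, dict) and "drug" in payload:
            payload = payload["drug"]
        return cls.from_dict(payload)


@dataclass(frozen=True)
class DrugDose:
    """A treatment: ``S1`` µM afatinib and ``S2`` µM RP4010."""

    S1: float = 0.0
    S2: float = 0.0

    def __post_init__(self) -> None:
        if self.S1 < 0.0 or self.S2 < 0.0:
            raise ParameterError(f"doses must be non-negative, got {self}")


def _packaged(name: str):
    return resources.files("caoscsim.data").joinpath(name)


def kyse150_parameters() -> ModelParameters:
    """Calibrated KYSE-150 parameter set shipped with the package."""
    with resources.as_file(_packaged("params_kyse150.yaml")) as path:
        return ModelParameters.from_yaml(path)


def het1a_parameters() -> ModelParameters:
    """Het-1A (non-tumorous esophageal epithelium) set: k_f/5 and alpha1/3."""
    with resources.as_file(_packaged("params_het1a.yaml")) as path:
        return ModelParameters.from_yaml(path)


def baseline_drug_parameters() -> DrugParameters:
    """Fitted drug constants (c1..c3, k1..k3) for the KYSE-150 model."""
    return DrugParameters()
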