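"""Nonlinear least-squares calibration against dose–period data.

Calibration is staged, mirroring how the model was built: first the
baseline kinetics are adjusted so the untreated cell reproduces the control
period (:func:`fit_baseline`), then — with the baseline frozen — the six
Michaelis–Menten drug constants are fitted to dose–period tables
(:func:`fit_drug_params`).  Joint refitting is available by passing several
tables at once.

The simulated-period objective is non-smooth where a trial parameter set
kills the oscillation; such trial points receive a large penalty residual
(10x the largest observed period) instead of crashing the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .drugs import drug_factors
from .parameters import DrugDose, DrugParameters, ModelParameters
from .simulate import extract_period, integrate_factors

__all__ = ["DosePeriodTable", "FitResult", "fit_baseline", "fit_drug_params",
           "DEFAULT_DRUG_BOUNDS"]

#: c_i are fractional maximal inhibitions; k_i are half-effect doses in µM
DEFAULT_DRUG_BOUNDS = {
    "c1": (0.0, 1.0), "c2": (0.0, 1.0), "c3": (0.0, 1.0),
    "k1": (0.01, 100.0), "k2": (0.01, 100.0), "k3": (0.01, 100.0),
}

_BASELINE_FITTABLE = ("k_f", "alpha1", "tau_max", "V_serca", "p_s")


class FitInfeasibleError(RuntimeError):
    """No oscillation anywhere in the search region."""


@dataclass
class DosePeriodTable:
    """Rows of (S1 µM afatinib, S2 µM RP4010, period mean ± SEM in s)."""

    frame: pd.DataFrame

    REQUIRED = ("S1_uM", "S2_uM", "period_s", "sem_s")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValueError(f"dose-period table missing columns {sorted(missing)}")
        if len(self.frame) == 0:
            raise ValueError("dose-period table is empty")
        if (self.frame["period_s"] <= 0).any():
            raise ValueError("periods must be positive")
        if (self.frame[["S1_uM", "S2_uM"]] < 0).any().any():
            raise ValueError("doses must be non-negative")
        if (self.frame["sem_s"] < 0).any():
            raise ValueError("SEMs must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DosePeriodTable":
        return cls(pd.read_csv(path, comment="#"))

    @property
    def doses(self) -> list[DrugDose]:
        return [DrugDose(float(r.S1_uM), float(r.S2_uM))
                for r in self.frame.itertuples(index=False)]


@dataclass
class FitResult:
    parameters: dict
    residuals: np.ndarray
    cost: float
    success: bool
    n_evaluations: int
    message: str = ""
    model_parameters: ModelParameters | None = None
    drug_parameters: DrugParameters | None = None
    history: list = field(default_factory=list)


def _period_or_none(params: ModelParameters, d1: float, d2: float,
                    t_end: float, cutoff: float, method: str) -> float | None:
    try:
        traj = integrate_factors(params, d1, d2, t_end=t_end,
                                 transient_cutoff=cutoff, method=method)
    except Exception:
        return None
    summ = extract_period(traj)
    return summ.period_mean if summ.oscillating else None


def fit_baseline(target_period: float,
                 params0: ModelParameters,
                 free: tuple[str, ...] = ("p_s",),
                 bounds_factor: float = 10.0,
                 t_end: float = 4000.0,
                 transient_cutoff: float = 1000.0,
                 method: str = "rk45",
                 xtol: float = 1e-10) -> FitResult:
    """Adjust a subset of baseline kinetic constants to hit a target period.

    ``free`` may include any of k_f, alpha1, tau_max, V_serca and p_s; the
    search runs on log-scaled parameters inside a box spanning
    ``bounds_factor`` either side of the starting value.  Succeeds when the
    fitted set reproduces the target within 1%.
    """
    if target_period <= 0:
        raise ValueError("target_period must be positive")
    bad = set(free) - set(_BASELINE_FITTABLE)
    if bad:
        raise ValueError(f"cannot fit {sorted(bad)}; fittable: {_BASELINE_FITTABLE}")

    x0 = np.log([getattr(params0, name) for name in free])
    lo, hi = x0 - np.log(bounds_factor), x0 + np.log(bounds_factor)
    penalty = 10.0 * target_period
    history: list = []

    def residual(x: np.ndarray) -> np.ndarray:
        trial = params0.replace(**{n: float(v) for n, v in zip(free, np.exp(x))})
        period = _period_or_none(trial, 1.0, 1.0, t_end, transient_cutoff, method)
        value = penalty if period is None else period - target_period
        history.append((dict(zip(free, np.exp(x))), period))
        return np.array([value])

    if _period_or_none(params0, 1.0, 1.0, t_end, transient_cutoff, method) is None:
        # starting point does not oscillate: scan the box diagonal for an
        # oscillating start before declaring infeasibility
        for scale in np.geomspace(1.0 / bounds_factor, bounds_factor, 9):
            trial = params0.replace(**{n: float(getattr(params0, n) * scale) for n in free})
            if _period_or_none(trial, 1.0, 1.0, t_end, transient_cutoff, method) is not None:
                x0 = np.log([getattr(trial, n) for n in free])
                break
        else:
            raise FitInfeasibleError("no oscillation found in the search box")

    sol = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                        xtol=xtol, ftol=1e-12, gtol=1e-12, diff_step=1e-3)
    fitted = params0.replace(**{n: float(v) for n, v in zip(free, np.exp(sol.x))})
    achieved = _period_or_none(fitted, 1.0, 1.0, t_end, transient_cutoff, method)
    ok = achieved is not None and abs(achieved - target_period) / target_period < 0.01
    return FitResult(parameters={n: float(v) for n, v in zip(free, np.exp(sol.x))},
                     residuals=sol.fun, cost=float(sol.cost), success=bool(ok),
                     n_evaluations=int(sol.nfev), message=sol.message,
                     model_parameters=fitted, history=history)


def fit_drug_params(tables: list[DosePeriodTable] | DosePeriodTable,
                    params: ModelParameters,
                    dp0: DrugParameters | None = None,
                    free: tuple[str, ...] = DrugParameters._FIELDS,
                    bounds: dict | None = None,
                    weight: str | None = None,
                    t_end: float = 6000.0,
                    transient_cutoff: float = 1500.0,
                    method: str = "rk45",
                    max_nfev: int | None = None) -> FitResult:
    """Fit the Michaelis–Menten drug constants to dose–period tables.

    Minimizes sum over rows of (simulated_period(dose; dp) - period_mean)^2,
    optionally SEM-weighted (``weight="sem"``).  The baseline kinetics in
    ``params`` stay frozen.  Trial points that kill the oscillation at some
    dose contribute a penalty residual of 10x the largest observed period.
    """
    if isinstance(tables, DosePeriodTable):
        tables = [tables]
    if not tables:
        raise ValueError("need at least one dose-period table")
    data = pd.concat([t.frame for t in tables], ignore_index=True)
    doses = [DrugDose(float(r.S1_uM), float(r.S2_uM)) for r in data.itertuples(index=False)]
    observed = data["period_s"].to_numpy(float)
    if weight == "sem":
        sem = data["sem_s"].to_numpy(float)
        w = 1.0 / np.where(sem > 0, sem, np.nanmin(sem[sem > 0]) if (sem > 0).any() else 1.0)
    elif weight is None:
        w = np.ones_like(observed)
    else:
        raise ValueError("weight must be None or 'sem'")

    dp0 = DrugParameters() if dp0 is None else dp0
    bounds = DEFAULT_DRUG_BOUNDS if bounds is None else bounds
    x0 = np.array([getattr(dp0, n) for n in free], dtype=float)
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    x0 = np.clip(x0, lo, hi)
    penalty = 10.0 * float(observed.max())

    def build(x: np.ndarray) -> DrugParameters:
        values = dp0.to_dict()
        values.update({n: float(v) for n, v in zip(free, x)})
        return DrugParameters(**values)

    def residual(x: np.ndarray) -> np.ndarray:
        dp = build(x)
        out = np.empty(len(doses))
        for i, dose in enumerate(doses):
            d1, d2 = drug_factors(dose, dp)
            period = _period_or_none(params, d1, d2, t_end, transient_cutoff, method)
            out[i] = penalty if period is None else w[i] * (period - observed[i])
        return out

    sol = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                        diff_step=1e-3, xtol=1e-10, ftol=1e-10, gtol=1e-10,
                        max_nfev=max_nfev)
    fitted = build(sol.x)
    return FitResult(parameters={n: float(v) for n, v in zip(free, sol.x)},
                     residuals=sol.fun, cost=float(sol.cost),
                     success=bool(sol.success), n_evaluations=int(sol.nfev),
                     message=sol.message, drug_parameters=fitted)
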