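"""Core dynamics: IP3R gating, membrane fluxes and the ODE right-hand side.

The cell is described by four state variables:

* ``c`` — cytosolic Ca2+ (µM),
* ``ce`` — ER Ca2+ (µM),
* ``h`` — slow IP3R gating variable (fraction of receptors not
  Ca2+-inactivated, in [0, 1]),
* ``p`` — IP3 concentration (µM).

Ca2+ leaves the ER through the IP3 receptor (``J_IPR``), is pumped back by
SERCA (``J_serca``), enters the cell through a constitutive leak plus
store-operated entry (``J_in``) and is extruded by the plasma-membrane pump
(``J_pm``).  Drug action enters through two multiplicative factors: ``D1``
scales IP3 production and ``D2`` scales the store-operated influx term (see
:mod:`caoscsim.drugs`); ``D1 = D2 = 1`` is the untreated cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters

__all__ = ["ModelState", "Fluxes", "open_probability", "h_inf", "tau_h",
           "compute_fluxes", "rhs"]


class DomainError(ValueError):
    """Raised for state values outside the model's physical domain."""


@dataclass(frozen=True)
class ModelState:
    c: float
    ce: float
    h: float
    p: float

    def to_array(self) -> np.ndarray:
        return np.array([self.c, self.ce, self.h, self.p], dtype=np.float64)

    @classmethod
    def from_array(cls, y) -> "ModelState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class Fluxes:
    """Instantaneous membrane/ER fluxes, all in µM/s."""

    J_IPR: float
    J_serca: float
    J_in: float
    J_pm: float


def h_inf(c: float, params: ModelParameters) -> float:
    """Steady-state of the gating variable, ``K_h^4 / (K_h^4 + c^4)``."""
    k4 = params.K_h ** 4
    return k4 / (k4 + c ** 4)


def tau_h(c: float, params: ModelParameters) -> float:
    """Relaxation time of ``h`` (seconds): ``tau_max K_tau^4/(K_tau^4+c^4)``.

    Tends to ``tau_max`` as c -> 0; no lower bound is imposed.
    """
    k4 = params.K_tau ** 4
    return params.tau_max * k4 / (k4 + c ** 4)


def open_probability(c: float, p: float, h: float, params: ModelParameters) -> float:
    """IP3R open probability ``P_O = beta / (beta + k_beta (beta + alpha))``.

    ``beta = B(p) m(c) h`` is the activation rate and
    ``alpha = A(p) (1 - m(c) h_inf(c))`` the inactivation rate, with the
    shared Ca2+ activation curve ``m(c) = c^4/(K_c^4 + c^4)`` and the IP3
    dependencies ``B(p) = p^2/(K_p^2 + p^2)`` and ``A(p) = 1 - B(p)``.

    The 0/0 ambiguity at ``alpha = beta = 0`` is resolved to a closed
    channel (the continuous limit as p -> 0).
    """
    if c < 0.0 or p < 0.0:
        raise DomainError(f"concentrations must be non-negative, got c={c}, p={p}")
    if not 0.0 <= h <= 1.0:
        raise DomainError(f"h must lie in [0, 1], got {h}")
    c4 = c ** 4
    m = c4 / (params.K_c ** 4 + c4)
    b_p = p * p / (params.K_p ** 2 + p * p)
    alpha = (1.0 - b_p) * (1.0 - m * h_inf(c, params))
    beta = b_p * m * h
    denominator = beta + params.k_beta * (beta + alpha)
    if denominator <= 0.0:
        return 0.0
    return beta / denominator


def compute_fluxes(state: ModelState, params: ModelParameters,
                   drug_factor_D2: float = 1.0) -> Fluxes:
    """Evaluate the four Ca2+ fluxes at a state.

    ``drug_factor_D2`` scales only the store-operated (SOCE) part of
    ``J_in``; the constitutive leak ``alpha0`` is untouched by drug.
    """
    c, ce = state.c, state.ce
    if c < 0.0 or ce < 0.0:
        raise DomainError(f"concentrations must be non-negative, got c={c}, ce={ce}")
    po = open_probability(c, state.p, state.h, params)
    j_ipr = params.k_f * po * (ce - c)
    j_serca = params.V_serca * (c * c - params.K_bar * ce * ce) / (c * c + params.k_serca_half ** 2)
    ke4 = params.K_e ** 4
    j_in = params.alpha0 + drug_factor_D2 * params.alpha1 * ke4 / (ke4 + ce ** 4)
    j_pm = params.V_pm * c * c / (params.K_pm ** 2 + c * c)
    return Fluxes(J_IPR=j_ipr, J_serca=j_serca, J_in=j_in, J_pm=j_pm)


def rhs(t: float, y, params: ModelParameters, D1: float = 1.0,
        D2: float = 1.0) -> np.ndarray:
    """Time derivatives ``(dc/dt, dce/dt, dh/dt, dp/dt)``.

    dc/dt  = J_IPR - J_serca + delta (J_in - J_pm)
    dce/dt = gamma (J_serca - J_IPR)
    dh/dt  = (h_inf(c) - h) / tau_h(c)
    dp/dt  = D1 nu - beta_p p,      nu = beta_p p_s

    The combination ``c + ce/gamma`` therefore changes only through the
    plasma-membrane terms ``delta (J_in - J_pm)``: ER release and reuptake
    conserve total cell Ca2+.
    """
    c, ce, h, p = y
    state = ModelState(max(c, 0.0), max(ce, 0.0), min(max(h, 0.0), 1.0), max(p, 0.0))
    fx = compute_fluxes(state, params, drug_factor_D2=D2)
    dc = fx.J_IPR - fx.J_serca + params.delta * (fx.J_in - fx.J_pm)
    dce = params.gamma * (fx.J_serca - fx.J_IPR)
    dh = (h_inf(state.c, params) - state.h) / tau_h(state.c, params)
    dp = D1 * params.beta_p * params.p_s - params.beta_p * state.p
    return np.array([dc, dce, dh, dp])
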