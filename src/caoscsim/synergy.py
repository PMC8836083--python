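"""Chou–Talalay median-effect analysis and combination index.

The median-effect model relates dose D to affected fraction fa through

    fa / (1 - fa) = (D / Dm)^m,

a straight line of slope m in log-odds vs log-dose coordinates, with Dm the
dose producing a half-maximal effect.  For a combination dose (D1, D2) with
observed effect fa, the (mutually exclusive, classic) combination index is

    CI = D1 / Dx1 + D2 / Dx2,      Dx_i = Dm_i (fa/(1-fa))^(1/m_i),

where Dx_i is the dose of drug i alone that would produce the same effect.
CI < 1 indicates synergy, CI = 1 additivity, CI > 1 antagonism.

For oscillation-period readouts, :func:`period_fraction_affected` maps the
period lengthening onto a fraction-affected scale,
fa = (T - T0)/(T_plateau - T0), with T0 the drug-free period and T_plateau
a configurable ceiling (default: 1.1x the largest observed period).  This
transform is a convention of this package; the effect scale used by the
original CompuSyn analyses is not published.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["DoseEffectCurve", "median_effect_fit", "dose_for_effect",
           "combination_index", "period_fraction_affected"]


@dataclass
class DoseEffectCurve:
    """Fitted median-effect line: Dm (µM), slope m, and the points used."""

    Dm: float
    m: float
    doses: np.ndarray
    fa: np.ndarray
    r_squared: float

    def effect_at(self, dose: float) -> float:
        """Predicted fa at a dose (inverse of the median-effect line)."""
        ratio = (dose / self.Dm) ** self.m
        return ratio / (1.0 + ratio)


def median_effect_fit(doses, fa) -> DoseEffectCurve:
    """Fit the median-effect line by least squares in log-log coordinates.

    Points with fa of exactly 0 or 1 carry infinite log-odds and are
    excluded with a warning; at least 3 usable points are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise ValueError("doses and fa must have the same shape")
    usable = (doses > 0) & (fa > 0.0) & (fa < 1.0)
    if (~usable).any():
        warnings.warn(f"excluding {int((~usable).sum())} point(s) with fa outside (0,1) "
                      "or non-positive dose", stacklevel=2)
    if usable.sum() < 3:
        raise ValueError("need at least 3 dose points with fa strictly in (0, 1)")
    x = np.log10(doses[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DoseEffectCurve(Dm=float(10.0 ** (-intercept / slope)), m=float(slope),
                           doses=doses[usable], fa=fa[usable], r_squared=r2)


def dose_for_effect(curve: DoseEffectCurve, fa: float) -> float:
    """Dose of the single agent producing fraction affected fa."""
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must lie strictly in (0, 1)")
    return curve.Dm * (fa / (1.0 - fa)) ** (1.0 / curve.m)


def combination_index(single1: DoseEffectCurve,
                      single2: DoseEffectCurve,
                      combo_doses,
                      combo_fa) -> np.ndarray:
    """Classic (mutually exclusive) Chou–Talalay CI per combination point.

    ``combo_doses`` is a sequence of (D1, D2) pairs and ``combo_fa`` the
    observed effect of each pair.  Points with fa outside (0, 1) are
    skipped with a warning and reported as NaN.
    """
    combo_doses = np.asarray(combo_doses, dtype=float).reshape(-1, 2)
    combo_fa = np.asarray(combo_fa, dtype=float)
    if len(combo_fa) != len(combo_doses):
        raise ValueError("combo_doses and combo_fa length mismatch")
    ci = np.full(len(combo_fa), np.nan)
    for i, ((d1, d2), fa) in enumerate(zip(combo_doses, combo_fa)):
        if not 0.0 < fa < 1.0:
            warnings.warn(f"combination point {i} has fa={fa} outside (0,1); skipped",
                          stacklevel=2)
            continue
        ci[i] = d1 / dose_for_effect(single1, fa) + d2 / dose_for_effect(single2, fa)
    return ci


def period_fraction_affected(periods, control_period: float,
                             plateau_period: float | None = None) -> np.ndarray:
    """Map period lengthening onto a fraction-affected scale in [0, 1).

    fa = (T - T0) / (T_plateau - T0).  By default T_plateau is 1.1x the
    largest period in the input, keeping every fa strictly below 1.
    """
    periods = np.asarray(periods, dtype=float)
    if plateau_period is None:
        plateau_period = 1.1 * float(np.nanmax(periods))
    if plateau_period <= control_period:
        raise ValueError("plateau period must exceed the control period")
    fa = (periods - control_period) / (plateau_period - control_period)
    return np.clip(fa, 0.0, 1.0)
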