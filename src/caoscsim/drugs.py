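"""Dose-to-channel-factor mapping for afatinib and RP4010.

Each drug effect is a saturating Michaelis–Menten function of dose,
``f_i(S) = c_i S / (k_i + S)``.  The factors applied to the model are

* ``D1 = 1 - f1(S1)`` — afatinib (S1) throttles IP3 production through the
  EGFR/PLC-gamma axis, lowering the steady-state IP3 level;
* ``D2 = 1 - f2(S2) + f3(S1)`` — RP4010 (S2) blocks the Orai1 channel and
  hence store-operated entry, while the ``f3`` term carries afatinib's
  crosstalk onto SOCE.

The sign of the ``f3`` term follows the fitted model's sensitivity table
(increasing ``c3`` shortens the oscillation period, increasing ``k3``
lengthens it), which together with the single-drug and combination
dose–period data pins the crosstalk term as entering D2 with a positive
sign.  D2 is clamped below at 0 (it scales a channel flux) but may exceed 1;
D1 stays in [0, 1] by construction.
"""

from __future__ import annotations

from .parameters import DrugDose, DrugParameters, ParameterError

__all__ = ["mm_effect", "drug_factors"]


def mm_effect(S: float, c_i: float, k_i: float) -> float:
    """Michaelis–Menten drug effect ``c_i S / (k_i + S)``.

    Zero at S = 0, strictly increasing, asymptote ``c_i``.
    """
    if k_i <= 0.0:
        raise ParameterError(f"half-effect dose must be > 0, got k_i={k_i}")
    if S < 0.0:
        raise ParameterError(f"dose must be non-negative, got S={S}")
    return c_i * S / (k_i + S)


def drug_factors(dose: DrugDose, dp: DrugParameters) -> tuple[float, float]:
    """Map a dose pair to the channel factors ``(D1, D2)``.

    D1 = 1 - f1(S1)               (IP3 production factor, in [0, 1])
    D2 = 1 - f2(S2) + f3(S1)      (SOCE factor, clamped to >= 0)
    """
    f1 = mm_effect(dose.S1, dp.c1, dp.k1)
    f2 = mm_effect(dose.S2, dp.c2, dp.k2)
    f3 = mm_effect(dose.S1, dp.c3, dp.k3)
    d1 = min(max(1.0 - f1, 0.0), 1.0)
    d2 = max(1.0 - f2 + f3, 0.0)
    return d1, d2
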