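"""Perceived Correctness Score (PCS): composite configuration scoring.

PCS condenses one subject-configuration simulation into a single
dimensionless score,

    PCS = w_neuro * u_pattern * ln(1 + E_focus)

with three multiplicative factors:

* ``E_focus = Emax / (Eavg + eps)`` - field focusing (how peaked the
  field-magnitude distribution is relative to its volume average);
* ``w_neuro = logistic((Vpeak - Vth) * k)`` - neural activation weight,
  0.5 exactly at threshold, saturating towards 1 for strong
  depolarisation (Vth = -55 mV, k = 0.05 / mV);
* ``u_pattern = 1 / (1 + C)`` - descriptor balance, where C is the
  coefficient of variation (population standard deviation over mean) of
  the absolute magnitudes of the three field descriptors
  {|Emax|, |Eavg|, |Eint|}.

All three factors are monotone, so a drop in any one lowers PCS; the
logarithm is natural (base changes only rescale scores monotonically and
leave every ranking unchanged).  C mixes descriptors of different units
by design - it is an internal balancing term computed on SI numeric
magnitudes, not a physical quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .cable import NeuralFeatures
from .field import FieldFeatures

EPSILON = 1e-9
DEFAULT_V_TH_MV = -55.0
DEFAULT_K_PER_MV = 0.05


@dataclass(frozen=True)
class PCSComponents:
    """The composite score with all intermediate factors, for audit."""

    e_focus: float
    w_neuro: float
    u_pattern: float
    spread: float
    pcs: float
    epsilon: float = EPSILON


def efocus(e_max: float, e_avg: float, epsilon: float = EPSILON) -> float:
    """Field-focusing ratio Emax / (Eavg + eps)."""
    if e_max < 0 or e_avg < 0:
        raise ValueError("field magnitudes must be non-negative")
    return e_max / (e_avg + epsilon)


def neuro_weight(
    v_peak_mv: float, v_th_mv: float = DEFAULT_V_TH_MV, k_per_mv: float = DEFAULT_K_PER_MV
) -> float:
    """Logistic activation weight, 0.5 at threshold, increasing in Vpeak."""
    if not math.isfinite(v_peak_mv):
        raise ValueError("v_peak must be finite")
    return 1.0 / (1.0 + math.exp(-(v_peak_mv - v_th_mv) * k_per_mv))


def spread_term(e_max: float, e_avg: float, e_int: float) -> float:
    """Coefficient of variation C of the three absolute descriptor magnitudes.

    Population (n = 3) standard deviation divided by the mean.  For an
    all-zero descriptor set C is defined as 0 (the caller's PCS is zero
    anyway since E_focus vanishes).
    """
    xs = (abs(e_max), abs(e_avg), abs(e_int))
    mu = sum(xs) / 3.0
    if mu == 0.0:
        return 0.0
    var = sum((x - mu) ** 2 for x in xs) / 3.0
    return math.sqrt(var) / mu


def upattern(spread: float) -> float:
    """Descriptor-balance factor 1 / (1 + C), in (0, 1]."""
    if spread < 0:
        raise ValueError("spread must be non-negative")
    return 1.0 / (1.0 + spread)


def compute_pcs(
    field: FieldFeatures,
    neural: NeuralFeatures,
    *,
    v_th_mv: float = DEFAULT_V_TH_MV,
    k_per_mv: float = DEFAULT_K_PER_MV,
    epsilon: float = EPSILON,
    descriptor_scales: Sequence[float] | None = None,
) -> PCSComponents:
    """Compose the PCS from field and neural features.

    ``descriptor_scales``, if given, divides (Emax, Eavg, Eint) by fixed
    reference scales before the balance term C - an optional
    pre-normalisation switch, off by default.
    """
    ef = efocus(field.e_max, field.e_avg, epsilon)
    w = neuro_weight(neural.v_peak_mv, v_th_mv, k_per_mv)
    if descriptor_scales is not None:
        sx, sa, si = descriptor_scales
        c = spread_term(field.e_max / sx, field.e_avg / sa, field.e_int / si)
    else:
        c = spread_term(field.e_max, field.e_avg, field.e_int)
    u = upattern(c)
    score = w * u * math.log1p(ef)
    return PCSComponents(e_focus=ef, w_neuro=w, u_pattern=u, spread=c, pcs=score, epsilon=epsilon)
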