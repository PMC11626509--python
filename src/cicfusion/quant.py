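"""Small quantitation formulas shared across the package's companion assays.

These are the normalization and summary conventions used when measuring
fusion-construct activity: ΔCt relative expression, two-anchor percent
normalization (negative control ↦ 0%, full-length fusion ↦ 100%), one-way
ANOVA with Šidák-adjusted pairwise comparisons, the (π/6)·l·w·h ellipsoid
tumor-volume estimate, and background-subtracted crystal-violet totals.

Replicate aggregation order matters for the effective n: technical
replicates are averaged within an experiment first, then experiment-level
means are aggregated (:func:`aggregate_replicates`).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats


class DegenerateInputError(ValueError):
    pass


def _require_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite input {v!r}")


def relative_expression(ct_target: float, ct_housekeeping: float) -> float:
    """Fold expression by the 2^(Ct_housekeeping − Ct_target) method."""
    _require_finite(ct_target, ct_housekeeping)
    return 2.0 ** (ct_housekeeping - ct_target)


def anchor_normalize(
    x: float | Sequence[float],
    ev_values: Sequence[float],
    cd4_values: Sequence[float],
) -> float | np.ndarray:
    """Rescale so the EV (negative control) mean maps to 0% and the
    full-length-fusion (CD4) mean maps to 100%."""
    ev_mean = float(np.mean(ev_values))
    cd4_mean = float(np.mean(cd4_values))
    _require_finite(ev_mean, cd4_mean)
    if cd4_mean == ev_mean:
        raise DegenerateInputError("anchor conditions have equal means")
    out = 100.0 * (np.asarray(x, dtype=float) - ev_mean) / (cd4_mean - ev_mean)
    return float(out) if np.ndim(x) == 0 else out


def sidak_adjust(p: float, m: int) -> float:
    """Šidák multiple-comparison adjustment: 1 − (1 − p)^m, clipped to [0, 1].

    ``m`` is the number of pairwise comparisons actually made.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if m == 1:
        return float(p)
    if p == 1.0:
        return 1.0
    # -expm1(m*log1p(-p)) == 1-(1-p)^m without underflow at tiny p
    return float(min(1.0, max(0.0, -math.expm1(m * math.log1p(-p)))))


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Requires at least two groups of at least two values each; zero
    within-group variance makes the F ratio undefined and raises.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite value in group")
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    if ss_within == 0.0:
        raise DegenerateInputError(
            "zero within-group variance: F statistic undefined"
        )
    f_stat, p_value = stats.f_oneway(*arrays)
    return float(f_stat), float(p_value)


def aggregate_replicates(experiments: Sequence[Sequence[float]]) -> list[float]:
    """Average technical replicates within each experiment; the returned
    per-experiment means are the units for any downstream test."""
    out = []
    for exp in experiments:
        arr = np.asarray(exp, dtype=float)
        if arr.size == 0:
            raise ValueError("empty replicate set")
        out.append(float(arr.mean()))
    return out


def tumor_volume(length: float, width: float, height: float) -> float:
    """Ellipsoid approximation: (π/6) · length · width · height."""
    for name, v in (("length", length), ("width", width), ("height", height)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    return (math.pi / 6.0) * length * width * height


def crystal_violet_total(
    mean_signal: float, area: float, background_mean: float
) -> float:
    """Background-subtracted total stain intensity:
    mean signal × area − background mean × area."""
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    return mean_signal * area - background_mean * area
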