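"""Cell and polymer morphometrics: aspect ratios and the Mann-Whitney test.

Aspect ratio is the longer over the shorter cell axis (>= 1 by construction;
1 for a sphere).  It can come from direct length/width measurements or from
a binary mask, where it is the major/minor axis ratio of the ellipse with
the same second central moments.  Two-condition comparisons use the
Mann-Whitney U rank test: exact two-sided p by full enumeration of all
C(n+m, n) labelings when n + m <= 16 and the pooled values are tie-free,
otherwise the normal approximation with continuity correction and
tie-corrected variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ConfigurationError, TieFallbackWarning

EXACT_LIMIT = 16  # n + m above which enumeration (C(16,8) = 12,870) is skipped


@dataclass(frozen=True)
class CellShape:
    """Either direct (length, width) measurements or a binary pixel mask."""

    length_um: float | None = None
    width_um: float | None = None
    mask: np.ndarray | None = None
    pixel_size_um: float = 1.0

    def __post_init__(self):
        direct = self.length_um is not None and self.width_um is not None
        if direct == (self.mask is not None):
            raise ConfigurationError("give either length/width or a mask, not both/neither")
        if direct and (self.length_um <= 0 or self.width_um <= 0):
            raise ConfigurationError("axes must be positive")


def aspect_ratio(shape: CellShape) -> float:
    """Longer-axis / shorter-axis ratio of one cell; always >= 1.

    Direct measurements are canonicalized max/min, so a swapped length/width
    pair cannot yield a ratio below 1.  For a mask the ratio comes from the
    second-central-moment-equivalent ellipse (pixel size cancels).
    """
    if shape.mask is not None:
        from skimage.measure import regionprops

        mask = np.asarray(shape.mask) > 0
        if mask.sum() < 10:
            raise ConfigurationError(
                f"mask has {int(mask.sum())} foreground pixels; need at least 10"
            )
        props = regionprops(mask.astype(np.uint8))[0]
        minor = props.axis_minor_length
        if minor == 0:
            raise ConfigurationError("mask is degenerate (zero minor axis)")
        return max(props.axis_major_length / minor, 1.0)
    hi = max(shape.length_um, shape.width_um)
    lo = min(shape.length_um, shape.width_um)
    return hi / lo


class SampleSummary(NamedTuple):
    n: int
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


def sample_summary(x) -> SampleSummary:
    """Order statistics (linear-interpolation quartiles) of one sample."""
    v = np.asarray(x, float)
    if v.size == 0:
        raise ConfigurationError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return SampleSummary(int(v.size), float(med), float(q1), float(q3), float(v.min()), float(v.max()))


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float  # U for the first sample; U + U_swapped = n * m
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    tie_corrected: bool
    degenerate: bool = False


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u_a), pooled


def _exact_p(pooled_sorted_ranks: np.ndarray, n: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating every n-subset of the pooled ranks."""
    N = pooled_sorted_ranks.size
    base = n * (n + 1) / 2.0
    us = np.array(
        [sum(pooled_sorted_ranks[list(c)]) - base for c in combinations(range(N), n)]
    )
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney(a, b) -> RankTestResult:
    """Two-sided Mann-Whitney U test between two samples.

    The statistic is computed from rank sums with midranks for ties.  For
    n + m <= 16 with no ties the two-sided p is exact (min(1, 2 x one-sided)
    over the full enumeration); otherwise the normal approximation with
    continuity correction and tie-corrected variance is used.  Exact
    enumeration refuses tied data and falls back to the approximation with a
    warning.  Identical samples are flagged degenerate with p = 1.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both samples must be non-empty")
    n, m = a.size, b.size
    u_a, pooled = _u_statistic(a, b)
    if np.ptp(pooled) == 0:
        return RankTestResult(u_a, 1.0, "normal_approx", False, degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= EXACT_LIMIT:
        if not has_ties:
            ranks = rankdata(pooled)
            p = _exact_p(np.sort(ranks), n, u_a)
            return RankTestResult(u_a, p, "exact", False)
        warnings.warn(
            "tied values: exact enumeration skipped, using the normal approximation",
            TieFallbackWarning,
            stacklevel=2,
        )
    N = n + m
    mu = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return RankTestResult(u_a, 1.0, "normal_approx", has_ties, degenerate=True)
    z = (abs(u_a - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return RankTestResult(u_a, p, "normal_approx", has_ties)
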