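"""Descriptive statistics for polyp-leaf-count distributions.

Leaf-count samples from different survey methods (trawl catch vs ROV video)
are compared through four moments with small-sample bias corrections:

* bias-corrected standard deviation  sigma  (the 1/(M-1) form),
* uncorrected standard deviation     sigma' (the 1/M form),
* bias-corrected skewness  G1 = sqrt(M(M-1))/(M-2) * m3 / sigma'^3,
* bias-corrected, non-excess kurtosis
  k = (M-1)/((M-2)(M-3)) * [ (M+1) * m4/sigma'^4 - 3(M-1) ] + 3,

with m3, m4 the central sample moments. A normal sample has k ≈ 3 under
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import EmptyInputError, ValidationError
from .records import ColonyRecord
from . import biometry

__all__ = [
    "MomentSummary",
    "DispersionRow",
    "DistributionComparison",
    "moment_summary",
    "dispersion_by_count",
    "compare_distributions",
    "relative_difference",
]


@dataclass(frozen=True)
class MomentSummary:
    """Sample size plus the four (bias-corrected) moments of a count sample.

    ``skewness`` and ``kurtosis`` are None when the sample is too small
    (m < 4) or degenerate (zero spread), never infinities.
    """

    m: int
    mean: float
    sd_corrected: Optional[float]    # sigma, 1/(M-1)
    sd_uncorrected: Optional[float]  # sigma', 1/M
    skewness: Optional[float]
    kurtosis: Optional[float]        # non-excess


def moment_summary(counts: Sequence[float]) -> MomentSummary:
    """Compute the four-moment summary of a leaf-count sample."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise EmptyInputError("moment_summary needs a non-empty 1-D sample")
    m = int(x.size)
    mean = float(np.mean(x))
    if m < 2:
        return MomentSummary(m, mean, None, None, None, None)
    dev = x - mean
    ssq = float(np.sum(dev ** 2))
    sd_uncorrected = float(np.sqrt(ssq / m))
    sd_corrected = float(np.sqrt(ssq / (m - 1)))
    if m < 4 or sd_uncorrected == 0.0:
        return MomentSummary(m, mean, sd_corrected, sd_uncorrected, None, None)
    m3 = float(np.mean(dev ** 3))
    m4 = float(np.mean(dev ** 4))
    skewness = (
        np.sqrt(m * (m - 1)) / (m - 2) * m3 / sd_uncorrected ** 3
    )
    kurtosis = (
        (m - 1) / ((m - 2) * (m - 3))
        * ((m + 1) * m4 / sd_uncorrected ** 4 - 3 * (m - 1))
        + 3.0
    )
    return MomentSummary(
        m, mean, sd_corrected, sd_uncorrected, float(skewness), float(kurtosis)
    )


@dataclass(frozen=True)
class DispersionRow:
    """Rachis-length spread among colonies sharing one max-side leaf count."""

    leaf_count: int
    m: int
    mean_rachis: float                 # mm
    sd_rachis: Optional[float]         # mm, bias-corrected; None when m == 1


def dispersion_by_count(
    colonies: Sequence[ColonyRecord], min_count: int = 15
) -> List[DispersionRow]:
    """Group rachis lengths by max-side leaf count and summarise each group.

    Counts below ``min_count`` are excluded — single small colonies give no
    usable length variation. Rows are sorted by ascending count.
    """
    if min_count < 0:
        raise ValidationError("min_count must be >= 0")
    groups: Dict[int, List[float]] = {}
    for colony in colonies:
        n = biometry.leaf_count_for_size(colony)
        if n >= min_count:
            groups.setdefault(n, []).append(biometry.rachis_length(colony))
    rows = []
    for n in sorted(groups):
        values = np.asarray(groups[n])
        sd = float(np.std(values, ddof=1)) if values.size > 1 else None
        rows.append(
            DispersionRow(
                leaf_count=n,
                m=int(values.size),
                mean_rachis=float(np.mean(values)),
                sd_rachis=sd,
            )
        )
    return rows


@dataclass(frozen=True)
class DistributionComparison:
    """Two leaf-count samples compared by moments and shared-bin histograms.

    Sample ``b`` is the reference for the relative differences (in this
    package's pipeline: the ROV set). A zero reference moment leaves the
    corresponding difference as None.
    """

    summary_a: MomentSummary
    summary_b: MomentSummary
    relative_mean_diff: Optional[float]
    relative_skewness_diff: Optional[float]
    histogram_a: Dict[int, int]
    histogram_b: Dict[int, int]


def relative_difference(value: float, reference: float) -> Optional[float]:
    """|value - reference| / |reference|, or None for a zero reference."""
    if reference == 0:
        return None
    return abs(value - reference) / abs(reference)


def _integer_histogram(x: np.ndarray, lo: int, hi: int) -> Dict[int, int]:
    values, counts = np.unique(np.rint(x).astype(int), return_counts=True)
    hist = {int(k): 0 for k in range(lo, hi + 1)}
    for v, c in zip(values, counts):
        hist[int(v)] = int(c)
    return hist


def compare_distributions(
    a: Sequence[float], b: Sequence[float]
) -> DistributionComparison:
    """Compare two leaf-count samples; ``b`` is the reference set."""
    summary_a = moment_summary(a)
    summary_b = moment_summary(b)
    rel_mean = relative_difference(summary_a.mean, summary_b.mean)
    if summary_a.skewness is None or summary_b.skewness is None:
        rel_skew = None
    else:
        rel_skew = relative_difference(summary_a.skewness, summary_b.skewness)
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    lo = int(np.rint(min(xa.min(), xb.min())))
    hi = int(np.rint(max(xa.max(), xb.max())))
    return DistributionComparison(
        summary_a=summary_a,
        summary_b=summary_b,
        relative_mean_diff=rel_mean,
        relative_skewness_diff=rel_skew,
        histogram_a=_integer_histogram(xa, lo, hi),
        histogram_b=_integer_histogram(xb, lo, hi),
    )
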