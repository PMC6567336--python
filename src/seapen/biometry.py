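"""Size and weight models for sea pen colonies.

The polyp-leaf count ``n`` is the only size proxy measurable from imagery,
so every model here predicts a physical quantity from it (or from another
predicted quantity):

* rachis length  ``lr_hat(n) = slope*n + intercept``   (linear, max-side count)
* total length   ``lt_hat(n) = slope*n + intercept``   (linear, max-side count)
* fresh weight   ``wf_hat(n) = c3*n^3 + c2*n^2 + c1*n + c0``  (cubic,
  mean-side count; not applicable below a validity threshold of 15 leaves)
* fresh weight, refined  ``w2f_hat(n, lr)``  (cubic in n plus a linear
  rachis-length term)
* dry weight     ``wd_hat(wf)``  (cubic in fresh weight)

Fits are ordinary least squares; goodness of fit is reported both as the
fitting residual and as the field's root-mean-square *relative* error

    e = sqrt( (1/M) * sum_i ((pred_i - obs_i) / obs_i)^2 ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import EmptyInputError, RankDeficiencyError, ValidationError
from .records import ColonyRecord

logger = logging.getLogger(__name__)

DEFAULT_VALIDITY_MIN_N = 15


# ---------------------------------------------------------------------------
# per-record helpers

def rachis_length(record: ColonyRecord) -> float:
    """Rachis length in mm: total minus peduncle (positive by invariant)."""
    return record.total_length - record.peduncle_length


def leaf_count_for_size(record: ColonyRecord) -> int:
    """Max-side leaf count — the predictor for the length models."""
    return max(record.leaves_left, record.leaves_right)


def leaf_count_for_weight(record: ColonyRecord) -> float:
    """Mean-side leaf count (may be half-integral) — predictor for weight."""
    return (record.leaves_left + record.leaves_right) / 2.0


# ---------------------------------------------------------------------------
# error metric

def rms_relative_error(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root-mean-square relative error of predictions against observations."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValidationError("predicted and observed must be equal-length 1-D")
    if pred.size == 0:
        raise EmptyInputError("rms_relative_error needs at least one pair")
    if (obs == 0).any():
        raise ValidationError(
            "observed values must be nonzero for a relative error"
        )
    return float(np.sqrt(np.mean(((pred - obs) / obs) ** 2)))


# ---------------------------------------------------------------------------
# fitted-model containers

@dataclass(frozen=True)
class LinearSizeModel:
    """A length (mm) as a line in the max-side leaf count."""

    slope: float                 # mm per leaf
    intercept: float             # mm
    rms_relative_error: float    # fraction
    correlation: float           # Pearson r of the fitted pairs
    n_fit: int
    slope_stderr: float          # OLS standard error of the slope

    def slope_confidence_interval(self, level: float = 0.95) -> Tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        t = stats.t.ppf(0.5 + level / 2.0, self.n_fit - 2)
        return (self.slope - t * self.slope_stderr, self.slope + t * self.slope_stderr)


@dataclass(frozen=True)
class CubicWeightModel:
    """Fresh weight (g) as a cubic in the mean-side leaf count.

    The model is not trusted below ``validity_min_n`` leaves (exclusive):
    too few small colonies support it, and prediction returns
    "not applicable" there rather than a number.
    """

    c3: float
    c2: float
    c1: float
    c0: float
    rms_relative_error: float
    validity_min_n: float = DEFAULT_VALIDITY_MIN_N
    n_fit: int = 0

    @property
    def coefficients(self) -> Tuple[float, float, float, float]:
        return (self.c3, self.c2, self.c1, self.c0)


@dataclass(frozen=True)
class SurfaceWeightModel:
    """Fresh weight (g) as a cubic in leaf count plus a rachis-length term."""

    a3: float
    a2: float
    a1: float
    b1: float                    # g per mm of rachis
    a0: float
    rms_relative_error: float
    n_fit: int = 0


@dataclass(frozen=True)
class DryWeightModel:
    """Dry weight (g) as a cubic in measured fresh weight (g)."""

    d3: float
    d2: float
    d1: float
    d0: float
    rms_relative_error: float
    n_fit: int = 0

    @property
    def coefficients(self) -> Tuple[float, float, float, float]:
        return (self.d3, self.d2, self.d1, self.d0)


# ---------------------------------------------------------------------------
# fitting

def _check_pairs(pairs: Sequence[Tuple[float, float]], min_pairs: int,
                 min_distinct: int, what: str) -> Tuple[np.ndarray, np.ndarray]:
    if len(pairs) < min_pairs:
        raise ValidationError(f"{what} needs at least {min_pairs} pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(x).size < min_distinct:
        raise RankDeficiencyError(
            f"{what} needs at least {min_distinct} distinct predictor values"
        )
    return x, y


def fit_linear_size(pairs: Sequence[Tuple[float, float]]) -> LinearSizeModel:
    """Ordinary least-squares line through (leaf count, length mm) pairs."""
    x, y = _check_pairs(pairs, 3, 2, "fit_linear_size")
    result = stats.linregress(x, y)
    predicted = result.slope * x + result.intercept
    return LinearSizeModel(
        slope=float(result.slope),
        intercept=float(result.intercept),
        rms_relative_error=rms_relative_error(predicted, y),
        correlation=float(result.rvalue),
        n_fit=int(x.size),
        slope_stderr=float(result.stderr),
    )


def predict_length(model: LinearSizeModel, n: float) -> float:
    """Evaluate a length model at a leaf count; warns on extrapolated negatives."""
    if n < 0:
        raise ValidationError("leaf count must be >= 0")
    value = model.slope * n + model.intercept
    if value < 0:
        logger.warning(
            "length model extrapolates to %.2f mm at n=%s; returning it as-is",
            value, n,
        )
    return value


def _polyfit_cubic(x: np.ndarray, y: np.ndarray, what: str) -> np.ndarray:
    design = np.vander(x, 4)
    if np.linalg.matrix_rank(design) < 4:
        raise RankDeficiencyError(f"{what}: cubic design matrix is rank deficient")
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coefs


def fit_cubic_weight(
    pairs: Sequence[Tuple[float, float]],
    validity_min_n: float = DEFAULT_VALIDITY_MIN_N,
) -> CubicWeightModel:
    """Least-squares cubic through (mean-side leaf count, fresh weight g) pairs.

    The stored relative error is computed only over pairs above the validity
    threshold, mirroring how the model is used downstream.
    """
    x, y = _check_pairs(pairs, 5, 4, "fit_cubic_weight")
    c3, c2, c1, c0 = _polyfit_cubic(x, y, "fit_cubic_weight")
    valid = x > validity_min_n
    if valid.any():
        predicted = np.polyval([c3, c2, c1, c0], x[valid])
        error = rms_relative_error(predicted, y[valid])
    else:
        logger.warning(
            "no pairs above the validity threshold n>%s; relative error is NaN",
            validity_min_n,
        )
        error = float("nan")
    return CubicWeightModel(
        c3=float(c3), c2=float(c2), c1=float(c1), c0=float(c0),
        rms_relative_error=error,
        validity_min_n=validity_min_n,
        n_fit=int(x.size),
    )


def predict_fresh_weight(model: CubicWeightModel, n: float) -> Optional[float]:
    """Fresh weight at a leaf count, or None below the validity threshold.

    A negative cubic value (bad extrapolation) is clamped to 0 with a warning
    so downstream biomass sums stay non-negative.
    """
    if n < 0:
        raise ValidationError("leaf count must be >= 0")
    if n <= model.validity_min_n:
        return None
    value = float(np.polyval(model.coefficients, n))
    if value < 0:
        logger.warning(
            "fresh-weight cubic negative (%.3f g) at n=%s; clamped to 0", value, n
        )
        return 0.0
    return value


def fit_weight_surface(
    triples: Sequence[Tuple[float, float, float]]
) -> SurfaceWeightModel:
    """Least squares in the basis {n^3, n^2, n, lr, 1} for fresh weight.

    ``triples`` are (mean-side leaf count, rachis length mm, fresh weight g).
    """
    if len(triples) < 6:
        raise ValidationError("fit_weight_surface needs at least 6 triples")
    n = np.array([t[0] for t in triples], dtype=float)
    lr = np.array([t[1] for t in triples], dtype=float)
    w = np.array([t[2] for t in triples], dtype=float)
    design = np.column_stack([n ** 3, n ** 2, n, lr, np.ones_like(n)])
    if np.linalg.matrix_rank(design) < 5:
        raise RankDeficiencyError(
            "fit_weight_surface: design {n^3, n^2, n, lr, 1} is rank deficient "
            "(rachis length may be collinear with leaf count)"
        )
    coefs, *_ = np.linalg.lstsq(design, w, rcond=None)
    predicted = design @ coefs
    return SurfaceWeightModel(
        a3=float(coefs[0]), a2=float(coefs[1]), a1=float(coefs[2]),
        b1=float(coefs[3]), a0=float(coefs[4]),
        rms_relative_error=rms_relative_error(predicted, w),
        n_fit=int(n.size),
    )


def predict_surface_weight(model: SurfaceWeightModel, n: float, lr: float) -> float:
    """Evaluate the leaf-count + rachis-length weight surface (g)."""
    return (
        model.a3 * n ** 3 + model.a2 * n ** 2 + model.a1 * n
        + model.b1 * lr + model.a0
    )


def fit_dry_weight(pairs: Sequence[Tuple[float, float]]) -> DryWeightModel:
    """Least-squares cubic of dry weight on fresh weight, both in g."""
    x, y = _check_pairs(pairs, 5, 4, "fit_dry_weight")
    d3, d2, d1, d0 = _polyfit_cubic(x, y, "fit_dry_weight")
    predicted = np.polyval([d3, d2, d1, d0], x)
    return DryWeightModel(
        d3=float(d3), d2=float(d2), d1=float(d1), d0=float(d0),
        rms_relative_error=rms_relative_error(predicted, y),
        n_fit=int(x.size),
    )


def predict_dry_weight(model: DryWeightModel, fresh_weight: float) -> float:
    """Evaluate the dry-from-fresh cubic (g)."""
    return float(np.polyval(model.coefficients, fresh_weight))
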