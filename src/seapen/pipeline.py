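"""End-to-end non-invasive biomass estimation.

The procedure mirrors how a sea pen field is actually assessed: a trawl
sample of physically measured colonies calibrates the biometric models;
ROV video of the same population yields per-colony leaf counts; the fitted
fresh-weight cubic converts each visible count into a predicted weight
(zero for small colonies where the model is not applicable); and the mean
predicted weight, scaled by colony density delta and survey area S, gives
the population total

    w_tot = w_mean * delta * S.

The trawl sample's measured mean weight then validates the imaging-based
prediction; size-selective trawl nets undersample small colonies, which
biases the measured mean upward and the relative error negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import biometry, io, popstats
from .biometry import CubicWeightModel
from .config import RunConfig
from .errors import EmptyInputError, SeapenError, ValidationError
from .records import ColonyRecord, RovObservation
from .synthetic import apply_trawl_selectivity, generate_colonies, simulate_rov_counts

logger = logging.getLogger(__name__)

__all__ = [
    "BiomassEstimate",
    "ValidationResult",
    "predict_colony_weights",
    "mean_predicted_weight",
    "total_biomass",
    "relative_error",
    "validate_against_trawl",
    "run_pipeline",
]


@dataclass(frozen=True)
class BiomassEstimate:
    """Population biomass inferred from ROV counts alone."""

    m_observed: int
    mean_predicted_weight: float   # g, small colonies counted as 0
    density: float                 # colonies / m^2
    area: float                    # m^2
    total_weight: float            # g = mean * density * area
    n_not_applicable: int          # colonies zeroed by the validity rule


@dataclass(frozen=True)
class ValidationResult:
    """Imaging-predicted mean weight against the trawl-measured mean."""

    predicted_mean: float          # g
    measured_mean: float           # g
    relative_error: float          # signed fraction


def predict_colony_weights(
    observations: Sequence[RovObservation], model: CubicWeightModel
) -> List[float]:
    """Predicted fresh weight (g) per observed colony.

    Colonies at or below the model's validity threshold get exactly 0 — the
    model is not applicable there and small colonies contribute negligible
    biomass. Negative cubic values are clamped to 0.
    """
    weights = []
    for obs in observations:
        value = biometry.predict_fresh_weight(model, obs.leaf_count)
        weights.append(0.0 if value is None else value)
    return weights


def mean_predicted_weight(weights: Sequence[float]) -> float:
    """Arithmetic mean predicted weight, zeroed small colonies included."""
    if len(weights) == 0:
        raise EmptyInputError("mean_predicted_weight needs at least one colony")
    return float(np.mean(weights))


def total_biomass(mean_weight: float, density: float, area: float) -> float:
    """Total population weight (g): mean colony weight x density x area."""
    if mean_weight < 0 or density < 0 or area < 0:
        raise ValidationError("mean_weight, density and area must all be >= 0")
    return mean_weight * density * area


def relative_error(predicted: float, measured: float) -> float:
    """Signed relative prediction error (predicted - measured) / measured."""
    if measured == 0:
        raise ValidationError("measured value must be nonzero")
    return (predicted - measured) / measured


def validate_against_trawl(
    predicted_mean: float, trawl_colonies: Sequence[ColonyRecord]
) -> ValidationResult:
    """Compare the ROV-predicted mean weight with the trawl-measured mean."""
    if len(trawl_colonies) == 0:
        raise EmptyInputError("validation needs a non-empty trawl sample")
    measured = float(np.mean([c.fresh_weight for c in trawl_colonies]))
    return ValidationResult(
        predicted_mean=predicted_mean,
        measured_mean=measured,
        relative_error=relative_error(predicted_mean, measured),
    )


# ---------------------------------------------------------------------------
# orchestration

def _subsample(items: list, size: int, rng: np.random.Generator) -> list:
    if len(items) <= size:
        return list(items)
    idx = np.sort(rng.choice(len(items), size=size, replace=False))
    return [items[i] for i in idx]


DRY_WEIGHT_RESOLUTION_G = 0.01   # electronic-balance resolution
DRY_SUBSET_MIN_FRESH_G = 1.0     # only colonies heavy enough that the balance's
                                 # 0.04 g worst-case uncertainty stays ~10% of
                                 # the dry weight enter the calibration subset


def _dry_subset(colonies: Sequence[ColonyRecord], size: int) -> List[ColonyRecord]:
    """Colonies spread across the fresh-weight range, mimicking how a dry-weight
    subset is chosen in the laboratory (deterministic: evenly spaced order
    statistics of fresh weight). Colonies whose weights sit near the balance
    resolution are excluded — their relative errors are dominated by
    measurement, not biology."""
    with_dry = [
        c for c in colonies
        if c.dry_weight is not None
        and c.dry_weight >= DRY_WEIGHT_RESOLUTION_G
        and c.fresh_weight >= DRY_SUBSET_MIN_FRESH_G
    ]
    if len(with_dry) <= size:
        return with_dry
    ordered = sorted(with_dry, key=lambda c: (c.fresh_weight, c.colony_id))
    idx = np.linspace(0, len(ordered) - 1, size).round().astype(int)
    return [ordered[i] for i in sorted(set(int(i) for i in idx))]


def _summary_dict(s: popstats.MomentSummary) -> dict:
    return {
        "m": s.m,
        "mean": s.mean,
        "sd_corrected": s.sd_corrected,
        "sd_uncorrected": s.sd_uncorrected,
        "skewness": s.skewness,
        "kurtosis": s.kurtosis,
    }


def _fit_models(trawl: Sequence[ColonyRecord], config: RunConfig) -> dict:
    n_size = [biometry.leaf_count_for_size(c) for c in trawl]
    n_weight = [biometry.leaf_count_for_weight(c) for c in trawl]
    rachis = [biometry.rachis_length(c) for c in trawl]
    total = [c.total_length for c in trawl]
    fresh = [c.fresh_weight for c in trawl]

    rachis_model = biometry.fit_linear_size(list(zip(n_size, rachis)))
    total_model = biometry.fit_linear_size(list(zip(n_size, total)))
    cubic = biometry.fit_cubic_weight(
        list(zip(n_weight, fresh)), validity_min_n=config.validity_min_n
    )
    surface = biometry.fit_weight_surface(list(zip(n_weight, rachis, fresh)))

    dry_subset = _dry_subset(trawl, config.dry_subset_size)
    dry_model = None
    if len(dry_subset) >= 5:
        dry_model = biometry.fit_dry_weight(
            [(c.fresh_weight, c.dry_weight) for c in dry_subset]
        )
    return {
        "rachis": rachis_model,
        "total": total_model,
        "fresh_cubic": cubic,
        "fresh_surface": surface,
        "dry": dry_model,
        "dry_subset_size": len(dry_subset),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full assessment and return the JSON-ready report dict.

    With no input tables configured, a synthetic population is generated,
    trawled (optionally through the selectivity filter) and ROV-observed.
    With a measured colony table the models are fitted to it instead; the
    biomass and validation stages run only when ROV counts are available.
    The report is deterministic given the seed (see
    :func:`seapen.io.write_report` for byte-identical serialisation).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    report: Dict[str, object] = {"seed": config.seed}

    # --- inputs -----------------------------------------------------------
    try:
        if config.colony_table is not None:
            trawl = io.read_colony_table(config.colony_table)
            rov_obs = (
                io.read_rov_table(config.rov_table)
                if config.rov_table is not None
                else None
            )
            report["source"] = "measured"
        else:
            population = generate_colonies(
                config.generator, config.population_size, rng
            )
            catch = (
                apply_trawl_selectivity(population, config.generator, rng)
                if config.apply_selectivity
                else population
            )
            if len(catch) < 5:
                raise EmptyInputError(
                    "trawl selectivity retained too few colonies to fit models"
                )
            trawl = _subsample(catch, config.trawl_sample_size, rng)
            rov_colonies = _subsample(population, config.rov_sample_size, rng)
            rov_obs = simulate_rov_counts(rov_colonies, config.generator, rng)
            report["source"] = "synthetic"
    except SeapenError as exc:
        raise type(exc)(f"[inputs] {exc}") from exc

    # --- biometric models -------------------------------------------------
    try:
        models = _fit_models(trawl, config)
    except SeapenError as exc:
        raise type(exc)(f"[model-fitting] {exc}") from exc
    rm, tm = models["rachis"], models["total"]
    cm, sm, dm = models["fresh_cubic"], models["fresh_surface"], models["dry"]
    report["models"] = {
        "rachis_length": {
            "slope_mm_per_leaf": rm.slope, "intercept_mm": rm.intercept,
            "rms_relative_error": rm.rms_relative_error,
            "correlation": rm.correlation, "n_fit": rm.n_fit,
        },
        "total_length": {
            "slope_mm_per_leaf": tm.slope, "intercept_mm": tm.intercept,
            "rms_relative_error": tm.rms_relative_error,
            "correlation": tm.correlation, "n_fit": tm.n_fit,
        },
        "fresh_weight_cubic": {
            "coefficients_g": list(cm.coefficients),
            "rms_relative_error": cm.rms_relative_error,
            "validity_min_n": cm.validity_min_n, "n_fit": cm.n_fit,
        },
        "fresh_weight_surface": {
            "coefficients": [sm.a3, sm.a2, sm.a1, sm.b1, sm.a0],
            "rms_relative_error": sm.rms_relative_error, "n_fit": sm.n_fit,
        },
        "dry_weight": None if dm is None else {
            "coefficients": list(dm.coefficients),
            "rms_relative_error": dm.rms_relative_error, "n_fit": dm.n_fit,
        },
    }

    # --- population statistics -------------------------------------------
    try:
        trawl_counts = [biometry.leaf_count_for_size(c) for c in trawl]
        report["moments"] = {"trawl": _summary_dict(popstats.moment_summary(trawl_counts))}
        rows = popstats.dispersion_by_count(trawl, min_count=int(config.validity_min_n))
        report["dispersion"] = [
            {
                "leaf_count": r.leaf_count, "m": r.m,
                "mean_rachis_mm": r.mean_rachis, "sd_rachis_mm": r.sd_rachis,
            }
            for r in rows
        ]
        if rov_obs is not None:
            rov_counts = [o.leaf_count for o in rov_obs]
            comparison = popstats.compare_distributions(trawl_counts, rov_counts)
            report["moments"]["rov"] = _summary_dict(comparison.summary_b)
            report["comparison"] = {
                "reference": "rov",
                "relative_mean_diff": comparison.relative_mean_diff,
                "relative_skewness_diff": comparison.relative_skewness_diff,
                "histogram_trawl": {
                    str(k): v for k, v in comparison.histogram_a.items()
                },
                "histogram_rov": {
                    str(k): v for k, v in comparison.histogram_b.items()
                },
            }
    except SeapenError as exc:
        raise type(exc)(f"[population-statistics] {exc}") from exc

    # --- biomass & validation --------------------------------------------
    if rov_obs is not None:
        try:
            weights = predict_colony_weights(rov_obs, cm)
            w_mean = mean_predicted_weight(weights)
            density = (
                config.density
                if config.density is not None
                else len(trawl) / config.area
            )
            estimate = BiomassEstimate(
                m_observed=len(rov_obs),
                mean_predicted_weight=w_mean,
                density=density,
                area=config.area,
                total_weight=total_biomass(w_mean, density, config.area),
                n_not_applicable=sum(1 for w_, o in zip(weights, rov_obs)
                                     if o.leaf_count <= cm.validity_min_n),
            )
            validation = validate_against_trawl(w_mean, trawl)
            report["biomass"] = {
                "m_observed": estimate.m_observed,
                "mean_predicted_weight_g": estimate.mean_predicted_weight,
                "density_per_m2": estimate.density,
                "density_source": "config" if config.density is not None
                                  else "trawl_count_over_area",
                "area_m2": estimate.area,
                "total_weight_g": estimate.total_weight,
                "n_not_applicable": estimate.n_not_applicable,
                "fraction_not_applicable": estimate.n_not_applicable
                                           / estimate.m_observed,
            }
            report["validation"] = {
                "predicted_mean_g": validation.predicted_mean,
                "measured_mean_g": validation.measured_mean,
                "relative_error": validation.relative_error,
            }
        except SeapenError as exc:
            raise type(exc)(f"[biomass] {exc}") from exc

    if config.report_path is not None:
        io.write_report(report, config.report_path)
    return report
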