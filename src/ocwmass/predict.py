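"""Body-mass prediction for new or fossil OCW observations.

Point estimates are produced by evaluating a fitted (or published reference)
ln-scale model at the transformed predictor, exponentiating, and multiplying
by the mean detransformation correction factor. 95% intervals come from the
standard OLS prediction-variance formula on the ln scale, back-transformed;
they use the t-distribution with the model's residual degrees of freedom and
the correction factor is applied to the bounds the same way as to the point
estimate. Published equations carry no residual covariance, so they yield
point estimates only.

Extrapolation beyond the training predictor range is permitted but always
flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .accuracy import CorrectionFactors
from .allometry import FittedModel
from .io import Morphotype

__all__ = [
    "PredictionResult",
    "ReferenceEquation",
    "REFERENCE_EQUATIONS",
    "predict_mass",
    "batch_predict",
    "results_to_frame",
]


@dataclass(frozen=True)
class ReferenceEquation:
    """A published log-power mass equation ln(mass) = a * ln(OCW)^b + c (+ dummies).

    ``covariate_coefficients`` holds additive intercept shifts on the ln scale
    keyed by dummy name (e.g. ``rabbit_like``). ``ocw_range`` is the span of
    the data behind the equation, used only for the extrapolation flag.
    """

    name: str
    slope: float
    intercept: float
    exponent: float = 2 / 3
    cf: float = 1.0
    n: int | None = None
    covariate_coefficients: Mapping[str, float] = field(default_factory=dict)
    ocw_range: tuple[float, float] = (4.0, 250.0)


#: Published mammalian OCW-to-body-mass regressions (species-average fits;
#: coefficients on the ln-gram scale, OCW in mm) with their averaged
#: correction factors: the all-species 2/3-power equation, the all-species
#: equation with condyle-shape (occiput morphotype) dummies, and the
#: Carnivora-only equation.
REFERENCE_EQUATIONS: dict[str, ReferenceEquation] = {
    "all_species": ReferenceEquation(
        name="all_species", slope=7.69289, intercept=-8.19502, cf=1.047, n=404,
    ),
    "condyle_shape": ReferenceEquation(
        name="condyle_shape", slope=7.75844, intercept=-8.35284, cf=1.025, n=404,
        covariate_coefficients={"rabbit_like": 0.71517, "monotreme_like": -1.14562},
    ),
    "carnivora": ReferenceEquation(
        name="carnivora", slope=8.5852, intercept=-10.2696, cf=1.031, n=81,
    ),
}


@dataclass
class PredictionResult:
    ocw: float  # mm
    model: str
    flags: dict[str, float]
    ln_point: float  # ln-gram scale, before correction
    mass_uncorrected: float  # g
    mass: float  # g, correction factor applied
    interval: tuple[float, float] | None  # g, 95% prediction interval
    extrapolated: bool
    label: str = ""

    @property
    def mass_kg(self) -> float:
        """Corrected mass in kg rounded to one decimal (report convention)."""
        return round(self.mass / 1000.0, 1)

    @property
    def interval_kg(self) -> tuple[float, float] | None:
        if self.interval is None:
            return None
        return (round(self.interval[0] / 1000.0, 1), round(self.interval[1] / 1000.0, 1))


def _flags_from(flags, required: list[str]) -> dict[str, float]:
    if flags is None:
        flags = {}
    elif isinstance(flags, Morphotype):
        flags = {
            "rabbit_like": 1.0 if flags is Morphotype.RABBIT_LIKE else 0.0,
            "monotreme_like": 1.0 if flags is Morphotype.MONOTREME_LIKE else 0.0,
        }
    missing = [name for name in required if name not in flags]
    if missing:
        raise ValueError(
            f"model requires morphotype/covariate dummies {missing}; "
            f"got {sorted(flags)}"
        )
    return {k: float(v) for k, v in flags.items()}


def predict_mass(
    model: FittedModel | ReferenceEquation,
    cf: CorrectionFactors | float | None,
    ocw: float,
    flags: Mapping[str, float] | Morphotype | None = None,
    label: str = "",
) -> PredictionResult:
    """Estimate body mass (g) from one OCW measurement (mm).

    ``cf`` may be a :class:`CorrectionFactors`, a bare float, or None (for a
    :class:`ReferenceEquation`, None falls back to the equation's own factor).
    """
    ocw = float(ocw)
    if ocw <= 1.0:
        raise ValueError(f"ocw must exceed 1 mm (log-power transform domain), got {ocw}")

    if isinstance(model, ReferenceEquation):
        if cf is None:
            mean_cf = model.cf
        else:
            mean_cf = float(cf)
        required = list(model.covariate_coefficients)
        used = _flags_from(flags, required)
        ln_point = (
            model.slope * math.log(ocw) ** model.exponent
            + model.intercept
            + sum(model.covariate_coefficients[k] * used.get(k, 0.0) for k in required)
        )
        uncorrected = math.exp(ln_point)
        lo, hi = model.ocw_range
        return PredictionResult(
            ocw=ocw, model=model.name, flags=used, ln_point=ln_point,
            mass_uncorrected=uncorrected, mass=uncorrected * mean_cf,
            interval=None, extrapolated=not (lo <= ocw <= hi), label=label,
        )

    if cf is None:
        raise ValueError("a correction factor is required for fitted models")
    mean_cf = float(cf)
    spec = model.spec
    if len(spec.terms) != 1:
        raise ValueError("prediction supports single-predictor models")
    predictor = spec.terms[0].predictor
    required = [c for c in spec.covariates if isinstance(c, str)]
    used = _flags_from(flags, required)
    row = pd.DataFrame([{predictor: ocw, **{k: used.get(k, 0.0) for k in required}}])
    x0 = model.design_row(row)[0]
    ln_point = float(x0 @ model.params.values)
    uncorrected = math.exp(ln_point)
    # ln-scale 95% prediction interval, then back-transform and correct
    var_pred = model.s2 * (1.0 + x0 @ model._XtX_inv @ x0)
    tcrit = scipy.stats.t.ppf(0.975, model.df_resid)
    half = tcrit * math.sqrt(var_pred)
    interval = (
        math.exp(ln_point - half) * mean_cf,
        math.exp(ln_point + half) * mean_cf,
    )
    lo, hi = model.x_range[predictor]
    return PredictionResult(
        ocw=ocw, model=spec.label(), flags=used, ln_point=ln_point,
        mass_uncorrected=uncorrected, mass=uncorrected * mean_cf,
        interval=interval, extrapolated=not (lo <= ocw <= hi), label=label,
    )


def batch_predict(
    model: FittedModel | ReferenceEquation,
    cf: CorrectionFactors | float | None,
    table: pd.DataFrame,
) -> tuple[list[PredictionResult], list[tuple[int, str]]]:
    """Predict for every row of a table with columns ``ocw`` (or ``ocw_mm``),
    optional ``morphotype`` and ``label``. Failing rows are annotated and the
    batch continues; an error is raised only if every row fails.
    """
    results: list[PredictionResult] = []
    failures: list[tuple[int, str]] = []
    if len(table) == 0:
        return results, failures
    ocw_col = "ocw" if "ocw" in table.columns else "ocw_mm"
    for i, (_, row) in enumerate(table.iterrows()):
        try:
            flags = None
            if "morphotype" in table.columns and isinstance(row["morphotype"], str):
                text = row["morphotype"].strip().lower().replace("-", "_")
                if text:
                    flags = Morphotype(text)
            label = str(row["label"]) if "label" in table.columns else ""
            results.append(
                predict_mass(model, cf, float(row[ocw_col]), flags=flags, label=label)
            )
        except Exception as exc:
            failures.append((i, str(exc)))
    if not results and failures:
        raise ValueError(f"every row failed: {failures}")
    return results, failures


def results_to_frame(results: list[PredictionResult]) -> pd.DataFrame:
    """Report table in kg, one decimal, mirroring the fossil worked-example layout."""
    rows = []
    for r in results:
        lo, hi = (r.interval_kg if r.interval_kg is not None else (None, None))
        rows.append(
            {
                "label": r.label,
                "ocw_mm": r.ocw,
                "model": r.model,
                "mass_kg": r.mass_kg,
                "lower_kg": lo,
                "upper_kg": hi,
                "extrapolated": r.extrapolated,
            }
        )
    return pd.DataFrame(rows)
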