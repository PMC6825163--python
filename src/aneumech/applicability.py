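"""Maximum valid stretch of a model on a curve, cohort summaries, and the
deformation-regime model recommendation.

The applicability limit of a model is found by refitting it on expanding
prefixes of the curve (every data point is a candidate endpoint) and
keeping the largest endpoint whose prefix fit stays within the NRMSE
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constitutive import Model
from .errors import ValidationError
from .fitting import FitOptions, FitResult, fit_model
from .io_tensile import Status, TensileCurve

__all__ = [
    "LAMBDA_A",
    "LAMBDA_B",
    "ApplicabilityResult",
    "CohortSummary",
    "max_valid_stretch",
    "cohort_summary",
    "recommend_model",
]

#: Default regime boundaries (stretch) between small/medium/large deformation.
LAMBDA_A = 1.76
LAMBDA_B = 2.31


@dataclass(frozen=True)
class ApplicabilityResult:
    specimen_id: str
    model: Model
    lambda_limit: float
    nrmse_at_limit: float
    threshold: float
    converged: bool  # False when even the smallest prefix exceeds the threshold
    fit: FitResult


@dataclass(frozen=True)
class CohortSummary:
    """Five-number summary of applicability limits for one group and model."""

    group: str
    model: Model
    lower_fence: float
    q1: float
    mean: float
    q3: float
    upper_fence: float
    n: int


def max_valid_stretch(
    curve: TensileCurve,
    model: Model,
    threshold: float = 0.05,
    options: FitOptions | None = None,
    stride: int = 1,
) -> ApplicabilityResult:
    """Largest stretch up to which ``model`` fits ``curve`` within ``threshold``.

    Refits the model on every prefix (smallest admissible prefix has
    ``model.n_coeffs + 2`` points, endpoints advance by ``stride``, the
    full curve is always a candidate) and returns the largest endpoint
    whose fit has NRMSE <= threshold.  If no prefix qualifies, the result
    carries the smallest admissible prefix with ``converged=False``.
    """
    if not threshold > 0:
        raise ValidationError("threshold must be > 0", fields=["threshold"])
    if stride < 1:
        raise ValidationError("stride must be >= 1", fields=["stride"])
    n_min = model.n_coeffs + 2
    if len(curve) < n_min:
        raise ValidationError(
            f"need at least {n_min} points for {model.value}", fields=["curve"]
        )
    ends = list(range(n_min, len(curve) + 1, stride))
    if ends[-1] != len(curve):
        ends.append(len(curve))
    best: tuple[float, FitResult] | None = None
    smallest: FitResult | None = None
    for end in ends:
        fit = fit_model(curve.prefix(end), model, options)
        if smallest is None:
            smallest = fit
        if fit.nrmse <= threshold:
            best = (float(curve.stretch[end - 1]), fit)
    if best is not None:
        lam_limit, fit = best
        return ApplicabilityResult(
            curve.specimen_id, model, lam_limit, fit.nrmse, threshold, True, fit
        )
    assert smallest is not None
    return ApplicabilityResult(
        curve.specimen_id,
        model,
        float(curve.stretch[n_min - 1]),
        smallest.nrmse,
        threshold,
        False,
        smallest,
    )


def cohort_summary(
    results: list[ApplicabilityResult], groups: Mapping[str, Status | str]
) -> list[CohortSummary]:
    """Per (group, model) five-number summary of lambda limits.

    Quantiles use linear interpolation; fences are Tukey's Q1 - 1.5 IQR and
    Q3 + 1.5 IQR, clamped to the observed minimum/maximum.
    """
    missing = sorted({r.specimen_id for r in results} - set(groups))
    if missing:
        raise ValidationError("specimens without a group", fields=missing)
    buckets: dict[tuple[str, Model], list[float]] = {}
    for r in results:
        status = groups[r.specimen_id]
        label = status.value if isinstance(status, Status) else str(status)
        buckets.setdefault((label, r.model), []).append(r.lambda_limit)
    labels = {label for label, _ in buckets}
    for label in labels:
        if not any(values for (lbl, _), values in buckets.items() if lbl == label):
            raise ValidationError(f"group {label!r} is empty", fields=[label])
    out = []
    for (label, model), values in sorted(
        buckets.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        arr = np.asarray(values, dtype=float)
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        iqr = q3 - q1
        out.append(
            CohortSummary(
                group=label,
                model=model,
                lower_fence=float(max(q1 - 1.5 * iqr, arr.min())),
                q1=float(q1),
                mean=float(arr.mean()),
                q3=float(q3),
                upper_fence=float(min(q3 + 1.5 * iqr, arr.max())),
                n=arr.size,
            )
        )
    return out


def recommend_model(
    status: Status | str,
    stretch: float,
    lambda_a: float = LAMBDA_A,
    lambda_b: float = LAMBDA_B,
) -> Model:
    """Recommended hyperelastic model for an aneurysm status and stretch level.

    Ruptured: Neo-Hookean up to ``lambda_a``, Yeoh up to ``lambda_b``,
    5-parameter Mooney-Rivlin beyond.  Unruptured: Neo-Hookean up to
    ``lambda_b``, 5-parameter Mooney-Rivlin beyond.  A stretch exactly at a
    boundary belongs to the smaller-deformation regime.
    """
    if not stretch >= 1.0:
        raise ValidationError("stretch must be >= 1", fields=["stretch"])
    if not lambda_a < lambda_b:
        raise ValidationError("lambda_a must be < lambda_b", fields=["lambda_a"])
    status = status if isinstance(status, Status) else Status(status)
    if status is Status.NOT_APPLICABLE:
        raise ValidationError(
            "no recommendation defined for status 'not_applicable'", fields=["status"]
        )
    if status is Status.RUPTURED:
        if stretch <= lambda_a:
            return Model.NEO_HOOKEAN
        if stretch <= lambda_b:
            return Model.YEOH
        return Model.MR5
    if stretch <= lambda_b:
        return Model.NEO_HOOKEAN
    return Model.MR5
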