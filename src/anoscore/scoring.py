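"""Anomaly score computation and z-score standardization.

The raw score of an image X is the weighted sum of its two residuals under
the trained model,

    AS(X) = (1 - lambda) * R(X) + lambda * D(X),

where R(X) is the image-space reconstruction loss and D(X) the critic
feature-space dissimilarity (``compute_losses`` in :mod:`anoscore.anogan`).
The default weight lambda = 0.95 leans almost entirely on the feature term.
Raw scores are then standardized against a normal reference set — by
default the normal training images themselves — so that a score of z means
"z reference standard deviations more abnormal than a typical normal
breast render".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .anogan import GanModel, compute_losses

__all__ = ["DEFAULT_LAMBDA", "AnomalyResult", "ReferenceStats",
           "anomaly_score", "fit_reference", "standardize",
           "score_images", "score_timeseries"]

DEFAULT_LAMBDA = 0.95

VISIT_ORDER = ("pre_rt", "post_1y", "post_2y")


@dataclass(frozen=True)
class AnomalyResult:
    image_id: str
    r_term: float           # R(X): reconstruction (image-space) loss
    d_term: float           # D(X): critic feature dissimilarity
    lam: float
    raw_as: float
    z_as: float | None = None


@dataclass(frozen=True)
class ReferenceStats:
    mean: float
    sd: float
    n_reference: int
    source: str = "normal training images"

    def __post_init__(self):
        if self.n_reference < 2:
            raise ValueError("reference needs at least 2 scores")
        if not self.sd > 0:
            raise ValueError("reference sd must be strictly positive")


def anomaly_score(X, model: GanModel, lam: float = DEFAULT_LAMBDA,
                  image_id: str = "") -> AnomalyResult:
    """Score one image; ``z_as`` stays unset until standardized."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    r_term, d_term = compute_losses(X, model)
    raw = (1.0 - lam) * r_term + lam * d_term
    return AnomalyResult(image_id, r_term, d_term, lam, raw)


def fit_reference(normal_scores, source: str = "normal training images") -> ReferenceStats:
    """Mean and sample SD (n-1 denominator) of raw scores on normals."""
    scores = np.asarray(list(normal_scores), dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 reference scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("reference scores must be finite")
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        raise ValueError("reference scores have zero variance")
    return ReferenceStats(float(scores.mean()), sd, len(scores), source)


def standardize(result: AnomalyResult, ref: ReferenceStats) -> AnomalyResult:
    return replace(result, z_as=(result.raw_as - ref.mean) / ref.sd)


def score_images(images, model: GanModel, lam: float = DEFAULT_LAMBDA,
                 ref: ReferenceStats | None = None,
                 ids=None) -> list[AnomalyResult]:
    """Score a stack of images; standardize if a reference is given."""
    images = np.asarray(images, dtype=float)
    if ids is None:
        ids = [f"img{i:04d}" for i in range(len(images))]
    out = []
    for img, image_id in zip(images, ids):
        res = anomaly_score(img, model, lam, image_id)
        if ref is not None:
            res = standardize(res, ref)
        out.append(res)
    return out


def score_timeseries(images: dict, model: GanModel,
                     lam: float = DEFAULT_LAMBDA,
                     ref: ReferenceStats | None = None) -> dict:
    """Score one patient's visit images with a frozen model and reference.

    ``images`` maps visit names (pre_rt / post_1y / post_2y) to images;
    missing visits are simply absent from the output, never imputed.
    """
    if not images:
        raise ValueError("at least one visit image is required")
    unknown = set(images) - set(VISIT_ORDER)
    if unknown:
        raise ValueError(f"unknown visit name(s) {sorted(unknown)}; "
                         f"expected {VISIT_ORDER}")
    shapes = {np.asarray(img).shape for img in images.values()}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent image sizes across visits: {sorted(shapes)}")
    out = {}
    for visit in VISIT_ORDER:
        if visit in images:
            res = anomaly_score(images[visit], model, lam, image_id=visit)
            if ref is not None:
                res = standardize(res, ref)
            out[visit] = res
    return out
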