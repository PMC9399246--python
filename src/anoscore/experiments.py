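"""Reproducible headline experiments over the library.

Two study designs are packaged here so the analysis drivers, the test
suite and the acceptance script all run exactly the same computation:

* :func:`discrimination_experiment` — train the anomaly model on normal
  phantom renders at toy scale and check that severity-1 anomalous
  phantoms score higher than held-out normals.

* :func:`lme_recovery_experiment` — simulate longitudinal cohorts from
  the random-intercept model with the clinically estimated coefficients
  as generating truth (days 0.004, tissue expander 2.223, age 0.073 per
  year; all other effects zero; intercept SD 1.5, residual SD 1.0) and
  refit the mixed model, summarizing bias and confidence-interval
  coverage over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anogan import GanHyperparams, GanModel, train_encoder, train_wgan
from .longitudinal import FIXED_EFFECT_TERMS, fit_lme
from .phantoms import (DEFAULT_FIXED_EFFECTS, CohortGenSpec, PhantomSpec,
                       generate_cohort, generate_image_dataset)
from .scoring import DEFAULT_LAMBDA, fit_reference, score_images

__all__ = ["DiscriminationResult", "discrimination_experiment",
           "RecoveryResult", "lme_recovery_experiment",
           "train_toy_model", "TOY_HP"]

#: toy-scale training configuration: 64x64 renders, latent 32, narrow
#: hidden layer, 2000 generator steps / 1000 encoder steps
TOY_HP = GanHyperparams(input_size=64, latent_dim=32, hidden_dim=128,
                        n_steps=2000, encoder_steps=1000, seed=0)


def train_toy_model(n_normal: int = 200, hp: GanHyperparams = TOY_HP,
                    seed: int = 0) -> tuple[GanModel, np.ndarray]:
    """Train the full model on ``n_normal`` normal phantoms; returns
    (model, training images)."""
    import dataclasses
    hp = dataclasses.replace(hp, seed=seed)
    train_set = generate_image_dataset(
        n_normal, 0, PhantomSpec(image_size=hp.input_size), seed=seed)
    model = train_wgan(train_set.images, hp)
    model = train_encoder(model, train_set.images, hp)
    return model, train_set.images


@dataclass
class DiscriminationResult:
    z_normal: np.ndarray
    z_anomalous: np.ndarray
    labels_anomalous: list[str]
    mannwhitney_u: float
    p_value: float
    median_normal: float
    median_anomalous: float
    model: GanModel = field(repr=False, default=None)


def discrimination_experiment(n_train: int = 200, n_eval_per_group: int = 30,
                              hp: GanHyperparams = TOY_HP,
                              lam: float = DEFAULT_LAMBDA,
                              seed: int = 0,
                              model: GanModel | None = None,
                              train_images: np.ndarray | None = None
                              ) -> DiscriminationResult:
    """Normal-vs-anomalous scoring study on held-out phantoms.

    Held-out normals and severity-1.0 anomalies (all four kinds mixed) are
    scored with the trained model; group difference is assessed one-sided
    by Mann-Whitney U (anomalous > normal).
    """
    if model is None:
        model, train_images = train_toy_model(n_train, hp, seed)
    ref = fit_reference([r.raw_as for r in
                         score_images(train_images, model, lam)])

    eval_normal = generate_image_dataset(
        n_eval_per_group, 0, PhantomSpec(image_size=model.hp.input_size),
        seed=seed + 10_000)
    n_per_kind = int(np.ceil(n_eval_per_group / 4))
    eval_anom = generate_image_dataset(
        0, n_per_kind, PhantomSpec(image_size=model.hp.input_size),
        seed=seed + 20_000, severity=1.0)
    anom_images = eval_anom.images[:n_eval_per_group]
    anom_labels = eval_anom.labels[:n_eval_per_group]

    z_norm = np.array([r.z_as for r in
                       score_images(eval_normal.images, model, lam, ref)])
    z_anom = np.array([r.z_as for r in
                       score_images(anom_images, model, lam, ref)])
    u, p = stats.mannwhitneyu(z_anom, z_norm, alternative="greater")
    return DiscriminationResult(
        z_normal=z_norm, z_anomalous=z_anom, labels_anomalous=anom_labels,
        mannwhitney_u=float(u), p_value=float(p),
        median_normal=float(np.median(z_norm)),
        median_anomalous=float(np.median(z_anom)), model=model)


@dataclass
class RecoveryResult:
    truth: dict[str, float]
    estimates: pd.DataFrame          # one row per replicate, one col per term
    mean_estimates: dict[str, float]
    mc_se: dict[str, float]          # Monte-Carlo SE of the replicate mean
    coverage_95: float               # pooled over all terms and replicates
    n_patients: int
    n_replicates: int


def lme_recovery_experiment(truth: dict[str, float] | None = None,
                            n_patients: int = 200, n_replicates: int = 20,
                            random_intercept_sd: float = 1.5,
                            residual_sd: float = 1.0,
                            seed: int = 1) -> RecoveryResult:
    """Simulate-and-refit study of the random-intercept mixed model."""
    truth = dict(DEFAULT_FIXED_EFFECTS) if truth is None else dict(truth)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)

    full_truth = {t: float(truth.get(t, 0.0)) for t in FIXED_EFFECT_TERMS}
    rows, covered, total = [], 0, 0
    for rep_seed in rep_seeds:
        cohort = generate_cohort(CohortGenSpec(
            n_patients=n_patients, fixed_effects=truth,
            random_intercept_sd=random_intercept_sd,
            residual_sd=residual_sd, seed=int(rep_seed)))
        fit = fit_lme(cohort, response="as_true")
        rows.append({t: fit.coefficients[t].estimate for t in FIXED_EFFECT_TERMS})
        for t in FIXED_EFFECT_TERMS:
            ce = fit.coefficients[t]
            covered += int(ce.ci_low <= full_truth[t] <= ce.ci_high)
            total += 1
    est = pd.DataFrame(rows)
    return RecoveryResult(
        truth=full_truth,
        estimates=est,
        mean_estimates={t: float(est[t].mean()) for t in FIXED_EFFECT_TERMS},
        mc_se={t: float(est[t].std(ddof=1) / np.sqrt(n_replicates))
               for t in FIXED_EFFECT_TERMS},
        coverage_95=covered / total,
        n_patients=n_patients,
        n_replicates=n_replicates,
    )
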