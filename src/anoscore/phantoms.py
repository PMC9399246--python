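"""Seeded synthetic data: torso surface phantoms and longitudinal cohorts.

Two generators live here.

* Image phantoms: a half-torso density slab with two hemispherical breast
  mounds on its anterior face, optionally deformed on one side by a
  severity-graded anomaly (asymmetry, missing mound, contracture, expander
  bulge).  Rendered through :mod:`anoscore.preprocess` they yield the 2D
  frontal depth maps the anomaly network trains and scores on.  The
  anomalies are geometric stand-ins for clinical deformity: each produces
  an image deviation that grows monotonically with ``severity`` and
  vanishes at severity 0.

* Cohort simulator: per-patient anomaly-score trajectories over three CT
  visits (baseline before radiotherapy, one and two years after), generated
  by a random-intercept linear model

      AS_ij = beta0 + sum_k beta_k x_ijk + b_i + eps_ij,
      b_i ~ N(0, sd_intercept^2),  eps_ij ~ N(0, sd_residual^2),

  with binary treatment covariates sampled from stated marginal
  frequencies, age uniform over 30-70 years (entering the model centered
  at 50), and visit-day offsets drawn uniformly over the observed
  interquartile ranges (1-year visit 343-512 days, 2-year visit 741-951
  days after baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import RenderedImage, VolumeGrid, render_frontal, resize_normalize

__all__ = [
    "AnomalyKind", "PhantomSpec", "CohortGenSpec", "ImageSet",
    "make_phantom_volume", "generate_image_dataset", "generate_cohort",
    "COEFFICIENT_NAMES", "DEFAULT_FIXED_EFFECTS", "DEFAULT_COVARIATE_MARGINALS",
    "DEFAULT_VISIT_DAY_RANGES", "AGE_CENTER", "AGE_RANGE",
]


class AnomalyKind(str, Enum):
    NONE = "none"
    ASYMMETRY = "asymmetry"
    MISSING_MOUND = "missing_mound"
    CONTRACTURE = "contracture"
    EXPANDER_BULGE = "expander_bulge"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of one synthetic torso render."""

    image_size: int = 64
    torso_width_frac: float = 0.8
    mound_radius_frac: float = 0.16
    mound_separation_frac: float = 0.40
    anomaly_kind: AnomalyKind = AnomalyKind.NONE
    severity: float = 0.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not isinstance(self.anomaly_kind, AnomalyKind):
            try:
                object.__setattr__(self, "anomaly_kind", AnomalyKind(self.anomaly_kind))
            except ValueError:
                valid = [k.value for k in AnomalyKind]
                raise ValueError(
                    f"unknown anomaly_kind {self.anomaly_kind!r}; valid: {valid}"
                ) from None
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        for name in ("torso_width_frac", "mound_radius_frac", "mound_separation_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_phantom_volume(spec: PhantomSpec) -> VolumeGrid:
    """Build the 3D density field of one torso phantom.

    The field is a binary occupancy map (slab + mounds) smoothed with a
    small Gaussian and perturbed by seeded voxel noise; values are clipped
    to [0, 1].  Axis order matches :mod:`anoscore.preprocess`:
    (anterior-posterior, left-right, cranio-caudal), anterior at index 0.
    """
    s = spec.image_size
    rng = np.random.default_rng(spec.seed)

    ap = np.arange(s)[:, None, None].astype(float)
    lr = np.arange(s)[None, :, None] - (s - 1) / 2.0   # symmetric about mid-plane
    cc = np.arange(s)[None, None, :] - (s - 1) / 2.0

    chest_front = 0.55 * s                    # anterior face of the slab
    half_w = spec.torso_width_frac * s / 2.0
    half_h = 0.45 * s
    slab = (ap >= chest_front) & (ap <= 0.95 * s) & \
           (np.abs(lr) <= half_w) & (np.abs(cc) <= half_h)

    radius = spec.mound_radius_frac * s
    sep = spec.mound_separation_frac * s / 2.0
    sev = spec.severity

    occupancy = slab.astype(float)
    for side in (-1.0, +1.0):                  # side -1 carries the anomaly
        r_eff, y_c, ap_c = radius, side * sep, chest_front
        front_clip = None
        if side < 0 and sev > 0:
            kind = spec.anomaly_kind
            if kind is AnomalyKind.MISSING_MOUND:
                r_eff = radius * (1.0 - sev)
            elif kind is AnomalyKind.CONTRACTURE:
                r_eff = radius * (1.0 - 0.5 * sev)
                ap_c = chest_front + 0.5 * sev * radius
            elif kind is AnomalyKind.ASYMMETRY:
                r_eff = radius * (1.0 - 0.25 * sev)
                y_c = side * sep * (1.0 - 0.5 * sev)
            elif kind is AnomalyKind.EXPANDER_BULGE:
                # progressive widening with a flattened anterior cap; the
                # cap never protrudes past the normal mound so the render's
                # depth span (and hence its normalization) stays comparable
                r_eff = radius * (1.0 + 0.8 * sev)
                front_clip = chest_front - min(
                    radius, (1.0 - 0.5 * sev) * r_eff)
        if r_eff <= 0:
            continue
        dist2 = (ap - ap_c) ** 2 + (lr - y_c) ** 2 + cc ** 2
        mound = (dist2 <= r_eff ** 2) & (ap <= chest_front)
        if front_clip is not None:
            mound &= ap >= front_clip          # flattened over-inflated cap
        occupancy = np.maximum(occupancy, mound.astype(float))

    # noise models smooth density inhomogeneity, so it is added before the
    # smoothing pass: post-hoc voxel noise would let single voxels near the
    # iso level flip grazing rays and destabilize the render's depth range
    if spec.noise_sd > 0:
        occupancy = occupancy + rng.normal(0.0, spec.noise_sd,
                                           size=occupancy.shape)
    density = ndimage.gaussian_filter(occupancy, sigma=1.0)
    return VolumeGrid(np.clip(density, 0.0, 1.0))


@dataclass
class ImageSet:
    """Labelled stack of rendered phantom images."""

    images: np.ndarray          # (n, size, size) in [0, 1]
    labels: list[str]           # "normal" or the anomaly kind
    severities: np.ndarray
    specs: list[PhantomSpec]

    def __len__(self) -> int:
        return len(self.labels)


#: per-image relative jitter applied to mound geometry so normal phantoms
#: form a distribution rather than a single image
_GEOMETRY_JITTER = 0.05


def generate_image_dataset(n_normal: int, n_anomalous_per_kind: int,
                           spec_template: PhantomSpec | None = None,
                           seed: int = 0,
                           severity: float = 1.0) -> ImageSet:
    """Render a labelled set of normal and anomalous phantoms.

    Each image gets its own sub-seed and a small (±5%) jitter of the mound
    radius and separation, both drawn from a generator seeded only by
    ``seed`` — the output is bit-reproducible.
    """
    if n_normal < 0 or n_anomalous_per_kind < 0:
        raise ValueError("counts must be non-negative")
    template = spec_template or PhantomSpec()
    rng = np.random.default_rng(seed)

    plan: list[tuple[AnomalyKind, float]] = [(AnomalyKind.NONE, 0.0)] * n_normal
    for kind in (AnomalyKind.ASYMMETRY, AnomalyKind.MISSING_MOUND,
                 AnomalyKind.CONTRACTURE, AnomalyKind.EXPANDER_BULGE):
        plan += [(kind, severity)] * n_anomalous_per_kind

    images, labels, sevs, specs = [], [], [], []
    for kind, sev in plan:
        jit_r, jit_s = 1.0 + _GEOMETRY_JITTER * rng.uniform(-1, 1, size=2)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            template,
            mound_radius_frac=template.mound_radius_frac * jit_r,
            mound_separation_frac=template.mound_separation_frac * jit_s,
            anomaly_kind=kind, severity=sev, seed=sub_seed)
        volume = make_phantom_volume(spec)
        img = render_frontal(volume, spec.image_size)
        images.append(img.pixels)
        labels.append("normal" if kind is AnomalyKind.NONE else kind.value)
        sevs.append(sev)
        specs.append(spec)

    size = template.image_size
    stack = np.stack(images) if images else np.zeros((0, size, size))
    return ImageSet(stack, labels, np.asarray(sevs), specs)


# ---------------------------------------------------------------------------
# Longitudinal cohort simulation
# ---------------------------------------------------------------------------

#: canonical fixed-effect terms of the anomaly-score mixed model
COEFFICIENT_NAMES = (
    "intercept", "days", "expander", "expander_x_days",
    "hypo", "hypo_x_days", "nsm_ssm", "scl", "imn", "boost",
    "imrt", "complication", "age", "bmi_gt23",
)

#: generating truth used by the parameter-recovery experiments: the three
#: effects estimated as non-null in the clinical fit (anomaly-score units)
DEFAULT_FIXED_EFFECTS = {
    "days": 0.004,        # per day after baseline
    "expander": 2.223,    # tissue expander vs autologous reconstruction
    "age": 0.073,         # per year, age centered at 50
}

#: cohort marginal frequencies of the binary covariates
DEFAULT_COVARIATE_MARGINALS = {
    "expander": 0.230,
    "hypo": 0.131,
    "nsm_ssm": 0.361,
    "scl": 0.5,
    "imn": 0.5,
    "boost": 0.197,
    "imrt": 0.213,
    "complication": 0.164,
    "bmi_gt23": 0.475,
}

#: uniform sampling ranges (days after baseline) for the two follow-up CTs
DEFAULT_VISIT_DAY_RANGES = {"post_1y": (343.0, 512.0), "post_2y": (741.0, 951.0)}

AGE_CENTER = 50.0
AGE_RANGE = (30.0, 70.0)

VISITS = ("pre_rt", "post_1y", "post_2y")


@dataclass(frozen=True)
class CohortGenSpec:
    n_patients: int = 200
    fixed_effects: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    random_intercept_sd: float = 1.5
    residual_sd: float = 1.0
    visit_day_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_VISIT_DAY_RANGES))
    covariate_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS))
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        unknown = set(self.fixed_effects) - set(COEFFICIENT_NAMES)
        if unknown:
            raise ValueError(
                f"unknown coefficient name(s) {sorted(unknown)}; "
                f"valid names: {list(COEFFICIENT_NAMES)}")
        for name, p in self.covariate_marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal for {name!r} must be in [0, 1], got {p}")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components must be non-negative")
        lo1, hi1 = self.visit_day_ranges["post_1y"]
        lo2, hi2 = self.visit_day_ranges["post_2y"]
        if not (0 < lo1 <= hi1 < lo2 <= hi2):
            raise ValueError("visit day ranges must satisfy 0 < 1Y range < 2Y range")


def generate_cohort(spec: CohortGenSpec) -> pd.DataFrame:
    """Simulate a three-visit cohort table, one row per (patient, visit).

    Columns: patient_id, visit, day, recon_type, fractionation, mastectomy,
    scl, imn, boost, plan, complication, age, bmi_gt23, as_true.  ``as_true``
    is the simulated anomaly score (already on the standardized scale the
    analysis operates on).
    """
    rng = np.random.default_rng(spec.seed)
    beta = {name: float(spec.fixed_effects.get(name, 0.0))
            for name in COEFFICIENT_NAMES}
    marg = spec.covariate_marginals

    rows = []
    for pid in range(spec.n_patients):
        x = {name: int(rng.random() < marg.get(name, 0.5))
             for name in ("expander", "hypo", "nsm_ssm", "scl", "imn",
                          "boost", "imrt", "complication", "bmi_gt23")}
        age = float(rng.uniform(*AGE_RANGE))
        b_i = rng.normal(0.0, spec.random_intercept_sd)
        day_1y = float(rng.uniform(*spec.visit_day_ranges["post_1y"]))
        day_2y = float(rng.uniform(*spec.visit_day_ranges["post_2y"]))
        for visit, day in zip(VISITS, (0.0, day_1y, day_2y)):
            eps = rng.normal(0.0, spec.residual_sd)
            mean = (beta["intercept"]
                    + beta["days"] * day
                    + beta["expander"] * x["expander"]
                    + beta["expander_x_days"] * x["expander"] * day
                    + beta["hypo"] * x["hypo"]
                    + beta["hypo_x_days"] * x["hypo"] * day
                    + beta["nsm_ssm"] * x["nsm_ssm"]
                    + beta["scl"] * x["scl"]
                    + beta["imn"] * x["imn"]
                    + beta["boost"] * x["boost"]
                    + beta["imrt"] * x["imrt"]
                    + beta["complication"] * x["complication"]
                    + beta["age"] * (age - AGE_CENTER)
                    + beta["bmi_gt23"] * x["bmi_gt23"])
            rows.append({
                "patient_id": pid,
                "visit": visit,
                "day": day,
                "recon_type": "expander" if x["expander"] else "autologous",
                "fractionation": "hypo" if x["hypo"] else "conventional",
                "mastectomy": "nsm_ssm" if x["nsm_ssm"] else "total_radical",
                "scl": x["scl"], "imn": x["imn"], "boost": x["boost"],
                "plan": "imrt" if x["imrt"] else "3d",
                "complication": x["complication"],
                "age": age,
                "bmi_gt23": x["bmi_gt23"],
                "as_true": mean + b_i + eps,
            })
    return pd.DataFrame(rows)


def save_images_png(image_set: ImageSet, out_dir) -> list[str]:
    """Write each image as an 8-bit grayscale PNG; returns the file names."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (px, label) in enumerate(zip(image_set.images, image_set.labels)):
        name = f"{i:04d}_{label}.png"
        arr = np.round(px * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / name)
        names.append(name)
    return names


def load_images_png(path) -> np.ndarray:
    """Read a directory of grayscale PNGs back into an (n, s, s) stack."""
    from pathlib import Path

    from PIL import Image

    files = sorted(p for p in Path(path).iterdir() if p.suffix == ".png")
    if not files:
        raise ValueError(f"no PNG images found in {path}")
    return np.stack([np.asarray(Image.open(f), dtype=float) / 255.0 for f in files])
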