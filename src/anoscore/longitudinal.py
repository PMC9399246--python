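"""Longitudinal analysis of anomaly-score trajectories.

Implements the cohort statistics run on the three-visit score table:
pairwise paired t-tests between visits (overall and stratified), a
per-patient trajectory-pattern classifier, a random-intercept linear
mixed-effects model of the anomaly score with the full clinical covariate
set, and model-based expander-vs-autologous (or hypo-vs-conventional)
contrasts on a grid of days after radiotherapy.

The mixed model is

    AS_ij = x_ij' beta + b_i + eps_ij,   b_i ~ N(0, tau^2), eps ~ N(0, s^2)

fit by maximum likelihood (statsmodels MixedLM) with Wald 95% intervals
and p-values.  Fixed effects: days after baseline, reconstruction type
(expander vs autologous) and its interaction with days, fractionation
(hypo vs conventional) and its interaction with days, mastectomy type,
supraclavicular and internal-mammary irradiation, boost, plan (IMRT vs
3D), major complication, age (centered at 50 years) and BMI > 23.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .phantoms import AGE_CENTER, VISITS

__all__ = [
    "PairedTResult", "CoefEstimate", "LmeFit", "ContrastEstimate",
    "AnalysisReport", "paired_t_test", "classify_trajectory", "fit_lme",
    "predict_contrasts", "run_analysis", "FIXED_EFFECT_TERMS",
]

FIXED_EFFECT_TERMS = (
    "intercept", "days", "expander", "expander_x_days", "hypo",
    "hypo_x_days", "nsm_ssm", "scl", "imn", "boost", "imrt",
    "complication", "age", "bmi_gt23",
)

TRAJECTORY_PATTERNS = ("decreasing", "increasing", "inc_dec", "dec_inc", "flat")

DEFAULT_TRAJECTORY_TOL = 0.1
DEFAULT_CONTRAST_DAYS = (0.0, 180.0, 360.0, 540.0, 720.0)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n_pairs: int


def paired_t_test(a, b) -> PairedTResult:
    """Two-sided paired t-test on the differences a - b.

    Pairs where either member is missing (NaN) are dropped.  Degenerate
    inputs — fewer than two complete pairs, or zero variance of the
    differences — are rejected rather than returning an infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    n = len(d)
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    mean = float(d.mean())
    t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTResult(float(t), df, float(p), mean, n)


def classify_trajectory(z_pre: float, z_1y: float, z_2y: float,
                        tol: float = DEFAULT_TRAJECTORY_TOL) -> str:
    """Classify a three-visit score trajectory into one of five patterns.

    Changes with magnitude <= ``tol`` count as "no change".  Both segments
    flat -> "flat"; otherwise a flat segment inherits the direction of the
    non-flat one, giving the four monotone/turning patterns.
    """
    for v in (z_pre, z_1y, z_2y):
        if not np.isfinite(v):
            raise ValueError("trajectory values must be finite")
    d1, d2 = z_1y - z_pre, z_2y - z_1y
    s1 = 0 if abs(d1) <= tol else (1 if d1 > 0 else -1)
    s2 = 0 if abs(d2) <= tol else (1 if d2 > 0 else -1)
    if s1 == 0 and s2 == 0:
        return "flat"
    if s1 == 0:
        s1 = s2
    if s2 == 0:
        s2 = s1
    return {(1, 1): "increasing", (-1, -1): "decreasing",
            (1, -1): "inc_dec", (-1, 1): "dec_inc"}[(s1, s2)]


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoefEstimate:
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LmeFit:
    coefficients: dict[str, CoefEstimate]
    random_intercept_sd: float
    residual_sd: float
    n_patients: int
    n_obs: int
    converged: bool
    cov_fixed: pd.DataFrame = field(repr=False, default=None)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {term: asdict(ce) for term, ce in self.coefficients.items()}).T


def _design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    x = pd.DataFrame(index=cohort.index)
    x["intercept"] = 1.0
    x["days"] = cohort["day"].astype(float)
    x["expander"] = (cohort["recon_type"] == "expander").astype(float)
    x["expander_x_days"] = x["expander"] * x["days"]
    x["hypo"] = (cohort["fractionation"] == "hypo").astype(float)
    x["hypo_x_days"] = x["hypo"] * x["days"]
    x["nsm_ssm"] = (cohort["mastectomy"] == "nsm_ssm").astype(float)
    for col in ("scl", "imn", "boost", "complication", "bmi_gt23"):
        x[col] = cohort[col].astype(float)
    x["imrt"] = (cohort["plan"] == "imrt").astype(float)
    x["age"] = cohort["age"].astype(float) - AGE_CENTER
    return x[list(FIXED_EFFECT_TERMS)]


def fit_lme(cohort: pd.DataFrame, response: str = "as_value",
            reml: bool = False) -> LmeFit:
    """Fit the random-intercept mixed model by maximum likelihood.

    ``response`` names the score column (``as_true`` for simulated cohorts,
    ``as_value`` for scored ones).  Constant (unidentifiable) covariate
    columns are a rank-deficiency and are rejected by name.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    if response not in cohort.columns:
        if response == "as_value" and "as_true" in cohort.columns:
            response = "as_true"
        else:
            raise ValueError(f"no response column {response!r} in cohort")
    counts = cohort.groupby("patient_id")["visit"].count()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 patients with >= 2 visits each")

    x = _design_matrix(cohort)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        degenerate = [c for c in x.columns if c != "intercept"
                      and x[c].nunique() <= 1]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {x.shape[1]}); "
            f"collinear/constant terms: {degenerate or 'interaction terms'}")

    y = cohort[response].astype(float).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, x.to_numpy(), groups=cohort["patient_id"].to_numpy())
        result = None
        # lbfgs can hit a singular hessian when the intercept variance
        # collapses; fall back to gradient-free optimizers
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                result = model.fit(reml=reml, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if result is None:
            raise RuntimeError("mixed-model optimization failed to run")

    k = x.shape[1]
    params = result.fe_params[:k]
    bse = result.bse_fe[:k]
    zcrit = stats.norm.ppf(0.975)
    coefficients = {}
    for i, term in enumerate(FIXED_EFFECT_TERMS):
        est, se = float(params[i]), float(bse[i])
        pval = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        coefficients[term] = CoefEstimate(
            est, se, est - zcrit * se, est + zcrit * se, float(pval))
    cov = pd.DataFrame(np.asarray(result.cov_params())[:k, :k],
                       index=FIXED_EFFECT_TERMS, columns=FIXED_EFFECT_TERMS)
    return LmeFit(
        coefficients=coefficients,
        random_intercept_sd=float(np.sqrt(np.asarray(result.cov_re)[0, 0])),
        residual_sd=float(np.sqrt(result.scale)),
        n_patients=int(cohort["patient_id"].nunique()),
        n_obs=len(cohort),
        converged=bool(result.converged),
        cov_fixed=cov,
    )


@dataclass(frozen=True)
class ContrastEstimate:
    day: float
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


def predict_contrasts(fit: LmeFit, days_grid=DEFAULT_CONTRAST_DAYS,
                      main: str = "expander",
                      interaction: str | None = None) -> list[ContrastEstimate]:
    """Model-based between-group difference at each day on the grid.

    estimate(d) = beta_main + d * beta_interaction, with a delta-method
    (linear-combination) Wald interval from the fixed-effect covariance.
    """
    if interaction is None:
        interaction = f"{main}_x_days"
    for term in (main, interaction):
        if term not in fit.coefficients:
            raise ValueError(f"term {term!r} not in the fitted model")
    bm = fit.coefficients[main].estimate
    bi = fit.coefficients[interaction].estimate
    v = fit.cov_fixed
    vmm = v.loc[main, main]
    vii = v.loc[interaction, interaction]
    vmi = v.loc[main, interaction]
    zcrit = stats.norm.ppf(0.975)
    out = []
    for d in days_grid:
        est = bm + d * bi
        var = vmm + d * d * vii + 2.0 * d * vmi
        se = float(np.sqrt(max(var, 0.0)))
        p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        out.append(ContrastEstimate(float(d), float(est),
                                    float(est - zcrit * se),
                                    float(est + zcrit * se), float(p)))
    return out


# ---------------------------------------------------------------------------
# Full analysis bundle
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    pairwise_tests: pd.DataFrame
    trajectories: pd.DataFrame
    lme: LmeFit | None
    contrasts: pd.DataFrame
    log: list[str]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pairwise_tests.to_csv(out / "pairwise_tests.csv", index=False)
        self.trajectories.to_csv(out / "trajectories.csv", index=False)
        self.contrasts.to_csv(out / "contrasts.csv", index=False)
        if self.lme is not None:
            payload = {
                "coefficients": {t: asdict(c)
                                 for t, c in self.lme.coefficients.items()},
                "random_intercept_sd": self.lme.random_intercept_sd,
                "residual_sd": self.lme.residual_sd,
                "n_patients": self.lme.n_patients,
                "n_obs": self.lme.n_obs,
                "converged": self.lme.converged,
            }
            (out / "lme_fit.json").write_text(json.dumps(payload, indent=2))
        (out / "analysis_log.txt").write_text("\n".join(self.log) + "\n")


def _wide_scores(cohort: pd.DataFrame, response: str) -> pd.DataFrame:
    return cohort.pivot_table(index="patient_id", columns="visit",
                              values=response, aggfunc="first")


def run_analysis(cohort: pd.DataFrame, response: str = "as_value",
                 tol: float = DEFAULT_TRAJECTORY_TOL,
                 bonferroni: bool = True) -> AnalysisReport:
    """Run the full trajectory analysis on a three-visit cohort table.

    Produces pairwise paired t-tests between visits — overall and within
    strata of major complication and reconstruction type — per-patient
    trajectory patterns, the mixed-model fit, and day-grid contrasts for
    reconstruction type and fractionation.  Degenerate strata (too few
    pairs, zero-variance differences) are reported as such, not dropped
    silently.
    """
    if response not in cohort.columns and "as_true" in cohort.columns:
        response = "as_true"
    log = [f"n_patients={cohort['patient_id'].nunique()} "
           f"n_rows={len(cohort)} response={response}"]

    strata = [("overall", cohort)]
    for col, label in (("complication", "complication"),
                       ("recon_type", "recon")):
        for level, sub in cohort.groupby(col):
            strata.append((f"{label}={level}", sub))

    rows = []
    for stratum, sub in strata:
        wide = _wide_scores(sub, response)
        for va, vb in combinations([v for v in VISITS if v in wide.columns], 2):
            try:
                res = paired_t_test(wide[vb], wide[va])
                rows.append({"stratum": stratum, "visit_a": va, "visit_b": vb,
                             "mean_diff": res.mean_diff, "t": res.t,
                             "df": res.df, "p": res.p, "n_pairs": res.n_pairs,
                             "note": ""})
            except ValueError as err:
                rows.append({"stratum": stratum, "visit_a": va, "visit_b": vb,
                             "mean_diff": np.nan, "t": np.nan, "df": 0,
                             "p": np.nan, "n_pairs": 0,
                             "note": f"degenerate: {err}"})
    pairwise = pd.DataFrame(rows)
    if bonferroni and len(pairwise):
        m = pairwise["p"].notna().sum()
        pairwise["p_bonferroni"] = (pairwise["p"] * max(m, 1)).clip(upper=1.0)

    wide_all = _wide_scores(cohort, response)
    traj_rows = []
    for pid, row in wide_all.iterrows():
        if all(v in row and np.isfinite(row[v]) for v in VISITS):
            pattern = classify_trajectory(row["pre_rt"], row["post_1y"],
                                          row["post_2y"], tol)
        else:
            pattern = "incomplete"
        traj_rows.append({"patient_id": pid, "pattern": pattern})
    trajectories = pd.DataFrame(traj_rows)

    lme = None
    contrast_rows = []
    try:
        lme = fit_lme(cohort, response=response)
        log.append(f"lme converged={lme.converged} "
                   f"tau={lme.random_intercept_sd:.4f} "
                   f"sigma={lme.residual_sd:.4f}")
        for main in ("expander", "hypo"):
            for c in predict_contrasts(lme, main=main):
                contrast_rows.append({"contrast": main, **asdict(c)})
    except ValueError as err:
        log.append(f"lme skipped: {err}")
    contrasts = pd.DataFrame(contrast_rows)
    return AnalysisReport(pairwise, trajectories, lme, contrasts, log)
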