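"""Cohort-level statistics: stratum ANOVA, univariate screening and linear
mixed models with stratum-level random effects.

The mixed models regress the per-(subject x stratum) mean normalized NAWM
intensity on the lesion-volume quartile (numeric 1-4, a single
"per-quartile-increase" coefficient), age in decades and hypertension, with
the five NAWM distance strata as the clustering variable:

    nawm_m = b0 + b1*quartile + b2*age_decades + b3*hypertension
             + u0(stratum) [+ u1(stratum)*quartile] + eps

Model 1 has random intercepts only; model 2 adds random slopes on the
quartile.  Models are compared by AIC and a 2-df chi-square likelihood-ratio
test on maximum-likelihood fits (the boundary constraint on the slope
variance makes the plain chi-square conservative); the reported models are
refitted by restricted maximum likelihood.  Fixed-effect inference is Wald
(estimate +/- 1.96*SE) -- appropriate for the large observation count, and
documented so the numbers are exactly reproducible.  With only five
clusters the random-effect variances are weakly identified; boundary fits
are flagged, not hidden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["FixedEffect", "LMMResult", "ModelComparison", "LMMConvergenceError",
           "strata_anova", "univariate_screen", "fit_lmm", "compare_models"]

log = logging.getLogger(__name__)

FIXED_TERMS = ["intercept", "lka_quartile", "age_decades", "hypertension"]

#: Wald multiplier for 95% confidence intervals (stated convention)
WALD_Z = 1.96


class LMMConvergenceError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


@dataclass(frozen=True)
class FixedEffect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class LMMResult:
    """A fitted linear mixed model (one clustering level: NAWM strata)."""
    fixed_effects: dict[str, FixedEffect]
    random_effects: dict[str, dict[str, float]]  # stratum -> conditional modes
    variance_components: dict[str, float]
    log_likelihood: float
    aic: float
    method: str                  # ML or REML
    has_random_slopes: bool
    n_obs: int
    n_groups: int
    boundary_fit: bool = False   # singular / boundary random-effect covariance

    def per_stratum_slopes(self) -> dict[str, float]:
        """Total per-stratum quartile effect: fixed slope + conditional mode."""
        fixed = self.fixed_effects["lka_quartile"].estimate
        return {g: fixed + re.get("slope", 0.0)
                for g, re in sorted(self.random_effects.items())}

    def per_stratum_intercepts(self) -> dict[str, float]:
        fixed = self.fixed_effects["intercept"].estimate
        return {g: fixed + re.get("intercept", 0.0)
                for g, re in sorted(self.random_effects.items())}

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"term": t, "estimate": fe.estimate, "se": fe.se,
                 "ci_low": fe.ci_low, "ci_high": fe.ci_high}
                for t, fe in self.fixed_effects.items()]
        return pd.DataFrame(rows)


@dataclass
class ModelComparison:
    """Random-intercepts vs random-intercepts+slopes comparison (ML)."""
    aic_intercepts: float
    aic_slopes: float
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    reml_intercepts: LMMResult = field(repr=False, default=None)
    reml_slopes: LMMResult = field(repr=False, default=None)


def _analysis_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the models: the numbered strata only, complete cases.

    The descriptive 'full' NAWM row is never entered as a sixth cluster: it
    contains the strata and would double-count their voxels.
    """
    df = table[table["stratum"].astype(str) != "full"].copy()
    df["stratum"] = df["stratum"].astype(str)
    needed = ["nawm_m", "lka_quartile", "age_decades", "hypertension"]
    df = df.dropna(subset=needed)
    return df


def strata_anova(table: pd.DataFrame) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of nawm_m across strata 1..n.

    Subjects are the replicates within each stratum group, mirroring an
    analysis that treats the stratum as a plain grouping factor.
    """
    df = _analysis_rows(table)
    groups = [g["nawm_m"].to_numpy() for _, g in df.groupby("stratum")
              if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 strata with >= 2 observations each")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def univariate_screen(subject_table: pd.DataFrame,
                      covariates: dict[str, str],
                      outcome: str = "nawm_m",
                      normality_alpha: float = 0.05) -> pd.DataFrame:
    """Screen subject-level covariates against the outcome.

    Binary covariates: two-sample t-test when both groups pass the Shapiro
    normality check at ``normality_alpha``, otherwise Wilcoxon rank-sum.
    Quantitative covariates: Pearson correlation when both variables pass,
    otherwise Spearman.  Covariates with a single observed level are skipped
    with a log entry (mirroring sparse-covariate exclusions).
    """
    rows = []
    y = subject_table[outcome].to_numpy(dtype=float)
    for name, kind in covariates.items():
        x = subject_table[name].to_numpy()
        if kind == "binary":
            levels = np.unique(x)
            if len(levels) < 2:
                log.info("covariate %s has a single level; skipped", name)
                rows.append({"covariate": name, "kind": kind,
                             "test": "skipped", "statistic": np.nan,
                             "p": np.nan})
                continue
            g0, g1 = y[x == levels[0]], y[x == levels[1]]
            if _is_normal(g0, normality_alpha) and _is_normal(g1, normality_alpha):
                stat, p = sps.ttest_ind(g0, g1)
                test = "t"
            else:
                stat, p = sps.ranksums(g0, g1)
                test = "wilcoxon"
        elif kind == "quantitative":
            xf = x.astype(float)
            if np.ptp(xf) == 0:
                log.info("covariate %s is constant; skipped", name)
                rows.append({"covariate": name, "kind": kind,
                             "test": "skipped", "statistic": np.nan,
                             "p": np.nan})
                continue
            if _is_normal(xf, normality_alpha) and _is_normal(y, normality_alpha):
                stat, p = sps.pearsonr(xf, y)
                test = "pearson"
            else:
                stat, p = sps.spearmanr(xf, y)
                test = "spearman"
        else:
            raise ValueError(f"covariate kind must be binary/quantitative, "
                             f"got {kind!r} for {name}")
        rows.append({"covariate": name, "kind": kind, "test": test,
                     "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)


def fit_lmm(table: pd.DataFrame, random_slopes: bool = False,
            method: str = "REML") -> LMMResult:
    """Fit the stratum-clustered linear mixed model.

    Raises :class:`LMMConvergenceError` when the optimizer reports
    non-convergence; a singular (boundary) random-effect covariance is
    flagged on the result, not silently accepted.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    df = _analysis_rows(table)
    groups = df["stratum"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 stratum clusters to fit a mixed model")
    y = df["nawm_m"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)),
                         df["lka_quartile"].to_numpy(dtype=float),
                         df["age_decades"].to_numpy(dtype=float),
                         df["hypertension"].to_numpy(dtype=float)])
    exog_re = (np.column_stack([np.ones(len(df)),
                                df["lka_quartile"].to_numpy(dtype=float)])
               if random_slopes else np.ones((len(df), 1)))
    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    # boundary fits (random-effect variance ~ 0) routinely trip a single
    # optimizer; walk a chain of optimizers and keep the first converged fit
    res, attempts = None, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for opt in ("bfgs", "lbfgs", "powell", "cg", "nm"):
            try:
                cand = model.fit(reml=(method == "REML"), method=opt)
            except (np.linalg.LinAlgError, ValueError) as exc:
                attempts.append(f"{opt}: {exc}")
                continue
            if cand.converged or float(cand.scale) < 1e-10:
                res = cand
                break
            attempts.append(f"{opt}: not converged (llf={cand.llf:.6g})")
    if res is None:
        raise LMMConvergenceError(
            "mixed-model optimizer did not converge "
            f"(method={method}, random_slopes={random_slopes}); "
            f"attempts: {attempts}")
    degenerate = float(res.scale) < 1e-10  # perfect fit: variance boundary
    if degenerate:
        log.info("residual variance at zero (data fit exactly); "
                 "fixed effects are the exact GLS solution")

    fixed: dict[str, FixedEffect] = {}
    for i, term in enumerate(FIXED_TERMS):
        est, se = float(res.fe_params[i]), float(res.bse_fe[i])
        fixed[term] = FixedEffect(est, se, est - WALD_Z * se,
                                  est + WALD_Z * se)

    rand: dict[str, dict[str, float]] = {}
    try:
        modes_by_group = dict(res.random_effects)
    except (ValueError, np.linalg.LinAlgError):
        # singular covariance: the variance sits at zero, so the
        # conditional modes are identically zero (boundary fit)
        log.info("singular random-effect covariance; conditional modes "
                 "set to zero")
        width = 2 if random_slopes else 1
        modes_by_group = {g: np.zeros(width) for g in np.unique(groups)}
    for g, modes in modes_by_group.items():
        vals = np.asarray(modes, dtype=float)
        entry = {"intercept": float(vals[0])}
        if random_slopes:
            entry["slope"] = float(vals[1])
        rand[str(g)] = entry

    scale = float(res.scale)
    cov_re = np.atleast_2d(res.cov_re.to_numpy()
                           if hasattr(res.cov_re, "to_numpy") else res.cov_re)
    vc = {"residual_var": scale,
          "intercept_var": float(cov_re[0, 0]) * 1.0}
    if random_slopes:
        vc["slope_var"] = float(cov_re[1, 1])
        vc["intercept_slope_cov"] = float(cov_re[0, 1])
    boundary = bool(np.min(np.linalg.eigvalsh(cov_re)) < 1e-10) or degenerate
    if boundary:
        log.info("random-effect covariance at the boundary (singular fit)")

    n_re_params = 3 if random_slopes else 1
    k = len(FIXED_TERMS) + n_re_params + 1  # + residual variance
    llf = float(res.llf)
    return LMMResult(fixed_effects=fixed, random_effects=rand,
                     variance_components=vc, log_likelihood=llf,
                     aic=2.0 * k - 2.0 * llf, method=method,
                     has_random_slopes=random_slopes,
                     n_obs=len(df), n_groups=len(np.unique(groups)),
                     boundary_fit=boundary)


def compare_models(table: pd.DataFrame) -> ModelComparison:
    """AIC + likelihood-ratio comparison of the two random-effect structures.

    Both models are fitted by ML on identical rows (REML log-likelihoods are
    never compared here); the LRT has 2 df (slope variance plus
    intercept-slope covariance) against a plain chi-square, conservative at
    the variance boundary.  REML refits of both models are attached for
    reporting.
    """
    ml_int = fit_lmm(table, random_slopes=False, method="ML")
    ml_slo = fit_lmm(table, random_slopes=True, method="ML")
    lrt = 2.0 * (ml_slo.log_likelihood - ml_int.log_likelihood)
    if lrt < -1e-6:
        log.warning("negative LRT statistic %.3g (optimizer tolerance); "
                    "clamped to 0", lrt)
    lrt = max(lrt, 0.0)
    df = 2
    p = float(sps.chi2.sf(lrt, df))
    return ModelComparison(
        aic_intercepts=ml_int.aic, aic_slopes=ml_slo.aic,
        lrt_statistic=lrt, lrt_df=df, lrt_p=p,
        reml_intercepts=fit_lmm(table, random_slopes=False, method="REML"),
        reml_slopes=fit_lmm(table, random_slopes=True, method="REML"))
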