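"""Group statistics on global surface metrics and clinical correlations.

Two families of analyses that sit beside the network pipeline:

* ANCOVA on the per-subject global means of each morphological parameter
  (mean cortical thickness, fractal dimension, sulcus depth,
  gyrification), with age, sex and total intracranial volume as nuisance
  covariates, followed by pairwise post-hoc t-tests on covariate-adjusted
  values (Welch by default; pooled-variance optional);
* Spearman rank correlations between morphological features and clinical
  scores (ADOS-2 and Griffiths domains), Benjamini–Hochberg corrected
  across all feature-by-scale pairs tested.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .data_io import ClinicalTable, CohortTable
from .errors import ConfigError
from .permutation_inference import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_ANCOVA_COVARIATES = ("age", "sex", "tiv")
MIN_PAIRS = 5


@dataclass
class PostHocResult:
    group_a: str
    group_b: str
    t: float
    p: float
    mean_a_adj: float
    mean_b_adj: float


@dataclass
class AncovaResult:
    """Omnibus group F-test on one global metric, plus post-hoc pairs."""

    metric: str
    f: float
    p: float
    df_num: int
    df_den: int
    covariates: tuple[str, ...]
    group_means_raw: dict[str, float]
    group_means_adjusted: dict[str, float]
    posthoc: list[PostHocResult] = field(default_factory=list)


@dataclass
class CorrelationResult:
    feature: str
    scale: str
    rho: float
    p: float
    q: float
    n: int
    insufficient: bool = False


def _design(cohort: CohortTable, covariates: tuple[str, ...]):
    """Numeric covariate columns; constant columns dropped with a warning."""
    cols, names = [], []
    for name in covariates:
        col = (cohort.sex_indicator() if name == "sex"
               else pd.to_numeric(cohort.covariates[name], errors="coerce").to_numpy())
        if not np.isfinite(col).all():
            raise ConfigError(f"covariate {name!r} has missing values")
        if np.ptp(col) == 0:
            logger.warning("covariate %r constant; dropped from ANCOVA", name)
            continue
        cols.append(col.astype(float))
        names.append(name)
    return cols, tuple(names)


def ancova_global(
    cohort: CohortTable,
    metric: str = "mean_ct",
    covariates: tuple[str, ...] = DEFAULT_ANCOVA_COVARIATES,
    posthoc: str = "welch",
    run_posthoc: bool = True,
) -> AncovaResult:
    """ANCOVA of one global metric across groups, with post-hoc t-tests.

    Fits ``metric ~ group + covariates`` by OLS and reports the partial
    F-test for the group factor.  Post-hoc comparisons are two-sided
    t-tests on covariate-adjusted values (the metric minus the fitted
    covariate contribution, covariates centered), Welch by default.
    """
    if metric not in cohort.covariates.columns:
        raise ConfigError(f"metric {metric!r} not in cohort table")
    if posthoc not in ("welch", "pooled"):
        raise ConfigError("posthoc must be 'welch' or 'pooled'")
    y = pd.to_numeric(cohort.covariates[metric], errors="coerce").to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ConfigError(f"metric {metric!r} has missing values")
    groups = cohort.groups
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    glabels = cohort.covariates["group"].to_numpy()

    cov_cols, cov_names = _design(cohort, covariates)
    # group factor as dummies against the first group
    dummies = [(glabels == g).astype(float) for g in groups[1:]]
    X_full = np.column_stack([np.ones(len(y)), *dummies, *cov_cols])
    X_reduced = np.column_stack([np.ones(len(y)), *cov_cols])
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_reduced).fit()
    df_num = len(groups) - 1
    df_den = int(full.df_resid)
    f = float((reduced.ssr - full.ssr) / df_num / (full.ssr / df_den))
    p = float(stats.f.sf(f, df_num, df_den))

    # covariate-adjusted values: subtract fitted covariate effects
    # evaluated at centered covariates
    y_adj = y.copy()
    for i, col in enumerate(cov_cols):
        beta = full.params[1 + df_num + i]
        y_adj = y_adj - beta * (col - col.mean())

    means_raw = {g: float(y[glabels == g].mean()) for g in groups}
    means_adj = {g: float(y_adj[glabels == g].mean()) for g in groups}

    ph: list[PostHocResult] = []
    if run_posthoc:
        for g_a, g_b in itertools.combinations(groups, 2):
            a, b = y_adj[glabels == g_a], y_adj[glabels == g_b]
            t, pt = stats.ttest_ind(a, b, equal_var=(posthoc == "pooled"))
            ph.append(PostHocResult(group_a=g_a, group_b=g_b,
                                    t=float(t), p=float(pt),
                                    mean_a_adj=float(a.mean()),
                                    mean_b_adj=float(b.mean())))

    return AncovaResult(metric=metric, f=f, p=p, df_num=df_num, df_den=df_den,
                        covariates=cov_names, group_means_raw=means_raw,
                        group_means_adjusted=means_adj, posthoc=ph)


def spearman_clinical(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    fdr: bool = True,
    min_pairs: int = MIN_PAIRS,
) -> list[CorrelationResult]:
    """Spearman rank correlations between features and clinical scores.

    ``features`` must carry a ``subject_id`` column plus one column per
    morphological feature.  Every feature-by-scale pair with at least
    ``min_pairs`` complete observations enters one BH-FDR family;
    sparser pairs are returned flagged ``insufficient`` with q = NaN and
    excluded from the family.
    """
    if "subject_id" not in features.columns:
        raise ConfigError("features table requires a subject_id column")
    merged = features.merge(clinical.scores, on="subject_id", how="inner")
    feat_cols = [c for c in features.columns if c != "subject_id"]
    scale_cols = [c for c in clinical.scores.columns if c != "subject_id"]

    results: list[CorrelationResult] = []
    tested_idx: list[int] = []
    for feat in feat_cols:
        for scale in scale_cols:
            sub = merged[[feat, scale]].dropna()
            n = len(sub)
            if n < min_pairs:
                results.append(CorrelationResult(
                    feature=feat, scale=scale, rho=float("nan"),
                    p=float("nan"), q=float("nan"), n=n, insufficient=True))
                continue
            rho, pval = stats.spearmanr(sub[feat], sub[scale])
            tested_idx.append(len(results))
            results.append(CorrelationResult(
                feature=feat, scale=scale, rho=float(rho), p=float(pval),
                q=float(pval), n=n))
    if fdr and tested_idx:
        qs = bh_adjust(np.array([results[i].p for i in tested_idx]))
        for i, q in zip(tested_idx, qs):
            results[i].q = float(q)
    return results


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
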