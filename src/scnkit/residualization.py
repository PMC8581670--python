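"""Nuisance-covariate removal from regional cortical thickness.

Before covariance estimation, the effect of age, sex and each subject's
overall mean cortical thickness is regressed out of every region by
ordinary least squares, and the residuals carry forward.  "Overall mean
CT" is the unweighted mean of the subject's regional values.

The regression can be fitted pooled across all subjects (default — one
model per region over the whole cohort, with group networks later built
from group subsets) or separately within each group.  Group-wise fitting
with a dozen subjects and three covariates is unstable, which is why
pooled is the default; the choice is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CohortTable
from .errors import ConfigError, DimensionError

logger = logging.getLogger(__name__)

#: Covariates removed before covariance estimation by default.
DEFAULT_COVARIATES = ("age", "sex", "mean_ct_overall")


@dataclass
class ResidualTable:
    """Subjects x regions residual CT plus the fit that produced it.

    ``values`` rows align with ``subject_ids`` / ``group_labels``;
    ``coefficients`` is (number of design columns) x regions, with
    ``design_columns`` naming the rows (intercept first).
    """

    values: np.ndarray
    subject_ids: list[str]
    group_labels: list[str]
    region_labels: list[str]
    covariates: tuple[str, ...]
    scope: str
    coefficients: np.ndarray
    design_columns: list[str]
    dropped_covariates: list[str] = field(default_factory=list)

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.group_labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.region_labels)

    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coefficients, index=self.design_columns,
                            columns=self.region_labels)


def _covariate_column(cohort: CohortTable, name: str) -> np.ndarray:
    """Resolve a covariate name to a numeric column.

    ``sex`` maps to the F=0/M=1 indicator; ``mean_ct_overall`` is the
    per-subject unweighted mean of all regional values; anything else
    must be a numeric column of the covariate table.
    """
    if name == "sex":
        return cohort.sex_indicator()
    if name == "mean_ct_overall":
        return cohort.ct_matrix().mean(axis=1)
    if name not in cohort.covariates.columns:
        raise ConfigError(f"covariate {name!r} not in cohort table")
    col = pd.to_numeric(cohort.covariates[name], errors="coerce").to_numpy()
    if not np.isfinite(col).all():
        raise ConfigError(f"covariate {name!r} has missing/non-numeric values")
    return col


def _fit_block(Y: np.ndarray, covs: dict[str, np.ndarray]):
    """OLS of every region on intercept + covariates; drops constant
    (rank-deficient) covariates with a warning instead of failing."""
    n = Y.shape[0]
    kept, dropped = [], []
    cols = [np.ones(n)]
    for name, col in covs.items():
        if np.ptp(col) == 0:
            dropped.append(name)
            logger.warning("covariate %r constant in fitted set; dropped", name)
            continue
        kept.append(name)
        cols.append(col)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid, beta, ["intercept"] + kept, dropped


def residualize(cohort: CohortTable,
                covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
                scope: str = "pooled") -> ResidualTable:
    """Regress nuisance covariates out of every region's thickness.

    Parameters
    ----------
    cohort : CohortTable
    covariates : sequence of str
        Covariate names; default ``("age", "sex", "mean_ct_overall")``.
    scope : {"pooled", "per_group"}
        Fit one model per region over all subjects (default) or refit
        within each group separately.

    Returns
    -------
    ResidualTable
        Residuals are mean-zero per region within each fitted set and
        numerically orthogonal to every retained covariate column.
    """
    if scope not in ("pooled", "per_group"):
        raise ConfigError(f"scope must be 'pooled' or 'per_group', got {scope!r}")
    covariates = tuple(covariates)
    Y = cohort.ct_matrix()
    covs = {name: _covariate_column(cohort, name) for name in covariates}
    n, p = Y.shape[0], len(covariates)

    if scope == "pooled":
        if n <= p + 1:
            raise DimensionError(f"{n} subjects cannot support {p} covariates")
        resid, beta, design_cols, dropped = _fit_block(Y, covs)
    else:
        resid = np.empty_like(Y)
        groups = cohort.groups
        betas = []
        design_cols, dropped = None, []
        for g in groups:
            mask = cohort.group_mask(g)
            ng = int(mask.sum())
            if ng <= p + 1:
                raise DimensionError(
                    f"group {g!r} has {ng} subjects; cannot fit {p} covariates")
            sub_covs = {k: v[mask] for k, v in covs.items()}
            r, b, cols_g, drop_g = _fit_block(Y[mask], sub_covs)
            resid[mask] = r
            betas.append(b)
            dropped.extend(f"{g}:{d}" for d in drop_g)
            design_cols = cols_g if design_cols is None else design_cols
        # per-group coefficients are stacked group-blockwise; keep the
        # first group's design naming (identical unless a drop differed)
        beta = np.vstack(betas)
        design_cols = [f"{g}:{c}" for g in groups for c in
                       (design_cols or ["intercept"])][: beta.shape[0]]

    return ResidualTable(
        values=resid,
        subject_ids=cohort.subject_ids,
        group_labels=list(cohort.covariates["group"]),
        region_labels=list(cohort.atlas.labels),
        covariates=covariates,
        scope=scope,
        coefficients=beta,
        design_columns=design_cols,
        dropped_covariates=dropped,
    )


def write_residuals(residuals: ResidualTable, path, coef_path=None) -> None:
    """Write residuals as TSV; optionally the fitted coefficients too."""
    residuals.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    if coef_path is not None:
        residuals.coefficients_frame().to_csv(coef_path, sep="\t",
                                              float_format="%.17g")
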