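"""Tabular input/output for regional cortical-thickness cohorts.

The on-disk representation of a cohort is a single wide delimited table:
one row per subject, a ``subject_id`` column first, the demographic
covariates (``group``, ``age``, ``sex``, ``tiv`` and optionally ``dq``),
the per-subject global surface metrics (``mean_ct``, ``fd``, ``sd``,
``gi``), and one column per atlas region holding the region's mean
cortical thickness in millimetres.  TSV is the native format; CSV is
accepted on read (the delimiter is sniffed from the header line).

Atlas regions are indexed 0-based in memory but referenced by label
everywhere on disk, so that files remain self-describing and immune to
off-by-one drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, SchemaError

logger = logging.getLogger(__name__)

#: Covariate / global-metric columns that must be present in a cohort table.
MANDATORY_COLUMNS = ("subject_id", "group", "age", "sex", "tiv",
                     "mean_ct", "fd", "sd", "gi")

#: Optional covariate columns carried through when present.
OPTIONAL_COLUMNS = ("dq",)

#: Clinical score columns (ADOS-2 domains and Griffiths developmental
#: domains).  Missing values are permitted: typically-developing controls
#: are not administered these instruments.
CLINICAL_COLUMNS = (
    "ados_severity", "ados_sa", "ados_rrb", "ados_total",
    "griffith_gross_motor", "griffith_social", "griffith_language",
    "griffith_fine_motor", "griffith_performance",
)

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass(frozen=True)
class AtlasSpec:
    """A cortical parcellation: ordered region labels plus hemisphere tags.

    Parameters
    ----------
    labels : tuple of str
        Unique region labels, in region-index order.
    hemispheres : tuple of str
        One of ``"L"``/``"R"`` per region, aligned with ``labels``.
    """

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.hemispheres):
            raise DimensionError("labels and hemispheres must align")
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError("atlas labels must be unique")
        bad = set(self.hemispheres) - {"L", "R"}
        if bad:
            raise SchemaError(f"hemisphere tags must be L or R, got {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def hemisphere_counts(self) -> dict[str, int]:
        return {h: self.hemispheres.count(h) for h in ("L", "R")}


def default_atlas(n_regions: int = 360) -> AtlasSpec:
    """Build the default symmetric atlas of ``n_regions`` regions.

    The default parcellation mirrors a 360-region multimodal cortical
    atlas with 180 regions per hemisphere; labels are synthetic
    (``L_001`` ... ``R_180``).  Real parcellation labels can be supplied
    via :func:`read_atlas` instead.
    """
    if n_regions % 2 != 0 or n_regions < 2:
        raise SchemaError("n_regions must be a positive even integer "
                          "(hemispheres split 50/50)")
    half = n_regions // 2
    width = max(3, len(str(half)))
    labels = tuple(f"{h}_{i + 1:0{width}d}" for h in ("L", "R") for i in range(half))
    hemis = tuple(h for h in ("L", "R") for _ in range(half))
    return AtlasSpec(labels=labels, hemispheres=hemis)


def read_atlas(path: str | Path) -> AtlasSpec:
    """Read an atlas from a 3-column TSV (region_id, label, hemisphere)."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "hemisphere": str})
    for col in ("region_id", "label", "hemisphere"):
        if col not in df.columns:
            raise SchemaError(f"atlas file missing column {col!r}")
    df = df.sort_values("region_id")
    if not (df["region_id"].to_numpy() == np.arange(len(df))).all():
        raise SchemaError("atlas region_id must be 0-based and contiguous")
    return AtlasSpec(labels=tuple(df["label"]), hemispheres=tuple(df["hemisphere"]))


def write_atlas(atlas: AtlasSpec, path: str | Path) -> None:
    pd.DataFrame({
        "region_id": np.arange(atlas.n_regions),
        "label": atlas.labels,
        "hemisphere": atlas.hemispheres,
    }).to_csv(path, sep="\t", index=False)


@dataclass
class CohortTable:
    """Per-subject covariates plus the subjects x regions thickness matrix.

    Attributes
    ----------
    covariates : pandas.DataFrame
        One row per subject; contains at least :data:`MANDATORY_COLUMNS`.
    thickness : pandas.DataFrame
        Regional mean cortical thickness (mm), indexed by ``subject_id``
        with one column per atlas label, aligned with ``covariates``.
    atlas : AtlasSpec
    exclusions : list of (subject_id, reason)
        Subjects dropped during read-time quality control.
    """

    covariates: pd.DataFrame
    thickness: pd.DataFrame
    atlas: AtlasSpec
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cov, thick = self.covariates, self.thickness
        missing = [c for c in MANDATORY_COLUMNS if c not in cov.columns]
        if missing:
            raise SchemaError(f"cohort table missing mandatory columns: {missing}")
        ids = cov["subject_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise SchemaError(f"duplicate subject_id values: {dups}")
        if cov["group"].isna().any():
            raise SchemaError("every subject must carry a group label")
        if list(thick.columns) != list(self.atlas.labels):
            raise DimensionError(
                "thickness columns do not match the atlas "
                f"({len(thick.columns)} columns vs {self.atlas.n_regions} regions)")
        if len(thick) != len(cov):
            raise DimensionError("thickness and covariates row counts differ")
        vals = thick.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise SchemaError("regional CT values must be finite and positive")

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.covariates["subject_id"])

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.covariates["group"]))

    def group_mask(self, group: str) -> np.ndarray:
        return (self.covariates["group"] == group).to_numpy()

    def ct_matrix(self) -> np.ndarray:
        """Subjects x regions thickness matrix as a float array."""
        return self.thickness.to_numpy(dtype=float)

    def sex_indicator(self) -> np.ndarray:
        """Sex as a regression indicator: F=0, M=1."""
        return (self.covariates["sex"] == "M").to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    """ADOS-2 and Griffiths scores per subject; missing values permitted."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if "subject_id" not in self.scores.columns:
            raise SchemaError("clinical table requires a subject_id column")
        ids = self.scores["subject_id"]
        if ids.duplicated().any():
            raise SchemaError("duplicate subject_id in clinical table")

    def validate_against(self, cohort: CohortTable) -> None:
        unknown = set(self.scores["subject_id"]) - set(cohort.subject_ids)
        if unknown:
            raise SchemaError(
                f"clinical subjects absent from cohort: {sorted(unknown)}")

    def missingness(self) -> pd.Series:
        """Fraction of missing values per score column (flagged, not fatal)."""
        cols = [c for c in self.scores.columns if c != "subject_id"]
        return self.scores[cols].isna().mean()


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    sep = "\t" if "\t" in header else ","
    if sep == ",":
        logger.info("delimiter sniffed as comma for %s", path)
    return sep


def read_cohort(path: str | Path, atlas: AtlasSpec) -> CohortTable:
    """Read and validate a cohort table.

    Subjects with any non-finite or non-positive regional CT value are
    excluded (mirroring image-quality exclusion in real studies); each
    exclusion is logged and recorded on the returned table.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    DimensionError
        If the region columns do not match the atlas.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"subject_id": str},
                     float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing columns: {missing}")
    absent_regions = [lab for lab in atlas.labels if lab not in df.columns]
    if absent_regions:
        raise DimensionError(
            f"cohort file has {len(atlas.labels) - len(absent_regions)} of "
            f"{atlas.n_regions} atlas regions; first missing: {absent_regions[0]}")

    thick = df[list(atlas.labels)].apply(pd.to_numeric, errors="coerce")
    vals = thick.to_numpy(dtype=float)
    bad = ~np.isfinite(vals).all(axis=1) | (np.nan_to_num(vals, nan=1.0) <= 0).any(axis=1)
    exclusions: list[tuple[str, str]] = []
    if bad.any():
        for sid in df.loc[bad, "subject_id"]:
            exclusions.append((sid, "non-finite or non-positive regional CT"))
            logger.warning("excluding subject %s: bad regional CT", sid)
        df = df.loc[~bad].reset_index(drop=True)
        thick = thick.loc[~bad].reset_index(drop=True)

    keep = [c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    cov = df[keep].copy()
    thick.index = pd.Index(cov["subject_id"], name="subject_id")
    return CohortTable(covariates=cov, thickness=thick, atlas=atlas,
                       exclusions=exclusions)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as one wide TSV; numeric values round-trip exactly."""
    wide = pd.concat(
        [cohort.covariates.reset_index(drop=True),
         cohort.thickness.reset_index(drop=True)], axis=1)
    wide.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"subject_id": str},
                     float_precision="round_trip")
    return ClinicalTable(scores=df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.scores.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
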