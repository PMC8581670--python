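"""Build group structural covariance networks from residual thickness.

One network per group: Pearson correlation between every pair of regional
residual-CT vectors across the group's subjects, then thresholding to a
fixed edge density (default 15% of all region pairs) and binarizing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ConfigError, DimensionError, StructuralInputError

logger = logging.getLogger(__name__)

#: Edge density used throughout: fraction of the N(N-1)/2 possible region
#: pairs retained as network edges.
DEFAULT_SPARSITY = 0.15


@dataclass(frozen=True)
class GroupCovarianceMatrix:
    """Symmetric N x N Pearson correlation matrix for one group."""

    group: str
    matrix: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        M = self.matrix
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise DimensionError("correlation matrix must be square")
        if not np.allclose(M, M.T, atol=1e-12):
            raise StructuralInputError("correlation matrix must be symmetric")
        if not np.allclose(np.diagonal(M), 1.0):
            raise StructuralInputError("correlation matrix diagonal must be 1")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Sparsified, binarized adjacency at a stated edge density."""

    group: str
    adjacency: np.ndarray
    sparsity: float

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]


def pearson_matrix(residuals: np.ndarray, on_constant: str = "zero") -> np.ndarray:
    """Pearson r between all column pairs of a subjects x regions matrix.

    A region that is constant across subjects has undefined correlations;
    its row/column is set to 0 with a warning (``on_constant="zero"``,
    the default) or raises (``on_constant="raise"``).
    """
    X = np.asarray(residuals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise DimensionError("need a subjects x regions matrix with >= 3 subjects")
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        if on_constant == "raise":
            raise StructuralInputError(
                f"{int(constant.sum())} region(s) constant across subjects")
        logger.warning("%d degenerate (constant) region(s); correlations set to 0",
                       int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    # exact symmetry for downstream invariant checks
    C = (C + C.T) / 2.0
    np.clip(C, -1.0, 1.0, out=C)
    return C


def covariance_matrix(residuals, group: str,
                      on_constant: str = "zero") -> GroupCovarianceMatrix:
    """Group structural covariance matrix from a residual table.

    Parameters
    ----------
    residuals : ResidualTable
        Output of :func:`scnkit.residualization.residualize`.
    group : str
        Group label; the correlation is computed over that group's
        subjects only.
    """
    mask = residuals.group_mask(group)
    n = int(mask.sum())
    if n < 3:
        raise DimensionError(f"group {group!r} has {n} subjects; need >= 3")
    C = pearson_matrix(residuals.values[mask], on_constant=on_constant)
    return GroupCovarianceMatrix(group=group, matrix=C, n_subjects=n)


@lru_cache(maxsize=8)
def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def edge_count_for(n_regions: int, sparsity: float) -> int:
    """Number of edges retained at a given density: round(s * N(N-1)/2)."""
    return int(round(sparsity * n_regions * (n_regions - 1) / 2))


def threshold_matrix(C: np.ndarray, sparsity: float,
                     edge_rule: str = "signed") -> np.ndarray:
    """Binarize a correlation matrix at a fixed edge density.

    Ranks the upper-triangle entries by r (``edge_rule="signed"``,
    default: the most positive correlations win) or by \\|r\\|
    (``"absolute"``) and keeps the top ``round(sparsity * N(N-1)/2)`` as
    edges.  Exact ties at the cutoff are broken by lexicographic
    ``(i, j)`` region-index order so results are fully deterministic.
    """
    if not 0 < sparsity < 1:
        raise ConfigError(f"sparsity must be in (0, 1), got {sparsity}")
    if edge_rule not in ("signed", "absolute"):
        raise ConfigError(f"unknown edge_rule {edge_rule!r}")
    n = C.shape[0]
    k = edge_count_for(n, sparsity)
    if k < 1:
        raise ConfigError(f"sparsity {sparsity} retains 0 of "
                          f"{n * (n - 1) // 2} edges")
    ii, jj = _triu_indices(n)
    r = C[ii, jj]
    score = np.abs(r) if edge_rule == "absolute" else r
    # primary key: score descending; ties: (i, j) ascending
    order = np.lexsort((jj, ii, -score))
    top = order[:k]
    A = np.zeros((n, n), dtype=np.uint8)
    A[ii[top], jj[top]] = 1
    A |= A.T
    return A


def sparsify_binarize(cov: GroupCovarianceMatrix, sparsity: float = DEFAULT_SPARSITY,
                      edge_rule: str = "signed") -> BinaryNetwork:
    """Threshold a group covariance matrix into a binary network."""
    A = threshold_matrix(cov.matrix, sparsity, edge_rule=edge_rule)
    return BinaryNetwork(group=cov.group, adjacency=A, sparsity=sparsity)
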