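"""Synthetic multi-group cortical-thickness cohorts with planted structure.

The real study population (a monogenic SHANK3-deficient autism group, an
idiopathic autism group and typically developing controls, 12/24/25
subjects after quality control) has no deposited regional data, so every
downstream stage is exercised against cohorts generated here with a known
ground truth:

* each group's regional thickness is drawn from a multivariate normal
  whose covariance is built from a *planted* graph — a ring lattice for
  the regular-shifted group, Watts–Strogatz-style small-world graphs for
  the others — so network-recovery can be scored exactly;
* linear age, sex and intracranial-volume effects are added on top, so
  residualization has real work to do;
* clinical scores (ADOS-2 and Griffiths developmental domains, plus a
  general developmental quotient) are monotone transforms of a latent
  variable correlated with one designated region's thickness, giving the
  Spearman stage a known rank signal.

The planted covariance is ``Sigma = delta*I + rho*A`` with
``delta = rho * max_degree + noise_sd**2``: diagonally dominant by
construction (Gershgorin), hence positive definite with no eigenvalue
repair needed.  The pairwise correlation on a planted edge is
``rho / delta <= 1 / max_degree``, so denser planted graphs necessarily
carry weaker edge-level signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import CLINICAL_COLUMNS, AtlasSpec, ClinicalTable, CohortTable, default_atlas
from .errors import ConfigError, StructuralInputError
from .graph_metrics import validate_adjacency

GRAPH_FAMILIES = ("lattice", "small_world", "erdos_renyi")

#: Group means/SDs of the global surface metrics emulated per group:
#: fractal dimension (unitless), sulcus depth (mm), gyrification (deg).
_GLOBAL_METRIC_PARAMS = {
    "fd": {"SHANK3": (2.64, 0.34), "ASD": (2.66, 0.35), "TD": (2.65, 0.35)},
    "sd": {"SHANK3": (2.86, 0.77), "ASD": (2.89, 0.85), "TD": (2.90, 0.85)},
    "gi": {"SHANK3": (27.29, 0.50), "ASD": (27.19, 0.45), "TD": (27.28, 0.46)},
}

#: Output range (lo, hi) and link sign of each simulated clinical scale.
#: ADOS scores rise with severity (negative link to development);
#: Griffiths quotients rise with ability (positive link).
_CLINICAL_SCALES = {
    "ados_severity": (1.0, 10.0, -1.0),
    "ados_sa": (1.0, 22.0, -1.0),
    "ados_rrb": (0.0, 8.0, -1.0),
    "ados_total": (2.0, 28.0, -1.0),
    "griffith_gross_motor": (10.0, 110.0, 1.0),
    "griffith_social": (10.0, 110.0, 1.0),
    "griffith_language": (5.0, 100.0, 1.0),
    "griffith_fine_motor": (10.0, 105.0, 1.0),
    "griffith_performance": (10.0, 110.0, 1.0),
}


@dataclass(frozen=True)
class TopologySpec:
    """Ground-truth graph family for one group's planted network.

    ``k`` is the (even) lattice neighbour count, ``beta`` the rewiring
    probability for the small-world family, ``p`` the edge probability
    for the uniform-random family.
    """

    family: str
    k: int = 10
    beta: float = 0.2
    p: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in GRAPH_FAMILIES:
            raise ConfigError(
                f"unknown graph family {self.family!r}; choose from {GRAPH_FAMILIES}")


@dataclass(frozen=True)
class ClinicalLink:
    """Monotone link between one region's thickness and clinical scores.

    ``latent_r`` is the correlation between the standardized region value
    and the latent severity variable from which every scale is produced
    by a strictly increasing (sigmoidal) transform.  Because Spearman
    correlation is invariant under monotone maps, the expected observed
    rank correlation is ``(6/pi) * arcsin(latent_r / 2)``; the default
    0.62 therefore targets a rank correlation near 0.6.
    """

    region: int = 0
    latent_r: float = 0.62

    def __post_init__(self) -> None:
        if not 0 <= self.latent_r < 1:
            raise ConfigError("latent_r must be in [0, 1)")


def _default_group_sizes() -> dict[str, int]:
    return {"SHANK3": 12, "ASD": 24, "TD": 25}


def _default_topology() -> dict[str, TopologySpec]:
    # the monogenic group's network is planted regular (lattice); the
    # other two are small-world at increasing rewiring probability
    return {
        "SHANK3": TopologySpec("lattice", k=10),
        "ASD": TopologySpec("small_world", k=10, beta=0.2),
        "TD": TopologySpec("small_world", k=10, beta=0.3),
    }


def _default_betas() -> dict[str, float]:
    # mm per year, mm for male sex, mm per mm^3 of intracranial volume
    return {"age": -0.02, "sex": 0.01, "tiv": 1.0e-8}


def _default_ct_shift() -> dict[str, float]:
    # group offsets (mm) relative to baseline, emulating the reported
    # global means 2.96 / 2.58 / 2.81 mm
    return {"SHANK3": 0.15, "ASD": -0.23, "TD": 0.0}


def _default_sex_ratio() -> dict[str, float]:
    # male fraction per group (6:6, 20:4, 19:6)
    return {"SHANK3": 6 / 12, "ASD": 20 / 24, "TD": 19 / 25}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a simulated cohort.

    Defaults reproduce the emulated study conditions: three groups of
    12/24/25 subjects, 360 regions (180 per hemisphere), ages 2-8 years,
    regular vs. small-world planted topology, and a clinical link
    targeting a rank correlation near 0.6.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    n_regions: int = 360
    topology: dict[str, TopologySpec] = field(default_factory=_default_topology)
    edge_coupling: float = 0.02       # rho: covariance weight per planted edge
    noise_sd: float = 0.35            # per-region independent noise (mm)
    global_sd: float = 0.45           # per-subject global thickness factor (mm)
    covariate_betas: dict[str, float] = field(default_factory=_default_betas)
    baseline_ct: float = 2.81         # mm
    group_ct_shift: dict[str, float] = field(default_factory=_default_ct_shift)
    age_range: tuple[float, float] = (2.0, 8.0)
    sex_ratio: dict[str, float] = field(default_factory=_default_sex_ratio)
    tiv_mean: float = 1.35e6          # mm^3
    tiv_sd: float = 1.2e5
    clinical_link: ClinicalLink = field(default_factory=ClinicalLink)
    clinical_groups: tuple[str, ...] = ("SHANK3", "ASD")
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 3:
                raise ConfigError(f"group {g!r} size {n} < 3; correlations degenerate")
        if self.n_regions % 2 != 0 or self.n_regions < 4:
            raise ConfigError("n_regions must be even (hemisphere split) and >= 4")
        if self.edge_coupling <= 0:
            raise ConfigError("edge_coupling (rho) must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        missing = set(self.group_sizes) - set(self.topology)
        if missing:
            raise ConfigError(f"groups without a topology spec: {sorted(missing)}")
        if not 0 <= self.clinical_link.region < self.n_regions:
            raise ConfigError("clinical link region index out of range")

    def to_dict(self) -> dict:
        return {
            "group_sizes": dict(self.group_sizes),
            "n_regions": self.n_regions,
            "topology": {g: vars(t).copy() for g, t in self.topology.items()},
            "edge_coupling": self.edge_coupling,
            "noise_sd": self.noise_sd,
            "global_sd": self.global_sd,
            "covariate_betas": dict(self.covariate_betas),
            "baseline_ct": self.baseline_ct,
            "group_ct_shift": dict(self.group_ct_shift),
            "age_range": list(self.age_range),
            "sex_ratio": dict(self.sex_ratio),
            "tiv_mean": self.tiv_mean,
            "tiv_sd": self.tiv_sd,
            "clinical_link": vars(self.clinical_link).copy(),
            "clinical_groups": list(self.clinical_groups),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "topology" in d:
            d["topology"] = {g: TopologySpec(**t) for g, t in d["topology"].items()}
        if "clinical_link" in d:
            d["clinical_link"] = ClinicalLink(**d["clinical_link"])
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "clinical_groups" in d:
            d["clinical_groups"] = tuple(d["clinical_groups"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    adjacency: dict[str, np.ndarray]
    covariance: dict[str, np.ndarray]
    covariate_betas: dict[str, float]
    clinical_link: ClinicalLink
    seed: int


def make_reference_graph(family: str, n: int, k: int = 10, beta: float = 0.2,
                         p: float = 0.1, seed=None) -> np.ndarray:
    """Planted-topology generator: ring lattice, small-world rewire of a
    lattice (edge count conserved), or uniform random graph.

    Returns a symmetric hollow 0/1 adjacency matrix.
    """
    if family not in GRAPH_FAMILIES:
        raise ConfigError(f"unknown graph family {family!r}")
    if n < 4:
        raise ConfigError("need n >= 4 nodes")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if family in ("lattice", "small_world"):
        if k % 2 != 0 or not 0 < k < n:
            raise ConfigError(f"lattice k must be even and in (0, n); got k={k}, n={n}")
        beta_eff = 0.0 if family == "lattice" else beta
        G = nx.watts_strogatz_graph(n, k, beta_eff,
                                    seed=int(rng.integers(2**31)))
    else:
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    A = nx.to_numpy_array(G, nodelist=range(n), dtype=np.uint8)
    np.fill_diagonal(A, 0)
    return A


def build_planted_covariance(adjacency: np.ndarray, rho: float,
                             noise_sd: float) -> np.ndarray:
    """Positive-definite covariance with correlation only on planted edges.

    ``Sigma = delta*I + rho*A`` with ``delta = rho*max_degree +
    noise_sd**2``.  Every Gershgorin disc then lies strictly in the
    positive half-line, so the matrix is positive definite without any
    eigenvalue surgery.
    """
    if rho <= 0:
        raise StructuralInputError("rho must be positive")
    A = validate_adjacency(adjacency).astype(float)
    max_deg = float(A.sum(axis=1).max()) if A.size else 0.0
    delta = rho * max_deg + noise_sd**2
    sigma = delta * np.eye(A.shape[0]) + rho * A
    return sigma


def edge_recovery(estimated: np.ndarray, planted: np.ndarray) -> dict[str, float]:
    """Precision/recall of an estimated edge set against the planted one."""
    E = validate_adjacency(estimated).astype(bool)
    P = validate_adjacency(planted).astype(bool)
    iu = np.triu_indices(E.shape[0], k=1)
    e, p = E[iu], P[iu]
    tp = int((e & p).sum())
    precision = tp / max(int(e.sum()), 1)
    recall = tp / max(int(p.sum()), 1)
    return {"precision": precision, "recall": recall, "true_positives": tp}


def _clinical_scores(region_values: np.ndarray, link: ClinicalLink,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Monotone (rank-preserving sigmoidal) clinical scores.

    The latent severity variable is ``latent_r * z + sqrt(1-latent_r^2) * eps``
    with ``z`` the standardized designated-region thickness; each scale is
    a strictly increasing map of its own latent draw, so ranks — hence
    Spearman correlations — carry the planted signal exactly.
    """
    z = region_values - region_values.mean()
    sd = z.std()
    z = z / sd if sd > 0 else z
    r = link.latent_r
    out = {}
    for name, (lo, hi, sign) in _CLINICAL_SCALES.items():
        eps = rng.standard_normal(z.size)
        latent = r * sign * z + np.sqrt(1 - r**2) * eps
        out[name] = lo + (hi - lo) * expit(1.2 * latent)
    return pd.DataFrame(out)


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[CohortTable, ClinicalTable, GroundTruth]:
    """Draw a full synthetic cohort.

    Fully reproducible: the configured seed deterministically spawns
    independent substreams for graph construction, subject sampling and
    clinical noise.  Returns the cohort table, the clinical table
    (scores only for the configured clinical groups; missing — and
    flagged as such — elsewhere) and the planted ground truth.
    """
    atlas: AtlasSpec = default_atlas(config.n_regions)
    ss = np.random.SeedSequence(config.seed)
    graph_rng, subject_rng, clinical_rng = (np.random.default_rng(s)
                                            for s in ss.spawn(3))

    adjacency: dict[str, np.ndarray] = {}
    covariance: dict[str, np.ndarray] = {}
    cov_rows, thick_rows, ids = [], [], []
    age_ref = sum(config.age_range) / 2

    for group, n_g in config.group_sizes.items():
        topo = config.topology[group]
        A = make_reference_graph(topo.family, config.n_regions, k=topo.k,
                                 beta=topo.beta, p=topo.p, seed=graph_rng)
        sigma = build_planted_covariance(A, config.edge_coupling, config.noise_sd)
        adjacency[group] = A
        covariance[group] = sigma

        signal = subject_rng.multivariate_normal(
            np.zeros(config.n_regions), sigma, size=n_g, method="cholesky")
        # a per-subject global thickness factor: the shared variance the
        # "overall mean CT" nuisance covariate exists to remove
        global_factor = subject_rng.normal(0.0, config.global_sd, size=n_g)
        age = subject_rng.uniform(*config.age_range, size=n_g)
        sex = (subject_rng.random(n_g) < config.sex_ratio.get(group, 0.5)).astype(int)
        tiv = subject_rng.normal(config.tiv_mean, config.tiv_sd, size=n_g)
        b = config.covariate_betas
        ct = (config.baseline_ct
              + config.group_ct_shift.get(group, 0.0)
              + b.get("age", 0.0) * (age - age_ref)[:, None]
              + b.get("sex", 0.0) * sex[:, None]
              + b.get("tiv", 0.0) * (tiv - config.tiv_mean)[:, None]
              + global_factor[:, None]
              + signal)
        ct = np.maximum(ct, 0.05)  # thickness is physically positive

        gm = {}
        for metric, params in _GLOBAL_METRIC_PARAMS.items():
            mu, sdv = params.get(group, params["TD"])
            gm[metric] = np.maximum(
                subject_rng.normal(mu, sdv, size=n_g), 0.05)

        sids = [f"{group}_{i + 1:03d}" for i in range(n_g)]
        ids.extend(sids)
        thick_rows.append(ct)
        cov_rows.append(pd.DataFrame({
            "subject_id": sids,
            "group": group,
            "age": age,
            "sex": np.where(sex == 1, "M", "F"),
            "tiv": tiv,
            "mean_ct": ct.mean(axis=1),
            "fd": gm["fd"],
            "sd": gm["sd"],
            "gi": gm["gi"],
        }))

    covdf = pd.concat(cov_rows, ignore_index=True)
    thickness = pd.DataFrame(np.vstack(thick_rows),
                             index=pd.Index(ids, name="subject_id"),
                             columns=atlas.labels)

    # clinical scores + developmental quotient for the clinical groups only
    clin_mask = covdf["group"].isin(config.clinical_groups).to_numpy()
    dq = np.full(len(covdf), np.nan)
    if clin_mask.any():
        region_vals = thickness.to_numpy()[clin_mask, config.clinical_link.region]
        scores = _clinical_scores(region_vals, config.clinical_link, clinical_rng)
        scores.insert(0, "subject_id",
                      covdf.loc[clin_mask, "subject_id"].to_numpy())
        # DQ shares the scores' latent construction: increasing in development
        z = region_vals - region_vals.mean()
        z = z / z.std() if z.std() > 0 else z
        eps = clinical_rng.standard_normal(z.size)
        r = config.clinical_link.latent_r
        dq[clin_mask] = 20.0 + 90.0 * expit(
            1.2 * (r * z + np.sqrt(1 - r**2) * eps))
    else:
        scores = pd.DataFrame(
            {"subject_id": pd.Series(dtype=str),
             **{c: pd.Series(dtype=float) for c in CLINICAL_COLUMNS}})
    covdf["dq"] = dq

    cohort = CohortTable(covariates=covdf, thickness=thickness, atlas=atlas)
    clinical = ClinicalTable(scores=scores.reset_index(drop=True))
    truth = GroundTruth(adjacency=adjacency, covariance=covariance,
                        covariate_betas=dict(config.covariate_betas),
                        clinical_link=config.clinical_link, seed=config.seed)
    return cohort, clinical, truth


def write_ground_truth(truth: GroundTruth, json_path: str | Path,
                       edges_path: str | Path | None = None) -> None:
    """Persist the planted structure: summary JSON + TSV edge lists."""
    payload = {
        "seed": truth.seed,
        "covariate_betas": truth.covariate_betas,
        "clinical_link": vars(truth.clinical_link).copy(),
        "groups": {
            g: {"n_regions": int(A.shape[0]), "n_edges": int(A.sum()) // 2}
            for g, A in truth.adjacency.items()
        },
    }
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n",
                               encoding="utf-8")
    if edges_path is not None:
        rows = []
        for g, A in truth.adjacency.items():
            ii, jj = np.nonzero(np.triu(A, 1))
            rows.append(pd.DataFrame({"group": g, "region_i": ii, "region_j": jj}))
        pd.concat(rows, ignore_index=True).to_csv(edges_path, sep="\t", index=False)
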