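"""End-to-end orchestration: simulate/load -> residualize -> networks ->
metrics -> permutation inference -> morphometry statistics -> report.

A run writes everything under one output directory: the input tables (or
the simulated stand-ins), per-stage TSV/JSON artifacts, a plain-text
report, a log, and a machine-readable ``manifest.json`` with the config
echo, package version, seeds and SHA-256 hashes of every written file.
Given a fixed seed the run directory is byte-for-byte reproducible (the
log format carries no timestamps for exactly that reason).

A single master seed deterministically spawns per-stage substreams, so
stages can be re-run in isolation with identical randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, data_io, graph_metrics, morphometry_stats
from . import permutation_inference as pi
from . import residualization, scn_construction
from .errors import ConfigError, ScnkitError
from .synthetic_cohort import SyntheticConfig, generate_cohort, write_ground_truth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one full analysis run.

    Defaults follow the study conventions: 15% sparsity, K = 1,000
    permutation replicates with the 95th-percentile one-tailed critical
    value at alpha = 0.05, 100 rewired networks in the normalization
    ensemble, and a 360-region atlas.
    """

    cohort_path: str | None = None
    clinical_path: str | None = None
    atlas_path: str | None = None
    simulation: SyntheticConfig | None = None
    sparsity: float = scn_construction.DEFAULT_SPARSITY
    edge_rule: str = "signed"
    k_permutations: int = pi.DEFAULT_K
    n_random: int = graph_metrics.DEFAULT_N_RANDOM
    alpha: float = pi.DEFAULT_ALPHA
    residual_covariates: tuple[str, ...] = residualization.DEFAULT_COVARIATES
    residual_scope: str = "pooled"
    permutation_metrics: tuple[str, ...] = ("global_efficiency", "local_efficiency")
    tails: dict[str, str] = field(default_factory=dict)
    ancova_metrics: tuple[str, ...] = ("mean_ct", "fd", "sd", "gi")
    ancova_covariates: tuple[str, ...] = morphometry_stats.DEFAULT_ANCOVA_COVARIATES
    correlation_features: tuple[str, ...] = ("mean_ct", "fd", "sd", "gi")
    seed: int = 0
    out_dir: str = "scn_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SyntheticConfig.from_dict(d["simulation"])
        for key in ("residual_covariates", "permutation_metrics",
                    "ancova_metrics", "ancova_covariates",
                    "correlation_features"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        for key in ("residual_covariates", "permutation_metrics",
                    "ancova_metrics", "ancova_covariates",
                    "correlation_features"):
            d[key] = list(d[key])
        return d


class PipelineStageError(ScnkitError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_run_logging(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    # no timestamps: keeps repeat runs byte-identical
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("scnkit")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def _load_inputs(config: RunConfig, out: Path, rng_seed: int):
    if config.cohort_path is not None:
        atlas = (data_io.read_atlas(config.atlas_path)
                 if config.atlas_path else data_io.default_atlas())
        cohort = data_io.read_cohort(config.cohort_path, atlas)
        clinical = (data_io.read_clinical(config.clinical_path)
                    if config.clinical_path else None)
        truth = None
    else:
        sim = config.simulation or SyntheticConfig(seed=rng_seed)
        if config.simulation is None:
            logger.info("no input paths given; simulating the default cohort")
        cohort, clinical, truth = generate_cohort(sim)
        data_io.write_cohort(cohort, out / "cohort.tsv")
        data_io.write_clinical(clinical, out / "clinical.tsv")
        data_io.write_atlas(cohort.atlas, out / "atlas.tsv")
        write_ground_truth(truth, out / "ground_truth.json",
                           out / "ground_truth_edges.tsv")
    if clinical is not None:
        clinical.validate_against(cohort)
    return cohort, clinical, truth


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure aborts with :class:`PipelineStageError` naming the
    stage; the partial manifest records the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out)
    manifest: dict = {
        "package": "scnkit",
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    ss = np.random.SeedSequence(config.seed)
    sim_seed, metrics_ss, perm_ss = ss.spawn(3)
    stage = "inputs"
    try:
        cohort, clinical, _truth = _load_inputs(
            config, out, int(sim_seed.generate_state(1)[0] % 2**31))
        manifest["stages"]["inputs"] = {
            "n_subjects": cohort.n_subjects,
            "groups": {g: int(cohort.group_mask(g).sum()) for g in cohort.groups},
            "n_regions": cohort.atlas.n_regions,
            "excluded": cohort.exclusions,
        }

        stage = "residualization"
        resid = residualization.residualize(
            cohort, config.residual_covariates, scope=config.residual_scope)
        residualization.write_residuals(resid, out / "residuals.tsv",
                                        out / "residual_coefficients.tsv")
        manifest["stages"]["residualization"] = {
            "covariates": list(resid.covariates),
            "scope": resid.scope,
            "dropped": resid.dropped_covariates,
        }

        stage = "networks"
        networks = {}
        for g in cohort.groups:
            cov = scn_construction.covariance_matrix(resid, g)
            net = scn_construction.sparsify_binarize(cov, config.sparsity,
                                                     config.edge_rule)
            networks[g] = net
            labels = list(cohort.atlas.labels)
            pd.DataFrame(cov.matrix, index=labels, columns=labels).to_csv(
                out / f"covariance_{g}.tsv", sep="\t", float_format="%.17g")
            ii, jj = np.nonzero(np.triu(net.adjacency, 1))
            pd.DataFrame({
                "label_i": [labels[i] for i in ii],
                "label_j": [labels[j] for j in jj],
                "r": cov.matrix[ii, jj],
            }).to_csv(out / f"network_{g}_edges.tsv", sep="\t", index=False,
                      float_format="%.17g")
        manifest["stages"]["networks"] = {
            g: {"n_edges": n.n_edges, "sparsity": n.sparsity,
                "edge_rule": config.edge_rule}
            for g, n in networks.items()}

        stage = "graph_metrics"
        metric_rows = []
        metrics_by_group = {}
        for g, child in zip(cohort.groups, metrics_ss.spawn(len(cohort.groups))):
            m = graph_metrics.normalized_efficiencies(
                networks[g].adjacency, n_random=config.n_random,
                seed=np.random.default_rng(child))
            metrics_by_group[g] = m
            (out / f"metrics_{g}.json").write_text(
                json.dumps(m.as_dict(), indent=2) + "\n", encoding="utf-8")
            for name in ("ge", "le", "nge", "nle"):
                metric_rows.append({"group": g, "metric": name,
                                    "value": getattr(m, name)})
        pd.DataFrame(metric_rows).to_csv(out / "metrics.tsv", sep="\t",
                                         index=False, float_format="%.17g")
        deg = pd.DataFrame({g: m.degree for g, m in metrics_by_group.items()},
                           index=pd.Index(cohort.atlas.labels, name="label"))
        deg.to_csv(out / "degree.tsv", sep="\t")
        manifest["stages"]["graph_metrics"] = {
            g: {k: v for k, v in m.as_dict().items() if k != "degree"}
            for g, m in metrics_by_group.items()}

        stage = "permutation_inference"
        pairs = [(a, b) for i, a in enumerate(cohort.groups)
                 for b in cohort.groups[i + 1:]]
        perm_rows = []
        perm_children = iter(perm_ss.spawn(len(pairs) * (len(config.permutation_metrics) + 1)))
        for pair in pairs:
            for metric in config.permutation_metrics:
                res = pi.permute_metric(
                    resid, pair, metric=metric, k=config.k_permutations,
                    sparsity=config.sparsity, tail=config.tails.get(metric),
                    seed=np.random.default_rng(next(perm_children)),
                    edge_rule=config.edge_rule, alpha=config.alpha)
                perm_rows.append(res.as_dict())
            nodal = pi.permute_nodal_degree(
                resid, pair, k=config.k_permutations, sparsity=config.sparsity,
                seed=np.random.default_rng(next(perm_children)),
                edge_rule=config.edge_rule, alpha=config.alpha)
            pd.DataFrame({
                "label": nodal.region_labels,
                "observed_diff": nodal.observed,
                "p": nodal.p,
                "q": nodal.q,
                "significant": nodal.significant,
            }).to_csv(out / f"nodal_degree_{pair[0]}_vs_{pair[1]}.tsv",
                      sep="\t", index=False, float_format="%.17g")
        pd.DataFrame([{k: (",".join(v) if isinstance(v, list) else v)
                       for k, v in row.items()} for row in perm_rows]
                     ).to_csv(out / "permutation.tsv", sep="\t", index=False,
                              float_format="%.17g")
        manifest["stages"]["permutation_inference"] = {
            "k": config.k_permutations,
            "critical_percentile": pi.CRITICAL_PERCENTILE,
            "results": perm_rows,
        }

        stage = "morphometry_stats"
        anc_rows = []
        for metric in config.ancova_metrics:
            res = morphometry_stats.ancova_global(
                cohort, metric, covariates=config.ancova_covariates)
            anc_rows.append({"metric": metric, "F": res.f, "p": res.p,
                             "df_num": res.df_num, "df_den": res.df_den})
            for phr in res.posthoc:
                anc_rows.append({"metric": f"{metric}:{phr.group_a}-vs-{phr.group_b}",
                                 "F": phr.t, "p": phr.p,
                                 "df_num": np.nan, "df_den": np.nan})
        pd.DataFrame(anc_rows).to_csv(out / "ancova.tsv", sep="\t", index=False,
                                      float_format="%.17g")
        corr_results = []
        if clinical is not None:
            feats = cohort.covariates[["subject_id",
                                       *config.correlation_features]].copy()
            corr_results = morphometry_stats.spearman_clinical(feats, clinical)
            morphometry_stats.correlations_frame(corr_results).to_csv(
                out / "correlations.tsv", sep="\t", index=False,
                float_format="%.17g")
        manifest["stages"]["morphometry_stats"] = {
            "ancova_metrics": list(config.ancova_metrics),
            "n_correlations": len(corr_results),
        }

        stage = "report"
        report = _render_report(cohort, networks, metrics_by_group,
                                perm_rows, anc_rows, corr_results, config)
        (out / "report.txt").write_text(report, encoding="utf-8")

    except Exception as err:
        manifest["error"] = {"stage": stage, "message": str(err),
                             "type": type(err).__name__}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8")
        logging.getLogger("scnkit").removeHandler(handler)
        handler.close()
        if isinstance(err, ScnkitError):
            raise
        raise PipelineStageError(stage, err) from err

    logging.getLogger("scnkit").removeHandler(handler)
    handler.close()
    manifest["files"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8")
    return out


def _render_report(cohort, networks, metrics_by_group, perm_rows, anc_rows,
                   corr_results, config: RunConfig) -> str:
    lines = ["Structural covariance network analysis", "=" * 40, ""]
    lines.append(f"Subjects: {cohort.n_subjects} in groups "
                 + ", ".join(f"{g} (n={int(cohort.group_mask(g).sum())})"
                             for g in cohort.groups))
    lines.append(f"Atlas: {cohort.atlas.n_regions} regions "
                 f"({cohort.atlas.hemisphere_counts()['L']} per hemisphere)")
    lines.append("")
    lines.append(f"Networks at sparsity {config.sparsity:g} "
                 f"({config.edge_rule} thresholding):")
    for g, net in networks.items():
        lines.append(f"  {g}: {net.n_edges} edges")
    lines.append("")
    lines.append(f"Efficiency metrics (null ensemble of {config.n_random} "
                 "degree-preserving rewirings):")
    for g, m in metrics_by_group.items():
        lines.append(f"  {g}: GE={m.ge:.4f} LE={m.le:.4f} "
                     f"nGE={m.nge:.4f} nLE={m.nle:.4f} "
                     f"small-world={m.small_world}")
        top = np.argsort(m.degree)[::-1][:5]
        hubs = ", ".join(f"{cohort.atlas.labels[i]}({m.degree[i]})" for i in top)
        lines.append(f"    top hubs: {hubs}")
    lines.append("")
    lines.append(f"Permutation tests (K={config.k_permutations}, one-tailed, "
                 f"critical = {pi.CRITICAL_PERCENTILE}th percentile, "
                 f"alpha={config.alpha:g}):")
    for row in perm_rows:
        lines.append(f"  {row['groups'][0]} vs {row['groups'][1]} "
                     f"{row['metric']}: diff={row['observed']:+.4f} "
                     f"crit={row['critical']:+.4f} p={row['p']:.4g} "
                     f"tail={row['tail']} "
                     f"{'SIGNIFICANT' if row['significant'] else 'ns'}")
    lines.append("")
    lines.append("ANCOVA on global metrics "
                 f"(covariates: {', '.join(config.ancova_covariates)}):")
    for row in anc_rows:
        if np.isnan(row.get("df_num", np.nan)):
            lines.append(f"    post-hoc {row['metric']}: t={row['F']:.3f} "
                         f"p={row['p']:.4g}")
        else:
            lines.append(f"  {row['metric']}: F={row['F']:.3f} p={row['p']:.4g}")
    if corr_results:
        lines.append("")
        lines.append("Clinical Spearman correlations (BH-FDR corrected):")
        for r in corr_results:
            if r.insufficient:
                continue
            flag = " *" if r.q < config.alpha else ""
            lines.append(f"  {r.feature} ~ {r.scale}: rho={r.rho:+.3f} "
                         f"p={r.p:.4g} q={r.q:.4g} n={r.n}{flag}")
    lines.append("")
    return "\n".join(lines)
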