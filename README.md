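# scnkit

Structural covariance network (SCN) analysis of regional cortical
morphometry, built for studies that contrast a small monogenic patient
group (e.g. SHANK3-deficient autism) against idiopathic and typically
developing groups.

Brain regions that mature together tend to covary in thickness across
subjects. `scnkit` turns that observation into per-group graphs and asks
whether their topology differs: nodes are the regions of a cortical
atlas (default 360, 180 per hemisphere), and two regions are connected
when the across-subject Pearson correlation of their residualized
cortical thickness ranks in the top 15% of all region pairs. The
resulting binary networks are characterized by efficiency:

- global efficiency `GE = (1/(N(N−1))) Σ_{i≠j} 1/L_ij` (inverse
  shortest-path lengths; disconnected pairs contribute 0),
- local efficiency `LE = (1/N) Σ_i GE(G_i)` over neighbour-induced
  subgraphs `G_i`,
- normalized `nGE = GE/GE_random`, `nLE = LE/LE_random` against
  degree-preserving randomly rewired networks, with the small-world
  criterion `nLE > 1` and `nGE ≈ 1`,
- nodal degree for hub analysis.

Group differences are tested nonparametrically by reallocating subjects
between groups (K = 1,000 replicates, one-tailed 95th-percentile
critical values at α = 0.05; Benjamini–Hochberg FDR across regions for
nodal degree). The package also covers the surrounding tabular
statistics — ANCOVA with age/sex/intracranial-volume covariates on
global surface metrics, and Spearman correlations between morphological
features and clinical scores (ADOS-2, Griffiths) — and ships a synthetic
cohort generator with planted covariance topology, so every stage is
testable without access to patient data. See `docs/methods.md` for the
model details and design choices.

## Worked example

Simulate the default emulated cohort (three groups of 12/24/25 subjects,
360 regions) and test the monogenic group against controls on a reduced
scale:

```python
import numpy as np
from scnkit import (SyntheticConfig, generate_cohort, residualize,
                    covariance_matrix, sparsify_binarize,
                    normalized_efficiencies, permute_metric)
from scnkit.synthetic_cohort import TopologySpec

cfg = SyntheticConfig(
    n_regions=60, seed=7,
    topology={"SHANK3": TopologySpec("lattice", k=6),
              "ASD": TopologySpec("small_world", k=6, beta=0.2),
              "TD": TopologySpec("small_world", k=6, beta=0.3)})
cohort, clinical, truth = generate_cohort(cfg)
resid = residualize(cohort)                     # age, sex, overall mean CT

net = sparsify_binarize(covariance_matrix(resid, "TD"), 0.15)
m = normalized_efficiencies(net.adjacency, n_random=50, seed=1)
print(f"TD: {net.n_edges} edges, GE={m.ge:.3f} LE={m.le:.3f} "
      f"nGE={m.nge:.3f} nLE={m.nle:.3f} small-world={m.small_world}")

res = permute_metric(resid, ("SHANK3", "TD"), metric="global_efficiency",
                     k=1000, sparsity=0.15, tail="less", seed=2)
print(f"GE(SHANK3) - GE(TD) = {res.observed:+.4f}, "
      f"critical={res.critical:+.4f}, p={res.p:.3f}, "
      f"significant={res.significant}")
```

Output:

```
TD: 266 edges, GE=0.525 LE=0.454 nGE=0.975 nLE=2.094 small-world=True
GE(SHANK3) - GE(TD) = -0.0037, critical=-0.0204, p=0.937, significant=False
```

266 edges is exactly `round(0.15·60·59/2)`. The TD network is flagged
small-world (nLE = 2.09 ≫ 1 with nGE ≈ 0.98): thresholded correlation
matrices are intrinsically clustered relative to degree-matched
rewirings because correlation is transitive, so this signature appears
even at study-sized groups. The permutation test declines to reject the
GE comparison here — the observed difference (−0.0037) sits well inside
the null's 5th-percentile critical value (−0.0204) for the declared
"less" tail, as expected when 12-subject correlation matrices are this
noisy.

The same pipeline is scriptable from the shell:

```sh
scnkit simulate --seed 7 --out sim/
scnkit run --config run.yaml --out results/   # full staged run + report
scnkit permtest --cohort sim/cohort.tsv --atlas sim/atlas.tsv \
    --groups SHANK3,TD --metric global_efficiency --permutations 1000
scnkit report --run-dir results/
```

A full `scnkit run` writes TSV/JSON artifacts per stage, a plain-text
report and a `manifest.json` with config echo, seeds and file hashes;
repeated runs with the same seed are byte-identical.

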