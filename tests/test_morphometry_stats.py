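"""ANCOVA on global metrics and clinical Spearman correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scnkit.data_io import ClinicalTable
from scnkit.errors import ConfigError
from scnkit.morphometry_stats import ancova_global, spearman_clinical
from scnkit.synthetic_cohort import SyntheticConfig, TopologySpec, generate_cohort


def _null_cohort(seed, sizes=(15, 15, 15)):
    """Three groups from one distribution, zero covariate effects."""
    cfg = SyntheticConfig(
        group_sizes={"A": sizes[0], "B": sizes[1], "C": sizes[2]},
        n_regions=10,
        topology={g: TopologySpec("lattice", k=2) for g in "ABC"},
        covariate_betas={"age": 0.0, "sex": 0.0, "tiv": 0.0},
        group_ct_shift={"A": 0.0, "B": 0.0, "C": 0.0},
        edge_coupling=0.1, noise_sd=0.3, clinical_groups=(), seed=seed)
    return generate_cohort(cfg)[0]


class TestAncova:
    def test_zero_covariate_effects_reduce_to_one_way_anova(self):
        """When no covariates are passed, the group F must equal the
        classic one-way ANOVA F to numerical precision."""
        cohort = _null_cohort(3)
        res = ancova_global(cohort, "mean_ct", covariates=())
        y = cohort.covariates["mean_ct"]
        g = cohort.covariates["group"]
        f_ref, p_ref = stats.f_oneway(*[y[g == lab] for lab in cohort.groups])
        assert res.f == pytest.approx(f_ref, abs=1e-8)
        assert res.p == pytest.approx(p_ref, abs=1e-8)

    def test_planted_group_shift_gives_correctly_signed_posthoc(self):
        """Power simulation: with the planted group offsets in mean CT at
        study-like group sizes, the post-hoc t direction matches the
        planted sign in the large majority of repeated cohorts."""
        good_sa, good_at = 0, 0
        n_sim = 100
        for seed in range(n_sim):
            cfg = SyntheticConfig(  # SHANK3 +0.15, ASD -0.23 vs TD
                seed=seed, n_regions=20,
                topology={"SHANK3": TopologySpec("lattice", k=4),
                          "ASD": TopologySpec("small_world", k=4),
                          "TD": TopologySpec("small_world", k=4)})
            cohort, _, _ = generate_cohort(cfg)
            res = ancova_global(cohort, "mean_ct")
            pairs = {(r.group_a, r.group_b): r.t for r in res.posthoc}
            good_sa += pairs[("SHANK3", "ASD")] > 0  # SHANK3 thicker than ASD
            good_at += pairs[("ASD", "TD")] < 0      # ASD thinner than TD
        assert good_sa / n_sim > 0.9
        assert good_at / n_sim > 0.9

    def test_covariate_rescaling_leaves_omnibus_invariant(self):
        cohort = _null_cohort(8)
        res1 = ancova_global(cohort, "mean_ct", covariates=("age", "tiv"))
        cohort.covariates["age"] = cohort.covariates["age"] * 12 + 7  # months
        cohort.covariates["tiv"] = cohort.covariates["tiv"] / 1000    # cm^3
        res2 = ancova_global(cohort, "mean_ct", covariates=("age", "tiv"))
        assert res2.f == pytest.approx(res1.f, rel=1e-9)
        assert res2.p == pytest.approx(res1.p, rel=1e-9)

    def test_type_one_error_near_alpha(self):
        """Null simulation: omnibus rejection rate compatible with 0.05
        over 300 replicated null cohorts."""
        rejections = sum(
            ancova_global(_null_cohort(seed), "mean_ct").p < 0.05
            for seed in range(300))
        rate = rejections / 300
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)

    def test_welch_and_pooled_posthoc_differ_under_imbalance(self):
        cohort = _null_cohort(2, sizes=(8, 30, 10))
        w = ancova_global(cohort, "mean_ct", posthoc="welch").posthoc[0]
        p = ancova_global(cohort, "mean_ct", posthoc="pooled").posthoc[0]
        assert w.p != p.p

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigError):
            ancova_global(_null_cohort(1), "bmi")


def _clinical_frame(values: dict) -> ClinicalTable:
    n = len(next(iter(values.values())))
    df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], **values})
    return ClinicalTable(scores=df)


class TestSpearman:
    def test_strictly_monotone_link_gives_rho_one(self):
        x = np.array([0.3, 1.2, 0.7, 2.5, 1.9, 0.1, 3.3])
        feats = pd.DataFrame({"subject_id": [f"s{i}" for i in range(7)],
                              "feat": x})
        clin = _clinical_frame({"score": np.exp(3 * x) - 1})
        res = spearman_clinical(feats, clin)[0]
        assert res.rho == pytest.approx(1.0)

    def test_insufficient_pairs_flagged_and_excluded_from_family(self):
        feats = pd.DataFrame({"subject_id": [f"s{i}" for i in range(6)],
                              "feat": np.arange(6.0)})
        sparse = np.array([1.0, 2.0, np.nan, np.nan, np.nan, np.nan])
        dense = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        clin = _clinical_frame({"sparse": sparse, "dense": dense})
        res = {r.scale: r for r in spearman_clinical(feats, clin)}
        assert res["sparse"].insufficient and np.isnan(res["sparse"].q)
        assert not res["dense"].insufficient

    def test_fdr_family_spans_all_tested_pairs(self):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame({"subject_id": [f"s{i}" for i in range(20)],
                              "f1": rng.standard_normal(20),
                              "f2": rng.standard_normal(20)})
        clin = _clinical_frame({"c1": rng.standard_normal(20),
                                "c2": rng.standard_normal(20)})
        res = spearman_clinical(feats, clin)
        assert len(res) == 4
        assert all(r.q >= r.p - 1e-12 for r in res)

    def test_null_rejection_rate_near_alpha_without_correction(self):
        """Independent feature and score: |rho| small on average and the
        uncorrected rejection rate is near 0.05 (400 simulations)."""
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(400):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            hits += stats.spearmanr(x, y).pvalue < 0.05
        rate = hits / 400
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_generator_link_recovers_target_rank_correlation(self):
        """At the default link strength and a combined clinical sample of
        n~31, the observed DQ rank correlation lands near 0.6 (+-0.1 on
        average over 30 cohorts)."""
        rhos = []
        for seed in range(30):
            cfg = SyntheticConfig(seed=seed, n_regions=20,
                                  topology={
                                      "SHANK3": TopologySpec("lattice", k=4),
                                      "ASD": TopologySpec("small_world", k=4),
                                      "TD": TopologySpec("small_world", k=4)},
                                  group_sizes={"SHANK3": 11, "ASD": 20,
                                               "TD": 25})
            cohort, _, _ = generate_cohort(cfg)
            mask = cohort.covariates["group"].isin(["SHANK3", "ASD"])
            feat = cohort.ct_matrix()[mask.to_numpy(), 0]
            dq = cohort.covariates.loc[mask, "dq"]
            rhos.append(stats.spearmanr(feat, dq).statistic)
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.1)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_spearman_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(15)
    y = x + rng.standard_normal(15)
    base = stats.spearmanr(x, y).statistic
    assert stats.spearmanr(np.exp(x), y ** 3 if (y > 0).all() else y).statistic == pytest.approx(
        stats.spearmanr(np.exp(x), y).statistic)
    feats = pd.DataFrame({"subject_id": [f"s{i}" for i in range(15)],
                          "feat": np.exp(x)})
    clin = _clinical_frame({"score": 2 * y + 5})
    res = spearman_clinical(feats, clin, fdr=False)[0]
    assert res.rho == pytest.approx(base, abs=1e-12)
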