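"""Kruskal-Wallis correctness (hand-ranked example + permutation oracle),
site validation semantics, gene summaries and group descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimark import (GeneratorConfig, SelectionParams, beta_to_m,
                     double_pca_select, gene_summary, generate_dataset,
                     group_descriptives, kruskal_wallis, validate_sites)
from epimark.site_stats import test_sites as run_site_tests
from conftest import kw_permutation_midp


class TestKruskalWallis:
    def test_hand_ranked_worked_example(self):
        """{1,2,3} vs {4,5,6}: ranks 1..6, R1=6, R2=15 ->
        H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 3.857..."""
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6],
                              ["a", "a", "a", "b", "b", "b"])
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-12)
        assert round(h, 3) == 3.857
        assert p == pytest.approx(stats.chi2.sf(h, 1), abs=1e-12)

    def test_symmetric_ties_give_zero(self):
        h, p = kruskal_wallis([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_all_tied_degenerate_case(self):
        assert kruskal_wallis([5.0] * 6, ["a"] * 3 + ["b"] * 3) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], np.array(["a", "a"]))

    def test_three_groups_supported(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                              ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        sp = stats.kruskal([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(sp.statistic)
        assert p == pytest.approx(sp.pvalue)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_permutation_oracle(self, seed):
        """Chi-square p tracks the permutation mid-p within 0.03 at 8 vs 8
        with one-decimal ties (the documented approximation accuracy)."""
        rng = np.random.default_rng(seed)
        for _ in range(10):
            x = np.round(rng.normal(0, 1, 16), 1)
            if len(np.unique(x)) < 2:
                continue
            _, p = kruskal_wallis(x, ["a"] * 8 + ["b"] * 8)
            p_perm = kw_permutation_midp(x, 8, 10_000, rng)
            assert abs(p - p_perm) <= 0.03

    def test_null_type_one_error_in_binomial_band(self):
        """Rejection rate at alpha=0.05 on 5,000 continuous null sites with
        n = 9+9 lies inside the 99% binomial band around 0.05."""
        rng = np.random.default_rng(7)
        g = ["a"] * 9 + ["b"] * 9
        rej = 0
        n_sites = 5000
        X = rng.normal(size=(n_sites, 18))
        for i in range(n_sites):
            rej += kruskal_wallis(X[i], g)[1] < 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_sites)
        assert 0.05 - half <= rej / n_sites <= 0.05 + half


@pytest.fixture(scope="module")
def validated_run():
    cfg = GeneratorConfig(n_probes=3000, n_differential=20, n_predictive=0,
                          seed=42)
    data = generate_dataset(cfg)
    mb = beta_to_m(data.beta_baseline)
    mf = beta_to_m(data.beta_followup)
    selection = double_pca_select(mb, mf, SelectionParams())
    groups = data.sheet["group"]
    return data, mb, mf, selection, groups


class TestValidateSites:
    def test_requires_significance_at_both_timepoints(self, validated_run):
        data, mb, mf, selection, groups = validated_run
        out = validate_sites(selection, data.beta_baseline, data.beta_followup,
                             mb, mf, groups, alpha=0.05)
        for t in out:
            assert t.p_baseline < 0.05 and t.p_followup < 0.05

    def test_no_filter_identity(self, validated_run):
        """alpha = 1 with concordance off returns exactly the stage-2 set."""
        data, mb, mf, selection, groups = validated_run
        out = validate_sites(selection, data.beta_baseline, data.beta_followup,
                             mb, mf, groups, alpha=1.01,
                             require_concordance=False)
        assert sorted(t.probe_id for t in out) == selection.stage2_ids

    def test_direction_matches_planted_sign(self, validated_run):
        data, mb, mf, selection, groups = validated_run
        out = validate_sites(selection, data.beta_baseline, data.beta_followup,
                             mb, mf, groups)
        for t in out:
            planted = data.truth.differential.get(t.probe_id)
            if planted is None:
                continue
            expected = "hyper_in_stable" if planted > 0 else "hypo_in_stable"
            assert t.direction == expected

    def test_sorted_by_min_p_then_id(self, validated_run):
        data, mb, mf, selection, groups = validated_run
        out = validate_sites(selection, data.beta_baseline, data.beta_followup,
                             mb, mf, groups)
        keys = [(min(t.p_baseline, t.p_followup), t.probe_id) for t in out]
        assert keys == sorted(keys)

    def test_accepts_plain_id_list(self, validated_run):
        data, mb, mf, selection, groups = validated_run
        ids = selection.stage2_ids[:5]
        out = validate_sites(ids, data.beta_baseline, data.beta_followup,
                             mb, mf, groups, alpha=1.01,
                             require_concordance=False)
        assert sorted(t.probe_id for t in out) == sorted(ids)


class TestGeneSummary:
    def _mk(self, p_pairs):
        from epimark import SiteTestResult
        return [SiteTestResult(probe_id=pid, H_baseline=1, H_followup=1,
                               p_baseline=pb, p_followup=pf,
                               delta_beta_baseline=0.1,
                               delta_beta_followup=0.1,
                               direction="hyper_in_stable")
                for pid, pb, pf in p_pairs]

    def _manifest(self, genes):
        ids = [f"cg{i:08d}" for i in range(1, len(genes) + 1)]
        return pd.DataFrame(
            {"chrom": "chr1", "pos": range(1, len(genes) + 1), "gene": genes,
             "design_type": "II", "snp_flag": False},
            index=pd.Index(ids, name="probe_id"))

    def test_half_differential_gene(self):
        man = self._manifest(["G1"] * 4)
        tests = self._mk([("cg00000001", 0.01, 0.01),
                          ("cg00000002", 0.01, 0.02),
                          ("cg00000003", 0.5, 0.01),
                          ("cg00000004", 0.3, 0.4)])
        out = gene_summary(tests[:1], tests, man, alpha=0.05)
        assert len(out) == 1
        assert out[0].n_cpgs_on_array == 4
        assert out[0].n_differential == 2
        assert out[0].fraction_differential == pytest.approx(50.0)

    def test_single_cpg_gene_is_100pct(self):
        man = self._manifest(["G1"])
        tests = self._mk([("cg00000001", 0.001, 0.001)])
        out = gene_summary(tests, tests, man)
        assert out[0].fraction_differential == pytest.approx(100.0)

    def test_one_of_eight(self):
        man = self._manifest(["G1"] * 8)
        pairs = [(f"cg{i:08d}", 0.5, 0.5) for i in range(1, 9)]
        pairs[0] = ("cg00000001", 0.01, 0.01)
        tests = self._mk(pairs)
        out = gene_summary(tests[:1], tests, man)
        assert out[0].fraction_differential == pytest.approx(12.5)

    def test_fractions_bounded_and_ordered(self, validated_run):
        data, mb, mf, selection, groups = validated_run
        validated = validate_sites(selection, data.beta_baseline,
                                   data.beta_followup, mb, mf, groups)
        genes = {data.manifest.loc[t.probe_id, "gene"] for t in validated}
        probes = [p for p in data.manifest.index[
            data.manifest["gene"].isin(genes - {""})] if p in mb.index]
        tests = run_site_tests(probes, data.beta_baseline, data.beta_followup,
                               mb, mf, groups)
        out = gene_summary(validated, tests, data.manifest)
        fracs = [g.fraction_differential for g in out]
        assert all(0.0 <= f <= 100.0 for f in fracs)
        assert fracs == sorted(fracs, reverse=True)


class TestGroupDescriptives:
    def test_constant_covariate(self, small_dataset):
        sheet = small_dataset.sheet.copy()
        sheet["age"] = 50.0
        out = group_descriptives(sheet)
        row = out[(out["variable"] == "age")
                  & (out["timepoint"] == "baseline")].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)
        assert row["sd_stable_MHO"] == pytest.approx(0.0)

    def test_fisher_path_for_sparse_categorical(self):
        rows = []
        for i in range(9):
            for g, treat in (("stable_MHO", False),
                             ("unstable_MHO", i < 5)):
                rows.append({"sample_id": f"{g}{i}", "subject_id": f"{g}{i}",
                             "timepoint": "baseline", "group": g, "sex": "F",
                             "on_treatment": treat, "age": 50.0})
        sheet = pd.DataFrame(rows).set_index("sample_id")
        out = group_descriptives(sheet)
        row = out[out["variable"] == "on_treatment"].iloc[0]
        assert row["test"] == "fisher"
        # oracle: Fisher's exact on the 0/9 vs 5/9 table
        _, p = stats.fisher_exact([[9, 0], [4, 5]])
        assert row["p_value"] == pytest.approx(p)

    def test_group_indicator_covariate_is_significant(self, small_dataset):
        sheet = small_dataset.sheet.copy()
        sheet["age"] = np.where(sheet["group"] == "stable_MHO", 40.0, 60.0) \
            + np.random.default_rng(0).normal(0, 0.5, len(sheet))
        out = group_descriptives(sheet)
        for _, row in out[out["variable"] == "age"].iterrows():
            assert row["p_value"] < 0.01

    def test_triglycerides_higher_at_baseline_in_unstable(self, small_dataset):
        """The generator reproduces the cohort's baseline triglyceride
        difference between groups."""
        out = group_descriptives(small_dataset.sheet)
        row = out[(out["variable"] == "triglycerides")
                  & (out["timepoint"] == "baseline")].iloc[0]
        assert row["mean_unstable_MHO"] > row["mean_stable_MHO"]
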