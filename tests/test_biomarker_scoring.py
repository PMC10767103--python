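import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vaemarker as vm
from vaemarker.attribution import AttributionMatrix
from vaemarker.biomarker_scoring import (BiomarkerScoreTable, CandidateSet,
                                         ContributionThresholds)
from vaemarker.data_model import LabelVector


def _attr(values, sample_ids, gene_ids):
    return AttributionMatrix(np.asarray(values, float), tuple(sample_ids),
                             tuple(gene_ids), base_value=0.0)


class TestThresholds:
    def test_pooled_quantile_convention(self):
        vals = np.arange(1, 101, dtype=float).reshape(10, 10)
        thr = vm.compute_thresholds(_attr(vals, [f"s{i}" for i in range(10)],
                                          [f"g{i}" for i in range(10)]), 0.05)
        assert thr.pos_cutoff == pytest.approx(95.05)
        assert thr.neg_cutoff == pytest.approx(5.95)

    def test_symmetric_values_give_symmetric_cutoffs(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=500)
        vals = np.concatenate([half, -half]).reshape(10, 100)
        thr = vm.compute_thresholds(_attr(vals, [f"s{i}" for i in range(10)],
                                          [f"g{i}" for i in range(100)]), 0.05)
        assert thr.neg_cutoff == pytest.approx(-thr.pos_cutoff)

    def test_degenerate_q_rejected(self):
        a = _attr(np.zeros((2, 2)), ["s1", "s2"], ["g1", "g2"])
        for q in (0.5, 0.0, 0.7):
            with pytest.raises(vm.ValidationError):
                vm.compute_thresholds(a, q)
        with pytest.raises(vm.ValidationError):
            vm.share_thresholds(0.5)

    def test_contribution_shares_sum_to_one_in_magnitude(self):
        vals = np.array([[3.0, -1.0], [0.0, 0.0]])
        shares = vm.contribution_shares(_attr(vals, ["a", "b"], ["g1", "g2"]))
        assert np.abs(shares.values[0]).sum() == pytest.approx(1.0)
        assert np.allclose(shares.values[1], 0.0)  # all-zero row untouched


class TestScoreGenes:
    def _toy(self):
        # 4 genes x 6 samples (3 tumor, 3 normal); hand-set cutoffs +-1
        sample_ids = ["t1", "t2", "t3", "n1", "n2", "n3"]
        labels = LabelVector(tuple(sample_ids), np.array([1, 1, 1, 0, 0, 0]))
        values = np.array([
            #  gA    gB    gC    gD
            [2.0,  1.5,  0.0, -2.0],   # t1
            [1.5, -0.2,  0.5,  0.1],   # t2
            [0.2,  2.0,  0.3,  0.0],   # t3
            [-1.5, 0.0, -0.1,  1.9],   # n1
            [0.3, -1.2, -0.4,  0.2],   # n2
            [-0.8, -1.6, 0.9,  0.0],   # n3
        ])
        attr = _attr(values, sample_ids, ["gA", "gB", "gC", "gD"])
        thr = ContributionThresholds(q=0.1, pos_cutoff=1.0, neg_cutoff=-1.0)
        return attr, labels, thr

    def test_hand_counted_toy_matrix(self):
        attr, labels, thr = self._toy()
        table = vm.score_genes(attr, labels, thr).table
        # gA: tumors above +1: t1,t2 -> C_P=2; normals below -1: n1 -> C_N=1
        assert table.loc["gA", "C_P"] == 2 and table.loc["gA", "C_N"] == 1
        assert table.loc["gA", "score"] == pytest.approx(4 / 9)
        # gB: C_P=2 (t1,t3), C_N=2 (n2,n3) -> harmonic mean of 2/3,2/3 = 2/3
        assert table.loc["gB", "score"] == pytest.approx(2 / 3)
        # gC: no exceedances at all
        assert table.loc["gC", "C_P"] == 0 and table.loc["gC", "C_N"] == 0
        assert table.loc["gC", "score"] == 0.0
        # gD: discordant only (negative in tumor, positive in normal)
        assert table.loc["gD", "score"] == 0.0

    def test_zero_annihilator_not_nan(self):
        attr, labels, thr = self._toy()
        table = vm.score_genes(attr, labels, thr).table
        assert not table["score"].isna().any()

    def test_single_class_rejected(self):
        attr, _, thr = self._toy()
        all_tumor = LabelVector(attr.sample_ids, np.ones(6, int))
        with pytest.raises(vm.ValidationError):
            vm.score_genes(attr, all_tumor, thr)

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(0, 10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_score_bounds_symmetry_monotonicity(self, cp1, cn1, cp2, cn2):
        def score(cp, cn, nt=10, nn=10):
            pt, pn = cp / nt, cn / nn
            return 2 * pt * pn / (pt + pn) if pt + pn else 0.0

        s = score(cp1, cn1)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(score(cn1, cp1))  # symmetry
        if cp1 == 0 or cn1 == 0:
            assert s == 0.0  # annihilator
        if cp2 >= cp1 and cn2 >= cn1:
            assert score(cp2, cn2) >= s - 1e-12  # monotone in each count

    def test_widening_tails_never_decreases_counts(self):
        attr, labels, _ = self._toy()
        narrow = vm.score_genes(attr, labels,
                                ContributionThresholds(0.1, 1.5, -1.5)).table
        wide = vm.score_genes(attr, labels,
                              ContributionThresholds(0.2, 1.0, -1.0)).table
        assert (wide["C_P"] >= narrow["C_P"]).all()
        assert (wide["C_N"] >= narrow["C_N"]).all()


def _score_table(scores):
    import pandas as pd
    table = pd.DataFrame({"C_P": 1, "C_N": 1, "P_tumor": 0.1, "P_normal": 0.1,
                          "score": scores},
                         index=[f"g{i}" for i in range(len(scores))])
    return BiomarkerScoreTable(table, 3, 3,
                               ContributionThresholds(0.05, 1.0, -1.0))


class TestQuartileFilter:
    def test_eight_distinct_scores_keep_top_two(self):
        kept = vm.quartile_filter(_score_table(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]))
        assert set(kept) == {"g6", "g7"}

    def test_all_equal_scores_keep_everything(self):
        kept = vm.quartile_filter(_score_table([0.5] * 6))
        assert len(kept) == 6

    def test_interpolated_bound_on_four_scores(self):
        # sorted {0.1,0.4,0.8,0.9}: 75th percentile = 0.825 -> only 0.9 kept
        kept = vm.quartile_filter(_score_table([0.9, 0.8, 0.4, 0.1]))
        assert set(kept) == {"g0"}

    def test_fewer_than_four_genes_rejected(self):
        with pytest.raises(vm.ValidationError):
            vm.quartile_filter(_score_table([0.5, 0.2]))


class TestIntersection:
    def test_plain_intersection_with_provenance(self):
        sets = [CandidateSet(frozenset(g), {"i": i})
                for i, g in enumerate([{"A", "B", "C"}, {"B", "C", "D"},
                                       {"C", "B"}])]
        out = vm.intersect_candidates(sets)
        assert out.gene_ids == {"B", "C"}
        assert len(out.provenance["intersected"]) == 3

    def test_idempotence(self):
        s = CandidateSet(frozenset({"x", "y"}), {})
        assert vm.intersect_candidates([s, s]).gene_ids == s.gene_ids

    def test_empty_list_rejected(self):
        with pytest.raises(vm.ValidationError):
            vm.intersect_candidates([])


@pytest.fixture(scope="module")
def small_discovery(sim300):
    counts, labels, truth = sim300
    # single tail: at this 300-gene scale the feature set is ~15 genes, so
    # the narrower tails leave too few candidate slots to be useful
    cfg = vm.DiscoveryConfig(
        n_iterations=3, freq_thresholds=(), q_tails=(0.05,),
        n_sample_sets=2, seed=3,
        schedule=vm.TrainingSchedule(total_epochs=60, vae_only_epochs=15,
                                     mlp_only_epochs=15, joint_epochs=30,
                                     batch_size=64),
        attribution=vm.AttributionConfig(n_background=32, n_steps=32))
    return vm.run_discovery(counts, labels, cfg), cfg, truth


class TestRunDiscovery:
    def test_final_list_subset_of_every_candidate_set(self, small_discovery):
        result, _, _ = small_discovery
        final = set(result.gene_ids)
        for cand in result.candidate_sets:
            assert final <= set(cand.gene_ids)

    def test_no_null_genes_in_final_list(self, small_discovery, sim300):
        counts, _, _ = sim300
        result, _, truth = small_discovery
        nulls = truth.null_gene_ids(counts.gene_ids)
        assert not set(result.gene_ids) & nulls

    def test_biomarkers_outrank_heterogeneous_genes(self, small_discovery):
        result, _, truth = small_discovery
        bm = set(truth.biomarker_gene_ids)
        final = set(result.gene_ids)
        assert final & bm  # at least some planted biomarkers recovered
        assert len(final & bm) > len(final - bm)

    def test_determinism(self, sim300, small_discovery):
        counts, labels, truth = sim300
        result, cfg, _ = small_discovery
        again = vm.run_discovery(counts, labels, cfg)
        assert again.gene_ids == result.gene_ids

    def test_degenerate_single_everything(self, sim300):
        counts, labels, _ = sim300
        sub = counts.subset_genes(list(counts.gene_ids[:80]))
        cfg = vm.DiscoveryConfig(
            n_iterations=1, freq_thresholds=(), q_tails=(0.05,),
            n_sample_sets=1, seed=1,
            schedule=vm.TrainingSchedule(total_epochs=15, vae_only_epochs=5,
                                         mlp_only_epochs=5, joint_epochs=5,
                                         batch_size=64),
            attribution=vm.AttributionConfig(n_background=8, n_steps=8))
        result = vm.run_discovery(sub, labels, cfg)
        assert len(result.candidate_sets) == 1
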