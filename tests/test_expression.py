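"""Expression processing: FPKM, transcript collapsing, the permutation DEG
screen, profile-shape clustering, CV stability ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score

from oilseednet.expression import (cluster_profiles, collapse_transcripts,
                                   cv_stability, fpkm_normalize, screen_degs)
from tests.conftest import make_matrix


class TestFpkm:
    def test_formula_arithmetic(self):
        m = make_matrix([[100.0], [9_999_900.0]], lengths=[2000, 1000],
                        unit="count")
        out = fpkm_normalize(m)
        assert out.values.iloc[0, 0] == pytest.approx(5.0, abs=1e-12)

    def test_zero_count_gives_zero(self):
        m = make_matrix([[0.0], [50.0]], lengths=[1500, 1000], unit="count")
        assert fpkm_normalize(m).values.iloc[0, 0] == 0.0

    def test_single_gene_sample(self):
        m = make_matrix([[12345.0]], lengths=[1000], unit="count")
        assert fpkm_normalize(m).values.iloc[0, 0] == pytest.approx(1e6,
                                                                    abs=1e-6)

    def test_rank_order_preserved_for_equal_lengths(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 1000, size=(20, 4)).astype(float)
        m = make_matrix(counts, lengths=[1000] * 20, unit="count")
        out = fpkm_normalize(m)
        for j in range(4):
            assert (np.argsort(counts[:, j])
                    == np.argsort(out.values.iloc[:, j].to_numpy())).all()

    def test_requires_count_unit(self):
        with pytest.raises(ValueError, match="count"):
            fpkm_normalize(make_matrix([[1.0]], unit="fpkm"))


class TestCollapseTranscripts:
    def pairs(self, rows):
        return pd.DataFrame(rows, columns=["query", "subject", "identity",
                                           "coverage"])

    def test_qualifying_pair_sums_under_longest_id(self):
        m = make_matrix([[5.0], [3.0]], lengths=[1200, 900])
        out, clusters = collapse_transcripts(
            m, self.pairs([("g0", "g1", 0.95, 0.85)]))
        assert list(out.values.index) == ["g0"]
        assert out.values.iloc[0, 0] == pytest.approx(8.0)
        assert clusters[0].representative == "g0"

    def test_below_coverage_threshold_no_collapse(self):
        m = make_matrix([[5.0], [3.0]], lengths=[1200, 900])
        out, clusters = collapse_transcripts(
            m, self.pairs([("g0", "g1", 0.95, 0.70)]))
        assert out.n_genes == 2 and not clusters

    def test_empty_pair_table_is_identity(self):
        m = make_matrix([[5.0], [3.0]], lengths=[1200, 900])
        out, clusters = collapse_transcripts(m, self.pairs([]))
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_single_linkage_components_and_mass_conservation(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 10, size=(6, 3))
        m = make_matrix(vals, lengths=[500, 900, 700, 1100, 600, 800])
        chain = self.pairs([("g0", "g1", 0.95, 0.9), ("g1", "g2", 0.92, 0.85),
                            ("g3", "g4", 0.99, 0.9)])
        out, clusters = collapse_transcripts(m, chain)
        assert out.n_genes == 3
        np.testing.assert_allclose(out.values.sum(axis=0), vals.sum(axis=0))
        reps = {c.representative for c in clusters}
        assert reps == {"g1", "g3"}   # longest members of each component

    def test_unknown_gene_in_pairs_rejected(self):
        m = make_matrix([[1.0]], lengths=[500])
        with pytest.raises(ValueError, match="unknown gene"):
            collapse_transcripts(m, self.pairs([("g0", "zz", 0.95, 0.9)]))


class TestScreenDegs:
    def two_group_matrix(self, values):
        values = np.asarray(values, dtype=float)
        n = values.shape[1]
        ids = [f"sp1.40.{i + 1}" for i in range(n // 2)] + \
              [f"sp2.40.{i + 1}" for i in range(n - n // 2)]
        m = make_matrix(values, sample_ids=ids,
                        stages=[40] * n)
        return m, ids[:n // 2], ids[n // 2:]

    def test_identical_groups_nothing_called(self):
        vals = np.tile([[4.0, 7.0, 2.0]], (5, 2)).reshape(5, 6)
        m, a, b = self.two_group_matrix(vals)
        out = screen_degs(m, a, b, n_permutations=199, seed=0)
        assert np.allclose(out["log2fc"], 0.0)
        assert not out["is_de"].any()

    def test_planted_fold_change_detected(self):
        rng = np.random.default_rng(3)
        base = 2.0 ** rng.uniform(2, 8, size=(200, 1))
        noise = 2.0 ** rng.normal(0, 0.3, size=(200, 6))
        vals = base * noise
        vals[0, 3:] *= 4.0
        m, a, b = self.two_group_matrix(vals)
        out = screen_degs(m, a, b, n_permutations=499, seed=1)
        assert out.iloc[0]["q"] < 0.05 and bool(out.iloc[0]["is_de"])

    def test_null_p_values_uniform(self):
        """Pooled permutation p-values pass a KS uniformity check."""
        rng = np.random.default_rng(7)
        vals = 2.0 ** rng.normal(5, 0.5, size=(300, 6))
        m, a, b = self.two_group_matrix(vals)
        out = screen_degs(m, a, b, n_permutations=299, seed=2)
        assert kstest(out["p"], "uniform").pvalue > 0.01

    def test_few_permutations_warns_but_computes(self):
        m, a, b = self.two_group_matrix(np.ones((3, 6)))
        with pytest.warns(UserWarning, match="permutations"):
            out = screen_degs(m, a, b, n_permutations=50, seed=0)
        assert len(out) == 3

    def test_small_group_rejected(self):
        m, a, b = self.two_group_matrix(np.ones((3, 6)))
        with pytest.raises(ValueError, match="group A"):
            screen_degs(m, a[:1], b, n_permutations=199)


class TestClusterProfiles:
    def test_two_exact_archetypes_separate(self):
        up = np.linspace(1, 5, 5)
        down = up[::-1]
        vals = np.vstack([np.tile(up, (4, 1)), np.tile(down, (4, 1))])
        m = make_matrix(vals)
        labels = cluster_profiles(m, 2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_equals_n_genes(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        labels = cluster_profiles(m, 3)
        assert len(set(labels)) == 3

    def test_three_planted_shapes_recovered(self, planted_network_data):
        cfg, m, truth = planted_network_data
        lab = truth.labels_for("sp1")
        module_genes = lab.index[lab > 0]
        sub = m.subset_genes(module_genes)
        pred = cluster_profiles(sub, 3)
        assert adjusted_rand_score(lab.loc[module_genes], pred) >= 0.9

    def test_k_larger_than_genes_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_profiles(make_matrix(np.ones((2, 4))), 5)


class TestCvStability:
    def test_constant_gene_ranks_first(self):
        m = make_matrix([[5.0, 5.0, 5.0, 5.0], [1.0, 9.0, 1.0, 9.0]])
        out = cv_stability(m)
        assert out.loc["g0", "cv"] == 0.0 and out.loc["g0", "rank"] == 1

    def test_cv_arithmetic(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        assert cv_stability(m).loc["g0", "cv"] == pytest.approx(0.5, abs=1e-12)

    def test_ties_break_by_gene_id(self):
        m = make_matrix([[2.0, 4.0], [1.0, 2.0]])   # equal CV
        out = cv_stability(m)
        assert list(out.index) == ["g0", "g1"]

    def test_zero_mean_ranks_last(self):
        m = make_matrix([[0.0, 0.0], [1.0, 2.0]])
        out = cv_stability(m)
        assert np.isnan(out.loc["g0", "cv"]) and out.loc["g0", "rank"] == 2
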