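"""Network construction: correlation, soft threshold, TOM (with brute-force
oracle), module cutting, eigengenes, merging."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oilseednet.network import (AdjacencyMatrix, correlation_matrix,
                                cut_modules, merge_similar_modules,
                                module_eigengene, pick_beta, soft_threshold,
                                tom_similarity)
from tests.conftest import make_matrix


def tom_bruteforce(A: np.ndarray) -> np.ndarray:
    """Element-by-element triple-loop TOM oracle (independent of the
    vectorised implementation)."""
    n = A.shape[0]
    out = np.eye(n)
    k = [sum(A[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n)
                         if u != i and u != j)
            out[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


def adjacency_from(arr, beta=6.0):
    arr = np.asarray(arr, dtype=float)
    ids = [f"g{i}" for i in range(arr.shape[0])]
    return AdjacencyMatrix(matrix=pd.DataFrame(arr, index=ids, columns=ids),
                           beta=beta)


class TestCorrelation:
    def test_against_manual_covariance_formula(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 3.0, 7.0, 6.0, 4.0])
        m = make_matrix(np.vstack([x, y]))
        r = correlation_matrix(m).iloc[0, 1]
        manual = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(manual, abs=1e-12)

    def test_self_and_negation(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        m = make_matrix(np.vstack([x, 10.0 - x]))   # anti-correlated mirror
        c = correlation_matrix(m)
        assert c.iloc[0, 0] == 1.0
        assert c.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_gene_named_in_error(self):
        m = make_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="g0"):
            correlation_matrix(m)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(make_matrix([[1.0, 2.0], [2.0, 1.0]]))


class TestSoftThreshold:
    @pytest.mark.parametrize("r,beta,expected", [
        (1.0, 6.0, 1.0), (-1.0, 6.0, 0.0), (0.0, 6.0, 0.5 ** 6),
    ])
    def test_printed_formula(self, r, beta, expected):
        corr = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"],
                            columns=["a", "b"])
        adj = soft_threshold(corr, beta)
        assert adj.matrix.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_beta_below_r_one(self):
        rng = np.random.default_rng(0)
        rs = rng.uniform(-0.99, 0.99, size=10)
        prev = None
        for beta in (2, 4, 8, 16):
            vals = np.abs((1 + rs) / 2) ** beta
            if prev is not None:
                assert (vals <= prev + 1e-15).all()
            prev = vals

    def test_label_invariance_under_gene_permutation(self):
        rng = np.random.default_rng(1)
        vals = 2.0 ** rng.normal(5, 1, size=(12, 8))
        m = make_matrix(vals)
        corr = correlation_matrix(m)
        tom = tom_similarity(soft_threshold(corr, 6.0))
        perm = rng.permutation(12)
        genes = [f"g{i}" for i in perm]
        m2 = m.subset_genes(genes)
        tom2 = tom_similarity(soft_threshold(correlation_matrix(m2), 6.0))
        np.testing.assert_allclose(tom2.to_numpy(),
                                   tom.loc[genes, genes].to_numpy(),
                                   atol=1e-12)


class TestPickBeta:
    def corr_fixture(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        vals = 2.0 ** rng.normal(5, 0.5, size=(n, 10))
        vals[: n // 2] *= 2.0 ** (0.8 * rng.normal(0, 1, size=10))
        return correlation_matrix(make_matrix(vals))

    def test_returns_smallest_qualifying_candidate(self):
        corr = self.corr_fixture()
        sel = pick_beta(corr, candidates=(2, 4, 6, 8), r2_target=0.0)
        qualifying = sel.fits[sel.fits["r2"] >= 0.0]
        assert sel.beta == qualifying["beta"].iloc[0]
        assert not sel.fallback

    def test_single_candidate_meeting_target(self):
        sel = pick_beta(self.corr_fixture(), candidates=(6,), r2_target=0.0)
        assert sel.beta == 6.0

    def test_all_failing_returns_argmax_with_flag(self):
        corr = self.corr_fixture()
        sel = pick_beta(corr, candidates=(2, 4, 6), r2_target=0.9999)
        assert sel.fallback
        best_row = sel.fits.iloc[sel.fits["r2"].to_numpy().argmax()]
        assert sel.beta == best_row["beta"]

    def test_too_few_genes_rejected(self):
        corr = pd.DataFrame(np.eye(5))
        with pytest.raises(ValueError, match="20 genes"):
            pick_beta(corr)


class TestTom:
    def test_hand_evaluated_three_gene_case(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(adjacency_from(A))
        assert tom.iloc[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_identical_rows_full_overlap(self):
        # full-weight pair with identical (binary) neighbourhoods: maximal
        # topological overlap
        A = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        tom = tom_similarity(adjacency_from(A))
        assert tom.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, size=(40, 40))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(adjacency_from(A)).to_numpy()
        assert np.abs(tom - tom_bruteforce(A)).max() <= 1e-10

    def test_single_gene_degenerate(self):
        tom = tom_similarity(adjacency_from([[1.0]]))
        assert tom.iloc[0, 0] == 1.0


def block_tom(sizes, within, between):
    """Block-diagonal TOM fixture; ``within`` may be one value for all
    blocks or one value per block (e.g. a tight module over a loose
    background)."""
    n = sum(sizes)
    withins = [within] * len(sizes) if np.isscalar(within) else list(within)
    T = np.full((n, n), between)
    start = 0
    for s, w in zip(sizes, withins):
        T[start:start + s, start:start + s] = w
        start += s
    np.fill_diagonal(T, 1.0)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(T, index=ids, columns=ids)


class TestCutModules:
    def test_two_planted_blocks_recovered_exactly(self):
        tom = block_tom([30, 30], 0.9, 0.05)
        part = cut_modules(tom, min_module_size=10)
        truth = [0] * 30 + [1] * 30
        assert len(part.module_labels) == 2
        assert adjusted_rand_score(truth, part.labels) == 1.0

    def test_isolated_gene_unassigned(self):
        tom = block_tom([30, 1], 0.9, 0.02)
        part = cut_modules(tom, min_module_size=10, cut_height=0.5)
        assert part.labels.iloc[-1] == 0

    def test_cut_near_one_yields_single_module(self):
        tom = block_tom([15, 15], 0.9, 0.3)
        part = cut_modules(tom, min_module_size=10, cut_height=0.999)
        assert len(part.module_labels) == 1
        assert (part.labels == 1).all()

    def test_invalid_cut_height_rejected(self):
        tom = block_tom([10, 10], 0.9, 0.05)
        with pytest.raises(ValueError, match="cut_height"):
            cut_modules(tom, min_module_size=5, cut_height=1.5)

    def test_min_module_size_floor(self):
        with pytest.raises(ValueError, match="min_module_size"):
            cut_modules(block_tom([10], 0.9, 0.0), min_module_size=2)


class TestEigengene:
    def partition_for(self, m, labels):
        from oilseednet.network import ModulePartition
        return ModulePartition(labels=pd.Series(labels, index=m.values.index))

    def test_identical_profiles_recover_the_profile(self):
        prof = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        vals = np.vstack([prof * s for s in (1.0, 2.0, 0.5)])
        m = make_matrix(vals)
        eig = module_eigengene(m, self.partition_for(m, [1, 1, 1]))[1]
        z = (prof - prof.mean()) / prof.std(ddof=1)
        r = np.corrcoef(eig, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_profile_and_negation_sign_anchored(self):
        prof = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        vals = np.vstack([prof, -prof + 10.0])
        m = make_matrix(vals)
        eig = module_eigengene(m, self.partition_for(m, [1, 1]))[1]
        assert np.linalg.norm(eig) == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        vals = 2.0 ** rng.normal(5, 1, size=(10, 10))
        m = make_matrix(vals)
        eig = module_eigengene(m, self.partition_for(m, [1] * 10))[1].to_numpy()
        Z = (vals - vals.mean(axis=1, keepdims=True)) \
            / vals.std(axis=1, ddof=1, keepdims=True)
        w, v = np.linalg.eigh(Z.T @ Z)
        lead = v[:, -1]
        assert min(np.abs(eig - lead).max(),
                   np.abs(eig + lead).max()) <= 1e-8

    def test_zero_variance_module_rejected(self):
        m = make_matrix(np.ones((3, 4)))
        with pytest.raises(ValueError, match="variance"):
            module_eigengene(m, self.partition_for(m, [1, 1, 1]))


class TestMergeModules:
    def modules_with_eigengene_correlations(self, r_ab, r_bc, r_ac, seed=0):
        """Three 3-gene modules whose latent profiles have the requested
        pairwise correlations (Gram construction over 30 samples)."""
        rng = np.random.default_rng(seed)
        G = np.array([[1.0, r_ab, r_ac], [r_ab, 1.0, r_bc],
                      [r_ac, r_bc, 1.0]])
        L = np.linalg.cholesky(G + 1e-9 * np.eye(3))
        raw = rng.standard_normal((3, 30))
        raw = (raw - raw.mean(axis=1, keepdims=True))
        raw /= raw.std(axis=1, keepdims=True)
        # orthogonalise so the realised correlations match the target Gram
        q, _ = np.linalg.qr(raw.T)
        profs = (L @ q.T[:3]) * 3.0
        vals = np.vstack([np.tile(p, (3, 1)) + 5.0 for p in profs])
        m = make_matrix(vals, stages=list(range(30)))
        labels = pd.Series([1] * 3 + [2] * 3 + [3] * 3, index=m.values.index)
        from oilseednet.network import ModulePartition
        return m, ModulePartition(labels=labels)

    def test_identical_eigengenes_merge(self):
        m, part = self.modules_with_eigengene_correlations(1.0, 0.0, 0.0)
        merged, _ = merge_similar_modules(m, part, merge_correlation=0.75)
        assert len(merged.module_labels) == 2

    def test_uncorrelated_pair_unmerged(self):
        m, part = self.modules_with_eigengene_correlations(0.0, 0.0, 0.0)
        merged, _ = merge_similar_modules(m, part, merge_correlation=0.75)
        assert len(merged.module_labels) == 3

    def test_transitive_closure_of_merging(self):
        m, part = self.modules_with_eigengene_correlations(0.9, 0.9, 0.65)
        merged, _ = merge_similar_modules(m, part, merge_correlation=0.75)
        assert len(merged.module_labels) == 1

    def test_planted_modules_survive_network_chain(self, planted_network_data):
        """End-to-end network chain recovers the planted partition."""
        cfg, m, truth = planted_network_data
        corr = correlation_matrix(m)
        sel = pick_beta(corr)
        beta = sel.beta if not sel.fallback else 6.0
        tom = tom_similarity(soft_threshold(corr, beta))
        part = cut_modules(tom, min_module_size=10)
        lab = truth.labels_for("sp1").loc[m.values.index]
        assert adjusted_rand_score(lab, part.labels) >= 0.8
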