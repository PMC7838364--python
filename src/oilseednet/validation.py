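"""Benchmark computations on the planted synthetic study design.

Each function here re-runs a slice of the analysis on generated data with
known ground truth and returns the recovered quantity (an ARI, a
precision/recall pair, a type-I error rate, a round-trip error, an oracle
discrepancy).  The reference implementations used for the oracle checks
(`tom_reference`, `rbh_reference`, `hypergeom_reference`) are deliberately
written as direct, element-by-element transcriptions of the definitions,
independent of the vectorised production code they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import network
from .conservation import conserved_coexpressed
from .containers import ExpressionMatrix
from .expression import screen_degs
from .oilmodule import hypergeometric_test, permutation_robustness
from .orthology import build_orthogroups, reciprocal_best_hits
from .profiles import desaturation_efficiency
from .simulate import (DEGene, PlantedModule, SimConfig, simulate_expression,
                       simulate_fa_profiles, simulate_similarity_table)

DEFAULT_BETA = 6.0


# -- reference implementations (oracles) -----------------------------------

def tom_reference(A: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap, one element at a time."""
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


def rbh_reference(scores: np.ndarray) -> set[tuple[int, int]]:
    """Double-argmax reciprocal best hits on a score matrix (rows: species A
    genes, columns: species B genes); ties disqualify."""
    pairs = set()
    for i in range(scores.shape[0]):
        row = scores[i]
        j = int(row.argmax())
        if (row == row[j]).sum() > 1:
            continue
        col = scores[:, j]
        if (col == col.max()).sum() > 1:
            continue
        if int(col.argmax()) == i:
            pairs.add((i, j))
    return pairs


def hypergeom_reference(N: int, K: int, n: int, overlap: int) -> float:
    """Exact upper-tail hypergeometric probability by enumeration."""
    total = math.comb(N, n)
    return sum(math.comb(K, k) * math.comb(N - K, n - k)
               for k in range(overlap, min(K, n) + 1)) / total


# -- planted-structure recovery -------------------------------------------

def planted_module_ari(seed: int = 0) -> tuple[float, int]:
    """Adjusted Rand index of network-module recovery: three planted modules
    (sizes 60/40/30, within-correlation 0.8) among 500 background genes,
    15 samples."""
    cfg = SimConfig(n_species=1, n_background_genes=500,
                    planted_modules=(PlantedModule(60, "bell", 0.8),
                                     PlantedModule(40, "rising", 0.8),
                                     PlantedModule(30, "falling", 0.8)),
                    de_genes=(), paralog_events=(), seed=seed)
    matrices, truth = simulate_expression(cfg)
    m = matrices["sp1"]
    corr = network.correlation_matrix(m)
    sel = network.pick_beta(corr)
    beta = sel.beta if not sel.fallback else DEFAULT_BETA
    tom = network.tom_similarity(network.soft_threshold(corr, beta))
    part = network.cut_modules(tom, min_module_size=10)
    labels_true = truth.labels_for("sp1").loc[m.values.index]
    return float(adjusted_rand_score(labels_true, part.labels)), m.n_genes


def conserved_recovery(seed: int = 0, n_conserved: int = 50,
                       n_specific: int = 200,
                       decoy_rate: float = 0.3) -> tuple[float, float, int]:
    """Precision and recall of conserved-co-expressed gene recovery.

    Three species share 50 truly conserved oil-module gene families; each
    species' module additionally holds 200 species-specific genes (disjoint
    index ranges, so none of them is genuinely conserved).  Orthogroups are
    rebuilt from a decoy-laden similarity table.
    """
    n_core = n_conserved + 3 * n_specific
    cfg = SimConfig(n_species=3, n_background_genes=n_core - n_conserved,
                    planted_modules=(PlantedModule(n_conserved, "bell", 0.8),),
                    de_genes=(), paralog_events=(), seed=seed)
    _, truth = simulate_expression(cfg)
    hits = simulate_similarity_table(truth, decoy_rate=decoy_rate,
                                     seed=seed + 1)
    groups = build_orthogroups(hits, truth.species)
    species_of = {g: g.split("_g")[0] for grp in groups for g in grp}
    modules = {}
    for s_idx, sp in enumerate(truth.species):
        specific = range(n_conserved + s_idx * n_specific,
                         n_conserved + (s_idx + 1) * n_specific)
        modules[sp] = ({f"{sp}_g{i:04d}" for i in range(n_conserved)}
                       | {f"{sp}_g{i:04d}" for i in specific})
    predicted = conserved_coexpressed(modules, groups, truth.species[0],
                                      species_of)
    true_set = {f"{truth.species[0]}_g{i:04d}" for i in range(n_conserved)}
    tp = len(predicted & true_set)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(true_set)
    return precision, recall, n_core


def de_detection_rate(n_seeds: int = 20, n_genes: int = 200,
                      log2fc: float = 2.0) -> tuple[float, int]:
    """Fraction of seeds in which a planted 4-fold gene (n=3 vs 3
    replicates) is called at q < 0.05 by the permutation screen."""
    detected = 0
    for seed in range(n_seeds):
        cfg = SimConfig(n_species=2, n_background_genes=n_genes,
                        planted_modules=(), stages=(40, 50), n_replicates=3,
                        de_genes=(DEGene(0, 1, log2fc),),
                        paralog_events=(), seed=seed)
        matrices, truth = simulate_expression(cfg)
        m_a, m_b = matrices["sp1"], matrices["sp2"]
        cols_a = [c for c in m_a.values.columns if ".40." in c]
        cols_b = [c for c in m_b.values.columns if ".40." in c]
        vals_b = m_b.values[cols_b].copy()
        vals_b.index = m_a.values.index     # ortholog pairing by index
        combined = pd.concat([m_a.values[cols_a], vals_b], axis=1)
        samples = pd.concat([m_a.samples.loc[cols_a], m_b.samples.loc[cols_b]])
        joint = ExpressionMatrix(values=combined, samples=samples, unit="fpkm")
        degs = screen_degs(joint, cols_a, cols_b, n_permutations=499,
                           seed=seed + 1)
        if bool(degs.iloc[0]["is_de"]):
            detected += 1
    return detected / n_seeds, n_seeds


# -- statistical calibration ----------------------------------------------

def permutation_null_fraction(seed: int = 0, n_draws: int = 200,
                              n_network_genes: int = 100,
                              module_size: int = 10,
                              n_permutations: int = 199) -> tuple[float, int]:
    """Fraction of null module draws with permutation p < 0.05: random
    equal-size gene sets from an i.i.d. network are tested against the same
    null they were drawn from, so p should be uniform."""
    rng = np.random.default_rng(seed)
    T = rng.uniform(0, 0.5, size=(n_network_genes, n_network_genes))
    T = (T + T.T) / 2.0
    np.fill_diagonal(T, 1.0)
    ids = [f"g{i}" for i in range(n_network_genes)]
    tom = pd.DataFrame(T, index=ids, columns=ids)
    small = 0
    for d in range(n_draws):
        module = {ids[i] for i in rng.choice(n_network_genes, module_size,
                                             replace=False)}
        out = permutation_robustness(tom, module,
                                     n_permutations=n_permutations,
                                     seed=seed + 1000 + d)
        if out.p_value < 0.05:
            small += 1
    return small / n_draws, n_draws


def deg_null_type1(seed: int = 0, n_genes: int = 5000,
                   n_permutations: int = 199) -> tuple[float, int]:
    """Type-I rate of the DEG screen on a global null (no true signal):
    fraction of genes at p < 0.05 for a 3 vs 3 contrast."""
    rng = np.random.default_rng(seed)
    vals = 2.0 ** rng.normal(5.0, 0.5, size=(n_genes, 6))
    ids = [f"sp1.40.{i}" for i in range(1, 4)] + \
          [f"sp2.40.{i}" for i in range(1, 4)]
    genes = [f"g{i}" for i in range(n_genes)]
    samples = pd.DataFrame({"species": ["sp1"] * 3 + ["sp2"] * 3,
                            "tissue": "seed", "stage_daf": 40,
                            "replicate": [1, 2, 3, 1, 2, 3]},
                           index=pd.Index(ids, name="sample"))
    m = ExpressionMatrix(values=pd.DataFrame(vals, index=genes, columns=ids),
                         samples=samples, unit="fpkm")
    degs = screen_degs(m, ids[:3], ids[3:], n_permutations=n_permutations,
                       seed=seed + 1)
    return float((degs["p"] < 0.05).mean()), n_genes


# -- exact round-trips and oracle discrepancies ----------------------------

def fa_roundtrip_max_error(grid: int = 5) -> tuple[float, int]:
    """Max |target - recovered| desaturation efficiency over a grid of
    (omega-6, omega-3) targets in (0, 1]^2."""
    targets = np.linspace(0.2, 1.0, grid)
    worst = 0.0
    for de6 in targets:
        for de3 in targets:
            cfg = SimConfig(omega6_de_target=float(de6),
                            omega3_de_target=float(de3))
            final = [p for p in simulate_fa_profiles(cfg)
                     if p.stage_daf == cfg.stages[-1]][0]
            de = desaturation_efficiency(final)
            worst = max(worst, abs(de.omega6 - de6), abs(de.omega3 - de3))
    return worst, grid * grid


def tom_oracle_max_diff(n_instances: int = 50, n_genes: int = 40,
                        seed: int = 0) -> tuple[float, int]:
    """Max |TOM - triple-loop reference| over random adjacencies."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    ids = [f"g{i}" for i in range(n_genes)]
    for _ in range(n_instances):
        A = rng.uniform(0, 1, size=(n_genes, n_genes))
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, 1.0)
        adj = network.AdjacencyMatrix(
            matrix=pd.DataFrame(A, index=ids, columns=ids), beta=6.0)
        tom = network.tom_similarity(adj).to_numpy()
        worst = max(worst, float(np.abs(tom - tom_reference(A)).max()))
    return worst, n_instances


def rbh_oracle_agreement(n_instances: int = 50, seed: int = 0) -> tuple[float, int]:
    """Fraction of random score tables on which RBH equals the double-argmax
    reference exactly."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n_a, n_b = rng.integers(3, 21, size=2)
        scores = rng.integers(10, 200, size=(n_a, n_b)).astype(float)
        rows = []
        for i in range(n_a):
            for j in range(n_b):
                rows.append((f"A{i}", f"B{j}", "a", "b", scores[i, j], 0.9, 0.9))
                rows.append((f"B{j}", f"A{i}", "b", "a", scores[i, j], 0.9, 0.9))
        hits = pd.DataFrame(rows, columns=["query", "subject", "query_species",
                                           "subject_species", "score",
                                           "identity", "coverage"])
        got = reciprocal_best_hits(hits, "a", "b")
        expected = {(f"A{i}", f"B{j}") for i, j in rbh_reference(scores)}
        agree += int(got == expected)
    return agree / n_instances, n_instances


def hypergeom_oracle_max_diff(max_n: int = 60) -> tuple[float, int]:
    """Max |hypergeometric tail - exact enumeration| over a grid of
    backgrounds N <= max_n."""
    worst = 0.0
    cases = 0
    for N in range(10, max_n + 1, 10):
        for K in (2, N // 4, N // 2):
            for n in (2, N // 4, N // 2):
                for overlap in range(0, min(K, n) + 1):
                    module = {f"g{i}" for i in range(n)}
                    ann = [f"g{i}" for i in range(overlap)] + \
                          [f"h{i}" for i in range(K - overlap)]
                    from .containers import GeneSet
                    p = hypergeometric_test(
                        module, GeneSet.from_iterable("t", ann), N)
                    worst = max(worst, abs(p - hypergeom_reference(N, K, n,
                                                                   overlap)))
                    cases += 1
    return worst, cases
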