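"""Expression-matrix processing.

Covers FPKM normalisation, collapsing of highly similar transcripts into
single rows, a permutation-based differential-expression screen, shape
clustering of stage profiles, and coefficient-of-variation ranking of
reference-gene candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


def fpkm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert fragment counts to FPKM.

    FPKM = count * 1e9 / (transcript length in nt * total mapped fragments
    of the sample).
    """
    if m.unit != "count":
        raise ValueError("fpkm_normalize expects a count matrix")
    lengths = m.gene_lengths
    totals = m.values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    fpkm = m.values.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(values=fpkm, samples=m.samples.copy(),
                            unit="fpkm", gene_lengths=lengths.copy())


# -- transcript collapsing -------------------------------------------------

@dataclass
class TranscriptCluster:
    """Transcripts collapsed into one row: members, thresholds met, and the
    representative (longest member, ties broken lexicographically)."""

    members: list[str]
    representative: str
    min_identity: float
    min_coverage: float


def collapse_transcripts(m: ExpressionMatrix, pairs: pd.DataFrame,
                         identity_min: float = 0.90,
                         coverage_min: float = 0.80,
                         ) -> tuple[ExpressionMatrix, list[TranscriptCluster]]:
    """Collapse highly similar transcripts (redundant assembly contigs).

    Pairs whose identity and coverage reach the thresholds (defaults: 90%
    identity, 80% coverage) define edges; single-linkage connected
    components become clusters.  Each cluster is emitted as one row, the
    element-wise sum of its members, under the id of its longest member.
    Genes in no cluster pass through unchanged; row order is preserved with
    each cluster at its representative's position.
    """
    if m.gene_lengths is None:
        raise ValueError("collapse_transcripts requires gene lengths")
    required = {"query", "subject", "identity", "coverage"}
    if len(pairs) and not required <= set(pairs.columns):
        raise ValueError(f"pair table needs columns {sorted(required)}")
    gene_pos = {g: i for i, g in enumerate(m.values.index)}
    parent = list(range(m.n_genes))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    qualifying = pairs[(pairs["identity"] >= identity_min)
                       & (pairs["coverage"] >= coverage_min)] if len(pairs) else pairs
    for _, row in qualifying.iterrows():
        q, s = row["query"], row["subject"]
        for g in (q, s):
            if g not in gene_pos:
                raise ValueError(f"pair table references unknown gene {g!r}")
        ri, rj = find(gene_pos[q]), find(gene_pos[s])
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    comps: dict[int, list[int]] = {}
    for i in range(m.n_genes):
        comps.setdefault(find(i), []).append(i)

    genes = list(m.values.index)
    lengths = m.gene_lengths
    clusters: list[TranscriptCluster] = []
    rep_of_root: dict[int, str] = {}
    for root, idxs in comps.items():
        members = [genes[i] for i in idxs]
        # longest member wins; lexicographic tie-break keeps determinism
        rep = min(members, key=lambda g: (-int(lengths[g]), g))
        rep_of_root[root] = rep
        if len(members) > 1:
            sub = qualifying[[(row["query"] in members and row["subject"] in members)
                              for _, row in qualifying.iterrows()]] \
                if len(qualifying) else qualifying
            clusters.append(TranscriptCluster(
                members=sorted(members), representative=rep,
                min_identity=float(sub["identity"].min()) if len(sub) else float("nan"),
                min_coverage=float(sub["coverage"].min()) if len(sub) else float("nan")))

    rows, ids, new_lengths = [], [], []
    emitted: set[int] = set()
    for i, g in enumerate(genes):
        root = find(i)
        rep = rep_of_root[root]
        if g != rep or root in emitted:
            continue
        emitted.add(root)
        member_idx = comps[root]
        rows.append(m.values.iloc[member_idx].sum(axis=0))
        ids.append(rep)
        new_lengths.append(int(lengths[rep]))
    values = pd.DataFrame(rows, index=ids, columns=m.values.columns)
    collapsed = ExpressionMatrix(
        values=values, samples=m.samples.copy(), unit=m.unit,
        gene_lengths=pd.Series(new_lengths, index=ids, name="length_nt"))
    return collapsed, clusters


# -- differential-expression screen ---------------------------------------

def screen_degs(m: ExpressionMatrix, group_a: list[str], group_b: list[str],
                n_permutations: int = 999, q_threshold: float = 0.05,
                pseudocount: float = 1.0, seed: int = 0,
                pooled_null: bool = True) -> pd.DataFrame:
    """Permutation screen for differential expression between two groups.

    The statistic is the log2 fold change of pseudocounted group means.
    Group labels are shuffled ``n_permutations`` times; by default the null
    statistics are pooled across genes (the noise scale on the log scale is
    shared), which gives p-value granularity far finer than the number of
    distinct label assignments — essential with triplicate designs.  Each
    gene is compared against the pool of the *other* genes' permuted
    statistics (leave-one-out), so a strongly changed gene does not inflate
    its own null.  Set ``pooled_null=False`` for a strictly per-gene null.
    P-values use the add-one rule and are BH-adjusted into q.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``p``,
    ``q`` and ``is_de`` (q below ``q_threshold``).
    """
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs >= 2 samples for permutation")
        missing = [s for s in grp if s not in m.values.columns]
        if missing:
            raise ValueError(f"unknown samples in group {name}: {missing}")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values will be coarse",
                      stacklevel=2)
    na, nb = len(group_a), len(group_b)
    X = m.values[list(group_a) + list(group_b)].to_numpy(dtype=float)

    def stat(cols_a, cols_b):
        mean_a = X[:, cols_a].mean(axis=1)
        mean_b = X[:, cols_b].mean(axis=1)
        return np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)

    obs = stat(np.arange(na), np.arange(na, na + nb))
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, X.shape[0]))
    idx = np.arange(na + nb)
    for b in range(n_permutations):
        perm = rng.permutation(idx)
        null[b] = stat(perm[:na], perm[na:])

    abs_obs = np.abs(obs)
    if pooled_null:
        abs_null = np.abs(null)
        pool = np.sort(abs_null.ravel())
        ge_total = pool.size - np.searchsorted(pool, abs_obs, side="left")
        ge_own = (abs_null >= abs_obs[None, :]).sum(axis=0)
        n_eff = pool.size - n_permutations        # leave-one-gene-out pool
        p = (1.0 + ge_total - ge_own) / (n_eff + 1.0)
    else:
        ge = (np.abs(null) >= abs_obs[None, :]).sum(axis=0)
        p = (1.0 + ge) / (n_permutations + 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": obs, "p": p, "q": q,
                         "is_de": q < q_threshold}, index=m.values.index)


# -- profile clustering ----------------------------------------------------

def cluster_profiles(m: ExpressionMatrix, k: int) -> pd.Series:
    """Cluster genes by the shape of their stage-mean profile.

    Profiles are z-scored per gene (shape, not level, drives clusters) and
    grouped by average-linkage agglomerative clustering on 1 - Pearson
    correlation, cut to ``k`` clusters.  Flat (zero-variance) profiles are
    assigned correlation 0 to everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({m.n_genes})")
    prof = m.stage_means().to_numpy(dtype=float)
    if k == m.n_genes:
        return pd.Series(np.arange(1, k + 1), index=m.values.index)
    centered = prof - prof.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Z = centered / safe[:, None]
    corr = Z @ Z.T
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=m.values.index)


# -- reference-gene stability ----------------------------------------------

def cv_stability(m: ExpressionMatrix, candidates: list[str] | None = None) -> pd.DataFrame:
    """Rank genes by expression consistency across all samples.

    CV = sample standard deviation / mean over every sample (all stages and
    species present in the matrix); low CV means a stable reference-gene
    candidate.  Zero-mean genes have undefined CV and rank last; ties are
    broken by gene id.
    """
    genes = list(m.values.index) if candidates is None else list(candidates)
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise ValueError(f"unknown candidate genes: {missing}")
    vals = m.values.loc[genes]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    cv = pd.Series(np.where(mean > 0, sd / mean.replace(0, np.nan), np.nan),
                   index=vals.index, name="cv")
    order = sorted(genes, key=lambda g: (np.isnan(cv[g]), cv[g] if not np.isnan(cv[g]) else 0.0, g))
    out = pd.DataFrame({"cv": cv.loc[order]})
    out["rank"] = np.arange(1, len(order) + 1)
    return out
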