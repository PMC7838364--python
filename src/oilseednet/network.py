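"""Weighted gene co-expression network construction.

The chain is the classic one: pairwise Pearson correlation of expression
profiles; signed soft-threshold adjacency a_ij = ((1 + r_ij)/2)^beta (anti-
correlated genes get weight ~0); topological overlap (TOM), which credits
shared network neighbours; average-linkage clustering of 1 - TOM with a
static height cut plus a minimum module size (a deterministic
simplification of dynamic tree cut); module eigengenes (leading principal
component of the standardised module submatrix); and eigengene-correlation
merging of redundant modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix


def correlation_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation between all gene expression profiles.

    Requires at least 3 samples; a zero-variance gene is an error (it has
    no defined correlation) and is reported by name.
    """
    if m.n_samples < 3:
        raise ValueError("need >= 3 samples for meaningful correlations")
    vals = m.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        gene = m.values.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance gene {gene!r}: remove before "
                         "building the network")
    corr = np.corrcoef(vals)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=m.values.index, columns=m.values.index)


@dataclass
class AdjacencyMatrix:
    """Symmetric soft-threshold adjacency in [0, 1] with its beta."""

    matrix: pd.DataFrame
    beta: float

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def connectivity(self) -> pd.Series:
        """Per-gene weighted connectivity k_i = sum of off-diagonal weights."""
        return self.matrix.sum(axis=1) - 1.0


def soft_threshold(corr: pd.DataFrame, beta: float) -> AdjacencyMatrix:
    """Signed soft-threshold adjacency a_ij = |(1 + r_ij)/2|^beta."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    adj = np.power(np.abs((1.0 + corr.to_numpy(dtype=float)) / 2.0), beta)
    np.fill_diagonal(adj, 1.0)
    return AdjacencyMatrix(matrix=pd.DataFrame(adj, index=corr.index,
                                               columns=corr.columns),
                           beta=float(beta))


@dataclass
class BetaSelection:
    beta: float
    fits: pd.DataFrame          # columns: beta, r2, slope
    fallback: bool              # True when no beta reached the target fit


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) ~ log10 k over binned connectivities."""
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2, float(slope)


def pick_beta(corr: pd.DataFrame,
              candidates: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
              r2_target: float = 0.8) -> BetaSelection:
    """Choose the soft-thresholding power by the scale-free-topology fit.

    Returns the smallest candidate beta whose degree distribution fits a
    power law with R^2 at or above ``r2_target`` (only decreasing fits
    count); if none qualifies, the best-fitting beta is returned with
    ``fallback=True``.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate beta")
    if corr.shape[0] < 20:
        raise ValueError("scale-free fit is unreliable below 20 genes")
    rows = []
    for beta in candidates:
        adj = soft_threshold(corr, beta)
        k = adj.connectivity().to_numpy()
        r2, slope = _scale_free_fit(k)
        fit = r2 if slope < 0 else 0.0
        rows.append({"beta": float(beta), "r2": fit, "slope": slope})
    fits = pd.DataFrame(rows)
    ok = fits[fits["r2"] >= r2_target]
    if len(ok):
        return BetaSelection(beta=float(ok.iloc[0]["beta"]), fits=fits,
                             fallback=False)
    best = fits.iloc[int(fits["r2"].to_numpy().argmax())]
    return BetaSelection(beta=float(best["beta"]), fits=fits, fallback=True)


def tom_similarity(a: AdjacencyMatrix) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the off-diagonal row sum; the diagonal is set to 1.  Computed
    with matrix products; an element-wise oracle exists in the test suite.
    """
    A = a.matrix.to_numpy(dtype=float)
    n = A.shape[0]
    if n == 1:
        return pd.DataFrame([[1.0]], index=a.genes, columns=a.genes)
    k = A.sum(axis=1) - 1.0
    # (A @ A)_ij counts u = i and u = j; remove both (diagonal of A is 1)
    shared = A @ A - 2.0 * A
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    denom = np.where(denom <= 0, 1.0, denom)       # degenerate isolated pair
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=a.genes, columns=a.genes)


@dataclass
class ModulePartition:
    """Gene -> module labelling cut from the TOM dendrogram.

    Label 0 means unassigned (branch below the minimum module size);
    positive labels are sorted by decreasing module size.
    """

    labels: pd.Series
    merge_tree: np.ndarray | None = None
    cut_height: float | None = None
    min_module_size: int = 3

    @property
    def module_labels(self) -> list[int]:
        return sorted(int(l) for l in set(self.labels) if l != 0)

    @property
    def sizes(self) -> dict[int, int]:
        return {lab: int((self.labels == lab).sum()) for lab in self.module_labels}

    def genes_in(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _default_cut(tree: np.ndarray, min_module_size: int,
                 max_height: float) -> float:
    """Data-driven static cut: the midpoint of the largest gap in the sorted
    merge heights, ignoring the lowest 5% of merges (near-duplicate pairs
    join at tiny heights and would otherwise dominate the gap search)."""
    if not len(tree):
        return 0.5
    heights = np.sort(tree[:, 2])
    skip = max(1, int(0.05 * heights.size)) if heights.size > 1 else 0
    gaps = np.diff(heights)
    if gaps.size <= skip or gaps[skip:].max() <= 0:
        return 0.99 * max_height if max_height > 0 else 0.5
    gi = skip + int(np.argmax(gaps[skip:]))
    cut = float(0.5 * (heights[gi] + heights[gi + 1]))
    if not (0.0 < cut < 1.0):
        return 0.99 * max_height if max_height > 0 else 0.5
    return cut


def cut_modules(tom: pd.DataFrame, min_module_size: int = 30,
                cut_height: float | None = None) -> ModulePartition:
    """Define modules as dendrogram branches of the TOM clustering.

    Genes are clustered by average linkage on dissimilarity 1 - TOM and the
    tree is cut statically at ``cut_height``.  The default cut is data
    driven: candidate heights are the midpoints of the largest gaps in the
    sorted merge heights (where tight branch formation ends and the diffuse
    background starts agglomerating), and the candidate retaining the most
    modules of at least ``min_module_size`` genes wins (ties: wider gap).
    Branches smaller than ``min_module_size`` are left unassigned
    (label 0); remaining modules are relabelled 1..M by decreasing size.
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    dist = np.clip(1.0 - tom.to_numpy(dtype=float), 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    max_height = float(tree[:, 2].max()) if len(tree) else 0.0
    if cut_height is None:
        cut_height = _default_cut(tree, min_module_size, max_height)
    if not (0.0 < cut_height < 1.0):
        raise ValueError("cut_height must lie in (0, 1)")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = [lab for lab in sizes.index if sizes[lab] >= min_module_size]
    # decreasing size, original label as deterministic tie-break
    keep.sort(key=lambda lab: (-sizes[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(keep)}
    final = labels.map(lambda lab: remap.get(lab, 0))
    return ModulePartition(labels=final, merge_tree=tree,
                           cut_height=float(cut_height),
                           min_module_size=min_module_size)


def module_eigengene(m: ExpressionMatrix, p: ModulePartition) -> pd.DataFrame:
    """Module eigengenes: samples x modules matrix of unit-norm vectors.

    The eigengene of a module is the leading right singular vector (over
    samples) of the gene-standardised module submatrix — the module's
    representative expression profile.  Its sign is anchored so that the
    correlation with the module's mean standardised profile is >= 0.
    """
    out = {}
    for lab in p.module_labels:
        genes = p.genes_in(lab)
        if len(genes) < 2:
            raise ValueError(f"module {lab} has fewer than 2 genes")
        sub = m.values.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if np.all(sd == 0):
            raise ValueError(f"module {lab} has zero total variance")
        Z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        eig = vt[0]
        anchor = float(eig @ Z.mean(axis=0))
        if anchor < 0 or (anchor == 0 and eig[np.flatnonzero(eig)[0]] < 0
                          if np.any(eig) else False):
            eig = -eig
        out[lab] = eig
    return pd.DataFrame(out, index=m.values.columns)


def merge_similar_modules(m: ExpressionMatrix, p: ModulePartition,
                          merge_correlation: float = 0.75,
                          eigengenes: pd.DataFrame | None = None,
                          ) -> tuple[ModulePartition, pd.DataFrame]:
    """Merge modules whose eigengenes are highly correlated.

    Modules with pairwise eigengene Pearson correlation at or above
    ``merge_correlation`` are united transitively (connected components of
    the similarity graph); labels are reassigned by decreasing merged size
    and eigengenes recomputed.
    """
    if not p.module_labels:
        raise ValueError("partition has no modules to merge")
    if eigengenes is None:
        eigengenes = module_eigengene(m, p)
    labs = list(eigengenes.columns)
    g = nx.Graph()
    g.add_nodes_from(labs)
    E = eigengenes.to_numpy(dtype=float)
    for i, a in enumerate(labs):
        for j in range(i + 1, len(labs)):
            r = float(np.corrcoef(E[:, i], E[:, j])[0, 1])
            if r >= merge_correlation:
                g.add_edge(a, labs[j])
    groups = [sorted(c) for c in nx.connected_components(g)]
    sizes = p.sizes
    groups.sort(key=lambda grp: (-sum(sizes[l] for l in grp), grp[0]))
    remap = {old: new + 1 for new, grp in enumerate(groups) for old in grp}
    merged = ModulePartition(
        labels=p.labels.map(lambda lab: remap.get(lab, 0)),
        merge_tree=p.merge_tree, cut_height=p.cut_height,
        min_module_size=p.min_module_size)
    return merged, module_eigengene(m, merged)


def export_edge_list(tom: pd.DataFrame, weight_floor: float = 0.1) -> pd.DataFrame:
    """Weighted edge list (gene1, gene2, tom) for external network viewers,
    keeping only edges at or above ``weight_floor``."""
    genes = list(tom.index)
    T = tom.to_numpy(dtype=float)
    rows = [(genes[i], genes[j], float(T[i, j]))
            for i in range(len(genes)) for j in range(i + 1, len(genes))
            if T[i, j] >= weight_floor]
    return pd.DataFrame(rows, columns=["gene1", "gene2", "tom"])
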