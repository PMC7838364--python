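"""Selection and validation of the oil-biosynthesis module.

Modules that contain pathway seed genes (core fatty-acid-synthesis /
desaturase / TAG-assembly enzymes) and share the seed-richest module's
expression pattern are merged into one oil-biosynthesis gene set; its
cohesion is validated by a gene-set permutation test on the topological
overlap matrix, and its association with the pathway annotation by an
upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import GeneSet
from .network import ModulePartition


def select_oil_module(p: ModulePartition, eigengenes: pd.DataFrame,
                      seeds: GeneSet, pattern_correlation: float = 0.75) -> set[str]:
    """Unite seed-containing modules with a shared expression pattern.

    Modules holding at least one seed gene are candidates; those whose
    eigengene correlates at or above ``pattern_correlation`` with the
    seed-richest module's eigengene (including that module itself) are
    merged into one gene set.
    """
    labels = p.labels
    seed_counts: dict[int, int] = {}
    for gene in seeds.genes:
        if gene in labels.index and labels[gene] != 0:
            lab = int(labels[gene])
            seed_counts[lab] = seed_counts.get(lab, 0) + 1
    if not seed_counts:
        raise ValueError("no seed gene is assigned to any module")
    # seed-richest module; smaller label breaks ties deterministically
    anchor = min(seed_counts, key=lambda lab: (-seed_counts[lab], lab))
    anchor_eig = eigengenes[anchor].to_numpy(dtype=float)
    selected = []
    for lab in seed_counts:
        r = float(np.corrcoef(anchor_eig, eigengenes[lab].to_numpy(dtype=float))[0, 1])
        if lab == anchor or r >= pattern_correlation:
            selected.append(lab)
    out: set[str] = set()
    for lab in selected:
        out |= set(p.genes_in(lab))
    return out


@dataclass
class ModuleValidation:
    """Result of the cohesion permutation test on a module."""

    statistic: float            # mean (or median) intramodular TOM
    p_value: float
    n_permutations: int
    null_mean: float
    null_sd: float


def permutation_robustness(tom: pd.DataFrame, module: set[str],
                           n_permutations: int = 5000, seed: int = 0,
                           statistic: str = "mean") -> ModuleValidation:
    """Validate module cohesion against random equal-size gene sets.

    The statistic is the mean (or median) off-diagonal TOM within the
    module; the null draws ``n_permutations`` random gene sets of the same
    size from the network and recomputes it.  The p-value uses the add-one
    rule p = (1 + #{null >= observed}) / (n_permutations + 1), so it can
    never be 0.
    """
    genes = list(tom.index)
    module = sorted(module)
    missing = [g for g in module if g not in tom.index]
    if missing:
        raise ValueError(f"module genes absent from the network: {missing[:5]}")
    if len(module) < 2:
        raise ValueError("module must contain at least 2 genes")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    agg = {"mean": np.mean, "median": np.median}.get(statistic)
    if agg is None:
        raise ValueError(f"unknown statistic {statistic!r}")
    T = tom.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}

    def cohesion(idx: np.ndarray) -> float:
        sub = T[np.ix_(idx, idx)]
        off = sub[~np.eye(len(idx), dtype=bool)]
        return float(agg(off))

    observed = cohesion(np.array([pos[g] for g in module]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    n, k = len(genes), len(module)
    for b in range(n_permutations):
        null[b] = cohesion(rng.choice(n, size=k, replace=False))
    p = (1.0 + float((null >= observed).sum())) / (n_permutations + 1.0)
    return ModuleValidation(statistic=observed, p_value=p,
                            n_permutations=n_permutations,
                            null_mean=float(null.mean()),
                            null_sd=float(null.std(ddof=1)) if n_permutations > 1 else 0.0)


def hypergeometric_test(module: set[str], annotated: GeneSet,
                        background_size: int) -> float:
    """Upper-tail hypergeometric probability of the module/annotation overlap.

    P(X >= observed overlap) for X ~ Hypergeometric(N=background_size,
    K=|annotated|, n=|module|).  Both sets must fit inside the background.
    """
    overlap = len(set(module) & set(annotated.genes))
    n_mod, n_ann = len(set(module)), len(annotated.genes)
    if background_size < len(set(module) | set(annotated.genes)):
        raise ValueError("background smaller than the union of the sets")
    if overlap > min(n_mod, n_ann):
        raise ValueError("overlap exceeds set sizes: inconsistent inputs")
    return float(hypergeom.sf(overlap - 1, background_size, n_ann, n_mod))


def enrich_terms(module: set[str], terms: list[GeneSet], background_size: int,
                 q_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene set against a term -> gene map.

    One upper-tail test per term, BH-corrected across terms.  Term
    assignment (GO/KEGG retrieval) is upstream of this interface; any
    caller-supplied list of named gene sets works.
    """
    if not terms:
        raise ValueError("no terms supplied")
    rows = []
    for term in terms:
        overlap = len(set(module) & set(term.genes))
        p = hypergeometric_test(module, term, background_size)
        rows.append({"term": term.name, "overlap": overlap,
                     "term_size": len(term.genes), "p": p})
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["p", "overlap"], ascending=[True, False])
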