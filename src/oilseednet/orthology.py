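"""Cross-species gene correspondence from similarity hit tables.

One-to-one orthologs come from the reciprocal-best-hit (RBH) rule; putative
gene families (orthogroups) from connected components of the
normalised-score similarity graph.  The package consumes tabular hits; the
sequence search that produces them is upstream of this interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .containers import validate_hits


def _best_hits(hits: pd.DataFrame) -> dict[str, str | None]:
    """Unique best subject per query: highest score, identity as tie-break;
    a remaining tie disqualifies the query (maps to None)."""
    best: dict[str, str | None] = {}
    for query, sub in hits.groupby("query"):
        top_score = sub["score"].max()
        at_top = sub[sub["score"] == top_score]
        if len(at_top) > 1:
            top_ident = at_top["identity"].max()
            at_top = at_top[at_top["identity"] == top_ident]
        if len(at_top) == 1:
            best[query] = at_top.iloc[0]["subject"]
        else:
            best[query] = None          # ambiguous best hit
    return best


def reciprocal_best_hits(hits: pd.DataFrame, species_a: str,
                         species_b: str) -> set[tuple[str, str]]:
    """One-to-one ortholog pairs between two species by reciprocal best hit.

    (a, b) is a pair iff b is a's unique top-scoring hit among species-B
    subjects and a is b's unique top-scoring hit among species-A subjects.
    Score ties are first broken by identity; a residual tie disqualifies
    the gene (ambiguous orthology must not seed cross-species claims).
    Pairs are returned with the species-A gene first.
    """
    validate_hits(hits)
    if hits.empty:
        return set()
    a_to_b = hits[(hits["query_species"] == species_a)
                  & (hits["subject_species"] == species_b)]
    b_to_a = hits[(hits["query_species"] == species_b)
                  & (hits["subject_species"] == species_a)]
    best_ab = _best_hits(a_to_b)
    best_ba = _best_hits(b_to_a)
    pairs = set()
    for a, b in best_ab.items():
        if b is not None and best_ba.get(b) == a:
            pairs.add((a, b))
    return pairs


@dataclass
class OrthologySet:
    """RBH pairs per species pair plus multi-species orthogroups."""

    rbh_pairs: dict[tuple[str, str], set[tuple[str, str]]] = field(default_factory=dict)
    orthogroups: list[frozenset[str]] = field(default_factory=list)

    def group_of(self) -> dict[str, int]:
        out = {}
        for i, grp in enumerate(self.orthogroups):
            for g in grp:
                out[g] = i
        return out


def build_orthogroups(hits: pd.DataFrame, species: list[str],
                      score_floor: float = 0.5) -> list[frozenset[str]]:
    """Group genes into putative ortholog families by similarity.

    Each hit's score is normalised by its query's own best score; hits at
    or above ``score_floor`` become undirected edges, and connected
    components are the orthogroups.  Genes appearing in the table but left
    without qualifying edges are emitted as singleton groups.  This is a
    deterministic graph-clustering procedure (no phylogeny awareness).
    """
    validate_hits(hits)
    if len(species) < 2:
        raise ValueError("orthogroups need at least 2 species")
    if score_floor < 0:
        raise ValueError("score_floor must be non-negative")
    g = nx.Graph()
    all_genes = sorted(set(hits["query"]) | set(hits["subject"]))
    g.add_nodes_from(all_genes)
    if len(hits):
        best = hits.groupby("query")["score"].max()
        norm = hits["score"] / hits["query"].map(best)
        for q, s, keep in zip(hits["query"], hits["subject"], norm >= score_floor):
            if keep and q != s:
                g.add_edge(q, s)
    groups = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(groups, key=lambda grp: sorted(grp)[0])


def map_gene_sets(groups: list[frozenset[str]], sets: dict[str, set[str]],
                  species_of: dict[str, str]) -> tuple[list[frozenset[str]], dict[str, bool]]:
    """Find orthogroups shared by every species' gene set.

    ``sets`` maps species -> gene set (e.g. each species' oil module).  An
    orthogroup is shared iff it contains at least one set member from every
    species; genes in shared groups are flagged conserved.

    Returns (shared orthogroups, gene -> conserved flag over all set members).
    """
    covered = {species_of.get(g) for grp in groups for g in grp}
    missing = [sp for sp in sets if sp not in covered]
    if missing:
        raise ValueError(f"species absent from the orthogroups: {missing}")
    shared = []
    for grp in groups:
        ok = True
        for sp, members in sets.items():
            if not any(g in members and species_of.get(g) == sp for g in grp):
                ok = False
                break
        if ok:
            shared.append(grp)
    shared_genes = {g for grp in shared for g in grp}
    flags = {g: (g in shared_genes) for members in sets.values() for g in members}
    return shared, flags
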