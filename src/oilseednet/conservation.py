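"""Cross-species conserved co-expression.

The headline question: which genes of a focal species' oil-biosynthesis
module are co-expressed with the pathway in *every* species examined?
Membership is compared at orthogroup resolution — a focal gene counts as
conserved when its ortholog family contains oil-module members from each
other species — and the conserved set is then intersected with the
interspecific differential-expression results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


def conserved_coexpressed(modules: dict[str, set[str]],
                          groups: list[frozenset[str]],
                          focal: str,
                          species_of: dict[str, str]) -> set[str]:
    """Focal-species module genes whose orthogroup is covered in all species.

    A focal gene is conserved iff its orthogroup contains at least one
    oil-module member from every non-focal species in ``modules``.  Any
    module membership in the other species counts (same-module identity
    across species is not required).
    """
    if focal not in modules:
        raise ValueError(f"focal species {focal!r} not among the module sets")
    covered = {species_of.get(g) for grp in groups for g in grp}
    missing = [sp for sp in modules if sp not in covered]
    if missing:
        raise ValueError(f"no orthogroup coverage for species: {missing}")
    group_of: dict[str, int] = {}
    for i, grp in enumerate(groups):
        for g in grp:
            group_of[g] = i
    others = [sp for sp in modules if sp != focal]
    out = set()
    for gene in modules[focal]:
        gi = group_of.get(gene)
        if gi is None:
            continue
        grp = groups[gi]
        if all(any(h in modules[sp] and species_of.get(h) == sp for h in grp)
               for sp in others):
            out.add(gene)
    return out


def intersect_with_degs(conserved: set[str], degs: pd.DataFrame) -> set[str]:
    """Conserved genes that are also interspecifically differentially
    expressed (``is_de`` in the DEG screen results)."""
    missing = [g for g in conserved if g not in degs.index]
    if missing:
        raise ValueError(f"DEG results do not cover genes: {missing[:5]}")
    de = set(degs.index[degs["is_de"]])
    return set(conserved) & de


def coexpression_neighbors(tom: pd.DataFrame, anchors: set[str],
                           top_k: int | None = None,
                           weight_floor: float | None = None,
                           ) -> dict[str, set[str]]:
    """Genes tightly co-expressed with each anchor (e.g. FAD2/FAD3).

    Selection is either all genes with TOM >= ``weight_floor`` or the
    ``top_k`` highest-TOM partners; exactly one criterion must be given.
    """
    if (top_k is None) == (weight_floor is None):
        raise ValueError("give exactly one of top_k or weight_floor")
    missing = [a for a in anchors if a not in tom.index]
    if missing:
        raise ValueError(f"anchor genes absent from the network: {missing}")
    out: dict[str, set[str]] = {}
    for anchor in sorted(anchors):
        weights = tom.loc[anchor].drop(anchor)
        if weight_floor is not None:
            out[anchor] = set(weights.index[weights >= weight_floor])
        else:
            k = min(top_k, len(weights))
            out[anchor] = set(weights.nlargest(k).index)
    return out


def neighbor_consensus(neighbor_unions: dict[str, set[str]],
                       groups: list[frozenset[str]],
                       focal: str,
                       species_of: dict[str, str]) -> set[str]:
    """Cross-species consensus of anchor neighbourhoods.

    ``neighbor_unions`` maps species -> union of its anchors' neighbour
    sets.  A focal-species neighbour is in the consensus when its
    orthogroup intersects every species' neighbour union (a neighbour
    "matches" if any member of its family is a neighbour elsewhere).
    """
    if focal not in neighbor_unions:
        raise ValueError(f"focal species {focal!r} has no neighbour set")
    group_of: dict[str, int] = {}
    for i, grp in enumerate(groups):
        for g in grp:
            group_of[g] = i
    others = [sp for sp in neighbor_unions if sp != focal]
    out = set()
    for gene in neighbor_unions[focal]:
        gi = group_of.get(gene)
        if gi is None:
            continue
        grp = groups[gi]
        if all(grp & neighbor_unions[sp] for sp in others):
            out.add(gene)
    return out


@dataclass
class ConservationReport:
    """Bundled outcome of the cross-species comparison.

    Invariant chain: ``conserved_and_de`` ⊆ ``conserved`` ⊆ the focal
    species' oil module; checked on construction.
    """

    focal: str
    modules: dict[str, set[str]]
    shared_orthogroups: list[frozenset[str]]
    conserved: set[str]
    conserved_and_de: set[str]
    fad_neighbors: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    neighbor_consensus: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.conserved_and_de <= self.conserved:
            raise ValueError("conserved_and_de must be a subset of conserved")
        if not self.conserved <= self.modules[self.focal]:
            raise ValueError("conserved genes must lie in the focal oil module")

    def counts(self) -> dict[str, int]:
        return {
            "focal_module_size": len(self.modules[self.focal]),
            "shared_orthogroups": len(self.shared_orthogroups),
            "conserved_coexpressed": len(self.conserved),
            "conserved_and_de": len(self.conserved_and_de),
            "neighbor_consensus": len(self.neighbor_consensus),
        }
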