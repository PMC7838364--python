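"""Pathway expression stoichiometry across species.

Expression stoichiometry is a pathway gene's share of the pathway's total
transcript abundance at a developmental stage: fraction_g,stage =
mean expr(g) / sum over all pathway genes of the mean expr.  Comparing the
per-stage fraction vectors across species (squared Pearson correlation)
and the per-gene coefficient of variation of the pooled fractions
quantifies how conserved the pathway's internal transcript balance is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet


@dataclass
class StoichiometryTable:
    """Per species: pathway-gene transcript fractions by stage.

    ``fractions`` is genes x stages; for each stage the fractions over the
    combined pathway (FA synthesis plus TAG assembly) sum to 1.
    """

    species: str
    fractions: pd.DataFrame
    fas_genes: frozenset[str]
    tag_genes: frozenset[str]

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1 per stage")

    @property
    def stages(self) -> list[int]:
        return list(self.fractions.columns)


def stoichiometry_fractions(m: ExpressionMatrix, fas: GeneSet, tag: GeneSet,
                            enzyme_map: dict[str, str] | None = None,
                            ) -> StoichiometryTable:
    """Transcript fraction of each pathway gene per developmental stage.

    Replicates are averaged per stage before fractions are taken, and the
    denominator is the summed mean expression of the combined FA-synthesis
    and TAG-assembly sets.  With ``enzyme_map`` (transcript id -> enzyme
    symbol) multiple transcripts of one enzyme are summed to the symbol
    before fractions, so the table is enzyme-level.
    """
    pathway = sorted(set(fas.genes) | set(tag.genes))
    missing = [g for g in pathway if g not in m.values.index]
    if missing:
        raise ValueError(f"pathway genes absent from the matrix: {missing[:5]}")
    species = m.samples["species"].unique()
    if len(species) != 1:
        raise ValueError("one species per stoichiometry table")
    means = m.stage_means().loc[pathway]
    fas_ids, tag_ids = set(fas.genes), set(tag.genes)
    if enzyme_map is not None:
        grouping = [enzyme_map.get(g, g) for g in means.index]
        fas_ids = {enzyme_map.get(g, g) for g in fas_ids}
        tag_ids = {enzyme_map.get(g, g) for g in tag_ids}
        means = means.groupby(grouping).sum()
    totals = means.sum(axis=0)
    if (totals <= 0).any():
        stage = totals.index[totals <= 0][0]
        raise ValueError(f"zero pathway expression at stage {stage}")
    fractions = means.div(totals, axis=1)
    return StoichiometryTable(species=str(species[0]), fractions=fractions,
                              fas_genes=frozenset(fas_ids),
                              tag_genes=frozenset(tag_ids))


def _aligned(a: StoichiometryTable, b: StoichiometryTable,
             genes=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    if a.stages != b.stages:
        raise ValueError("tables cover different stages")
    genes = sorted(set(a.fractions.index)) if genes is None else sorted(genes)
    for tab, name in ((a, "first"), (b, "second")):
        missing = [g for g in genes if g not in tab.fractions.index]
        if missing:
            raise ValueError(f"genes absent from the {name} table: {missing[:5]}")
    return a.fractions.loc[genes], b.fractions.loc[genes]


def stoichiometry_cv(a: StoichiometryTable, b: StoichiometryTable,
                     genes=None) -> pd.Series:
    """Per-gene CV (sd/mean) of the stoichiometry fractions pooled over the
    stages of both species — low CV marks a conserved transcript share."""
    fa, fb = _aligned(a, b, genes)
    pooled = np.hstack([fa.to_numpy(dtype=float), fb.to_numpy(dtype=float)])
    mean = pooled.mean(axis=1)
    sd = pooled.std(axis=1, ddof=1)
    cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    return pd.Series(cv, index=fa.index, name="cv")


def stage_correlation(a: StoichiometryTable, b: StoichiometryTable,
                      genes=None) -> pd.Series:
    """Squared Pearson correlation of the two species' per-stage fraction
    vectors; needs >= 3 genes, NaN where a vector has zero variance."""
    fa, fb = _aligned(a, b, genes)
    if fa.shape[0] < 3:
        raise ValueError("need at least 3 genes for a stage correlation")
    out = {}
    for stage in fa.columns:
        x = fa[stage].to_numpy(dtype=float)
        y = fb[stage].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            out[stage] = np.nan
        else:
            out[stage] = float(np.corrcoef(x, y)[0, 1]) ** 2
    return pd.Series(out, name="r2")
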