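"""Core in-memory containers shared across the package.

The analysis revolves around a small set of tabular objects: a gene x sample
expression matrix with sample metadata, named gene sets, and similarity hit
tables.  All of them wrap :mod:`pandas` structures so that indexing, joins
and I/O stay idiomatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every sample table must carry
SAMPLE_COLS = ("species", "tissue", "stage_daf", "replicate")


def sample_id(species: str, stage_daf: int, replicate: int, tissue: str = "seed") -> str:
    """Canonical sample identifier ``species.stage.rep`` (tissue omitted for seed)."""
    if tissue == "seed":
        return f"{species}.{stage_daf}.{replicate}"
    return f"{species}.{tissue}.{stage_daf}.{replicate}"


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``species``, ``tissue``,
        ``stage_daf`` and ``replicate``; its index must match the columns of
        ``values`` (same order).
    unit
        ``"count"`` for raw fragment counts (then ``gene_lengths`` is
        required) or ``"fpkm"`` for length/depth-normalised values.
    gene_lengths
        Transcript lengths in nucleotides, indexed like ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "fpkm"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ValueError("expression matrix needs at least one sample")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if (np.asarray(self.values, dtype=float) < 0).any():
            raise ValueError("expression values must be non-negative")
        if list(self.samples.index) != list(self.values.columns):
            raise ValueError("sample table index must match value columns")
        missing = [c for c in SAMPLE_COLS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table lacks columns: {missing}")
        if self.unit not in ("count", "fpkm"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit == "count" and self.gene_lengths is None:
            raise ValueError("count matrices require gene_lengths")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
            if self.gene_lengths.isna().any():
                gene = self.gene_lengths.index[self.gene_lengths.isna()][0]
                raise ValueError(f"no length for gene {gene!r}")
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene lengths must be positive")

    # -- convenience -------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def stage_means(self) -> pd.DataFrame:
        """Replicate-averaged expression, one column per developmental stage.

        Stages are ordered ascending by days-after-flowering.
        """
        stages = self.samples["stage_daf"]
        out = {}
        for stage in sorted(stages.unique()):
            cols = stages.index[stages == stage]
            out[stage] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[genes]
        return ExpressionMatrix(
            values=self.values.loc[genes].copy(),
            samples=self.samples.copy(),
            unit=self.unit,
            gene_lengths=lengths,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene ids (pathway seeds, annotation terms ...)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    @staticmethod
    def from_iterable(name: str, genes, description: str = "") -> "GeneSet":
        genes = list(genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {name!r} has duplicate members")
        return GeneSet(name=name, genes=frozenset(genes), description=description)


#: required columns of a similarity hit table (outfmt-6-like plus species)
HIT_COLS = ("query", "subject", "query_species", "subject_species",
            "score", "identity", "coverage")


def validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Check a similarity hit table and return it unchanged.

    ``identity`` and ``coverage`` are fractions in [0, 1]; ``score`` is a
    non-negative bit-score-like number.
    """
    missing = [c for c in HIT_COLS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table lacks columns: {missing}")
    if len(hits):
        if (hits["score"] < 0).any():
            raise ValueError("hit scores must be non-negative")
        for col in ("identity", "coverage"):
            if ((hits[col] < 0) | (hits[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
    return hits


@dataclass
class FattyAcidProfile:
    """Per-sample fatty-acid composition as mass fractions of total FA.

    ``proportions`` maps keys like ``"C18:1"`` to fractions in [0, 1]; with
    the optional ``"other"`` bucket included the fractions sum to 1.
    """

    species: str
    stage_daf: int
    replicate: int
    proportions: dict[str, float] = field(default_factory=dict)
    tissue: str = "seed"

    def __post_init__(self) -> None:
        for key, frac in self.proportions.items():
            if not (0.0 <= frac <= 1.0 + 1e-9):
                raise ValueError(f"proportion {key}={frac} outside [0, 1]")
        total = sum(self.proportions.values())
        if "other" in self.proportions and abs(total - 1.0) > 1e-6:
            raise ValueError(f"proportions sum to {total}, expected 1")

    def get(self, key: str, default: float = 0.0) -> float:
        return self.proportions.get(key, default)
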