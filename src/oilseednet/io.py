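"""Readers and writers for the plain-text formats used by the pipeline.

Expression matrices travel as TSV (first column ``gene_id``, sample ids
``species.stage.rep`` in the header), fatty-acid tables as CSV, similarity
hits as outfmt-6-like TSV with a species-map sidecar, gene sets as GMT.
All floats are written with a fixed format so that reruns are byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, FattyAcidProfile, GeneSet, validate_hits

FLOAT_FMT = "%.10g"


# -- expression matrices ---------------------------------------------------

def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression(path, samples: pd.DataFrame | None = None,
                    unit: str = "fpkm",
                    gene_lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV; sample metadata is parsed from the header
    (``species.stage.rep``) unless an explicit sample table is given."""
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    if samples is None:
        rows = []
        for sid in values.columns:
            parts = sid.split(".")
            if len(parts) == 3:
                species, stage, rep = parts
                tissue = "seed"
            elif len(parts) == 4:
                species, tissue, stage, rep = parts
            else:
                raise ValueError(f"cannot parse sample id {sid!r}")
            rows.append({"sample": sid, "species": species, "tissue": tissue,
                         "stage_daf": int(stage), "replicate": int(rep)})
        samples = pd.DataFrame(rows).set_index("sample")
    return ExpressionMatrix(values=values, samples=samples, unit=unit,
                            gene_lengths=gene_lengths)


def write_gene_lengths(lengths: pd.Series, path) -> None:
    df = lengths.rename("length_nt").to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_gene_lengths(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="gene_id")["length_nt"]


# -- fatty-acid tables -----------------------------------------------------

def write_fa_profiles(profiles: list[FattyAcidProfile], path) -> None:
    keys = sorted({k for p in profiles for k in p.proportions})
    rows = []
    for p in profiles:
        row = {"species": p.species, "tissue": p.tissue,
               "stage_daf": p.stage_daf, "replicate": p.replicate}
        row.update({k: p.proportions.get(k, 0.0) for k in keys})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_fa_profiles(path) -> list[FattyAcidProfile]:
    df = pd.read_csv(path)
    meta = {"species", "tissue", "stage_daf", "replicate"}
    keys = [c for c in df.columns if c not in meta]
    out = []
    for _, row in df.iterrows():
        out.append(FattyAcidProfile(
            species=row["species"], tissue=row.get("tissue", "seed"),
            stage_daf=int(row["stage_daf"]), replicate=int(row["replicate"]),
            proportions={k: float(row[k]) for k in keys},
        ))
    return out


# -- similarity hit tables -------------------------------------------------

#: column order of the outfmt-6-like on-disk representation
_HIT_FILE_COLS = ["qseqid", "sseqid", "pident", "length", "bitscore", "qcovs"]


def write_hits(hits: pd.DataFrame, path, species_map_path=None) -> None:
    """Write hits as outfmt-6-like TSV; identity/coverage stored as percent.

    If ``species_map_path`` is given, a two-column gene id -> species sidecar
    is written alongside so the table can be reread without the species
    columns.
    """
    validate_hits(hits)
    out = pd.DataFrame({
        "qseqid": hits["query"],
        "sseqid": hits["subject"],
        "pident": hits["identity"] * 100.0,
        "length": hits.get("length", pd.Series([0] * len(hits))).astype(int)
        if "length" in hits.columns else 0,
        "bitscore": hits["score"],
        "qcovs": hits["coverage"] * 100.0,
    })
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    if species_map_path is not None:
        pairs = pd.concat([
            hits[["query", "query_species"]].rename(
                columns={"query": "gene_id", "query_species": "species"}),
            hits[["subject", "subject_species"]].rename(
                columns={"subject": "gene_id", "subject_species": "species"}),
        ]).drop_duplicates().sort_values("gene_id")
        pairs.to_csv(species_map_path, sep="\t", index=False)


def read_hits(path, species_map_path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    smap = pd.read_csv(species_map_path, sep="\t").set_index("gene_id")["species"]
    hits = pd.DataFrame({
        "query": raw["qseqid"],
        "subject": raw["sseqid"],
        "query_species": raw["qseqid"].map(smap),
        "subject_species": raw["sseqid"].map(smap),
        "score": raw["bitscore"],
        "identity": raw["pident"] / 100.0,
        "coverage": raw["qcovs"] / 100.0,
    })
    if hits["query_species"].isna().any() or hits["subject_species"].isna().any():
        raise ValueError("species map does not cover all hit-table genes")
    return validate_hits(hits)


# -- gene sets (GMT) -------------------------------------------------------

def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


def read_gmt(path) -> list[GeneSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, description, *members = line.split("\t")
            out.append(GeneSet.from_iterable(name, members, description))
    return out


# -- generic JSON-ish key-value artifacts ----------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)}")
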