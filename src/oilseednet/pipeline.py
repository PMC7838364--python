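"""End-to-end orchestration: simulate -> profiles -> DEGs -> networks ->
oil-module selection/validation -> orthology -> conservation ->
stoichiometry -> report.

Every stage writes its artifacts into the output directory in dependency
order; a manifest records the full configuration, per-stage gene counts
and SHA-256 digests of every artifact, so a rerun with the same config and
seed is byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, io, network, oilmodule, orthology, profiles, stoichiometry
from .conservation import (ConservationReport, coexpression_neighbors,
                           conserved_coexpressed, intersect_with_degs,
                           neighbor_consensus)
from .containers import GeneSet
from .simulate import (SimConfig, simulate_expression, simulate_fa_profiles,
                       simulate_similarity_table)

FLOAT_FMT = io.FLOAT_FMT


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending input."""


@dataclass
class RunConfig:
    """All pipeline thresholds in one place, serialised into the manifest.

    Defaults follow the analysis conventions this pipeline implements:
    transcript collapsing at 90% identity / 80% coverage, 5,000 gene-set
    permutations with significance at 1e-3, hypergeometric validation at
    1e-6, BH q < 0.05 for differential expression.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    q_threshold: float = 0.05
    n_deg_permutations: int = 499
    identity_min: float = 0.90
    coverage_min: float = 0.80
    beta_grid: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
    r2_target: float = 0.8
    default_beta: float = 6.0     # used when no beta reaches the fit target
    min_module_size: int = 20
    cut_height: float | None = None
    merge_correlation: float = 0.75
    pattern_correlation: float = 0.75
    n_permutations: int = 5000
    permutation_alpha: float = 1e-3
    hypergeometric_alpha: float = 1e-6
    neighbor_floor_quantile: float = 0.99
    score_floor: float = 0.5
    decoy_rate: float = 0.1
    n_seed_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_threshold", "identity_min", "coverage_min",
                     "r2_target", "merge_correlation", "pattern_correlation",
                     "permutation_alpha", "hypergeometric_alpha",
                     "neighbor_floor_quantile"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.n_permutations < 1 or self.n_deg_permutations < 1:
            raise ValueError("permutation counts must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["planted_modules"] = [list(dataclasses.astuple(m))
                                       for m in self.sim.planted_modules]
        d["sim"]["de_genes"] = [list(dataclasses.astuple(g))
                                for g in self.sim.de_genes]
        d["sim"]["paralog_events"] = [list(dataclasses.astuple(e))
                                      for e in self.sim.paralog_events]
        d["sim"]["stages"] = list(self.sim.stages)
        d["beta_grid"] = list(self.beta_grid)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .simulate import DEGene, ParalogEvent, PlantedModule
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        sim_kwargs = dict(sim_raw)
        if "planted_modules" in sim_kwargs:
            sim_kwargs["planted_modules"] = tuple(
                PlantedModule(*m) for m in sim_kwargs["planted_modules"])
        if "de_genes" in sim_kwargs:
            sim_kwargs["de_genes"] = tuple(DEGene(*g) for g in sim_kwargs["de_genes"])
        if "paralog_events" in sim_kwargs:
            sim_kwargs["paralog_events"] = tuple(
                ParalogEvent(*e) for e in sim_kwargs["paralog_events"])
        if "stages" in sim_kwargs:
            sim_kwargs["stages"] = tuple(sim_kwargs["stages"])
        if "beta_grid" in raw:
            raw["beta_grid"] = tuple(raw["beta_grid"])
        return cls(sim=SimConfig(**sim_kwargs), **raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> ConservationReport:
    """Run every stage on the synthetic study design and write all artifacts.

    Returns the :class:`ConservationReport`; the manifest
    (``manifest.yaml``) lists the serialized config, per-stage counts and
    the SHA-256 digest of every written file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "artifacts": {}}
    written: list[Path] = []

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    # the run-level seed is authoritative for every source of randomness
    sim = dataclasses.replace(config.sim, seed=config.seed)

    # -- stage: simulate ---------------------------------------------------
    try:
        matrices, truth = simulate_expression(sim)
        fa = simulate_fa_profiles(sim)
        hits = simulate_similarity_table(truth, decoy_rate=config.decoy_rate,
                                         seed=sim.seed + 1)
    except Exception as exc:
        raise PipelineError(f"simulate stage failed: {exc}") from exc
    species = list(matrices)
    focal = species[0]
    for sp, m in matrices.items():
        save(f"expression_{sp}.tsv", lambda p, m=m: io.write_expression(m, p))
        save(f"gene_lengths_{sp}.tsv",
             lambda p, m=m: io.write_gene_lengths(m.gene_lengths, p))
    save("fa_profiles.csv", lambda p: io.write_fa_profiles(fa, p))
    save("similarity_hits.tsv",
         lambda p: io.write_hits(hits, p, species_map_path=out / "species_map.tsv"))
    written.append(out / "species_map.tsv")

    # pathway gene sets: FA-synthesis enzymes live in the first planted
    # module, TAG-assembly enzymes in the second
    mod1 = [g for g, lab in truth.module_membership.items() if lab == 1]
    mod2 = [g for g, lab in truth.module_membership.items() if lab == 2]
    seed_sets: dict[str, dict[str, GeneSet]] = {}
    for sp in species:
        fas = sorted(g for g in mod1 if g.startswith(sp + "_") and "c" not in
                     g.split("_g")[1])[: config.n_seed_genes]
        tag = sorted(g for g in mod2 if g.startswith(sp + "_") and "c" not in
                     g.split("_g")[1])[: config.n_seed_genes]
        seed_sets[sp] = {
            "fas": GeneSet.from_iterable(f"fas_{sp}", fas, "FA-synthesis seeds"),
            "tag": GeneSet.from_iterable(f"tag_{sp}", tag, "TAG-assembly seeds"),
        }
        save(f"seed_genes_{sp}.gmt",
             lambda p, sp=sp: io.write_gmt(list(seed_sets[sp].values()), p))
    manifest["stages"]["simulate"] = {
        "species": species,
        "genes_per_species": {sp: matrices[sp].n_genes for sp in species},
        "samples_per_species": {sp: matrices[sp].n_samples for sp in species},
    }

    # -- stage: fatty-acid profiles ---------------------------------------
    try:
        rows = []
        final_stage = sim.stages[-1]
        for p in fa:
            if p.stage_daf != final_stage or p.replicate != 1:
                continue
            de = profiles.desaturation_efficiency(p)
            sfa_ufa, mufa_pufa = profiles.saturation_ratios(p)
            rows.append({"species": p.species, "stage_daf": p.stage_daf,
                         "omega6_de": de.omega6, "omega3_de": de.omega3,
                         "sfa_ufa": sfa_ufa, "mufa_pufa": mufa_pufa})
        de_table = pd.DataFrame(rows)
        save("desaturation.tsv",
             lambda p: de_table.to_csv(p, sep="\t", index=False,
                                       float_format=FLOAT_FMT))
    except Exception as exc:
        raise PipelineError(f"profiles stage failed: {exc}") from exc
    manifest["stages"]["profiles"] = {"rows": len(de_table)}

    # -- stage: interspecific DEG screen (focal vs second species) --------
    try:
        sp_a, sp_b = species[0], species[1]
        rbh = orthology.reciprocal_best_hits(hits, sp_a, sp_b)
        pair_of = dict(rbh)
        paired = [g for g in matrices[sp_a].genes if g in pair_of]
        vals_a = matrices[sp_a].values.loc[paired]
        vals_b = matrices[sp_b].values.loc[[pair_of[g] for g in paired]]
        vals_b.index = paired
        combined = pd.concat([vals_a, vals_b], axis=1)
        samples = pd.concat([matrices[sp_a].samples, matrices[sp_b].samples])
        joint = expression.ExpressionMatrix(values=combined, samples=samples,
                                            unit="fpkm")
        degs = expression.screen_degs(
            joint, list(matrices[sp_a].values.columns),
            list(matrices[sp_b].values.columns),
            n_permutations=config.n_deg_permutations,
            q_threshold=config.q_threshold, seed=sim.seed + 2)
        save("degs_interspecific.tsv",
             lambda p: degs.to_csv(p, sep="\t", index_label="gene_id",
                                   float_format=FLOAT_FMT))
    except Exception as exc:
        raise PipelineError(f"degs stage failed: {exc}") from exc
    manifest["stages"]["degs"] = {"tested": len(degs),
                                  "de": int(degs["is_de"].sum())}

    # -- stage: per-species networks and oil modules ----------------------
    toms: dict[str, pd.DataFrame] = {}
    oil_modules: dict[str, set[str]] = {}
    validations: dict[str, dict] = {}
    for sp in species:
        try:
            m = matrices[sp]
            corr = network.correlation_matrix(m)
            beta_sel = network.pick_beta(corr, candidates=config.beta_grid,
                                         r2_target=config.r2_target)
            # a small planted network is not scale-free; when no candidate
            # meets the fit target, prefer the conventional default power
            # over the erratic max-fit argmax
            beta = beta_sel.beta if not beta_sel.fallback else config.default_beta
            adj = network.soft_threshold(corr, beta)
            tom = network.tom_similarity(adj)
            toms[sp] = tom
            part = network.cut_modules(tom, min_module_size=config.min_module_size,
                                       cut_height=config.cut_height)
            part, eig = network.merge_similar_modules(
                m, part, merge_correlation=config.merge_correlation)
            labels = part.labels.rename("module").to_frame()
            labels.index.name = "gene_id"
            save(f"modules_{sp}.tsv", lambda p, df=labels: df.to_csv(p, sep="\t"))
            edges = network.export_edge_list(tom, weight_floor=0.2)
            save(f"edges_{sp}.tsv",
                 lambda p, df=edges: df.to_csv(p, sep="\t", index=False,
                                               float_format=FLOAT_FMT))
            seeds_all = GeneSet.from_iterable(
                f"oil_seeds_{sp}",
                sorted(set(seed_sets[sp]["fas"].genes) | set(seed_sets[sp]["tag"].genes)))
            oil = oilmodule.select_oil_module(
                part, eig, seeds_all,
                pattern_correlation=config.pattern_correlation)
            oil_modules[sp] = oil
            val = oilmodule.permutation_robustness(
                tom, oil, n_permutations=config.n_permutations,
                seed=sim.seed + 3)
            hyper_p = oilmodule.hypergeometric_test(oil, seeds_all, m.n_genes)
            validations[sp] = {
                "beta": beta,
                "beta_fallback": beta_sel.fallback,
                "n_modules": len(part.module_labels),
                "oil_module_size": len(oil),
                "tom_statistic": val.statistic,
                "permutation_p": val.p_value,
                "permutation_pass": val.p_value < config.permutation_alpha,
                "hypergeometric_p": hyper_p,
                "hypergeometric_pass": hyper_p < config.hypergeometric_alpha,
            }
        except Exception as exc:
            raise PipelineError(f"network stage failed for {sp}: {exc}") from exc
    save("module_validation.tsv",
         lambda p: pd.DataFrame(validations).T.to_csv(p, sep="\t",
                                                      index_label="species",
                                                      float_format=FLOAT_FMT))
    manifest["stages"]["network"] = validations

    # -- stage: orthology --------------------------------------------------
    try:
        groups = orthology.build_orthogroups(hits, species,
                                             score_floor=config.score_floor)
        species_of = {g: g.split("_g")[0]
                      for grp in groups for g in grp}
        rows = [{"group_id": i, "members": ";".join(sorted(grp))}
                for i, grp in enumerate(groups)]
        save("orthogroups.tsv",
             lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
    except Exception as exc:
        raise PipelineError(f"orthology stage failed: {exc}") from exc
    manifest["stages"]["orthology"] = {"orthogroups": len(groups),
                                       "rbh_pairs": len(rbh)}

    # -- stage: conservation ----------------------------------------------
    try:
        shared, _flags = orthology.map_gene_sets(groups, oil_modules, species_of)
        conserved = conserved_coexpressed(oil_modules, groups, focal, species_of)
        conserved_in_screen = {g for g in conserved if g in degs.index}
        conserved_de = intersect_with_degs(conserved_in_screen, degs)
        anchors = {sp: set(sorted(seed_sets[sp]["fas"].genes)[:2]) for sp in species}
        unions: dict[str, set[str]] = {}
        neighbor_sets: dict[str, dict[str, set[str]]] = {}
        for sp in species:
            tom = toms[sp]
            off = tom.to_numpy()[~np.eye(len(tom), dtype=bool)]
            floor = float(np.quantile(off, config.neighbor_floor_quantile))
            nbrs = coexpression_neighbors(tom, anchors[sp], weight_floor=floor)
            neighbor_sets[sp] = nbrs
            unions[sp] = set().union(*nbrs.values()) if nbrs else set()
        consensus = neighbor_consensus(unions, groups, focal, species_of)
        report = ConservationReport(
            focal=focal, modules=oil_modules, shared_orthogroups=shared,
            conserved=conserved, conserved_and_de=conserved_de,
            fad_neighbors=neighbor_sets, neighbor_consensus=consensus)
        save("conservation_report.json",
             lambda p: io.write_json(
                 {"focal": focal,
                  "counts": report.counts(),
                  "conserved": sorted(conserved),
                  "conserved_and_de": sorted(conserved_de),
                  "neighbor_consensus": sorted(consensus)}, p))
    except Exception as exc:
        raise PipelineError(f"conservation stage failed: {exc}") from exc
    manifest["stages"]["conservation"] = report.counts()

    # -- stage: stoichiometry ---------------------------------------------
    try:
        tables = {}
        for sp in species:
            tables[sp] = stoichiometry.stoichiometry_fractions(
                matrices[sp], seed_sets[sp]["fas"], seed_sets[sp]["tag"])
            grid = tables[sp].fractions
            save(f"stoichiometry_{sp}.tsv",
                 lambda p, g=grid: g.to_csv(p, sep="\t", index_label="gene_id",
                                            float_format=FLOAT_FMT))
        # align the second species' table onto focal ids via the truth-free
        # RBH pairing so per-gene comparisons are possible
        sp_b_tab = tables[species[1]]
        rename = {b: a for a, b in rbh}
        aligned = stoichiometry.StoichiometryTable(
            species=species[1],
            fractions=sp_b_tab.fractions.rename(index=rename),
            fas_genes=frozenset(rename.get(g, g) for g in sp_b_tab.fas_genes),
            tag_genes=frozenset(rename.get(g, g) for g in sp_b_tab.tag_genes))
        common = sorted(set(tables[focal].fractions.index)
                        & set(aligned.fractions.index))
        cv = stoichiometry.stoichiometry_cv(tables[focal], aligned, common)
        r2 = stoichiometry.stage_correlation(tables[focal], aligned, common)
        summary = {"mean_cv": float(cv.mean()),
                   "r2_by_stage": {int(k): float(v) for k, v in r2.items()}}
        save("stoichiometry_summary.json", lambda p: io.write_json(summary, p))
    except Exception as exc:
        raise PipelineError(f"stoichiometry stage failed: {exc}") from exc
    manifest["stages"]["stoichiometry"] = summary

    for path in written:
        manifest["artifacts"][path.name] = _digest(path)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True, default_flow_style=False)
    return report
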