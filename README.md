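# oilseednet

Comparative co-expression analysis of seed-oil biosynthesis.

Oilseed species with similar oil content can differ sharply in how
unsaturated that oil is — whether oleic (18:1), linoleic (18:2) or
α-linolenic acid (18:3) dominates is set by the desaturase cascade
(SAD → FAD2 → FAD3) and its regulators during seed development. This
package implements the analysis chain used to hunt for those regulators by
comparing developmental time-course transcriptomes across species:

- **Fatty-acid statistics** — desaturation efficiencies
  DE₆ = (18:2+18:3)/(18:1+18:2+18:3) and DE₃ = 18:3/(18:2+18:3),
  SFA:UFA and MUFA:PUFA ratios, oil-accumulation summaries, 2^−ΔΔCt qPCR
  fold changes.
- **Expression processing** — FPKM normalisation, collapsing of redundant
  transcripts (≥90% identity, ≥80% coverage), a permutation
  differential-expression screen with BH correction, profile-shape
  clustering, CV-based reference-gene ranking.
- **Weighted co-expression networks** — Pearson correlation, signed
  soft-threshold adjacency ((1+r)/2)^β with scale-free β selection,
  topological overlap (TOM), dendrogram module detection, eigengenes,
  module merging.
- **Oil-module validation** — seed-gene-driven module selection, a
  5,000-draw permutation test on module cohesion (P < 10⁻³), hypergeometric
  gene-set validation (P < 10⁻⁶) and enrichment.
- **Orthology** — reciprocal-best-hit one-to-one pairs and orthogroup
  components from BLAST-tabular-like hit tables.
- **Cross-species conservation** — genes whose whole ortholog family is
  oil-co-expressed in every species, intersected with interspecific DEGs;
  desaturase neighbourhood consensus.
- **Expression stoichiometry** — each pathway gene's share of the summed
  pathway transcript pool, with per-stage cross-species r² and per-gene CV.

A bundled synthetic-data generator plants all of this structure (modules,
DE genes, paralogs, orthology, fatty-acid trajectories) with known ground
truth, so the whole pipeline is testable without any sequencing data.

## Worked example

```python
from oilseednet import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=0), "pipeline_out")
print(report.counts())
```

prints

```
{'focal_module_size': 41, 'shared_orthogroups': 40,
 'conserved_coexpressed': 41, 'conserved_and_de': 8,
 'neighbor_consensus': 18}
```

meaning: the focal species' oil-biosynthesis module holds 41 genes; 40
ortholog families are shared by all three species' modules; 41 focal genes
are conservatively co-expressed (their family is oil-co-expressed in every
species); 8 of those are also differentially expressed between the two
contrasted species — the candidate regulators; 18 genes sit in the
desaturase-neighbourhood consensus. All intermediate artifacts (expression
matrices, DEG tables, module assignments, orthogroups, validation report,
stoichiometry grids) land in `pipeline_out/` together with a manifest of
thresholds and file digests; a rerun with the same seed is byte-identical.

Shorter, single-capability scripts live in `examples/`:

| script | shows |
| --- | --- |
| `fatty_acid_profiles.py` | desaturation efficiencies, saturation ratios, ΔΔCt |
| `coexpression_network.py` | correlation → β → TOM → modules, ARI vs planted truth |
| `oil_module_validation.py` | module selection, permutation + hypergeometric tests |
| `cross_species_conservation.py` | RBH, orthogroups, conserved ∩ DE genes |
| `expression_stoichiometry.py` | pathway fractions, per-stage r², CV |
| `run_full_pipeline.py` | the end-to-end run above |

A thin CLI wraps the same calls: `oilseednet run-all --seed 0 --out out/`,
plus `simulate`, `degs`, `network`, `cluster` subcommands.

## Layout

```
src/oilseednet/
  simulate.py        synthetic data with ground truth
  profiles.py        fatty-acid and qPCR statistics
  expression.py      FPKM, collapsing, DEG screen, clustering, CV
  network.py         adjacency, TOM, modules, eigengenes
  oilmodule.py       oil-module selection and validation
  orthology.py       RBH and orthogroups
  conservation.py    cross-species conserved co-expression
  stoichiometry.py   pathway transcript fractions
  pipeline.py        end-to-end orchestration + manifest
  validation.py      planted-structure benchmarks and oracles
  cli.py             thin command-line interface
```

See `docs/methods.md` for the models, defaults and their rationale, and
the limits of what the synthetic benchmarks establish.
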