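"""Cross-species conserved co-expression with the oil pathway.

Simulates three species sharing one oil-biosynthesis module, rebuilds
orthology from a decoy-laden similarity table (RBH pairs + orthogroup
components), finds focal-species genes whose whole ortholog family is
oil-co-expressed, and intersects them with interspecific DEGs.
"""

import pandas as pd

from oilseednet import (DEGene, PlantedModule, SimConfig, build_orthogroups,
                        conserved_coexpressed, intersect_with_degs,
                        reciprocal_best_hits, screen_degs,
                        simulate_expression, simulate_similarity_table)
from oilseednet.containers import ExpressionMatrix

cfg = SimConfig(n_species=3, n_background_genes=200,
                planted_modules=(PlantedModule(40, "bell", 0.8),),
                de_genes=tuple(DEGene(i, 1, 2.0) for i in range(8)),
                paralog_events=(), seed=0)
matrices, truth = simulate_expression(cfg)
hits = simulate_similarity_table(truth, decoy_rate=0.3, seed=1)

rbh = reciprocal_best_hits(hits, "sp1", "sp2")
groups = build_orthogroups(hits, truth.species)
species_of = {g: g.split("_g")[0] for grp in groups for g in grp}
print(f"RBH one-to-one pairs sp1-sp2: {len(rbh)}")
print(f"orthogroups across 3 species: {len(groups)}")

# each species' oil module: here the planted-truth module sets
modules = {sp: set(truth.labels_for(sp).pipe(lambda s: s.index[s == 1]))
           for sp in truth.species}
conserved = conserved_coexpressed(modules, groups, "sp1", species_of)
print(f"sp1 genes conservatively co-expressed in all 3 species: "
      f"{len(conserved)}")

# interspecific DEG screen on RBH-paired genes (sp1 vs sp2, all samples)
pair_of = dict(rbh)
paired = [g for g in matrices["sp1"].genes if g in pair_of]
vals_b = matrices["sp2"].values.loc[[pair_of[g] for g in paired]].copy()
vals_b.index = paired
combined = pd.concat([matrices["sp1"].values.loc[paired], vals_b], axis=1)
samples = pd.concat([matrices["sp1"].samples, matrices["sp2"].samples])
joint = ExpressionMatrix(values=combined, samples=samples, unit="fpkm")
degs = screen_degs(joint, list(matrices["sp1"].values.columns),
                   list(matrices["sp2"].values.columns),
                   n_permutations=499, seed=2)
conserved_de = intersect_with_degs(conserved & set(degs.index), degs)
print(f"of them, interspecifically differentially expressed: "
      f"{len(conserved_de)}")
# these are the prime candidates: pathway-co-expressed in every species AND
# shifted between the species with contrasting oil composition.
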