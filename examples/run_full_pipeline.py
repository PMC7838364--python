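"""End-to-end run of the default synthetic study design.

Simulate three species -> fatty-acid statistics -> interspecific DEG screen
-> per-species networks and oil modules -> orthology -> cross-species
conservation -> stoichiometry; all artifacts and a manifest land in
./pipeline_out.
"""

from oilseednet import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=0), "pipeline_out")
for key, value in report.counts().items():
    print(f"{key}: {value}")
# focal_module_size: genes in the focal species' oil-biosynthesis module;
# conserved_coexpressed: those whose ortholog family is oil-co-expressed in
# every species; conserved_and_de: the subset also differentially expressed
# between the two focal species — the candidate regulators.
print("artifacts and manifest written to pipeline_out/")
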