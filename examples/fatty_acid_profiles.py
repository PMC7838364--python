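"""Fatty-acid composition statistics of a developing oilseed.

Builds one seed-oil composition, computes the omega-6/omega-3 desaturation
efficiencies, the SFA:UFA and MUFA:PUFA ratios, and a qPCR fold change.
"""

from oilseednet import CtRecord, FattyAcidProfile
from oilseednet.profiles import (desaturation_efficiency, relative_expression,
                                 saturation_ratios)

# a mature ALA-rich seed: alpha-linolenic acid (C18:3) dominates
profile = FattyAcidProfile(
    species="ala_rich", stage_daf=100, replicate=1,
    proportions={"C16:0": 0.06, "C18:0": 0.02, "C18:1": 0.22,
                 "C18:2": 0.27, "C18:3": 0.41, "C20:0": 0.01, "C22:0": 0.01})

de = desaturation_efficiency(profile)
sfa_ufa, mufa_pufa = saturation_ratios(profile)
print(f"omega-6 desaturation efficiency: {de.omega6:.4f}")
print(f"omega-3 desaturation efficiency: {de.omega3:.4f}")
print(f"SFA:UFA = {sfa_ufa:.4f}   MUFA:PUFA = {mufa_pufa:.4f}")
# omega-6 DE is the fraction of the C18 unsaturated pool carried past 18:1;
# high values mean the FAD2/FAD3 cascade converts most oleic acid onward.

# qPCR: a desaturase measured against a stable reference gene, relative to
# an early-stage calibrator sample (2^-ddCt)
sample = CtRecord("seed_100daf", ct_target=21.0, ct_reference=18.5)
calibrator = CtRecord("seed_10daf", ct_target=24.0, ct_reference=18.6)
fold = relative_expression(sample, calibrator)
print(f"relative desaturase expression vs 10 DAF: {fold:.2f}-fold")
# > 1 means the gene is up-regulated in the maturing seed.
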