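"""Fatty-acid composition statistics and qPCR relative expression.

Desaturation efficiency (DE) measures the fraction of available substrate
converted to downstream product(s) along the C18 desaturation cascade
18:1 -> 18:2 -> 18:3:

    omega-6 DE = (18:2 + 18:3) / (18:1 + 18:2 + 18:3)
    omega-3 DE =  18:3         / (18:2 + 18:3)

Ratios with a zero denominator are reported as ``None`` (undefined), never
coerced to 0 or infinity, so downstream summaries stay honest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FattyAcidProfile

SFA_KEYS = ("C16:0", "C18:0", "C20:0", "C22:0")
MUFA_KEYS = ("C18:1",)
PUFA_KEYS = ("C18:2", "C18:3")


@dataclass(frozen=True)
class DesaturationEfficiency:
    """omega-6 and omega-3 desaturation efficiencies; ``None`` = undefined."""

    omega6: float | None
    omega3: float | None


def desaturation_efficiency(p: FattyAcidProfile | dict) -> DesaturationEfficiency:
    """Compute omega-6 and omega-3 desaturation efficiencies of a profile.

    A zero denominator (no C18 unsaturates for omega-6; no 18:2+18:3 for
    omega-3) yields ``None`` for that component.
    """
    get = p.get
    p181, p182, p183 = get("C18:1", 0.0), get("C18:2", 0.0), get("C18:3", 0.0)
    pool6 = p181 + p182 + p183
    pool3 = p182 + p183
    omega6 = (p182 + p183) / pool6 if pool6 > 0 else None
    omega3 = p183 / pool3 if pool3 > 0 else None
    return DesaturationEfficiency(omega6=omega6, omega3=omega3)


def saturation_ratios(p: FattyAcidProfile | dict) -> tuple[float | None, float | None]:
    """Return (SFA:UFA, MUFA:PUFA) ratios of a fatty-acid profile.

    SFA = C16:0 + C18:0 + C20:0 + C22:0, MUFA = C18:1,
    PUFA = C18:2 + C18:3.  A zero denominator gives ``None``; an all-zero
    profile is an error.
    """
    get = p.get
    sfa = sum(get(k, 0.0) for k in SFA_KEYS)
    mufa = sum(get(k, 0.0) for k in MUFA_KEYS)
    pufa = sum(get(k, 0.0) for k in PUFA_KEYS)
    if sfa + mufa + pufa == 0:
        raise ValueError("all-zero fatty-acid profile")
    sfa_ufa = sfa / (mufa + pufa) if (mufa + pufa) > 0 else None
    mufa_pufa = mufa / pufa if pufa > 0 else None
    return sfa_ufa, mufa_pufa


def group_others(p: FattyAcidProfile) -> FattyAcidProfile:
    """Aggregate the long-chain saturates C20:0 + C22:0 into ``other``
    (the composition-figure grouping)."""
    props = {k: v for k, v in p.proportions.items() if k not in ("C20:0", "C22:0")}
    props["other"] = p.get("C20:0", 0.0) + p.get("C22:0", 0.0) + p.get("other", 0.0)
    return FattyAcidProfile(species=p.species, stage_daf=p.stage_daf,
                            replicate=p.replicate, tissue=p.tissue,
                            proportions=props)


# -- RT-qPCR ---------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    """A qPCR measurement: target and reference-gene threshold cycles."""

    sample: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_expression(sample: CtRecord, calibrator: CtRecord) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (target Ct - reference Ct) of the sample minus the same quantity
    of the calibrator; the result is the fold change versus the calibrator.
    """
    ddct = sample.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)


# -- accumulation dynamics -------------------------------------------------

def accumulation_summary(oil_content: pd.DataFrame,
                         onset_fraction: float = 0.1) -> dict:
    """Summarise an oil-accumulation time course.

    Parameters
    ----------
    oil_content
        DataFrame with columns ``stage_daf`` and ``oil_content`` (one row
        per replicate measurement; replicates optional).
    onset_fraction
        The onset of rapid accumulation is the first stage whose increment
        over the previous stage exceeds this fraction of the series range.

    Returns a dict with the per-stage mean/SE table (``table``), the stage
    of maximal oil content (``peak_stage``) and the onset stage
    (``onset_stage``, ``None`` if the series never accelerates).  SE is
    ``None`` wherever a stage has a single replicate.
    """
    if not {"stage_daf", "oil_content"} <= set(oil_content.columns):
        raise ValueError("need columns stage_daf and oil_content")
    stages = list(dict.fromkeys(oil_content["stage_daf"]))
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    if stages != sorted(stages):
        raise ValueError("stages must be given in increasing order")
    grouped = oil_content.groupby("stage_daf", sort=True)["oil_content"]
    means = grouped.mean()
    counts = grouped.count()
    ses = grouped.std(ddof=1) / np.sqrt(counts)
    table = pd.DataFrame({
        "mean": means,
        "se": [None if n < 2 else s for s, n in zip(ses, counts)],
        "n": counts,
    })
    peak_stage = int(means.idxmax())
    rng_span = float(means.max() - means.min())
    onset_stage = None
    if rng_span > 0:
        increments = means.diff()
        for stage, inc in increments.items():
            if not math.isnan(inc) and inc > onset_fraction * rng_span:
                onset_stage = int(stage)
                break
    return {"table": table, "peak_stage": peak_stage, "onset_stage": onset_stage}
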