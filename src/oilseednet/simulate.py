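"""Synthetic multi-species seed-development data with known ground truth.

The generator emulates the study design this package targets: a handful of
species sampled over five seed-development stages (days after flowering)
with three replicates each, a co-expressed oil-biosynthesis module whose
latent profile tracks oil accumulation (bell/rising/falling shapes),
interspecifically differentially expressed genes, duplicated (paralogous)
genes with optionally diverged stage profiles, fatty-acid composition
trajectories pinned to chosen desaturation efficiencies, and a similarity
hit table from which orthology can be re-derived.

Everything is driven by one :class:`SimConfig` and a single integer seed;
a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FattyAcidProfile, sample_id

PROFILE_SHAPES = ("bell", "rising", "falling", "flat")

#: fatty-acid keys carried by the simulated composition tables
FA_KEYS = ("C16:0", "C18:0", "C18:1", "C18:2", "C18:3", "C20:0", "C22:0")

# near-uniform stage-0 composition: a small, evenly split C18-unsaturated
# pool and the rest in saturated acids (seeds start fat-poor and saturated)
_START_UNSAT_TOTAL = 0.45
_START_SAT = {"C16:0": 0.30, "C18:0": 0.15, "C20:0": 0.05, "C22:0": 0.05}


@dataclass(frozen=True)
class PlantedModule:
    """A correlated gene block sharing one latent stage profile."""

    size: int
    profile_shape: str = "bell"
    within_module_correlation: float = 0.8


@dataclass(frozen=True)
class DEGene:
    """A gene given a mean log2 expression offset in one species."""

    gene_index: int
    species_index: int
    log2_fold_change: float


@dataclass(frozen=True)
class ParalogEvent:
    """A duplication: ``child_count`` copies of an ancestral gene per species.

    When ``diverged`` is set the children receive a stage-shifted latent
    profile (young-seed/leaf-like instead of maturing-seed), mimicking
    subfunctionalised desaturase duplicates; the shift magnitude is the
    config's ``paralog_divergence``.
    """

    ancestral_gene: int
    child_count: int = 1
    diverged: bool = False


@dataclass(frozen=True)
class SimConfig:
    n_species: int = 3
    stages: tuple[int, ...] = (0, 40, 50, 60, 100)
    n_replicates: int = 3
    n_background_genes: int = 300
    planted_modules: tuple[PlantedModule, ...] = (
        PlantedModule(40, "bell", 0.8),
        PlantedModule(30, "rising", 0.8),
        PlantedModule(30, "falling", 0.8),
    )
    de_genes: tuple[DEGene, ...] = tuple(
        [DEGene(i, 1, 2.0) for i in range(8)]
        + [DEGene(110 + i, 1, -2.0) for i in range(4)]
    )
    paralog_events: tuple[ParalogEvent, ...] = (
        ParalogEvent(0, 1, True),
        ParalogEvent(41, 1, False),
    )
    omega6_de_target: float = 0.75
    omega3_de_target: float = 0.6
    c18_final_total: float = 0.9
    paralog_divergence: float = 0.6
    noise_sd: float = 0.3
    seed: int = 0

    # -- derived ----------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    @property
    def n_module_genes(self) -> int:
        return sum(m.size for m in self.planted_modules)

    @property
    def n_core_genes(self) -> int:
        """Genes before paralog children: planted modules then background."""
        return self.n_module_genes + self.n_background_genes

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if len(self.stages) < 2 or list(self.stages) != sorted(set(self.stages)):
            raise ValueError("stages must be >= 2 strictly increasing DAF values")
        if self.n_replicates < 1 or self.n_background_genes < 0:
            raise ValueError("replicates and background count must be positive")
        for m in self.planted_modules:
            if m.size < 3:
                raise ValueError(
                    f"module size {m.size} < 3: cannot form a correlated block")
            if m.profile_shape not in PROFILE_SHAPES:
                raise ValueError(f"unknown profile shape {m.profile_shape!r}")
            if not (0.0 <= m.within_module_correlation <= 1.0):
                raise ValueError("within_module_correlation must be in [0, 1]")
            if m.within_module_correlation == 1.0 and self.noise_sd > 0:
                raise ValueError(
                    "within_module_correlation=1 requires noise_sd=0")
        for d in self.de_genes:
            if not (0 <= d.gene_index < self.n_core_genes):
                raise ValueError(f"DE gene index {d.gene_index} out of range")
            if not (0 <= d.species_index < self.n_species):
                raise ValueError(f"DE species index {d.species_index} out of range")
        for ev in self.paralog_events:
            if not (0 <= ev.ancestral_gene < self.n_core_genes):
                raise ValueError(f"paralog ancestor {ev.ancestral_gene} out of range")
            if ev.child_count < 1:
                raise ValueError("child_count must be >= 1")
        for name, val in (("omega6_de_target", self.omega6_de_target),
                          ("omega3_de_target", self.omega3_de_target)):
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic data.

    ``module_membership`` maps every generated gene id (all species) to its
    planted module label (0 = background; diverged paralog children are
    background by construction).  ``orthogroups`` are the true cross-species
    gene families (ancestral copies plus all their paralog children).
    """

    species: list[str]
    module_membership: dict[str, int]
    de_genes: set[tuple[str, str]]                # (species, gene id)
    orthogroups: list[frozenset[str]]
    fa_truth: dict[int, dict[str, float]]         # stage -> C18:x proportions
    ancestral_index: dict[str, int]               # gene id -> ancestral index

    def labels_for(self, species: str) -> pd.Series:
        ids = [g for g in self.module_membership if g.startswith(species + "_")]
        return pd.Series({g: self.module_membership[g] for g in sorted(ids)})

    def true_rbh(self, species_a: str, species_b: str) -> set[tuple[str, str]]:
        """One-to-one pairs between the ancestral copies of two species."""
        pairs = set()
        indices = sorted({i for g, i in self.ancestral_index.items()
                          if "c" not in g.split("_g")[1]})
        for i in indices:
            pairs.add((_gene_id(species_a, i), _gene_id(species_b, i)))
        return pairs


def _gene_id(species: str, index: int, child: int | None = None) -> str:
    base = f"{species}_g{index:04d}"
    return base if child is None else f"{base}c{child}"


def _shape_values(shape: str, x: np.ndarray) -> np.ndarray:
    """Latent profile over normalised stage positions x in [0, 1]."""
    if shape == "bell":
        return np.exp(-(((x - 0.5) / 0.25) ** 2))
    if shape == "rising":
        return 1.0 / (1.0 + np.exp(-8.0 * (x - 0.5)))
    if shape == "falling":
        return 1.0 / (1.0 + np.exp(8.0 * (x - 0.5)))
    if shape == "flat":
        return np.zeros_like(x)
    raise ValueError(f"unknown profile shape {shape!r}")


def _standardise(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-sd latent; a flat (zero-variance) profile is replaced
    by a random latent so within-module correlation is still realisable."""
    sd = v.std()
    if sd == 0:
        v = rng.standard_normal(v.size)
        sd = v.std()
    return (v - v.mean()) / sd


def _amplitude_for(z: np.ndarray, r: float, noise_sd: float) -> float:
    """Latent amplitude giving expected pairwise Pearson correlation r on
    the expression scale.

    Module genes are 2^(b + a*z + e) with shared standardised latent z and
    independent e ~ N(0, sd^2).  Conditional on z, the population
    correlation of two such genes is

        corr(a) = (m2 - m1^2) u1^2 / (m2 u2 - m1^2 u1^2),
        m_k = mean(exp(k c a z)),  u1^2 = exp(c^2 sd^2),  u2 = exp(2 c^2 sd^2)

    with c = ln 2; the amplitude solving corr(a) = r is found by bisection.
    This accounts for the attenuation the exponentiation introduces, so the
    calibration holds on the scale the network is built from.
    """
    if r <= 0.0:
        return 0.0
    if r >= 1.0:
        return 1.0          # noise_sd is 0 by validation: exact proportionality
    if noise_sd == 0.0:
        raise ValueError("within_module_correlation < 1 requires noise_sd > 0")
    c = math.log(2.0)
    u1sq = math.exp(c * c * noise_sd * noise_sd)
    u2 = math.exp(2.0 * c * c * noise_sd * noise_sd)

    def corr_of(a: float) -> float:
        w = np.exp(c * a * z)
        m1 = w.mean()
        m2 = (w * w).mean()
        num = (m2 - m1 * m1) * u1sq
        den = m2 * u2 - m1 * m1 * u1sq
        return num / den

    lo, hi = 0.0, 1.0
    while corr_of(hi) < r and hi < 64:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if corr_of(mid) < r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_expression(config: SimConfig) -> tuple[dict[str, ExpressionMatrix], SyntheticTruth]:
    """Generate one FPKM-like expression matrix per species plus the truth.

    Values are built on the log2 scale (per-gene base level + module latent
    + Gaussian replicate noise) and exponentiated, which yields the
    positivity and right skew of FPKM data.  The latent amplitude of each
    planted module is calibrated (see :func:`_amplitude_for`) so that the
    expected pairwise Pearson correlation of module genes — measured on the
    expression scale — equals the configured within-module correlation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stages = np.asarray(config.stages, dtype=float)
    x = (stages - stages.min()) / (stages.max() - stages.min())
    n_samples = len(config.stages) * config.n_replicates
    stage_of_sample = np.repeat(np.arange(len(config.stages)), config.n_replicates)

    # latent profiles per module, shared across species (conserved dynamics)
    latents, latents_shifted = [], []
    for mod in config.planted_modules:
        prof = _shape_values(mod.profile_shape, x)[stage_of_sample]
        latents.append(_standardise(prof, rng))
        shifted = _shape_values(mod.profile_shape, 1.0 - x)[stage_of_sample]
        latents_shifted.append(_standardise(shifted, rng))

    n_core = config.n_core_genes
    base = rng.uniform(2.0, 8.0, size=n_core)          # log2 FPKM levels
    lengths_core = rng.integers(500, 3001, size=n_core)

    # gene bookkeeping: module label and latent row per core gene
    module_of = np.zeros(n_core, dtype=int)
    offset = 0
    for label, mod in enumerate(config.planted_modules, start=1):
        module_of[offset:offset + mod.size] = label
        offset += mod.size

    amplitudes = [_amplitude_for(latents[i], mod.within_module_correlation,
                                 config.noise_sd)
                  for i, mod in enumerate(config.planted_modules)]

    de_offset = {(d.species_index, d.gene_index): d.log2_fold_change
                 for d in config.de_genes}

    # paralog children: (parent index, child ordinal, diverged)
    children: list[tuple[int, int, bool]] = []
    for ev in config.paralog_events:
        for j in range(1, ev.child_count + 1):
            children.append((ev.ancestral_gene, j, ev.diverged))
    child_lengths = [int(np.clip(lengths_core[p] + rng.integers(-100, 101), 300, None))
                     for p, _, _ in children]

    species = config.species_names
    matrices: dict[str, ExpressionMatrix] = {}
    membership: dict[str, int] = {}
    ancestral_index: dict[str, int] = {}
    sample_ids = [sample_id(sp, s, r)
                  for sp in species
                  for s in config.stages for r in range(1, config.n_replicates + 1)]

    for s_idx, sp in enumerate(species):
        ids = [_gene_id(sp, i) for i in range(n_core)]
        ids += [_gene_id(sp, p, j) for p, j, _ in children]
        log2 = np.empty((len(ids), n_samples))
        # core genes
        for i in range(n_core):
            row = np.full(n_samples, base[i])
            lab = module_of[i]
            if lab:
                row = row + amplitudes[lab - 1] * latents[lab - 1]
            if (s_idx, i) in de_offset:
                row = row + de_offset[(s_idx, i)]
            log2[i] = row
        # paralog children copy the ancestral mean profile (possibly shifted)
        for c, (p, _j, diverged) in enumerate(children):
            row = np.full(n_samples, base[p])
            lab = module_of[p]
            if lab:
                lat = latents[lab - 1]
                if diverged:
                    d = config.paralog_divergence
                    mix = (1.0 - d) * lat + d * latents_shifted[lab - 1]
                    sd = mix.std()
                    lat = mix / sd if sd > 0 else mix
                row = row + amplitudes[lab - 1] * lat
            log2[n_core + c] = row
        log2 += rng.normal(0.0, config.noise_sd, size=log2.shape)

        cols = [sid for sid in sample_ids if sid.startswith(sp + ".")]
        values = pd.DataFrame(np.power(2.0, log2), index=ids, columns=cols)
        samples = pd.DataFrame(
            {"species": sp,
             "tissue": "seed",
             "stage_daf": [int(c.split(".")[1]) for c in cols],
             "replicate": [int(c.split(".")[2]) for c in cols]},
            index=pd.Index(cols, name="sample"))
        lengths = pd.Series(
            np.concatenate([lengths_core, np.asarray(child_lengths, dtype=int)])
            if children else lengths_core,
            index=ids, name="length_nt")
        matrices[sp] = ExpressionMatrix(values=values, samples=samples,
                                        unit="fpkm", gene_lengths=lengths)
        for i in range(n_core):
            membership[_gene_id(sp, i)] = int(module_of[i])
            ancestral_index[_gene_id(sp, i)] = i
        for (p, j, diverged) in children:
            gid = _gene_id(sp, p, j)
            membership[gid] = 0 if diverged else int(module_of[p])
            ancestral_index[gid] = p

    de_set = {(species[d.species_index], _gene_id(species[d.species_index], d.gene_index))
              for d in config.de_genes}
    groups = []
    for i in range(n_core):
        members = {_gene_id(sp, i) for sp in species}
        for (p, j, _div) in children:
            if p == i:
                members |= {_gene_id(sp, p, j) for sp in species}
        groups.append(frozenset(members))

    truth = SyntheticTruth(
        species=list(species),
        module_membership=membership,
        de_genes=de_set,
        orthogroups=groups,
        fa_truth=_fa_trajectory(config),
        ancestral_index=ancestral_index,
    )
    return matrices, truth


# -- fatty-acid composition ------------------------------------------------

def c18_split(omega6_de: float, omega3_de: float, total: float) -> tuple[float, float, float]:
    """Constructive inversion of the desaturation-efficiency formulas.

    Given a total C18-unsaturated pool ``total`` and target efficiencies,
    returns (18:1, 18:2, 18:3) proportions such that
    omega-6 DE = (18:2+18:3)/(18:1+18:2+18:3) and
    omega-3 DE = 18:3/(18:2+18:3) hold exactly.
    """
    p183 = total * omega6_de * omega3_de
    p182 = total * omega6_de * (1.0 - omega3_de)
    p181 = total * (1.0 - omega6_de)
    return p181, p182, p183


def _fa_trajectory(config: SimConfig) -> dict[int, dict[str, float]]:
    """Per-stage C18-unsaturate proportions, linear from a near-uniform start
    to the constructed final composition."""
    de6, de3 = config.omega6_de_target, config.omega3_de_target
    if de6 <= 0.0 and de3 > 0.0:
        raise ValueError("omega6 DE of 0 with positive omega3 DE: "
                         "no substrate path to 18:3")
    if not (0.0 < de6 <= 1.0) or not (0.0 < de3 <= 1.0):
        raise ValueError("DE targets must lie in (0, 1]")
    final = c18_split(de6, de3, config.c18_final_total)
    start = (_START_UNSAT_TOTAL / 3.0,) * 3
    out = {}
    stages = config.stages
    for stage in stages:
        t = (stage - stages[0]) / (stages[-1] - stages[0])
        p181, p182, p183 = (s + t * (f - s) for s, f in zip(start, final))
        out[stage] = {"C18:1": p181, "C18:2": p182, "C18:3": p183}
    return out


def simulate_fa_profiles(config: SimConfig) -> list[FattyAcidProfile]:
    """Fatty-acid composition per species x stage x replicate.

    The composition is deterministic (replicates identical): the C18
    unsaturates follow :func:`_fa_trajectory`, so the desaturation
    efficiencies computed from the final stage recover the configured
    targets exactly; saturated acids fill the remainder in fixed ratio.
    """
    config.validate()
    traj = _fa_trajectory(config)
    sat_total0 = sum(_START_SAT.values())
    out = []
    for sp in config.species_names:
        for stage in config.stages:
            unsat = traj[stage]
            rest = 1.0 - sum(unsat.values())
            props = dict(unsat)
            for key, frac in _START_SAT.items():
                props[key] = rest * frac / sat_total0
            for rep in range(1, config.n_replicates + 1):
                out.append(FattyAcidProfile(species=sp, stage_daf=stage,
                                            replicate=rep, proportions=dict(props)))
    return out


# -- similarity hit tables -------------------------------------------------

def simulate_similarity_table(truth: SyntheticTruth, decoy_rate: float = 0.0,
                              seed: int = 0) -> pd.DataFrame:
    """Cross-species similarity hits consistent with the orthology truth.

    Every true ortholog pair gets the top reciprocal score for both of its
    members; paralog children hit their family with somewhat lower scores;
    decoy hits between unrelated genes are drawn at ``decoy_rate`` per true
    pair with scores strictly below any true-pair score.
    """
    if not truth.orthogroups:
        raise ValueError("orthology truth is empty")
    if not (0.0 <= decoy_rate < 1.0):
        raise ValueError("decoy_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    species = truth.species
    rows: list[tuple] = []

    def species_of(gene: str) -> str:
        return gene.split("_g")[0]

    all_genes_by_sp = {sp: sorted(g for g in truth.ancestral_index
                                  if species_of(g) == sp) for sp in species}

    def add(q, s, score, ident, cov):
        rows.append((q, s, species_of(q), species_of(s),
                     float(score), float(ident), float(cov)))

    base_of_group: dict[int, float] = {}
    for gi, group in enumerate(truth.orthogroups):
        base = 200.0 + rng.uniform(0.0, 50.0)
        base_of_group[gi] = base
        members = sorted(group)
        ancestors = {species_of(g): g for g in members if "c" not in g.split("_g")[1]}
        children = [g for g in members if "c" in g.split("_g")[1]]
        sps = sorted(ancestors)
        for i, a_sp in enumerate(sps):
            for b_sp in sps[i + 1:]:
                a, b = ancestors[a_sp], ancestors[b_sp]
                ident = 0.90 + rng.uniform(0.0, 0.08)
                cov = 0.85 + rng.uniform(0.0, 0.12)
                add(a, b, base, ident, cov)
                add(b, a, base, ident, cov)
        for child in children:
            c_sp = species_of(child)
            for o_sp, anc in ancestors.items():
                score = base * (0.95 if o_sp == c_sp else 0.90)
                ident = 0.80 + rng.uniform(0.0, 0.1)
                cov = 0.75 + rng.uniform(0.0, 0.15)
                add(child, anc, score, ident, cov)
                add(anc, child, score, ident, cov)

    # decoys: weaker secondary hits between non-orthologous genes
    group_of = {}
    for gi, group in enumerate(truth.orthogroups):
        for g in group:
            group_of[g] = gi
    n_pairs = sum(1 for _ in truth.orthogroups) * max(len(species) - 1, 1)
    n_decoys = int(round(decoy_rate * n_pairs)) if len(species) >= 2 else 0
    attempts = 0
    made = 0
    while made < n_decoys and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        a_sp, b_sp = rng.choice(species, size=2, replace=False)
        q = all_genes_by_sp[a_sp][rng.integers(len(all_genes_by_sp[a_sp]))]
        s = all_genes_by_sp[b_sp][rng.integers(len(all_genes_by_sp[b_sp]))]
        if group_of.get(q) == group_of.get(s):
            continue
        # a spurious hit's score tracks the fraction of the query it aligns
        # and how well: well below the query's own full-length ortholog match
        ident = rng.uniform(0.3, 0.7)
        cov = rng.uniform(0.4, 0.8)
        score = base_of_group[group_of[q]] * ident * cov
        add(q, s, score, ident, cov)
        made += 1

    hits = pd.DataFrame(rows, columns=["query", "subject", "query_species",
                                       "subject_species", "score",
                                       "identity", "coverage"])
    return hits.sort_values(["query", "subject", "score"],
                            ascending=[True, True, False]).reset_index(drop=True)
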