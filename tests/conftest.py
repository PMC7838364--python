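import numpy as np
import pandas as pd
import pytest

from oilseednet.containers import ExpressionMatrix
from oilseednet.simulate import PlantedModule, SimConfig, simulate_expression


def make_matrix(values, sample_ids=None, species="sp1", stages=None,
                lengths=None, unit="fpkm"):
    """Small helper: wrap a 2-D array into an ExpressionMatrix."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    if stages is None:
        stages = list(range(n_samples))
    if sample_ids is None:
        sample_ids = [f"{species}.{s}.1" for s in stages]
    samples = pd.DataFrame({
        "species": species, "tissue": "seed",
        "stage_daf": stages, "replicate": 1,
    }, index=pd.Index(sample_ids, name="sample"))
    gl = None if lengths is None else pd.Series(lengths, index=genes)
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes,
                                                columns=sample_ids),
                            samples=samples, unit=unit, gene_lengths=gl)


@pytest.fixture(scope="session")
def planted_network_data():
    """One-species dataset with three planted modules over 500 background
    genes — the standard planted-structure recovery fixture."""
    cfg = SimConfig(
        n_species=1, n_background_genes=500,
        planted_modules=(PlantedModule(60, "bell", 0.8),
                         PlantedModule(40, "rising", 0.8),
                         PlantedModule(30, "falling", 0.8)),
        de_genes=(), paralog_events=(), seed=0)
    matrices, truth = simulate_expression(cfg)
    return cfg, matrices["sp1"], truth
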