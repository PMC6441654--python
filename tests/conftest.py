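import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import degflow as d

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

PLANTED_SEED = 101


@pytest.fixture(scope="session")
def planted_sim():
    """Planted simulation at the default study conditions (2000 genes)."""
    cfg = d.SimulationConfig(n_genes=2000, seed=PLANTED_SEED)
    cm, meta, go, truth = d.simulate_experiment(cfg)
    return cfg, cm, meta, go, truth


@pytest.fixture(scope="session")
def planted_de(planted_sim):
    """DE results for both treatments on the planted simulation."""
    _, cm, meta, _, _ = planted_sim
    phi = d.estimate_dispersion(cm)
    return {t: d.call_degs(cm, meta, t, dispersion=phi) for t in d.TREATMENTS}


@pytest.fixture
def tiny_counts():
    """2 conditions x 2 timepoints x 2 replicates, 3 genes, hand-set counts."""
    samples = [
        d.SampleDesign(f"{c}_d{t}_r{r}", d.Condition(c), t, r)
        for c in ("control", "LTC")
        for t in (1, 2)
        for r in (1, 2)
    ]
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 200, size=(3, len(samples)))
    return d.CountMatrix(gene_ids=["g1", "g2", "g3"], samples=samples, counts=counts)


def de_frame(rows):
    """Helper: build a DE results table from (gene, treatment, day, call) tuples."""
    return pd.DataFrame(
        [
            {
                "gene_id": g,
                "treatment": tr,
                "timepoint_day": day,
                "log2fc": {"up": 2.0, "down": -2.0, "none": 0.1}[call],
                "p_value": 0.001 if call != "none" else 0.5,
                "fdr": 0.01 if call != "none" else 0.8,
                "call": call,
            }
            for g, tr, day, call in rows
        ]
    )
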