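import numpy as np
import pandas as pd
import pytest

from stressregulon import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Deterministic zero-noise dataset whose planted effects guarantee
    |d1| >= 3 on the log2 scale (constant effect size 3, 10% responsive)."""
    config = SimulationConfig(n_genes=3000, noise_log2_sd=0.0, effect_log2fc_sd=0.0,
                              effect_log2fc_mean=3.0, atfa_dependence_prob=0.5,
                              seed=7)
    matrix, design, truth = generate_dataset(config)
    return config, matrix, design, truth


@pytest.fixture()
def toy_matrix():
    """Four genes, one strain, one stress: the hand-computable D1 example."""
    matrix = pd.DataFrame(
        {"control:untreated": [100.0, 100.0, 100.0, 100.0],
         "control:MSB": [800.0, 100.0, 100.0, 100.0]},
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"))
    design = pd.DataFrame({
        "sample_id": ["control:untreated", "control:MSB"],
        "strain": ["control", "control"],
        "condition": ["untreated", "MSB"]})
    return matrix, design


def make_profiles(calls: dict[str, dict[tuple[str, str], str]]) -> pd.DataFrame:
    """Build a genes x (strain, stress) call table from explicit dicts;
    unmentioned cells default to 'none'."""
    columns = sorted({key for gene in calls.values() for key in gene})
    index = pd.MultiIndex.from_tuples(columns, names=["strain", "stress"])
    rows = {gene: [cells.get(col, "none") for col in columns]
            for gene, cells in calls.items()}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=index)
    out.index.name = "gene_id"
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
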