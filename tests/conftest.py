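import pandas as pd
import pytest

from panmark import dataio, simulate


@pytest.fixture(scope="session")
def small_screen():
    """A tiny planted screen shared by unit tests (4 tissues x 8 lines)."""
    cfg = simulate.SimulationConfig(
        n_tissues=4,
        lines_per_tissue=8,
        n_genes=60,
        n_drugs=6,
        n_pathways=2,
        seed=42,
    )
    return simulate.simulate_screen(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_screen):
    ds, _ = small_screen
    return ds


@pytest.fixture()
def toy_dataset():
    """Hand-built four-table dataset for QC edge cases."""
    lines = [f"L{i}" for i in range(6)]
    expression = pd.DataFrame(
        {"g1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "g2": [0.5, 0.1, 0.9, 0.3, 0.2, 0.7]},
        index=pd.Index(lines, name="cell_line_id"),
    )
    samples = pd.DataFrame(
        {
            "cell_line_id": lines,
            "cancer_type": ["A", "A", "A", "B", "B", "B"],
            "tumor_class": ["solid"] * 3 + ["non_solid"] * 3,
        }
    )
    response = pd.DataFrame(
        {
            "cell_line_id": lines * 2,
            "drug_id": ["d1"] * 6 + ["d2"] * 6,
            "auc": [0.5, 0.6, 0.7, 0.4, 0.3, 0.2] * 2,
        }
    )
    drugs = pd.DataFrame({"drug_id": ["d1", "d2"], "pathway": ["P", "P"]})
    return dataio.ScreenDataset(
        expression=expression, samples=samples, response=response, drugs=drugs
    )
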