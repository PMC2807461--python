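import numpy as np
import pandas as pd
import pytest

from embimpute import PanelDataset, SyntheticConfig, generate


@pytest.fixture
def tiny_panel() -> PanelDataset:
    """Handmade 2-protein, 2-condition panel with one missing cell."""
    rows = []
    for ct in ("Cancer", "Normal"):
        for t in (0.0, 30.0, 180.0):
            rows.append((ct, "TGFa", "MEKi", t, "AKT", 10.0 + t / 10))
            rows.append((ct, "TGFa", "MEKi", t, "ERK12", 100.0 + t))
    df = pd.DataFrame(
        rows, columns=["CellType", "Stimulus", "Inhibitor", "Time", "Protein", "Value"]
    )
    df.loc[0, "Value"] = np.nan
    return PanelDataset(df)


@pytest.fixture(scope="session")
def small_synth() -> PanelDataset:
    """6-protein full 7x7x{0,30,180} synthetic panel (fully observed)."""
    return generate(SyntheticConfig(n_proteins=6, seed=20240901))


@pytest.fixture(scope="session")
def mvn_matrix() -> np.ndarray:
    """Complete 60x4 matrix drawn from a fixed multivariate normal."""
    rng = np.random.default_rng(7)
    a = rng.normal(size=(4, 4))
    cov = a @ a.T + 2 * np.eye(4)
    return rng.multivariate_normal([1.0, -2.0, 0.5, 3.0], cov, size=60)
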