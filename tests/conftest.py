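import numpy as np
import pandas as pd
import pytest

from cytonet import PanelTable, default_cell_map, default_paperlike_config, simulate_panel


@pytest.fixture(scope="session")
def cell_map():
    return default_cell_map()


@pytest.fixture(scope="session")
def paperlike_panel():
    """One fixed draw of the study-like design (63 animals x 24 cytokines)."""
    return simulate_panel(default_paperlike_config(seed=2024))


@pytest.fixture()
def tiny_panel():
    """Hand-written 6-animal, 3-cytokine panel with known structure."""
    vals = pd.DataFrame(
        {
            "A": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "B": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
            "C": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
        },
        index=pd.Index([f"r{i}" for i in range(6)], name="animal_id"),
    )
    groups = pd.Series(["g1"] * 6, index=vals.index)
    tps = pd.Series(["t1"] * 6, index=vals.index)
    return PanelTable(values=vals, groups=groups, timepoints=tps)


def brute_force_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r, written independently of the implementation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) ** 0.5
        * sum((b - my) ** 2 for b in y) ** 0.5
    )
    return num / den
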