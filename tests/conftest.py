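import numpy as np
import pandas as pd
import pytest

from phenotil import SimConfig, gen_cell_map
from phenotil.cellmap import DESCRIPTOR_COLS, CellMap


def small_sim_config(**kw) -> SimConfig:
    defaults = dict(tile_size=512, n_til_hotspots=3, offspring_mean=20,
                    lambda_nontil=600, hotspot_dispersion=50)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_map():
    cm, truth = gen_cell_map(small_sim_config(), seed=11)
    return cm, truth


def random_cell_map(n_cells: int, seed: int, tile: int = 1000,
                    til_frac: float = 0.4) -> CellMap:
    """Random cell map with arbitrary descriptors (oracle-test substrate)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.uniform(0.1, 50.0, (n_cells, len(DESCRIPTOR_COLS))),
                      columns=DESCRIPTOR_COLS)
    df["eccentricity"] = rng.uniform(0, 1, n_cells)
    df["solidity"] = rng.uniform(0.5, 1.0, n_cells)
    df.insert(0, "cell_id", np.arange(1, n_cells + 1))
    df.insert(1, "x", rng.uniform(0, tile, n_cells))
    df.insert(2, "y", rng.uniform(0, tile, n_cells))
    df.insert(3, "class", np.where(rng.random(n_cells) < til_frac, "TIL", "nonTIL"))
    return CellMap(df, tile_id=f"rand-{seed}", shape=(tile, tile))
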