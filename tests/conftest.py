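import numpy as np
import pandas as pd
import pytest

from chromarch import BinTable, ContactMatrix, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """One 5 Mb chromosome at 25 kb bins: fast but structurally complete."""
    return SimulationConfig(chrom_sizes={"chr1": 5_000_000}, seed=7)


@pytest.fixture
def bins8() -> BinTable:
    return BinTable.from_chrom_sizes({"chr1": 200_000}, 25_000)


def two_block_matrix(bins: BinTable, within: float = 10.0, cross: float = 1.0,
                     split: int | None = None) -> ContactMatrix:
    """Checkerboard fixture: two blocks, flat decay, dense counts."""
    n = bins.n_bins
    split = n // 2 if split is None else split
    ii, jj, cc = [], [], []
    for i in range(n):
        for j in range(i, n):
            same = (i < split) == (j < split)
            ii.append(i)
            jj.append(j)
            cc.append(within if same else cross)
    return ContactMatrix.from_coo(bins, ii, jj, cc)


@pytest.fixture
def step_track() -> pd.DataFrame:
    """Signal 0 on [0, 100k), 1 on [100k, 200k)."""
    return pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [0, 100_000],
        "end": [100_000, 200_000],
        "value": [0.0, 1.0],
    })


def profile_from_labels(bins: BinTable, labels: list[str]):
    from chromarch.compartments import CompartmentProfile

    lab = np.array(labels, dtype="U2")
    cscore = np.where(lab == "A", 0.5, np.where(lab == "B", -0.5, np.nan))
    return CompartmentProfile(bins=bins, cscore=cscore, label=lab)
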