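import numpy as np
import pandas as pd
import pytest

from tumorclones.synthetic import BarcodeLibrary, generate_inoculum
from tumorclones.tables import CountTable


@pytest.fixture(scope="session")
def small_library() -> BarcodeLibrary:
    """A 1000-barcode inoculum with the study's narrow six-fold spread."""
    return generate_inoculum(1000, fold_range=6.0, central_mass=0.99,
                             total_cells=125_000, seed=42)


@pytest.fixture(scope="session")
def study_scale_library() -> BarcodeLibrary:
    """A 40,000-barcode inoculum at the study's 5e6-cell injection size."""
    return generate_inoculum(40_000, fold_range=6.0, central_mass=0.99,
                             total_cells=5e6, seed=42)


@pytest.fixture()
def t0_fixture_table() -> CountTable:
    """A 5-barcode, 4-replicate T0 table with hand-checkable RPM patterns.

    Depth of every replicate is 1e6 reads, so raw counts equal RPM:
      bcA: 11 RPM in reps 1,2   -> passes (2 hits above 10)
      bcB: 11 RPM in rep 1 only -> fails  (1 hit)
      bcC: 10 RPM in all reps   -> fails  (10 is not strictly above 10)
      bcD: 500 RPM everywhere   -> passes
      bcE: 0 everywhere         -> fails
    A filler barcode absorbs the rest of each replicate's depth.
    """
    counts = pd.DataFrame(
        {
            "T0_rep1": [11, 11, 10, 500, 0],
            "T0_rep2": [11, 0, 10, 500, 0],
            "T0_rep3": [0, 0, 10, 500, 0],
            "T0_rep4": [0, 0, 10, 500, 0],
        },
        index=["bcA", "bcB", "bcC", "bcD", "bcE"],
    )
    filler = 1_000_000 - counts.sum(axis=0)
    counts.loc["bcFill"] = filler
    return CountTable(counts, units="reads")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
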