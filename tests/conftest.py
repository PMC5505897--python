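import numpy as np
import pandas as pd
import pytest

from dietmem import AmpliconSpec, CountTable


@pytest.fixture(scope="session")
def toy_counts() -> CountTable:
    """10-gene, two-library toy table used for brute-force DE checks.

    Gene g01 runs at 10x the AL rate in DR; the rest are near-null draws.
    Depths are 10^6 in both libraries.
    """
    counts = pd.DataFrame(
        {
            "AL": [100, 100, 250, 80, 0, 5, 1000, 40, 0, 300],
            "DR": [105, 1000, 240, 85, 0, 9, 1015, 36, 3, 310],
        },
        index=pd.Index([f"g{i:02d}" for i in range(10)], name="gene"),
    )
    totals = pd.Series({"AL": 1_000_000, "DR": 1_000_000}, dtype=float)
    return CountTable(counts, totals)


@pytest.fixture(scope="session")
def small_amplicon() -> AmpliconSpec:
    """Hand-written 40 bp amplicon with 2 CG sites (offsets 4 and 20)."""
    #           0123456789...
    seq = "ATGACGTTACATTAGGATTACGATTAGGCATTAGGATTAG"
    return AmpliconSpec.from_sequence("toy", seq)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)
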