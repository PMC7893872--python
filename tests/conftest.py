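import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from ngslod.variant_io import AFTable, TargetVariant


@pytest.fixture
def small_targets() -> list[TargetVariant]:
    return [
        TargetVariant("chr1", 115256530, "G", "T", 33.5),
        TargetVariant("chr2", 25398284, "C", "A", 10.0),
        TargetVariant("chr7", 55259515, "T", "C", 1.0),
    ]


def make_af_table(
    afs, replicate_id="rep1", label="15Gbp", depth=200, loci=None
) -> AFTable:
    """AFTable with the given AFs (percent) at uniform depth."""
    if loci is None:
        loci = [f"chrS:{10_000 + i * 1000}:G>T" for i in range(len(afs))]
    rows = []
    for locus, af in zip(loci, afs):
        alt = int(round(af / 100.0 * depth))
        rows.append((locus, depth, alt, 100.0 * alt / depth))
    df = pd.DataFrame(rows, columns=["locus", "depth", "alt_count", "af_percent"])
    return AFTable(replicate_id=replicate_id, data_size_label=label, data=df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
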