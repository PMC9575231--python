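import numpy as np
import pandas as pd
import pytest

from schicnd import ContactTable


def make_table(records, resolution=1_000_000, chrom_sizes=None):
    """Build a ContactTable from (cell, chrom, bin1, bin2, count) tuples."""
    df = pd.DataFrame(records, columns=["cell", "chrom", "bin1", "bin2",
                                        "count"])
    if chrom_sizes is None:
        chrom_sizes = {c: int(df.loc[df["chrom"] == c, "bin2"].max()) + 1
                       for c in df["chrom"].unique()}
    return ContactTable(df, resolution, chrom_sizes)


def random_table(rng, n_cells=5, d=8, chrom="chr1", density=0.5,
                 resolution=1_000_000, include_diagonal=True):
    """Random sparse upper-triangular integer contact table."""
    records = []
    for c in range(n_cells):
        for i in range(d):
            start = i if include_diagonal else i + 1
            for j in range(start, d):
                if rng.random() < density:
                    records.append((f"c{c}", chrom, i, j,
                                    int(rng.integers(1, 10))))
    if not records:
        records.append(("c0", chrom, 0, min(1, d - 1), 1))
    df = pd.DataFrame(records, columns=["cell", "chrom", "bin1", "bin2",
                                        "count"])
    df = df.groupby(["cell", "chrom", "bin1", "bin2"],
                    as_index=False)["count"].sum()
    return ContactTable(df, resolution, {chrom: d})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
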