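"""Scaling normalizers for scHi-C: CellScale, BandScale, and BandNorm.

All three act on the long-format :class:`~schicnd.contacts_io.ContactTable`
and differ only in the scope of the size factor:

* CellScale — one factor per cell (library size to a common target).
* BandScale — one factor per cell *and* band: divide by the cell's band mean,
  removing the contact-decay profile entirely.
* BandNorm — BandScale's depth removal followed by adding back a common
  band-dependent decay estimate: ``C = (Y / L_cv) * alpha(v)`` where ``L_cv``
  is the cell's band total and ``alpha(v)`` the mean band total across cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .contacts_io import ContactTable

logger = logging.getLogger("schicnd")


@dataclass
class BandNormFactors:
    """Cross-cell band means ``alpha(v)`` per (chrom, band), plus N and m_v.

    ``alpha(v) = sum_c L_cv / N`` with N = all retained cells — cells with a
    zero total in a band still count in the denominator.
    """

    table: pd.DataFrame  # columns: chrom, band, alpha, m_v
    n_cells: int

    def alpha(self, chrom: str, band: int) -> float:
        sub = self.table[(self.table["chrom"] == chrom)
                         & (self.table["band"] == band)]
        if sub.empty:
            return 0.0
        return float(sub["alpha"].iloc[0])

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _with_band(df: pd.DataFrame) -> pd.DataFrame:
    return df.assign(band=df["bin2"] - df["bin1"])


def cell_scale(t: ContactTable, target: float = 10_000.0) -> ContactTable:
    """Scale each cell's contacts to a common library size (default 10,000)."""
    totals = t.df.groupby("cell", observed=True)["count"].transform("sum")
    zero = totals == 0
    if zero.any():
        bad = sorted(t.df.loc[zero, "cell"].unique())
        logger.warning("skipping %d zero-total cells: %s", len(bad), bad[:5])
    out = t.df.copy()
    out["count"] = np.where(zero, 0.0, out["count"] / totals * target)
    return ContactTable(out, t.resolution, t.chrom_sizes)


def band_scale(t: ContactTable) -> ContactTable:
    """Divide each entry by its cell's mean count over the band's m_v pairs.

    Bands with a zero cell total are left all-zero.  After BandScale every
    nonzero (cell, chrom, band) has mean exactly 1 over its m_v locus pairs.
    """
    df = _with_band(t.df)
    l_cv = df.groupby(["cell", "chrom", "band"], observed=True)["count"]
    totals = l_cv.transform("sum")
    m_v = np.array([t.chrom_sizes[ch] for ch in df["chrom"]]) - df["band"]
    out = t.df.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = df["count"] / (totals / m_v)
    out["count"] = np.where(totals > 0, scaled, 0.0)
    return ContactTable(out, t.resolution, t.chrom_sizes)


def compute_band_factors(t: ContactTable,
                         cell_ids: list[str] | None = None) -> BandNormFactors:
    """Per (chrom, band) mean band total ``alpha(v)`` over all N cells."""
    cells = cell_ids if cell_ids is not None else t.cell_ids
    n = len(cells)
    if n == 0:
        raise ValueError("no cells")
    df = _with_band(t.df[t.df["cell"].isin(cells)])
    sums = (df.groupby(["chrom", "band"], observed=True)["count"]
              .sum().reset_index())
    sums["alpha"] = sums["count"] / n
    sums["m_v"] = [t.chrom_sizes[ch] - b
                   for ch, b in zip(sums["chrom"], sums["band"])]
    return BandNormFactors(sums[["chrom", "band", "alpha", "m_v"]], n)


def band_norm(
    t: ContactTable,
    factors: BandNormFactors | None = None,
) -> tuple[ContactTable, BandNormFactors]:
    """BandNorm: ``C_r^cv = (Y_r^cv / L_cv) * alpha(v)``.

    Depth-normalizes each cell within each band, then multiplies by the
    cross-cell mean band total so that a common contact-decay profile is
    restored.  Supplying precomputed ``factors`` applies a frozen decay
    estimate (e.g. to held-out cells); otherwise factors are estimated from
    ``t`` and returned for reuse.
    """
    if factors is None:
        factors = compute_band_factors(t)
    df = _with_band(t.df)
    l_cv = df.groupby(["cell", "chrom", "band"], observed=True)["count"]
    totals = l_cv.transform("sum")
    alpha = df.merge(factors.table[["chrom", "band", "alpha"]],
                     on=["chrom", "band"], how="left")["alpha"]
    alpha = alpha.fillna(0.0).to_numpy()
    out = t.df.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = df["count"].to_numpy() / totals.to_numpy() * alpha
    out["count"] = np.where(totals.to_numpy() > 0, normed, 0.0)
    return ContactTable(out, t.resolution, t.chrom_sizes), factors


@dataclass
class CellByPairMatrix:
    """Vectorized cells x locus-pairs matrix with a (chrom, bin1, bin2) index."""

    cell_ids: list[str]
    pairs: list[tuple[str, int, int]]
    matrix: sparse.csr_matrix

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(), index=self.cell_ids,
                            columns=pd.MultiIndex.from_tuples(self.pairs))


def vectorize_cells(t: ContactTable,
                    max_band: int | None = None) -> CellByPairMatrix:
    """Pivot the long table into one column per observed locus pair.

    Only pairs observed (nonzero) in at least one cell become columns;
    ``max_band`` restricts to pairs with ``bin2 - bin1 <= max_band``.
    """
    df = t.df[t.df["count"] != 0]
    if max_band is not None:
        df = df[df["bin2"] - df["bin1"] <= max_band]
    cells = sorted(df["cell"].unique())
    pairs = sorted(set(zip(df["chrom"], df["bin1"], df["bin2"])))
    row_of = {c: k for k, c in enumerate(cells)}
    col_of = {p: k for k, p in enumerate(pairs)}
    rows = [row_of[c] for c in df["cell"]]
    cols = [col_of[p] for p in zip(df["chrom"], df["bin1"], df["bin2"])]
    mat = sparse.coo_matrix(
        (df["count"].to_numpy(dtype=float), (rows, cols)),
        shape=(len(cells), len(pairs)),
    ).tocsr()
    return CellByPairMatrix(cells, pairs, mat)
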