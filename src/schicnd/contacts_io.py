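"""Reading, validation, filtering, and band transformation of sparse scHi-C contacts.

A single-cell Hi-C experiment yields, per cell, a symmetric binned contact
matrix per chromosome.  Only the upper triangle is stored, as sparse triplets
``(cell, chrom, bin_i, bin_j, count)`` with ``bin_i <= bin_j``.  The *band*
``v = bin_j - bin_i`` groups locus pairs at the same genomic distance; bands
are the unit on which all normalization in this package operates.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger("schicnd")

COLUMNS = ["cell", "chrom", "bin1", "bin2", "count"]

#: chromosomes excluded by default when reading chromosome-size files
DEFAULT_EXCLUDE_CHROMS = ("chrY", "chrM", "Y", "M", "MT", "chrMT")


@dataclass
class ContactTable:
    """Sparse upper-triangular intra-chromosomal contacts for many cells.

    Parameters
    ----------
    df
        Long-format table with columns ``cell, chrom, bin1, bin2, count``;
        ``bin1 <= bin2`` (0-based bin indices), counts non-negative.
    resolution
        Base pairs per bin.
    chrom_sizes
        Mapping ``chrom -> number of bins D`` on that chromosome.
    """

    df: pd.DataFrame
    resolution: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.df["cell"].unique())

    @property
    def total(self) -> float:
        return float(self.df["count"].sum())

    def validate(self) -> None:
        df = self.df
        if (df["count"] < 0).any():
            raise ValueError("negative contact counts")
        if (df["bin1"] > df["bin2"]).any():
            raise ValueError("bin1 > bin2: table not canonicalized")
        for chrom, sub in df.groupby("chrom", observed=True):
            if chrom not in self.chrom_sizes:
                raise ValueError(f"unknown chromosome: {chrom!r}")
            d = self.chrom_sizes[chrom]
            if (sub["bin2"] >= d).any() or (sub["bin1"] < 0).any():
                raise ValueError(f"bin index out of range for {chrom!r} (D={d})")
        if df.duplicated(["cell", "chrom", "bin1", "bin2"]).any():
            raise ValueError("duplicate (cell, chrom, bin1, bin2) keys")


@dataclass
class BandMatrix:
    """Cells x locus-pairs matrix for one band (or pooled band group).

    Columns are ordered band by band; within band ``v`` the ``m_v = D - v``
    locus pairs ``(i, i+v)`` appear in order of ``i``.
    """

    chrom: str
    bands: list[int]
    cell_ids: list[str]
    matrix: sparse.csr_matrix
    D: int

    def __post_init__(self) -> None:
        expected = sum(self.D - v for v in self.bands)
        if self.matrix.shape != (len(self.cell_ids), expected):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != "
                f"({len(self.cell_ids)}, {expected})"
            )

    @property
    def pair_index(self) -> list[tuple[int, int, int]]:
        """(band, bin_i, bin_j) for every column, in column order."""
        out = []
        for v in self.bands:
            out.extend((v, i, i + v) for i in range(self.D - v))
        return out

    @property
    def band_of_column(self) -> np.ndarray:
        return np.concatenate(
            [np.full(self.D - v, v, dtype=int) for v in self.bands]
        )


@dataclass
class CellMetadata:
    """Per-cell annotations: optional cell type and batch labels."""

    df: pd.DataFrame  # columns: cell, [cell_type], [batch]

    def __post_init__(self) -> None:
        if self.df["cell"].duplicated().any():
            raise ValueError("duplicate cell ids in metadata")

    def batches_for(self, cell_ids: list[str]) -> np.ndarray:
        if "batch" not in self.df.columns:
            return np.zeros(len(cell_ids), dtype=int)
        lookup = self.df.set_index("cell")["batch"]
        codes, _ = pd.factorize(self.df["batch"])
        code_of = dict(zip(self.df["cell"], codes))
        return np.array([code_of[c] for c in cell_ids], dtype=int)


def read_chrom_sizes(
    path: str,
    resolution: int,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE_CHROMS,
) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length_bp`` file into bins per chromosome.

    Y and mitochondrial chromosomes are excluded by default; X is kept.
    """
    sizes = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                        comment="#")
    out = {}
    for chrom, length in zip(sizes["chrom"], sizes["length"]):
        if chrom in exclude:
            continue
        out[str(chrom)] = int(np.ceil(length / resolution))
    return out


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce bin1 <= bin2 and sum duplicate keys (never overwrite)."""
    swap = df["bin1"] > df["bin2"]
    if swap.any():
        b1 = df["bin1"].where(~swap, df["bin2"])
        b2 = df["bin2"].where(~swap, df["bin1"])
        df = df.assign(bin1=b1, bin2=b2)
    return (
        df.groupby(["cell", "chrom", "bin1", "bin2"], as_index=False,
                   observed=True)["count"].sum()
    )


def read_contacts(
    path: str,
    resolution: int,
    chrom_sizes: dict[str, int],
) -> ContactTable:
    """Read one long-format TSV, or a directory of per-cell triplet files.

    Accepted headers: ``cell,chrom,bin1,bin2,count`` (already binned) or
    ``cell,chrom,pos1,pos2,count`` (bp coordinates, binned here by
    ``floor(pos / resolution)``).  Per-cell files omit the ``cell`` column
    (the file stem is the cell id) and may carry a ``chrom2`` column;
    inter-chromosomal records are dropped and counted in the log.
    """
    if os.path.isdir(path):
        frames = []
        for name in sorted(os.listdir(path)):
            fp = os.path.join(path, name)
            if not os.path.isfile(fp):
                continue
            sub = pd.read_csv(fp, sep="\t")
            if "cell" not in sub.columns:
                sub.insert(0, "cell", os.path.splitext(name)[0])
            frames.append(sub)
        if not frames:
            raise ValueError(f"no contact files found in {path!r}")
        raw = pd.concat(frames, ignore_index=True)
    else:
        raw = pd.read_csv(path, sep="\t")

    if raw.empty:
        raise ValueError("empty contact input")

    if "chrom2" in raw.columns:
        inter = raw["chrom"] != raw["chrom2"]
        n_inter = int(inter.sum())
        if n_inter:
            logger.info("dropped %d inter-chromosomal records", n_inter)
        raw = raw.loc[~inter].drop(columns="chrom2")

    if {"pos1", "pos2"} <= set(raw.columns):
        raw = raw.assign(
            bin1=(raw["pos1"] // resolution).astype(int),
            bin2=(raw["pos2"] // resolution).astype(int),
        ).drop(columns=["pos1", "pos2"])
    elif not {"bin1", "bin2"} <= set(raw.columns):
        raise ValueError("expected columns bin1/bin2 or pos1/pos2")

    raw = raw[COLUMNS].copy()
    raw["cell"] = raw["cell"].astype(str)
    raw["chrom"] = raw["chrom"].astype(str)
    if (raw["count"] < 0).any():
        raise ValueError("negative contact counts in input")
    unknown = set(raw["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")

    table = ContactTable(_canonicalize(raw), resolution, dict(chrom_sizes))
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Sparse-cell filtering


def filter_sparse_cells(
    t: ContactTable,
    mode: str = "mb_rule",
    threshold: float = 0.999,
) -> tuple[ContactTable, list[str]]:
    """Remove extremely sparse cells.

    ``mb_rule`` (1 Mb resolution): a cell is removed if on *any* chromosome
    its number of non-zero locus pairs is strictly below ``x / 6`` where
    ``x`` is the chromosome length in Mb (x/6 is not rounded).

    ``sparsity_rule`` (high resolution): a cell is removed if the fraction of
    zero entries of its upper-triangular contact matrix (diagonal included)
    exceeds ``threshold`` on any chromosome; default 0.999.
    """
    if mode not in ("mb_rule", "sparsity_rule"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mb_rule" and t.resolution != 1_000_000:
        raise ValueError("mb_rule requires 1 Mb resolution")

    nonzero = t.df[t.df["count"] > 0]
    counts = nonzero.groupby(["cell", "chrom"], observed=True).size()

    removed: set[str] = set()
    for cell in t.cell_ids:
        for chrom, d in t.chrom_sizes.items():
            n_nonzero = int(counts.get((cell, chrom), 0))
            if mode == "mb_rule":
                x = d  # chromosome length in Mb at 1 Mb resolution
                if n_nonzero < x / 6:
                    removed.add(cell)
                    break
            else:
                n_pairs = d * (d + 1) // 2
                if 1.0 - n_nonzero / n_pairs > threshold:
                    removed.add(cell)
                    break

    kept = t.df[~t.df["cell"].isin(removed)].reset_index(drop=True)
    if kept.empty:
        logger.warning("all cells removed by %s filter", mode)
    return ContactTable(kept, t.resolution, t.chrom_sizes), sorted(removed)


# ---------------------------------------------------------------------------
# Band transformation


def band_split(
    t: ContactTable,
    chrom: str,
    drop_diagonal: bool = True,
    cell_ids: list[str] | None = None,
) -> list[BandMatrix]:
    """Stratify one chromosome's contacts into per-band cells x pairs matrices.

    Band ``v`` holds the locus pairs with ``bin2 - bin1 == v``; the diagonal
    band ``v = 0`` is dropped by default so that every returned band has
    ``v >= 1``.
    """
    if chrom not in t.chrom_sizes:
        raise ValueError(f"chromosome {chrom!r} not in chrom_sizes")
    d = t.chrom_sizes[chrom]
    cells = cell_ids if cell_ids is not None else t.cell_ids
    row_of = {c: k for k, c in enumerate(cells)}

    sub = t.df[t.df["chrom"] == chrom]
    v_all = (sub["bin2"] - sub["bin1"]).to_numpy()
    out = []
    for v in range(1 if drop_diagonal else 0, d):
        in_band = sub[v_all == v]
        rows = np.array([row_of[c] for c in in_band["cell"]], dtype=int)
        cols = in_band["bin1"].to_numpy(dtype=int)
        mat = sparse.coo_matrix(
            (in_band["count"].to_numpy(dtype=float), (rows, cols)),
            shape=(len(cells), d - v),
        ).tocsr()
        out.append(BandMatrix(chrom, [v], list(cells), mat, d))
    return out


def band_merge(bands: list[BandMatrix], resolution: int,
               chrom_sizes: dict[str, int] | None = None) -> ContactTable:
    """Inverse of :func:`band_split`: reassemble a long-format table."""
    records = []
    sizes: dict[str, int] = dict(chrom_sizes or {})
    for bm in bands:
        sizes.setdefault(bm.chrom, bm.D)
        coo = bm.matrix.tocoo()
        pairs = bm.pair_index
        for r, c, val in zip(coo.row, coo.col, coo.data):
            if val == 0:
                continue
            _, i, j = pairs[c]
            records.append((bm.cell_ids[r], bm.chrom, i, j, val))
    df = pd.DataFrame(records, columns=COLUMNS)
    df = df.groupby(["cell", "chrom", "bin1", "bin2"], as_index=False,
                    observed=True)["count"].sum()
    return ContactTable(df, resolution, sizes)


def pool_bands(bands: list[BandMatrix], band_group: list[int]) -> BandMatrix:
    """Concatenate the band matrices of a pooled group column-wise."""
    by_v = {bm.bands[0]: bm for bm in bands if len(bm.bands) == 1}
    chosen = [by_v[v] for v in band_group]
    first = chosen[0]
    mat = sparse.hstack([bm.matrix for bm in chosen], format="csr")
    return BandMatrix(first.chrom, list(band_group), first.cell_ids, mat,
                      first.D)


# ---------------------------------------------------------------------------
# Pseudo-bulk aggregation


def aggregate_pseudobulk(
    t: ContactTable,
    labels: dict[str, str],
) -> dict[str, ContactTable]:
    """Sum contacts per cell group into one pseudo-bulk table per group.

    Cells missing from ``labels`` are dropped with a warning.  Works on raw,
    normalized, or de-noised tables alike.
    """
    unlabeled = set(t.cell_ids) - set(labels)
    if unlabeled:
        logger.warning("dropping %d unlabeled cells", len(unlabeled))
    df = t.df[t.df["cell"].isin(labels)]
    groups = df["cell"].map(labels)
    out: dict[str, ContactTable] = {}
    for group in sorted(set(labels.values())):
        sub = df[groups == group]
        agg = sub.groupby(["chrom", "bin1", "bin2"], as_index=False,
                          observed=True)["count"].sum()
        agg.insert(0, "cell", group)
        if agg.empty:
            logger.warning("group %r is empty", group)
        out[group] = ContactTable(agg, t.resolution, t.chrom_sizes)
    return out


def write_contacts(t: ContactTable, path: str) -> None:
    t.df[COLUMNS].to_csv(path, sep="\t", index=False)
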