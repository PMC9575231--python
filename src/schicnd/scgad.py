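"""Single-cell gene associating domain (scGAD) scores and marker statistics.

The scGAD score of a gene in a cell is the ratio of the summed contact
frequency among bin pairs inside the gene body to the average of the same
quantity over the immediately adjacent upstream and downstream windows of
equal bin length, computed on depth/distance-normalized contacts.  Raw
ratios are then standardized into per-cell z-scores across genes.  High
scores mark genes whose body forms a self-interacting domain — a structural
signature of highly expressed and cell-type marker genes.

Only genes at least 100 kb long (and spanning at least two bins at the
working resolution) are scoreable; shorter genes cannot be distinguished
from background at the resolutions typical of chromatin-contact assays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .contacts_io import ContactTable

logger = logging.getLogger("schicnd")

MIN_GENE_LENGTH = 100_000


@dataclass
class GeneTable:
    """Gene annotations with derived bin spans at a working resolution."""

    df: pd.DataFrame  # gene, chrom, start, end, strand, bin_start, bin_end

    @classmethod
    def from_bed(cls, path_or_df, resolution: int,
                 min_length: int = MIN_GENE_LENGTH) -> "GeneTable":
        """Load BED6 (chrom, start, end, name, score, strand) gene annotations.

        Genes shorter than ``min_length`` bp or spanning fewer than two bins
        are dropped (logged).
        """
        if isinstance(path_or_df, pd.DataFrame):
            bed = path_or_df.copy()
        else:
            bed = pd.read_csv(path_or_df, sep="\t", header=None,
                              names=["chrom", "start", "end", "name",
                                     "score", "strand"],
                              usecols=range(6))
        if (bed["end"] <= bed["start"]).any():
            raise ValueError("gene with end <= start")
        bed["bin_start"] = bed["start"] // resolution
        bed["bin_end"] = (bed["end"] - 1) // resolution
        ok = ((bed["end"] - bed["start"] >= min_length)
              & (bed["bin_end"] - bed["bin_start"] >= 1))
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("dropped %d genes below length/bin-span rules",
                        n_dropped)
        out = bed.loc[ok, ["name", "chrom", "start", "end", "strand",
                           "bin_start", "bin_end"]]
        return cls(out.rename(columns={"name": "gene"}).reset_index(drop=True))


@dataclass
class GADMatrix:
    """Cells x genes scGAD scores: raw ratios, per-cell z-scores, missing mask."""

    cell_ids: list[str]
    gene_ids: list[str]
    raw: np.ndarray  # NaN where missing
    z: np.ndarray    # per-cell standardized, NaN where missing

    def mean_scores(self) -> pd.Series:
        """Cross-cell mean standardized score per gene (missing excluded)."""
        with np.errstate(invalid="ignore"):
            means = np.nanmean(self.z, axis=0)
        return pd.Series(means, index=self.gene_ids)


def compute_scgad(t: ContactTable, genes: GeneTable) -> GADMatrix:
    """Score every gene in every cell on a normalized contact table.

    The input is expected to be BandNorm-normalized (raw counts work but the
    score then confounds depth).  For gene bins ``[a, b]`` the within score
    sums all off-diagonal pairs ``a <= i < j <= b``; flank scores are
    computed identically on ``[a-w, a-1]`` and ``[b+1, b+w]`` with
    ``w = b - a + 1``.  A flank truncated by the chromosome edge is dropped;
    with both flanks unavailable, or a zero denominator, the score is missing.
    """
    cells = t.cell_ids
    cell_row = {c: i for i, c in enumerate(cells)}
    n_genes = len(genes.df)
    raw = np.full((len(cells), n_genes), np.nan)

    for chrom, gsub in genes.df.groupby("chrom", observed=True):
        if chrom not in t.chrom_sizes:
            continue
        d = t.chrom_sizes[chrom]
        sub = t.df[(t.df["chrom"] == chrom) & (t.df["bin1"] < t.df["bin2"])]
        if sub.empty:
            continue
        rows = np.array([cell_row[c] for c in sub["cell"]])
        i_arr = sub["bin1"].to_numpy()
        j_arr = sub["bin2"].to_numpy()
        vals = sub["count"].to_numpy(dtype=float)

        def window_sums(lo: int, hi: int) -> np.ndarray:
            mask = (i_arr >= lo) & (j_arr <= hi)
            out = np.zeros(len(cells))
            np.add.at(out, rows[mask], vals[mask])
            return out

        for gi, gene in gsub.iterrows():
            a, b = int(gene["bin_start"]), int(gene["bin_end"])
            if b >= d:
                continue
            w = b - a + 1
            within = window_sums(a, b)
            flanks = []
            if a - w >= 0:
                flanks.append(window_sums(a - w, a - 1))
            if b + w < d:
                flanks.append(window_sums(b + 1, b + w))
            if not flanks:
                continue
            denom = np.mean(flanks, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(denom > 0, within / denom, np.nan)
            raw[:, gi] = ratio

    # per-cell standardization across non-missing genes
    z = np.full_like(raw, np.nan)
    for r in range(raw.shape[0]):
        row = raw[r]
        ok = ~np.isnan(row)
        if ok.sum() >= 2:
            sd = row[ok].std(ddof=1)
            if sd > 0:
                z[r, ok] = (row[ok] - row[ok].mean()) / sd
    return GADMatrix(cells, list(genes.df["gene"]), raw, z)


# ---------------------------------------------------------------------------
# High-score threshold (slope-1 tangent)


def gad_score_threshold(g: GADMatrix) -> float:
    """Threshold above which a mean scGAD score counts as high.

    Genes are ranked by their cross-cell mean score; both the mean scores and
    the ranks are min-max scaled to [0, 1], giving a monotone score-vs-rank
    curve.  The threshold is the (unscaled) score at the point where a
    tangent to the monotone-spline-smoothed curve has slope 1; when several
    crossings exist the largest rank (most selective threshold) wins, and a
    perfectly linear curve (slope 1 everywhere) resolves to the midpoint.
    """
    means = g.mean_scores().dropna().sort_values().to_numpy()
    n = means.size
    if n < 10:
        raise ValueError("need >= 10 scoreable genes")
    lo, hi = means[0], means[-1]
    if hi - lo <= 0:
        raise ValueError("degenerate score curve (constant scores)")
    x = np.linspace(0.0, 1.0, n)
    y = (means - lo) / (hi - lo)
    # collapse duplicate x from tied ranks (none here: ranks are distinct)
    spline = PchipInterpolator(x, y)
    deriv = spline.derivative()

    grid = np.linspace(0.0, 1.0, 2001)
    dvals = deriv(grid) - 1.0
    if np.all(np.abs(dvals) < 1e-9):
        x_star = 0.5
    else:
        crossings = []
        for k in range(len(grid) - 1):
            if dvals[k] == 0.0:
                crossings.append(grid[k])
            elif dvals[k] * dvals[k + 1] < 0:
                crossings.append(brentq(lambda t: deriv(t) - 1.0,
                                        grid[k], grid[k + 1]))
        if not crossings:
            x_star = 0.5
        else:
            x_star = max(crossings)  # most selective threshold
    y_star = float(spline(x_star))
    return y_star * (hi - lo) + lo


# ---------------------------------------------------------------------------
# Tests against the threshold and between groups


def _bh(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _signed_rank_greater(values: np.ndarray, threshold: float) -> float:
    """One-sided (greater) one-sample Wilcoxon signed-rank p-value.

    Exact distribution for n <= 25 non-zero differences, normal approximation
    with continuity correction above.
    """
    diffs = values - threshold
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return 1.0
    method = "exact" if n <= 25 else "approx"
    try:
        res = stats.wilcoxon(diffs, alternative="greater", method=method,
                             correction=(method == "approx"))
    except ValueError:
        res = stats.wilcoxon(diffs, alternative="greater", method="approx",
                             correction=True)
    return float(res.pvalue)


def high_scgad_test(g: GADMatrix, labels: dict[str, str],
                    threshold: float) -> pd.DataFrame:
    """Per cell type, test each gene's cell-level scores against the threshold.

    One-sample Wilcoxon signed-rank, one-sided (greater); Benjamini-Hochberg
    adjustment across genes within each type.
    """
    rows = []
    z = pd.DataFrame(g.z, index=g.cell_ids, columns=g.gene_ids)
    for ctype in sorted(set(labels.values())):
        cells = [c for c in g.cell_ids if labels.get(c) == ctype]
        if len(cells) < 3:
            logger.warning("type %r has <3 cells, skipped", ctype)
            continue
        sub = z.loc[cells]
        pvals, genes = [], []
        for gene in g.gene_ids:
            vals = sub[gene].dropna().to_numpy()
            if vals.size == 0:
                continue
            genes.append(gene)
            pvals.append(_signed_rank_greater(vals, threshold))
        padj = _bh(np.array(pvals))
        rows.extend(zip([ctype] * len(genes), genes, pvals, padj))
    return pd.DataFrame(rows, columns=["cell_type", "gene", "p", "p_adj"])


def _lognormalize(raw: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Per-cell total normalization followed by log1p (missing stays NaN)."""
    filled = np.nan_to_num(raw, nan=0.0)
    totals = filled.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    out = np.log1p(filled / totals * scale)
    out[np.isnan(raw)] = np.nan
    return out


def celltype_markers(g: GADMatrix, labels: dict[str, str],
                     min_pct: float = 0.1,
                     logfc_threshold: float = 0.25) -> pd.DataFrame:
    """One-vs-rest marker detection on rescaled scGAD scores.

    Raw ratio scores are total-normalized per cell, log1p-transformed, then
    z-scaled per gene across cells.  A gene enters the test for a type only
    if it is detected (positive log-normalized score) in at least ``min_pct``
    of the type's cells and its in-group minus out-group mean log score is at
    least ``logfc_threshold``.  The test is a one-sided (greater) Wilcoxon
    rank-sum; BH adjustment within each type.
    """
    types = sorted(set(labels.values()))
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    lognorm = _lognormalize(g.raw)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(lognorm, axis=0)
        sd = np.nanstd(lognorm, axis=0, ddof=1)
    sd[~(sd > 0)] = 1.0
    scaled = (lognorm - mu) / sd

    cell_idx = {c: i for i, c in enumerate(g.cell_ids)}
    rows = []
    for ctype in types:
        in_ids = [cell_idx[c] for c in g.cell_ids if labels.get(c) == ctype]
        out_ids = [cell_idx[c] for c in g.cell_ids
                   if c in labels and labels[c] != ctype]
        if len(in_ids) < 3:
            logger.warning("type %r has <3 cells, skipped", ctype)
            continue
        genes, pvals, effects, pct_in_list, pct_out_list = [], [], [], [], []
        for j, gene in enumerate(g.gene_ids):
            ln_in = lognorm[in_ids, j]
            ln_out = lognorm[out_ids, j]
            ln_in = ln_in[~np.isnan(ln_in)]
            ln_out = ln_out[~np.isnan(ln_out)]
            if ln_in.size == 0 or ln_out.size == 0:
                continue
            pct_in = float((ln_in > 0).mean())
            pct_out = float((ln_out > 0).mean())
            if pct_in < min_pct:
                continue
            logfc = float(ln_in.mean() - ln_out.mean())
            if logfc < logfc_threshold:
                continue
            sc_in = scaled[in_ids, j]
            sc_out = scaled[out_ids, j]
            sc_in = sc_in[~np.isnan(sc_in)]
            sc_out = sc_out[~np.isnan(sc_out)]
            res = stats.mannwhitneyu(sc_in, sc_out, alternative="greater")
            genes.append(gene)
            pvals.append(float(res.pvalue))
            effects.append(logfc)
            pct_in_list.append(pct_in)
            pct_out_list.append(pct_out)
        padj = _bh(np.array(pvals))
        for k, gene in enumerate(genes):
            rows.append((ctype, gene, pvals[k], float(padj[k]), effects[k],
                         pct_in_list[k], pct_out_list[k]))
    return pd.DataFrame(rows, columns=["cell_type", "gene", "p", "p_adj",
                                       "effect", "pct_in", "pct_out"])


def differential_scgad(g: GADMatrix, two_labels: dict[str, str],
                       gene_set: list[str]) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene between two cell groups.

    Direction is the sign of the group-1 minus group-2 mean score; genes
    missing in at least half of either group are tested on the available
    cells and flagged.  BH adjustment across the gene set.
    """
    groups = sorted(set(two_labels.values()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = groups
    z = pd.DataFrame(g.z, index=g.cell_ids, columns=g.gene_ids)
    a_cells = [c for c in g.cell_ids if two_labels.get(c) == ga]
    b_cells = [c for c in g.cell_ids if two_labels.get(c) == gb]
    if not a_cells or not b_cells:
        raise ValueError("both groups must be non-empty")
    rows = []
    for gene in gene_set:
        va = z.loc[a_cells, gene].dropna().to_numpy()
        vb = z.loc[b_cells, gene].dropna().to_numpy()
        flagged = (va.size < len(a_cells) / 2) or (vb.size < len(b_cells) / 2)
        if va.size == 0 or vb.size == 0:
            rows.append((gene, np.nan, 0, True))
            continue
        if np.array_equal(np.sort(va), np.sort(vb)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(va, vb,
                                         alternative="two-sided").pvalue)
        direction = int(np.sign(va.mean() - vb.mean()))
        rows.append((gene, p, direction, flagged))
    out = pd.DataFrame(rows, columns=["gene", "p", "direction", "flagged"])
    ok = out["p"].notna()
    out.loc[ok, "p_adj"] = _bh(out.loc[ok, "p"].to_numpy())
    return out


def marker_overlap(set_a: set[str], set_b: set[str],
                   universe: set[str]) -> tuple[float, float]:
    """Fisher's exact test (enrichment) for the overlap of two gene sets.

    Returns the sample odds ratio and the one-sided p-value of the 2x2
    membership table over ``universe``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    both = len(set_a & set_b)
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    neither = len(universe) - both - only_a - only_b
    table = [[both, only_a], [only_b, neither]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)
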