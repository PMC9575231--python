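"""scGAD scores, the high-score threshold, and marker statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from schicnd import (
    GADMatrix,
    GeneTable,
    SyntheticConfig,
    celltype_markers,
    compute_scgad,
    differential_scgad,
    gad_score_threshold,
    high_scgad_test,
    marker_overlap,
    simulate_cells,
    simulate_genes,
    band_norm,
)
from schicnd.scgad import _bh, _signed_rank_greater
from conftest import make_table


def gene_table(entries, resolution=100_000):
    bed = pd.DataFrame(entries, columns=["chrom", "start", "end", "name",
                                         "score", "strand"])
    return GeneTable.from_bed(bed, resolution)


def full_uniform_table(d, value, cell="c1", chrom="chr1",
                       resolution=100_000):
    recs = [(cell, chrom, i, j, value)
            for i in range(d) for j in range(i + 1, d)]
    return make_table(recs, resolution=resolution, chrom_sizes={chrom: d})


class TestGeneTable:
    def test_length_and_span_rules(self):
        g = gene_table([
            ("chr1", 0, 400_000, "long", 0, "+"),       # 4 bins, 400 kb
            ("chr1", 0, 90_000, "short", 0, "+"),       # < 100 kb
            ("chr1", 1_000_000, 1_100_000, "onebin", 0, "+"),  # 1 bin
        ])
        assert g.df["gene"].tolist() == ["long"]

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            gene_table([("chr1", 500, 400, "bad", 0, "+")])


class TestComputeScgad:
    def test_uniform_map_gives_ratio_one(self):
        t = full_uniform_table(16, 3.0)
        g = gene_table([("chr1", 500_000, 800_000, "g", 0, "+")])  # bins 5-7
        gad = compute_scgad(t, g)
        assert gad.raw[0, 0] == pytest.approx(1.0)

    def test_hand_computed_toy_ratio(self):
        # gene bins [10, 12]: within (10,11)=1 (10,12)=2 (11,12)=3, sum 6
        # upstream [7, 9] sums to 2; downstream [13, 15] sums to 4 -> 6/3 = 2
        recs = [("c1", "chr1", 10, 11, 1), ("c1", "chr1", 10, 12, 2),
                ("c1", "chr1", 11, 12, 3),
                ("c1", "chr1", 7, 8, 1), ("c1", "chr1", 8, 9, 1),
                ("c1", "chr1", 13, 14, 2), ("c1", "chr1", 14, 15, 2)]
        t = make_table(recs, resolution=100_000, chrom_sizes={"chr1": 20})
        g = gene_table([("chr1", 1_000_000, 1_300_000, "g", 0, "+")])
        gad = compute_scgad(t, g)
        assert gad.raw[0, 0] == pytest.approx(2.0)

    def test_per_cell_z_scores_standardized(self, rng):
        t = full_uniform_table(30, 1.0)
        t.df["count"] = rng.uniform(0.5, 4.0, len(t.df))
        genes = gene_table([("chr1", s * 100_000, (s + 3) * 100_000,
                             f"g{s}", 0, "+") for s in (3, 9, 15, 21)])
        gad = compute_scgad(t, genes)
        row = gad.z[0]
        ok = ~np.isnan(row)
        assert row[ok].mean() == pytest.approx(0.0, abs=1e-6)
        assert row[ok].std(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_per_cell_scaling(self, rng):
        t = full_uniform_table(30, 1.0, cell="c1")
        t2 = full_uniform_table(30, 1.0, cell="c2")
        vals = rng.uniform(0.5, 4.0, len(t.df))
        t.df["count"] = vals
        t2.df["count"] = vals * 13.7  # same pattern, scaled depth
        both = make_table(
            list(pd.concat([t.df, t2.df]).itertuples(index=False)),
            resolution=100_000, chrom_sizes={"chr1": 30})
        genes = gene_table([("chr1", s * 100_000, (s + 3) * 100_000,
                             f"g{s}", 0, "+") for s in (3, 9, 15, 21)])
        gad = compute_scgad(both, genes)
        np.testing.assert_allclose(gad.raw[0], gad.raw[1], rtol=1e-9)
        np.testing.assert_allclose(gad.z[0], gad.z[1], atol=1e-9)

    def test_edge_gene_uses_available_flank_only(self):
        # gene bins [0, 2] of a D=6 chromosome: upstream is off-chromosome
        recs = [("c1", "chr1", 0, 1, 2), ("c1", "chr1", 0, 2, 2),
                ("c1", "chr1", 1, 2, 2),
                ("c1", "chr1", 3, 4, 1), ("c1", "chr1", 3, 5, 1),
                ("c1", "chr1", 4, 5, 1)]
        t = make_table(recs, resolution=100_000, chrom_sizes={"chr1": 6})
        g = gene_table([("chr1", 0, 300_000, "edge", 0, "+")])
        gad = compute_scgad(t, g)
        assert gad.raw[0, 0] == pytest.approx(6.0 / 3.0)

    def test_missing_when_no_flank_or_zero_denominator(self):
        # whole-chromosome gene: both flanks off -> missing
        t = full_uniform_table(3, 1.0)
        g = gene_table([("chr1", 0, 300_000, "whole", 0, "+")])
        assert np.isnan(compute_scgad(t, g).raw[0, 0])
        # flanks present but all-zero -> missing
        recs = [("c1", "chr1", 4, 5, 3.0)]
        t2 = make_table(recs, resolution=100_000, chrom_sizes={"chr1": 12})
        g2 = gene_table([("chr1", 400_000, 600_000, "gene", 0, "+")])
        assert np.isnan(compute_scgad(t2, g2).raw[0, 0])


def gad_from_means(means):
    """Single-cell GADMatrix whose mean scores are exactly ``means``."""
    means = np.asarray(means, dtype=float)
    return GADMatrix(["c1"], [f"g{i}" for i in range(means.size)],
                     means[None, :].copy(), means[None, :].copy())


class TestThreshold:
    def test_convex_curve_tangent_at_half(self):
        # scaled curve y = x^2: slope-1 tangency at x = 0.5, y = 0.25
        x = np.linspace(0, 1, 101)
        g = gad_from_means(x ** 2)
        assert gad_score_threshold(g) == pytest.approx(0.25, abs=0.01)

    def test_linear_curve_resolves_to_midpoint(self):
        g = gad_from_means(np.linspace(2.0, 6.0, 50))
        assert gad_score_threshold(g) == pytest.approx(4.0, abs=0.05)

    def test_threshold_within_score_range(self, rng):
        means = rng.normal(0, 1, 80)
        thr = gad_score_threshold(gad_from_means(means))
        assert means.min() <= thr <= means.max()

    def test_unscaling_maps_back_to_score_units(self):
        x = np.linspace(0, 1, 101)
        g = gad_from_means(5.0 + 3.0 * x ** 2)  # affine transform of x^2
        assert gad_score_threshold(g) == pytest.approx(5.0 + 3.0 * 0.25,
                                                       abs=0.05)

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gad_score_threshold(gad_from_means(np.full(20, 2.0)))
        with pytest.raises(ValueError, match=">= 10"):
            gad_score_threshold(gad_from_means(np.arange(5.0)))


def exact_signed_rank_greater(values, threshold):
    """Brute-force one-sided signed-rank p over all sign assignments."""
    diffs = np.asarray(values, dtype=float) - threshold
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w >= w_obs:
            count += 1
    return count / 2 ** n


class TestHighScgad:
    def test_p_matches_exact_enumeration(self, rng):
        for _ in range(5):
            vals = rng.normal(0.5, 1.0, 6)
            expected = exact_signed_rank_greater(vals, 0.0)
            assert _signed_rank_greater(vals, 0.0) == pytest.approx(expected)

    def test_all_below_threshold_one_sided(self, rng):
        vals = -np.abs(rng.normal(1, 0.2, 8))
        assert _signed_rank_greater(vals, 0.0) >= 0.5

    def test_all_equal_threshold_convention(self):
        assert _signed_rank_greater(np.full(5, 1.5), 1.5) == 1.0

    def test_bh_hand_computation(self):
        adjusted = _bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_table_layout_and_small_types_skipped(self, rng):
        raw = np.abs(rng.normal(1, 0.3, (8, 12)))
        g = GADMatrix([f"c{i}" for i in range(8)],
                      [f"g{j}" for j in range(12)], raw, raw.copy())
        labels = {f"c{i}": ("A" if i < 6 else "B") for i in range(8)}
        out = high_scgad_test(g, labels, threshold=1.0)
        assert set(out["cell_type"]) == {"A"}  # B has < 3 cells
        assert len(out) == 12
        assert ((out["p_adj"] >= out["p"] - 1e-12)).all()

    def test_type_one_error_calibrated_under_null(self, rng):
        """Null scores symmetric about the threshold: ~5% of genes at p<0.05."""
        n_cells, n_genes = 40, 300
        scores = rng.normal(0.0, 1.0, (n_cells, n_genes))
        g = GADMatrix([f"c{i}" for i in range(n_cells)],
                      [f"g{j}" for j in range(n_genes)], scores,
                      scores.copy())
        labels = {c: "A" for c in g.cell_ids}
        out = high_scgad_test(g, labels, threshold=0.0)
        frac = (out["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) < 3 * se + 1e-9


class TestCelltypeMarkers:
    def test_min_pct_filter_excludes_rare_gene(self, rng):
        n = 40
        raw = np.abs(rng.normal(1.0, 0.2, (n, 6)))
        raw[:, 0] = 0.0
        raw[0, 0] = 50.0  # detected in 1/20 = 5% of in-group cells
        g = GADMatrix([f"c{i}" for i in range(n)],
                      [f"g{j}" for j in range(6)], raw, raw.copy())
        labels = {f"c{i}": ("A" if i < 20 else "B") for i in range(n)}
        out = celltype_markers(g, labels)
        assert "g0" not in set(out[out["cell_type"] == "A"]["gene"])

    def test_identical_distributions_rarely_called(self, rng):
        hits = total = 0
        for rep in range(20):
            raw = np.abs(rng.lognormal(0.0, 0.5, (30, 10)))
            g = GADMatrix([f"c{i}" for i in range(30)],
                          [f"g{j}" for j in range(10)], raw, raw.copy())
            labels = {f"c{i}": ("A" if i < 15 else "B") for i in range(30)}
            out = celltype_markers(g, labels)
            hits += int((out["p_adj"] < 0.05).sum())
            total += 20  # genes x types per replicate
        assert hits / total <= 0.05

    def test_requires_two_types(self, rng):
        raw = np.abs(rng.normal(1, 0.2, (6, 4)))
        g = GADMatrix([f"c{i}" for i in range(6)],
                      [f"g{j}" for j in range(4)], raw, raw.copy())
        with pytest.raises(ValueError):
            celltype_markers(g, {c: "A" for c in g.cell_ids})


@pytest.fixture(scope="module")
def planted_marker_run():
    cfg = SyntheticConfig(n_cells_per_type=100, type_gammas=(0.9, 1.1),
                          type_amplitudes=(300.0, 300.0), n_bins=200,
                          n_marker_genes=20, marker_fold=3.0, seed=31)
    genes, markers = simulate_genes(cfg)
    table, meta, truth = simulate_cells(cfg, genes, markers)
    normed, _ = band_norm(table)
    gad = compute_scgad(normed, genes)
    labels = dict(zip(meta.df["cell"],
                      meta.df["cell_type"]))
    detected = celltype_markers(gad, labels)
    return truth, detected


class TestPlantedMarkerRecovery:
    def test_recall_of_planted_markers(self, planted_marker_run):
        truth, detected = planted_marker_run
        planted = truth["marker_genes"]
        sig = detected[detected["p_adj"] < 0.05]
        found = 0
        for _, row in planted.iterrows():
            ctype = f"type{row['type']}"
            hit = ((sig["cell_type"] == ctype)
                   & (sig["gene"] == row["gene"])).any()
            found += int(hit)
        assert found / len(planted) >= 0.9

    def test_markers_specific_to_their_type(self, planted_marker_run):
        truth, detected = planted_marker_run
        planted = truth["marker_genes"]
        sig = detected[detected["p_adj"] < 0.05]
        for _, row in planted.iterrows():
            wrong = f"type{1 - row['type']}"
            assert not ((sig["cell_type"] == wrong)
                        & (sig["gene"] == row["gene"])).any()


def exact_rank_sum_two_sided(a, b):
    """Brute-force two-sided rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    n = len(pooled)
    stats_all = [ranks[list(idx)].sum()
                 for idx in itertools.combinations(range(n), na)]
    stats_all = np.array(stats_all)
    mean_w = stats_all.mean()
    extreme = np.abs(stats_all - mean_w) >= abs(w_obs - mean_w) - 1e-12
    return extreme.mean()


class TestDifferentialScgad:
    def _gad(self, va, vb):
        vals = np.concatenate([va, vb])[:, None]
        n = len(vals)
        return GADMatrix([f"c{i}" for i in range(n)], ["g0"], vals,
                         vals.copy()), {
            f"c{i}": ("A" if i < len(va) else "B") for i in range(n)}

    def test_identical_groups_p_one(self):
        g, labels = self._gad(np.array([1.0, 2.0, 3.0]),
                              np.array([1.0, 2.0, 3.0]))
        out = differential_scgad(g, labels, ["g0"])
        assert out["p"].iloc[0] == 1.0

    def test_matches_exact_rank_sum(self, rng):
        for _ in range(5):
            va = rng.normal(0, 1, 3)
            vb = rng.normal(1, 1, 3)
            g, labels = self._gad(va, vb)
            out = differential_scgad(g, labels, ["g0"])
            assert out["p"].iloc[0] == pytest.approx(
                exact_rank_sum_two_sided(va, vb))

    def test_direction_flips_with_labels(self, rng):
        va, vb = rng.normal(2, 0.1, 4), rng.normal(0, 0.1, 4)
        g, labels = self._gad(va, vb)
        out = differential_scgad(g, labels, ["g0"])
        swapped = {c: ("B" if lab == "A" else "A")
                   for c, lab in labels.items()}
        out2 = differential_scgad(g, swapped, ["g0"])
        assert out["direction"].iloc[0] == -out2["direction"].iloc[0] != 0


class TestMarkerOverlap:
    def test_disjoint_cover_odds_zero(self):
        universe = {f"e{i}" for i in range(20)}
        a = {f"e{i}" for i in range(10)}
        odds, p = marker_overlap(a, universe - a, universe)
        assert odds == 0.0

    def test_matches_hypergeometric_summation(self):
        universe = {f"e{i}" for i in range(100)}
        a = {f"e{i}" for i in range(20)}
        b = {f"e{i}" for i in range(10, 30)}
        _, p = marker_overlap(a, b, universe)
        # oracle: P(overlap >= 10) drawing 20 of 100 with 20 marked
        expected = stats.hypergeom.sf(9, 100, 20, 20)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_identical_half_splits_highly_enriched(self):
        universe = {f"e{i}" for i in range(60)}
        a = {f"e{i}" for i in range(30)}
        _, p = marker_overlap(a, set(a), universe)
        assert p < 1e-6

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            marker_overlap(set(), set(), set())
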