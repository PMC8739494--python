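"""Binned tracks: coverage, ratios, quantile selection, state aggregation."""

import numpy as np
import pytest

from conftest import make_track
from uvsuscept.genome import GenomeLayout, GenomicInterval, LabeledSegmentation
from uvsuscept.lesion import (
    aggregate_by_state,
    bin_coverage,
    correlate_tracks,
    normalize_and_ratio,
    select_genes_by_overlap,
    select_quantile_bins,
)


class TestBinCoverage:
    def test_midpoint_rule(self):
        lay = GenomeLayout([("c", 400)])
        frags = [GenomicInterval("c", 0, 100), GenomicInterval("c", 150, 250)]
        track = bin_coverage(frags, lay, 100)
        assert list(track.values["c"]) == [1, 0, 1, 0]

    def test_empty_fragment_list_gives_zero_track(self, layout):
        track = bin_coverage([], layout, 100_000)
        assert track.total() == 0

    def test_unknown_chromosome_named_in_error(self, layout):
        with pytest.raises(ValueError, match="chrM"):
            bin_coverage([GenomicInterval("chrM", 0, 10)], layout, 100_000)

    def test_conserves_count_and_matches_histogram_oracle(self, layout, rng):
        frags = []
        for _ in range(10_000):
            chrom, length = layout.chromosomes[rng.integers(2)]
            s = int(rng.integers(0, length - 200))
            frags.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 200))))
        track = bin_coverage(frags, layout, 100_000)
        assert track.total() == len(frags)
        for chrom, arr in track.values.items():
            mids = [(f.start + f.end) // 2 for f in frags if f.chrom == chrom]
            oracle, _ = np.histogram(
                mids, bins=len(arr), range=(0, len(arr) * 100_000)
            )
            assert np.array_equal(arr, oracle)


class TestNormalizeAndRatio:
    def test_identical_tracks_give_zero_everywhere(self, layout, rng):
        a = make_track(layout, 100_000, lambda c, n: rng.poisson(20, n))
        fc = normalize_and_ratio(a, a, pseudocount=3.0, scale="cpm")
        for arr in fc.track.values.values():
            assert np.allclose(arr, 0)

    def test_simple_ratio_without_scaling(self):
        lay = GenomeLayout([("c", 100)])
        a = make_track(lay, 100, lambda c, n: [4.0])
        b = make_track(lay, 100, lambda c, n: [1.0])
        fc = normalize_and_ratio(a, b, pseudocount=0.0, scale="none")
        assert fc.track.values["c"][0] == pytest.approx(2.0)

    def test_matches_per_bin_formula(self, layout, rng):
        a = make_track(layout, 100_000, lambda c, n: rng.poisson(30, n))
        b = make_track(layout, 100_000, lambda c, n: rng.poisson(50, n))
        fc = normalize_and_ratio(a, b, pseudocount=1.0, scale="cpm")
        fa, fb = a.total() / 1e6, b.total() / 1e6
        for chrom in a.values:
            want = np.log2((a.values[chrom] / fa + 1.0) / (b.values[chrom] / fb + 1.0))
            assert np.allclose(fc.track.values[chrom], want, atol=1e-12)

    def test_antisymmetry_under_swap(self, layout, rng):
        a = make_track(layout, 100_000, lambda c, n: rng.poisson(30, n))
        b = make_track(layout, 100_000, lambda c, n: rng.poisson(50, n))
        ab = normalize_and_ratio(a, b, pseudocount=1.0, scale="cpm")
        ba = normalize_and_ratio(b, a, pseudocount=1.0, scale="cpm")
        for chrom in a.values:
            assert np.array_equal(ab.track.values[chrom], -ba.track.values[chrom])

    def test_missing_propagates(self, layout):
        a = make_track(layout, 100_000, lambda c, n: np.ones(n))
        b = make_track(layout, 100_000, lambda c, n: np.ones(n))
        a.values["chr1"][3] = np.nan
        fc = normalize_and_ratio(a, b, pseudocount=1.0, scale="none")
        assert np.isnan(fc.track.values["chr1"][3])

    def test_mismatched_structure_rejected(self, layout):
        a = make_track(layout, 100_000, lambda c, n: np.ones(n))
        b = make_track(layout, 50_000, lambda c, n: np.ones(n))
        with pytest.raises(ValueError):
            normalize_and_ratio(a, b)


class TestQuantileSelection:
    def test_top_decile_of_ten_values(self):
        lay = GenomeLayout([("c", 1000)])
        t = make_track(lay, 100, lambda c, n: np.arange(1, 11))
        sel = select_quantile_bins(t, 0.1, "top")
        assert list(sel["c"]) == [9]

    def test_ties_broken_by_genome_order(self):
        lay = GenomeLayout([("c", 1000)])
        t = make_track(lay, 100, lambda c, n: np.ones(n))
        sel = select_quantile_bins(t, 0.2, "top")
        assert list(sel["c"]) == [0, 1]

    def test_matches_sort_and_slice_oracle(self, layout, rng):
        t = make_track(layout, 100_000, lambda c, n: rng.normal(size=n))
        for tail in ("top", "bottom"):
            sel = select_quantile_bins(t, 0.25, tail)
            got = {(c, int(i)) for c, idx in sel.items() for i in idx}
            flat = [
                (v, c, i)
                for c in t.values
                for i, v in enumerate(t.values[c])
            ]
            flat.sort(key=lambda x: x[0], reverse=(tail == "top"))
            n_sel = round(0.25 * len(flat))
            want = {(c, i) for _, c, i in flat[:n_sel]}
            assert got == want

    def test_top_and_bottom_disjoint_on_tie_free_data(self, layout, rng):
        t = make_track(layout, 100_000, lambda c, n: rng.normal(size=n))
        top = select_quantile_bins(t, 0.5, "top")
        bottom = select_quantile_bins(t, 0.5, "bottom")
        for chrom in t.values:
            overlap = set(top.get(chrom, np.array([])).tolist()) & set(
                bottom.get(chrom, np.array([])).tolist()
            )
            assert not overlap

    def test_zero_bin_selection_rejected(self):
        lay = GenomeLayout([("c", 300)])
        t = make_track(lay, 100, lambda c, n: np.arange(n))
        with pytest.raises(ValueError):
            select_quantile_bins(t, 0.01, "top")


def _states(lay, segments):
    return LabeledSegmentation(
        intervals=[GenomicInterval(c, s, e) for c, s, e, _ in segments],
        labels=[lab for _, _, _, lab in segments],
    )


class TestAggregateByState:
    def test_uniform_track_all_states_at_genome_median(self):
        lay = GenomeLayout([("c", 1_000_000)])
        t = make_track(lay, 100_000, lambda c, n: np.full(n, 7.0))
        seg = _states(lay, [("c", 0, 500_000, "s1"), ("c", 500_000, 1_000_000, "s2")])
        agg = aggregate_by_state(t, seg).set_index("label")
        assert (agg["median"] == 7.0).all()
        assert (agg["mw_p"] == 1.0).all()

    def test_shifted_state_flagged_others_not(self):
        lay = GenomeLayout([("c", 4_000_000)])
        vals = np.zeros(40)
        vals[:10] += 1.0
        t = make_track(lay, 100_000, lambda c, n: vals)
        seg = _states(lay, [("c", 0, 1_000_000, "hot"), ("c", 1_000_000, 4_000_000, "cold")])
        agg = aggregate_by_state(t, seg).set_index("label")
        assert agg.loc["hot", "mw_p"] < 0.001
        assert agg.loc["hot", "median"] == 1.0

    def test_majority_assignment_and_partition(self, layout, rng):
        # random segmentation tiling chr1; brute-force per-label medians
        bounds = [0, 250_000, 900_000, 2_000_000, 5_500_000, 10_000_000]
        labels = ["a", "b", "a", "c", "b"]
        seg = _states(
            layout,
            [("chr1", s, e, lab) for s, e, lab in zip(bounds, bounds[1:], labels)],
        )
        t = make_track(layout, 100_000, lambda c, n: rng.normal(size=n))
        agg = aggregate_by_state(t, seg).set_index("label")
        # oracle: assign each chr1 bin to the label covering most of it
        by_label = {}
        for b in range(100):
            lo, hi = b * 100_000, (b + 1) * 100_000
            cover = {}
            for s, e, lab in zip(bounds, bounds[1:], labels):
                ov = max(0, min(e, hi) - max(s, lo))
                if ov:
                    cover[lab] = cover.get(lab, 0) + ov
            if cover:
                best = max(cover, key=lambda L: cover[L])
                by_label.setdefault(best, []).append(t.values["chr1"][b])
        for lab, vals in by_label.items():
            assert agg.loc[lab, "median"] == pytest.approx(np.median(vals))
            assert agg.loc[lab, "n"] == len(vals)
        assert agg["n"].sum() == 100  # partition: every chr1 bin assigned once

    def test_empty_label_reported_with_missing_stats(self, layout):
        t = make_track(layout, 100_000, lambda c, n: np.ones(n))
        seg = LabeledSegmentation(
            intervals=[GenomicInterval("chr1", 0, 100_000)],
            labels=["used"],
            label_universe={"used", "unused"},
        )
        agg = aggregate_by_state(t, seg).set_index("label")
        assert agg.loc["unused", "n"] == 0
        assert np.isnan(agg.loc["unused", "mw_p"])


class TestCorrelateTracks:
    def test_monotone_transform_gives_rho_one(self, layout, rng):
        a = make_track(layout, 100_000, lambda c, n: rng.normal(size=n))
        b = a.copy_with({c: np.exp(v) for c, v in a.values.items()})
        rho, _ = correlate_tracks(a, b)
        assert rho == pytest.approx(1.0)

    def test_negation_gives_rho_minus_one(self, layout, rng):
        a = make_track(layout, 100_000, lambda c, n: rng.normal(size=n))
        b = a.copy_with({c: -v for c, v in a.values.items()})
        rho, _ = correlate_tracks(a, b)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, layout, rng):
        from scipy import stats

        a = make_track(layout, 100_000, lambda c, n: rng.normal(size=n))
        b = make_track(layout, 100_000, lambda c, n: rng.normal(size=n))
        a.values["chr1"][:5] = np.nan
        rho, _ = correlate_tracks(a, b)
        x, y = a.flat(), b.flat()
        ok = ~np.isnan(x) & ~np.isnan(y)
        want = stats.pearsonr(stats.rankdata(x[ok]), stats.rankdata(y[ok]))[0]
        assert rho == pytest.approx(want, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        lay = GenomeLayout([("c", 300)])
        a = make_track(lay, 100, lambda c, n: [1.0, np.nan, 3.0])
        b = make_track(lay, 100, lambda c, n: [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate_tracks(a, b)


class TestGeneOverlapFilter:
    def _genes(self, spans):
        return LabeledSegmentation(
            intervals=[GenomicInterval("chr1", s, e) for s, e in spans],
            labels=[f"g{i}" for i in range(len(spans))],
        )

    def test_strict_threshold(self, layout):
        sel = {"chr1": np.array([0])}  # bin [0, 100kb)
        genes = self._genes([(99_850, 100_850), (99_900, 100_900)])
        kept = select_genes_by_overlap(genes, sel, layout, 100_000, min_fraction=0.10)
        # overlaps: 150 bp (15%, kept) and exactly 100 bp (10%, excluded)
        assert kept.labels == ["g0"]

    def test_matches_brute_force_overlap_oracle(self, layout, rng):
        sel = {
            "chr1": np.sort(rng.choice(100, size=20, replace=False)),
            "chr2": np.sort(rng.choice(80, size=10, replace=False)),
        }
        spans = []
        for _ in range(200):
            chrom, length = layout.chromosomes[rng.integers(2)]
            s = int(rng.integers(0, length - 50_000))
            spans.append((chrom, s, s + int(rng.integers(1_000, 50_000))))
        genes = LabeledSegmentation(
            intervals=[GenomicInterval(c, s, e) for c, s, e in spans],
            labels=[f"g{i}" for i in range(len(spans))],
        )
        kept = select_genes_by_overlap(genes, sel, layout, 100_000, min_fraction=0.10)
        want = []
        for (chrom, s, e), lab in zip(spans, genes.labels):
            bins = set(sel.get(chrom, np.array([])).tolist())
            ov = sum(
                max(0, min(e, (b + 1) * 100_000) - max(s, b * 100_000)) for b in bins
            )
            if ov / (e - s) > 0.10:
                want.append(lab)
        assert kept.labels == want

    def test_zero_length_gene_rejected(self, layout):
        genes = LabeledSegmentation(
            intervals=[GenomicInterval("chr1", 10, 11)], labels=["g"]
        )
        object.__setattr__(genes.intervals[0], "end", 10)  # force degenerate
        with pytest.raises(ValueError):
            select_genes_by_overlap(genes, {"chr1": np.array([0])}, layout, 100_000)
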