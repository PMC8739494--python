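"""Binned susceptibility tracks, fold changes, quantile selections and
per-chromatin-state aggregation.

Lesion immunoprecipitation fragments mark point events, so a fragment is
assigned to the bin containing its midpoint; the resulting counts feed
log2 fold-change tracks (knockout vs wild-type, or IP vs input), extreme
quantile selections, chromatin-state summaries and track-track rank
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    BinnedTrack,
    BinSelection,
    GenomeLayout,
    GenomicInterval,
    LabeledSegmentation,
    selection_to_intervals,
)


def bin_coverage(
    fragments: list[GenomicInterval], layout: GenomeLayout, bin_size: int
) -> BinnedTrack:
    """Count fragments per bin by midpoint (floor((start+end)/2)).

    Conserves fragment number: the track total equals ``len(fragments)``.
    """
    track = BinnedTrack.zeros(layout, bin_size)
    lengths = layout.lengths
    unknown = sorted({f.chrom for f in fragments} - set(lengths))
    if unknown:
        raise ValueError(f"fragments on unknown chromosomes: {unknown}")
    per_chrom: dict[str, list[int]] = {}
    for f in fragments:
        per_chrom.setdefault(f.chrom, []).append((f.start + f.end) // 2)
    for chrom, mids in per_chrom.items():
        n = layout.n_bins(chrom, bin_size)
        idx = np.asarray(mids) // bin_size
        track.values[chrom] = np.bincount(idx, minlength=n).astype(float)
    return track


@dataclass
class FoldChangeTrack:
    """log2 ratio track plus the normalisation provenance it was built with."""

    track: BinnedTrack
    pseudocount: float
    scale: str
    norm_factors: tuple[float, float]  # divisor applied to numerator, denominator


def normalize_and_ratio(
    numerator: BinnedTrack,
    denominator: BinnedTrack,
    pseudocount: float = 1.0,
    scale: str = "cpm",
) -> FoldChangeTrack:
    """Per-bin ``log2((a_norm + pc) / (b_norm + pc))``.

    ``scale="cpm"`` first divides each track by its total / 1e6
    (library-size normalisation); ``scale="none"`` uses raw values.  Bins
    missing in either input are missing in the output.  Swapping the two
    tracks negates every value exactly.
    """
    if not numerator.same_structure(denominator):
        raise ValueError("numerator and denominator have different bin structure")
    if scale not in ("cpm", "none"):
        raise ValueError(f"unknown scale {scale!r}")
    fa = numerator.total() / 1e6 if scale == "cpm" else 1.0
    fb = denominator.total() / 1e6 if scale == "cpm" else 1.0
    if scale == "cpm" and (fa == 0 or fb == 0):
        raise ValueError("cpm scaling needs a nonzero track total")
    values = {}
    for chrom in numerator.values:
        a = numerator.values[chrom] / fa
        b = denominator.values[chrom] / fb
        # log difference (not log of quotient) so swapping the inputs
        # negates every value bit-exactly
        with np.errstate(divide="ignore", invalid="ignore"):
            values[chrom] = np.log2(a + pseudocount) - np.log2(b + pseudocount)
    return FoldChangeTrack(
        track=numerator.copy_with(values),
        pseudocount=pseudocount,
        scale=scale,
        norm_factors=(fa, fb),
    )


def select_quantile_bins(
    track: BinnedTrack, fraction: float, tail: str = "top"
) -> BinSelection:
    """The most extreme ``round(fraction * n_nonmissing)`` bins.

    Ties at the threshold are broken deterministically by genome order
    (chromosome order, then bin index).
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if tail not in ("top", "bottom"):
        raise ValueError(f"tail must be 'top' or 'bottom', got {tail!r}")
    chroms, idxs, vals = [], [], []
    for ci, (chrom, arr) in enumerate(track.values.items()):
        ok = ~np.isnan(arr)
        chroms.append(np.full(ok.sum(), ci))
        idxs.append(np.nonzero(ok)[0])
        vals.append(arr[ok])
    chroms = np.concatenate(chroms)
    idxs = np.concatenate(idxs)
    vals = np.concatenate(vals)
    n_sel = int(np.floor(fraction * len(vals) + 0.5))
    if n_sel == 0:
        raise ValueError("fraction selects zero bins")
    key = -vals if tail == "top" else vals
    order = np.lexsort((idxs, chroms, key))[:n_sel]
    names = list(track.values)
    sel: BinSelection = {}
    for ci in np.unique(chroms[order]):
        sel[names[int(ci)]] = np.sort(idxs[order][chroms[order] == ci])
    return sel


def aggregate_by_state(
    track: BinnedTrack, states: LabeledSegmentation
) -> pd.DataFrame:
    """Per-chromatin-state signal summary with Mann-Whitney tests.

    Each nonmissing bin is assigned to the label covering the majority of
    the bin (ties go to the label whose covering interval starts first);
    unlabelled bins stay unassigned.  Per label: n, median, quartiles,
    two-sided Mann-Whitney U p against all nonmissing genome bins, and
    the median scaled by the genome median (NaN when that median is 0).
    Labels with no bins appear with n=0 and missing statistics.
    """
    by_chrom = states.by_chrom()
    label_values: dict[str, list[float]] = {lab: [] for lab in sorted(states.label_universe)}
    for chrom, arr in track.values.items():
        if chrom not in by_chrom:
            continue
        nb = len(arr)
        cover: dict[int, dict[str, int]] = {}
        first_start: dict[int, dict[str, int]] = {}
        for iv, lab in by_chrom[chrom]:
            first = iv.start // track.bin_size
            last = min((iv.end - 1) // track.bin_size, nb - 1)
            for b in range(first, last + 1):
                lo = max(iv.start, b * track.bin_size)
                hi = min(iv.end, (b + 1) * track.bin_size, track.chrom_lengths[chrom])
                if hi <= lo:
                    continue
                cover.setdefault(b, {}).setdefault(lab, 0)
                cover[b][lab] += hi - lo
                fs = first_start.setdefault(b, {})
                if lab not in fs:
                    fs[lab] = iv.start
        for b, lab_cov in cover.items():
            if np.isnan(arr[b]):
                continue
            best = max(lab_cov, key=lambda L: (lab_cov[L], -first_start[b][L]))
            label_values[best].append(float(arr[b]))

    genome = track.flat()
    genome = genome[~np.isnan(genome)]
    genome_median = float(np.median(genome)) if len(genome) else float("nan")
    rows = []
    for lab, vals in label_values.items():
        vals = np.asarray(vals)
        if len(vals) == 0:
            rows.append(
                dict(label=lab, n=0, median=np.nan, q25=np.nan, q75=np.nan,
                     mw_p=np.nan, scaled_median=np.nan)
            )
            continue
        if len(genome) and (np.ptp(genome) > 0 or np.ptp(vals) > 0 or vals[0] != genome[0]):
            mw_p = float(stats.mannwhitneyu(vals, genome, alternative="two-sided").pvalue)
        else:
            mw_p = 1.0  # all values identical: no evidence of difference
        med = float(np.median(vals))
        rows.append(
            dict(
                label=lab,
                n=len(vals),
                median=med,
                q25=float(np.percentile(vals, 25)),
                q75=float(np.percentile(vals, 75)),
                mw_p=mw_p,
                scaled_median=med / genome_median if genome_median else np.nan,
            )
        )
    df = pd.DataFrame(rows)
    df.attrs["genome_median"] = genome_median
    df.attrs["n_assigned"] = int(df["n"].sum())
    return df


def correlate_tracks(a: BinnedTrack, b: BinnedTrack) -> tuple[float, float]:
    """Spearman rank correlation over pairwise-nonmissing bins."""
    if not a.same_structure(b):
        raise ValueError("tracks have different bin structure")
    x, y = a.flat(), b.flat()
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 pairwise-complete bins")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def select_genes_by_overlap(
    genes: LabeledSegmentation,
    selected: BinSelection,
    layout: GenomeLayout,
    bin_size: int,
    min_fraction: float = 0.10,
) -> LabeledSegmentation:
    """Genes whose bp overlap with the selected bins exceeds ``min_fraction``.

    The threshold is strict: a gene at exactly ``min_fraction`` overlap is
    excluded.
    """
    sel_ivs = selection_to_intervals(selected, layout, bin_size)
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sel_ivs:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    kept_iv, kept_lab = [], []
    for iv, lab in zip(genes.intervals, genes.labels):
        if len(iv) == 0:
            raise ValueError(f"zero-length gene {lab}")
        ov = sum(iv.overlap_bp(s) for s in per_chrom.get(iv.chrom, []))
        if ov / len(iv) > min_fraction:
            kept_iv.append(iv)
            kept_lab.append(lab)
    return LabeledSegmentation(
        intervals=kept_iv, labels=kept_lab, label_universe=genes.label_universe
    )
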