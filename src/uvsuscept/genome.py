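"""Genome model, interval arithmetic, binning and dinucleotide content.

All coordinates are 0-based half-open (BED convention). A genome is
described by a :class:`GenomeLayout`: ordered chromosomes with lengths,
one centromere interval per chromosome, and telomeres modelled as the two
end anchors (position 0 and position ``length``) rather than intervals.

Binned signal lives in a :class:`BinnedTrack`: one float array per
chromosome with ``ceil(length / bin_size)`` entries, NaN marking
unmappable/missing bins.  The last bin may be partial and covers
``[i*bin_size, length)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeLayout:
    """Chromosome lengths plus centromere intervals and telomere anchors.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; names unique, lengths > 0.
    centromeres
        Map chromosome -> ``(start, end)`` interval, half-open, within
        ``[0, length)``.  Chromosomes may lack an entry (acrocentric /
        unplaced in real assemblies); operations that need one skip the
        chromosome with a logged warning.
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for chrom, (s, e) in self.centromeres.items():
            length = dict(self.chromosomes).get(chrom)
            if length is None:
                raise ValueError(f"centromere on unknown chromosome {chrom}")
            if not (0 <= s < e <= length):
                raise ValueError(f"centromere {chrom}:{s}-{e} outside [0, {length})")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def telomere_anchors(self, chrom: str) -> tuple[int, int]:
        """p-end and q-end anchor positions (0 and chromosome length)."""
        return 0, self.length(chrom)

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.length(chrom) / bin_size)

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass
class BinnedTrack:
    """Fixed-width per-bin signal, one float array per chromosome.

    ``values[chrom][i]`` covers ``[i*bin_size, min((i+1)*bin_size, length))``;
    NaN marks missing bins.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            self.values[chrom] = arr
            expect = math.ceil(self.chrom_lengths[chrom] / self.bin_size)
            if arr.shape != (expect,):
                raise ValueError(
                    f"{chrom}: expected {expect} bins, got {arr.shape}"
                )

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_size: int) -> "BinnedTrack":
        values = {
            chrom: np.zeros(math.ceil(length / bin_size))
            for chrom, length in layout.chromosomes
        }
        return cls(bin_size=bin_size, values=values, chrom_lengths=layout.lengths)

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def same_structure(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_lengths == other.chrom_lengths
            and list(self.values) == list(other.values)
        )

    def bin_width(self, chrom: str, i: int) -> int:
        """Covered width of bin ``i`` (smaller for a partial last bin)."""
        length = self.chrom_lengths[chrom]
        return min((i + 1) * self.bin_size, length) - i * self.bin_size

    def is_partial(self, chrom: str, i: int) -> bool:
        return self.bin_width(chrom, i) < self.bin_size

    def flat(self) -> np.ndarray:
        """All bin values concatenated in genome order."""
        return np.concatenate([self.values[c] for c in self.values])

    def copy_with(self, values: dict[str, np.ndarray]) -> "BinnedTrack":
        return BinnedTrack(
            bin_size=self.bin_size,
            values={c: np.asarray(v, dtype=float) for c, v in values.items()},
            chrom_lengths=dict(self.chrom_lengths),
        )

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.values.values()))


@dataclass
class LabeledSegmentation:
    """Genomic intervals each carrying a categorical label."""

    intervals: list[GenomicInterval]
    labels: list[str]
    label_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.labels):
            raise ValueError("intervals and labels differ in length")
        if not self.label_universe:
            self.label_universe = set(self.labels)
        bad = set(self.labels) - self.label_universe
        if bad:
            raise ValueError(f"labels outside universe: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, list[tuple[GenomicInterval, str]]]:
        out: dict[str, list[tuple[GenomicInterval, str]]] = {}
        for iv, lab in zip(self.intervals, self.labels):
            out.setdefault(iv.chrom, []).append((iv, lab))
        for chrom in out:
            out[chrom].sort(key=lambda t: (t[0].start, t[0].end))
        return out


# ---------------------------------------------------------------------------
# Landmark-region definitions
# ---------------------------------------------------------------------------

def define_pericentric(layout: GenomeLayout, flank: int = 1_000_000) -> list[GenomicInterval]:
    """Flanking regions around each centromere, clipped to the chromosome.

    For a centromere ``[s, e)`` the regions are ``[max(0, s-flank), s)``
    and ``[e, min(length, e+flank))``; the centromere body itself is
    excluded.  Chromosomes without a centromere entry are skipped with a
    warning.  ``flank=0`` yields no regions.
    """
    out: list[GenomicInterval] = []
    if flank < 0:
        raise ValueError("flank must be >= 0")
    for chrom, length in layout.chromosomes:
        if chrom not in layout.centromeres:
            logger.warning("no centromere recorded for %s; skipped", chrom)
            continue
        s, e = layout.centromeres[chrom]
        left = (max(0, s - flank), s)
        right = (e, min(length, e + flank))
        for a, b in (left, right):
            if b > a:
                out.append(GenomicInterval(chrom, a, b))
    return out


def define_subtelomeric(layout: GenomeLayout, flank: int = 100_000) -> list[GenomicInterval]:
    """The ``flank`` bp adjacent to each chromosome end.

    Returns ``[0, min(flank, len))`` and ``[max(0, len-flank), len)`` per
    chromosome.  On a chromosome shorter than ``2*flank`` the pair
    overlaps; both are kept with a warning.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out: list[GenomicInterval] = []
    for chrom, length in layout.chromosomes:
        if flank == 0:
            continue
        if length < 2 * flank:
            logger.warning(
                "%s (%d bp) shorter than twice the subtelomeric flank; "
                "p and q regions overlap", chrom, length,
            )
        out.append(GenomicInterval(chrom, 0, min(flank, length)))
        out.append(GenomicInterval(chrom, max(0, length - flank), length))
    return out


# ---------------------------------------------------------------------------
# Bin selection
# ---------------------------------------------------------------------------

BinSelection = dict[str, np.ndarray]
"""Per-chromosome sorted arrays of selected bin indices."""


def bins_overlapping(
    layout: GenomeLayout, bin_size: int, regions: list[GenomicInterval]
) -> BinSelection:
    """Bins overlapping any region by at least 1 bp (half-open semantics).

    A region ``[s, e)`` touches bins ``s // bin_size`` through
    ``(e-1) // bin_size`` inclusive; region ends falling exactly on a bin
    boundary do not select the following bin.
    """
    per_chrom: dict[str, list[np.ndarray]] = {}
    for iv in regions:
        n = layout.n_bins(iv.chrom, bin_size)
        first = iv.start // bin_size
        last = (iv.end - 1) // bin_size
        idx = np.arange(first, min(last, n - 1) + 1)
        per_chrom.setdefault(iv.chrom, []).append(idx)
    return {
        chrom: np.unique(np.concatenate(chunks))
        for chrom, chunks in per_chrom.items()
    }


def selection_size(sel: BinSelection) -> int:
    return int(sum(len(v) for v in sel.values()))


def selection_to_intervals(
    sel: BinSelection, layout: GenomeLayout, bin_size: int
) -> list[GenomicInterval]:
    """Materialise selected bins as genomic intervals (partial last bin clipped)."""
    out = []
    for chrom, idx in sel.items():
        length = layout.length(chrom)
        for i in idx:
            out.append(
                GenomicInterval(chrom, int(i) * bin_size, min((int(i) + 1) * bin_size, length))
            )
    return out


def selected_values(track: BinnedTrack, sel: BinSelection, drop_missing: bool = True) -> np.ndarray:
    """Track values at the selected bins, in genome order."""
    parts = [track.values[c][idx] for c, idx in sel.items() if c in track.values]
    vals = np.concatenate(parts) if parts else np.array([])
    if drop_missing:
        vals = vals[~np.isnan(vals)]
    return vals


# ---------------------------------------------------------------------------
# Dinucleotide content
# ---------------------------------------------------------------------------

_PY_DIMERS = ("TT", "TC", "CT", "CC")
_REVCOMP = {"TT": "AA", "TC": "GA", "CT": "AG", "CC": "GG"}


def dipyrimidine_content(sequences: list[str]) -> list[dict[str, float]]:
    """Double-stranded pyrimidine-dinucleotide frequencies per sequence.

    CPDs form between adjacent pyrimidines on either strand, so each
    plus-strand occurrence of a pyrimidine dimer *or of its reverse
    complement* (TT/AA, TC/GA, CT/AG, CC/GG) is counted, and the
    denominator is twice the number of valid dinucleotide windows (one
    contribution per strand).  Windows containing N are excluded from
    numerator and denominator alike.  Sequences with no valid window
    yield NaN frequencies, not zero.
    """
    results = []
    for seq in sequences:
        seq = seq.upper()
        if len(seq) < 2:
            results.append({d: float("nan") for d in _PY_DIMERS})
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        a, b = arr[:-1], arr[1:]
        known = np.isin(a, [b"A", b"C", b"G", b"T"]) & np.isin(b, [b"A", b"C", b"G", b"T"])
        n_windows = int(known.sum())
        if n_windows == 0:
            results.append({d: float("nan") for d in _PY_DIMERS})
            continue
        freqs = {}
        for dimer in _PY_DIMERS:
            count = 0
            for pat in (dimer, _REVCOMP[dimer]):
                hit = (a == pat[0].encode()) & (b == pat[1].encode())
                count += int((hit & known).sum())
            freqs[dimer] = count / (2 * n_windows)
        results.append(freqs)
    return results
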