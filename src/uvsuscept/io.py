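"""Readers and writers for the plain-text formats the pipeline touches.

Layout tables and Cq panels are TSV; regions and segmentations are
BED3/BED4; binned tracks are bedGraph with a fixed bin width; sequences
come from FASTA (random access via pyfaidx) or FASTQ/FASTA read streams
(Biopython, gzip transparent).
"""

from __future__ import annotations

import gzip
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genome import BinnedTrack, GenomeLayout, GenomicInterval, LabeledSegmentation

# -- genome layout ----------------------------------------------------------

LAYOUT_COLUMNS = ["chrom", "length", "cen_start", "cen_end"]


def read_layout(path: str | Path) -> GenomeLayout:
    """Read a layout TSV with header columns chrom, length, cen_start, cen_end.

    Missing centromere coordinates (empty fields) are allowed and leave
    the chromosome without a centromere entry.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(LAYOUT_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"layout file lacks columns: {sorted(missing)}")
    chromosomes = [(str(r.chrom), int(r.length)) for r in df.itertuples()]
    centromeres = {}
    if {"cen_start", "cen_end"} <= set(df.columns):
        for r in df.itertuples():
            if pd.notna(r.cen_start) and pd.notna(r.cen_end):
                centromeres[str(r.chrom)] = (int(r.cen_start), int(r.cen_end))
    return GenomeLayout(chromosomes=chromosomes, centromeres=centromeres)


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    rows = []
    for chrom, length in layout.chromosomes:
        cen = layout.centromeres.get(chrom, (None, None))
        rows.append({"chrom": chrom, "length": length, "cen_start": cen[0], "cen_end": cen[1]})
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.0f"
    )


# -- BED --------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3 (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed4(path: str | Path, label_universe: set[str] | None = None) -> LabeledSegmentation:
    """BED4: fourth column is the categorical label."""
    intervals, labels = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"BED4 line with {len(f)} fields: {line!r}")
            intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
            labels.append(f[3])
    return LabeledSegmentation(
        intervals=intervals,
        labels=labels,
        label_universe=label_universe or set(labels),
    )


def write_bed4(seg: LabeledSegmentation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, lab in zip(seg.intervals, seg.labels):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\n")


# -- bedGraph / BinnedTrack -------------------------------------------------

def read_bedgraph(path: str | Path, layout: GenomeLayout, bin_size: int) -> BinnedTrack:
    """Read a fixed-width bedGraph into a BinnedTrack.

    Every interval must start on a bin boundary and span exactly one bin
    (the last bin may be clipped at the chromosome end); ragged intervals
    raise.  Bins absent from the file are missing (NaN).
    """
    track = BinnedTrack(
        bin_size=bin_size,
        values={c: np.full(layout.n_bins(c, bin_size), np.nan) for c in layout.names},
        chrom_lengths=layout.lengths,
    )
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")
            s, e = int(s), int(e)
            if chrom not in track.values:
                raise ValueError(f"bedGraph chromosome {chrom} not in layout")
            i, r = divmod(s, bin_size)
            expected_end = min((i + 1) * bin_size, layout.length(chrom))
            if r != 0 or e != expected_end:
                raise ValueError(
                    f"ragged bedGraph interval {chrom}:{s}-{e} for bin size {bin_size}"
                )
            track.values[chrom][i] = float(v)
    return track


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write nonmissing bins; values at full float precision."""
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            length = track.chrom_lengths[chrom]
            for i, v in enumerate(arr):
                if math.isnan(v):
                    continue
                fh.write(
                    f"{chrom}\t{i * track.bin_size}"
                    f"\t{min((i + 1) * track.bin_size, length)}\t{float(v)!r}\n"
                )


# -- sequences --------------------------------------------------------------

def region_sequences(fasta_path: str | Path, regions: list[GenomicInterval]) -> list[str]:
    """Fetch the plus-strand sequence of each region from an indexed FASTA."""
    from pyfaidx import Fasta

    with Fasta(str(fasta_path)) as fa:
        return [str(fa[iv.chrom][iv.start:iv.end]) for iv in regions]


def read_sequences(path: str | Path) -> list[str]:
    """Read sequences from FASTQ or FASTA (optionally gzipped), as strings."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]


# -- tables -----------------------------------------------------------------

def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Cq TSV with columns target, condition, replicate, cq."""
    df = pd.read_csv(path, sep="\t")
    need = {"target", "condition", "replicate", "cq"}
    if not need <= set(df.columns):
        raise ValueError(f"Cq table needs columns {sorted(need)}")
    if (df["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    return df


def read_read_family_map(path: str | Path) -> dict[str, frozenset[str]]:
    """TSV mapping read_id -> comma-separated candidate repeat families.

    An empty second field means the read hit no repeat family.
    """
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError("read-family map must start with a read_id header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            fams = parts[1] if len(parts) > 1 else ""
            out[parts[0]] = frozenset(f for f in fams.split(",") if f)
    return out


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """MAF-like TSV: donor_id, gene, chrom, pos, ref, alt, feature."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"donor_id", "gene", "chrom", "pos", "ref", "alt", "feature"}
    if not need <= set(df.columns):
        raise ValueError(f"mutation table needs columns {sorted(need)}")
    return df
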