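"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: a genome layout
with centromeres, UV-lesion fragment sets with region-class rate
multipliers, histone ChIP/input fragments with per-state enrichment,
alternating A/B compartments with a configurable closed/open signal
ratio, melanoma-like mutation cohorts with specified marginal rates and
pairwise odds ratios, telomeric read sets, and replicated qPCR Cq
panels.  Each generator is a pure function of (config, seed) and emits a
machine-readable truth sidecar so downstream estimates can be checked
against what was simulated.

Default settings describe the emulated study: two 10-Mb chromosomes at
100-kb resolution, Poisson lesion counts with base rate 50 per bin, a
1.5x pericentric and subtelomeric susceptibility gain in the knockout,
a 1.5x closed/open compartment signal ratio, and a 1,000-donor cohort
with a log2 odds ratio of 2 between the two focal genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .genome import (
    BinnedTrack,
    GenomeLayout,
    GenomicInterval,
    LabeledSegmentation,
    bins_overlapping,
    define_pericentric,
    define_subtelomeric,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GenomeModel:
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    # midpoint fraction and width chosen so centromere edges do not land on
    # 100-kb bin boundaries: real assembly gap coordinates never align to
    # analysis bins, and aligned edges distort bin-overlap statistics
    centromere_fraction: float = 0.487
    centromere_width: int = 150_000


@dataclass
class LesionModel:
    bin_size: int = 100_000
    base_rate: float = 50.0            # Poisson mean fragments per full bin
    fragment_length: int = 150
    pericentric_flank: int = 1_000_000
    subtelomeric_flank: int = 100_000
    # per-condition multiplicative effects by region class
    multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "WT": {},
            "KO": {"pericentric": 1.5, "subtelomeric": 1.5},
        }
    )
    dipyrimidine_weighting: bool = False


@dataclass
class ChipModel:
    bin_size: int = 100_000
    base_rate: float = 50.0
    fragment_length: int = 150
    state_segment_length: int = 200_000
    states: tuple[str, ...] = tuple(f"state_{i:02d}" for i in range(1, 16))
    # per-mark, per-state enrichment of IP over input
    enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "H3K9me3": {"state_14": 3.0, "state_15": 2.0},
            "H3K27me3": {"state_13": 3.0, "state_14": 1.5},
        }
    )


@dataclass
class CompartmentModel:
    bin_size: int = 10_000
    compartment_length: int = 500_000  # one compartment = 50 track bins
    base_rate: float = 50.0            # Poisson mean per bin in open (A)
    b_over_a: float = 1.5              # closed/open signal ratio


@dataclass
class PairSpec:
    gene_a: str = "TERT"
    gene_b: str = "TPTE"
    p_a: float = 0.2
    p_b: float = 0.2
    log2_odds_ratio: float = 2.0


@dataclass
class CohortModel:
    n_donors: int = 1000
    pairs: list[PairSpec] = field(default_factory=lambda: [PairSpec()])
    background_genes: dict[str, float] = field(
        default_factory=lambda: {
            "RB1": 0.10, "CCND1": 0.05, "CCNE1": 0.05, "CDKN1A": 0.05,
            "CDKN1B": 0.05, "CDKN2A": 0.10, "CDKN2B": 0.05,
        }
    )
    solar_fraction: float = 0.8
    gene_length: int = 20_000
    feature_weights: dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.10, "upstream": 0.05, "downstream": 0.05,
            "exon": 0.30, "intron": 0.40, "UTR5": 0.05, "UTR3": 0.05,
        }
    )


@dataclass
class RepeatModel:
    n_reads: int = 5000
    families: dict[str, float] = field(
        default_factory=lambda: {
            "LINE_L1": 0.30, "Alu": 0.30, "ERV": 0.20, "Satellite": 0.20,
        }
    )
    multi_fraction: float = 0.30       # reads hitting a second family
    unassigned_fraction: float = 0.05
    # per-condition IP enrichment over input, by family
    enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"WT": {}, "KO": {"Satellite": 1.5}}
    )
    n_replicates: int = 3


@dataclass
class TelomereModel:
    n_reads: int = 10_000
    read_length: int = 100
    telomeric_fraction: float = 0.001
    background_gc: float = 0.5


@dataclass
class QpcrModel:
    n_replicates: int = 3
    replicate_sd: float = 0.1
    # true mean Cq per (target, condition)
    true_cq: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("telo", "WT"): 12.0, ("36B4", "WT"): 15.0,
            ("telo", "KO"): 11.5, ("36B4", "KO"): 15.0,
            ("TERT", "-UV"): 20.0, ("GAPDH", "-UV"): 18.0,
            ("TERT", "+UV"): 21.0, ("GAPDH", "+UV"): 18.0,
        }
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeModel = field(default_factory=GenomeModel)
    lesion: LesionModel = field(default_factory=LesionModel)
    chip: ChipModel = field(default_factory=ChipModel)
    compartment: CompartmentModel = field(default_factory=CompartmentModel)
    cohort: CohortModel = field(default_factory=CohortModel)
    repeat: RepeatModel = field(default_factory=RepeatModel)
    telomere: TelomereModel = field(default_factory=TelomereModel)
    qpcr: QpcrModel = field(default_factory=QpcrModel)


def stage_rng(config_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed.

    Uses a SeedSequence keyed on the stage name so stages are
    statistically independent and adding a stage never perturbs another.
    """
    key = [ord(c) for c in stage]
    return np.random.default_rng(np.random.SeedSequence([config_seed, *key]))


# ---------------------------------------------------------------------------
# Genome and region-rate machinery
# ---------------------------------------------------------------------------


def generate_layout(config: SimulationConfig) -> GenomeLayout:
    """Layout with one centromere per chromosome at the configured fraction."""
    g = config.genome
    chromosomes = [(f"chr{i + 1}", g.chrom_length) for i in range(g.n_chromosomes)]
    centromeres = {}
    for name, length in chromosomes:
        mid = int(length * g.centromere_fraction)
        half = g.centromere_width // 2
        s = max(0, mid - half)
        centromeres[name] = (s, min(length, s + g.centromere_width))
    return GenomeLayout(chromosomes=chromosomes, centromeres=centromeres)


def region_class_intervals(
    config: SimulationConfig, layout: GenomeLayout
) -> dict[str, list[GenomicInterval]]:
    return {
        "pericentric": define_pericentric(layout, config.lesion.pericentric_flank),
        "subtelomeric": define_subtelomeric(layout, config.lesion.subtelomeric_flank),
    }


def _rate_track(
    config: SimulationConfig, layout: GenomeLayout, condition: str
) -> BinnedTrack:
    """Per-bin Poisson mean for one condition (partial bins scaled by width)."""
    les = config.lesion
    track = BinnedTrack.zeros(layout, les.bin_size)
    classes = region_class_intervals(config, layout)
    mults = les.multipliers.get(condition, {})
    for chrom, arr in track.values.items():
        widths = np.array([track.bin_width(chrom, i) for i in range(len(arr))])
        arr[:] = les.base_rate * widths / les.bin_size
    for cls, m in mults.items():
        if cls not in classes:
            raise KeyError(f"unknown region class {cls!r}")
        sel = bins_overlapping(layout, les.bin_size, classes[cls])
        for chrom, idx in sel.items():
            track.values[chrom][idx] *= m
    return track


def _fragments_from_rates(
    rates: BinnedTrack,
    layout: GenomeLayout,
    fragment_length: int,
    rng: np.random.Generator,
    placement_weights: dict[str, np.ndarray] | None = None,
) -> list[GenomicInterval]:
    frags: list[GenomicInterval] = []
    for chrom, arr in rates.values.items():
        length = layout.length(chrom)
        counts = rng.poisson(arr)
        for b, k in enumerate(counts):
            if k == 0:
                continue
            lo = b * rates.bin_size
            hi = min((b + 1) * rates.bin_size, length)
            if placement_weights is not None:
                w = placement_weights[chrom][lo:hi]
                starts = rng.choice(hi - lo, size=k, p=w / w.sum()) + lo
            else:
                starts = rng.integers(lo, hi, size=k)
            for s in np.sort(starts):
                e = min(int(s) + fragment_length, length)
                s = int(s) if e > int(s) else e - 1
                frags.append(GenomicInterval(chrom, int(s), int(e)))
    return frags


def generate_sequences(
    config: SimulationConfig, layout: GenomeLayout
) -> dict[str, str]:
    """Uniform-random ACGT sequence per chromosome (deterministic)."""
    rng = stage_rng(config.seed, "sequence")
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    out = {}
    for chrom, length in layout.chromosomes:
        idx = rng.integers(0, 4, size=length)
        out[chrom] = alphabet[idx].tobytes().decode("ascii")
    return out


def generate_lesion_fragments(
    config: SimulationConfig,
    layout: GenomeLayout,
    condition: str,
    sequences: dict[str, str] | None = None,
) -> tuple[list[GenomicInterval], BinnedTrack]:
    """Lesion IP fragments for one condition, plus the true per-bin rates.

    Per bin the fragment count is Poisson with mean
    ``base_rate x (product of the condition's region-class multipliers
    covering the bin)``; fragments fall uniformly within the bin (or
    TT-weighted when dipyrimidine weighting is on and sequences are
    supplied).  Deterministic given the config seed and condition.
    """
    rng = stage_rng(config.seed, f"lesion:{condition}")
    rates = _rate_track(config, layout, condition)
    weights = None
    if config.lesion.dipyrimidine_weighting:
        if sequences is None:
            sequences = generate_sequences(config, layout)
        weights = {}
        for chrom, seq in sequences.items():
            arr = np.frombuffer(seq.encode(), dtype="S1")
            tt = np.zeros(len(seq))
            hit = (arr[:-1] == b"T") & (arr[1:] == b"T")
            tt[:-1][hit] = 1.0
            weights[chrom] = 1.0 + 9.0 * tt   # 10x weight at TpT sites
    frags = _fragments_from_rates(
        rates, layout, config.lesion.fragment_length, rng, weights
    )
    return frags, rates


# ---------------------------------------------------------------------------
# Chromatin states and ChIP
# ---------------------------------------------------------------------------


def generate_states(config: SimulationConfig, layout: GenomeLayout) -> LabeledSegmentation:
    """Tile the genome with fixed-width segments of random chromatin state."""
    rng = stage_rng(config.seed, "states")
    chip = config.chip
    intervals, labels = [], []
    for chrom, length in layout.chromosomes:
        for s in range(0, length, chip.state_segment_length):
            e = min(s + chip.state_segment_length, length)
            intervals.append(GenomicInterval(chrom, s, e))
            labels.append(chip.states[rng.integers(0, len(chip.states))])
    return LabeledSegmentation(
        intervals=intervals, labels=labels, label_universe=set(chip.states)
    )


def generate_chip_fragments(
    config: SimulationConfig,
    layout: GenomeLayout,
    states: LabeledSegmentation,
    mark: str,
    role: str = "ip",
) -> tuple[list[GenomicInterval], BinnedTrack]:
    """ChIP (or input) fragments with per-state IP enrichment, plus true rates."""
    chip = config.chip
    rng = stage_rng(config.seed, f"chip:{mark}:{role}")
    rates = BinnedTrack.zeros(layout, chip.bin_size)
    for chrom, arr in rates.values.items():
        widths = np.array([rates.bin_width(chrom, i) for i in range(len(arr))])
        arr[:] = chip.base_rate * widths / chip.bin_size
    if role == "ip":
        enr = chip.enrichment.get(mark, {})
        for state, m in enr.items():
            ivs = [
                iv for iv, lab in zip(states.intervals, states.labels) if lab == state
            ]
            sel = bins_overlapping(layout, chip.bin_size, ivs) if ivs else {}
            for chrom, idx in sel.items():
                rates.values[chrom][idx] *= m
    frags = _fragments_from_rates(rates, layout, chip.fragment_length, rng)
    return frags, rates


# ---------------------------------------------------------------------------
# Compartments
# ---------------------------------------------------------------------------


def generate_compartments(
    config: SimulationConfig, layout: GenomeLayout
) -> LabeledSegmentation:
    """Alternating A/B compartments of fixed length tiling each chromosome."""
    comp = config.compartment
    intervals, labels = [], []
    for chrom, length in layout.chromosomes:
        lab = "A"
        for s in range(0, length, comp.compartment_length):
            e = min(s + comp.compartment_length, length)
            intervals.append(GenomicInterval(chrom, s, e))
            labels.append(lab)
            lab = "B" if lab == "A" else "A"
    return LabeledSegmentation(intervals=intervals, labels=labels, label_universe={"A", "B"})


def generate_compartment_track(
    config: SimulationConfig,
    layout: GenomeLayout,
    compartments: LabeledSegmentation,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Poisson signal track realising the configured B/A rate ratio.

    Returns ``(observed, truth)`` where truth holds the per-bin Poisson
    means (``base_rate`` in A, ``base_rate * b_over_a`` in B, assigned by
    bin midpoint).
    """
    comp = config.compartment
    rng = stage_rng(config.seed, "compartment-track")
    truth = BinnedTrack.zeros(layout, comp.bin_size)
    by_chrom = compartments.by_chrom()
    for chrom, arr in truth.values.items():
        widths = np.array([truth.bin_width(chrom, i) for i in range(len(arr))])
        mids = np.arange(len(arr)) * comp.bin_size + widths / 2
        arr[:] = comp.base_rate * widths / comp.bin_size
        for iv, lab in by_chrom.get(chrom, []):
            if lab == "B":
                inside = (mids >= iv.start) & (mids < iv.end)
                arr[inside] *= comp.b_over_a
    observed = truth.copy_with(
        {c: rng.poisson(v).astype(float) for c, v in truth.values.items()}
    )
    return observed, truth


# ---------------------------------------------------------------------------
# Mutation cohort
# ---------------------------------------------------------------------------


def bivariate_bernoulli_cells(p_a: float, p_b: float, odds_ratio: float) -> np.ndarray:
    """Cell probabilities (p11, p10, p01, p00) from marginals and odds ratio.

    Solves the Plackett equation: with S = 1 + (p_a + p_b)(OR - 1),
    ``p11 = (S - sqrt(S^2 - 4 OR (OR-1) p_a p_b)) / (2 (OR-1))`` for
    OR != 1, and ``p11 = p_a p_b`` at independence.  Raises when the
    requested (marginals, OR) combination is infeasible.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("marginals must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio == 1.0:
        p11 = p_a * p_b
    else:
        s = 1.0 + (p_a + p_b) * (odds_ratio - 1.0)
        disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_a * p_b
        if disc < 0:
            raise ValueError("infeasible (odds ratio, marginals) combination")
        p11 = (s - math.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    p10, p01 = p_a - p11, p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    cells = np.array([p11, p10, p01, p00])
    if (cells < -1e-12).any():
        raise ValueError("infeasible (odds ratio, marginals) combination")
    return np.clip(cells, 0.0, 1.0)


def _gene_territories(
    config: SimulationConfig, layout: GenomeLayout, genes: list[str]
) -> dict[str, GenomicInterval]:
    """Deterministic non-overlapping territories tiled along the genome."""
    L = config.cohort.gene_length
    spacing = 2 * L
    out = {}
    chrom_iter = iter(layout.chromosomes)
    chrom, length = next(chrom_iter)
    pos = L
    for g in genes:
        if pos + L > length:
            chrom, length = next(chrom_iter)
            pos = L
        out[g] = GenomicInterval(chrom, pos, pos + L)
        pos += spacing
    return out


def generate_cohort(
    config: SimulationConfig, layout: GenomeLayout | None = None
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """MAF-like mutation records with known marginals and pairwise odds ratios.

    Each targeted gene pair's donor indicators are drawn from the exact
    bivariate Bernoulli with the specified marginals and odds ratio;
    background genes are independent Bernoulli.  Every mutated
    donor-gene yields one record whose substitution is C>T/G>A with the
    configured solar fraction, placed uniformly in the gene's territory
    with a genic feature drawn from the configured weights.
    """
    co = config.cohort
    if co.n_donors < 2:
        raise ValueError("need at least 2 donors")
    layout = layout or generate_layout(config)
    rng = stage_rng(config.seed, "cohort")
    donors = [f"donor_{i:05d}" for i in range(co.n_donors)]

    indicators: dict[str, np.ndarray] = {}
    truth_pairs = []
    for spec in co.pairs:
        cells = bivariate_bernoulli_cells(spec.p_a, spec.p_b, 2.0 ** spec.log2_odds_ratio)
        draw = rng.choice(4, size=co.n_donors, p=cells)
        indicators[spec.gene_a] = ((draw == 0) | (draw == 1)).astype(int)
        indicators[spec.gene_b] = ((draw == 0) | (draw == 2)).astype(int)
        truth_pairs.append(
            dict(gene_a=spec.gene_a, gene_b=spec.gene_b, p_a=spec.p_a, p_b=spec.p_b,
                 log2_odds_ratio=spec.log2_odds_ratio, cells=cells.tolist())
        )
    for gene, p in co.background_genes.items():
        if gene in indicators:
            raise ValueError(f"gene {gene} both targeted and background")
        indicators[gene] = (rng.random(co.n_donors) < p).astype(int)

    genes = list(indicators)
    territories = _gene_territories(config, layout, genes)
    feats = list(co.feature_weights)
    fw = np.array([co.feature_weights[f] for f in feats])
    fw = fw / fw.sum()

    rows = []
    for gene in genes:
        terr = territories[gene]
        hit_idx = np.nonzero(indicators[gene])[0]
        positions = rng.integers(terr.start, terr.end, size=len(hit_idx))
        solar = rng.random(len(hit_idx)) < co.solar_fraction
        strand_c = rng.random(len(hit_idx)) < 0.5
        features = rng.choice(len(feats), size=len(hit_idx), p=fw)
        for j, di in enumerate(hit_idx):
            if solar[j]:
                ref, alt = ("C", "T") if strand_c[j] else ("G", "A")
            else:
                ref, alt = ("T", "C") if strand_c[j] else ("A", "G")
            rows.append(dict(
                donor_id=donors[int(di)], gene=gene, chrom=terr.chrom,
                pos=int(positions[j]), ref=ref, alt=alt, feature=feats[int(features[j])],
            ))
    records = pd.DataFrame(
        rows, columns=["donor_id", "gene", "chrom", "pos", "ref", "alt", "feature"]
    ).sort_values(["donor_id", "gene", "pos"], kind="stable").reset_index(drop=True)

    truth = dict(
        n_donors=co.n_donors,
        donors=donors,
        marginals={g: float(indicators[g].mean()) for g in genes},
        pairs=truth_pairs,
        solar_fraction=co.solar_fraction,
        territories={g: [t.chrom, t.start, t.end] for g, t in territories.items()},
        cg_content={g: int(0.5 * co.gene_length) for g in genes},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Repeat-family read maps
# ---------------------------------------------------------------------------


def generate_read_family_map(
    config: SimulationConfig, condition: str, role: str, replicate: int = 1
) -> tuple[dict[str, frozenset[str]], dict[str, Any]]:
    """Read -> candidate-family map emulating multi-mapping repeat reads.

    A read's true family is drawn from the configured abundances
    (IP reads additionally weighted by the condition's per-family
    enrichment); with the configured probability the read also hits a
    second, random family (multi-mapper), and a small fraction maps to
    no family at all.  Deterministic per (seed, condition, role,
    replicate).
    """
    rep = config.repeat
    if role not in ("ip", "input"):
        raise ValueError("role must be 'ip' or 'input'")
    rng = stage_rng(config.seed, f"repeat:{condition}:{role}:{replicate}")
    fams = list(rep.families)
    weights = np.array([rep.families[f] for f in fams], dtype=float)
    if role == "ip":
        enr = rep.enrichment.get(condition, {})
        weights = weights * np.array([enr.get(f, 1.0) for f in fams])
    p = weights / weights.sum()
    out: dict[str, frozenset[str]] = {}
    true_counts = dict.fromkeys(fams, 0)
    for i in range(rep.n_reads):
        rid = f"{condition}_{role}_r{replicate}_{i:06d}"
        if rng.random() < rep.unassigned_fraction:
            out[rid] = frozenset()
            continue
        fi = int(rng.choice(len(fams), p=p))
        true_counts[fams[fi]] += 1
        members = {fams[fi]}
        if rng.random() < rep.multi_fraction and len(fams) > 1:
            other = int(rng.integers(0, len(fams) - 1))
            members.add(fams[other if other < fi else other + 1])
        out[rid] = frozenset(members)
    truth = dict(condition=condition, role=role, replicate=replicate,
                 probabilities=dict(zip(fams, map(float, p))),
                 true_counts=true_counts)
    return out, truth


# ---------------------------------------------------------------------------
# Telomere reads and qPCR panels
# ---------------------------------------------------------------------------

_MOTIF = "TTAGGG"
_MOTIF_RC = "CCCTAA"


def generate_telomere_reads(
    config: SimulationConfig,
) -> tuple[list[str], dict[str, Any]]:
    """Read set with the configured telomeric fraction, plus truth.

    Telomeric reads are pure tandem ``TTAGGG`` repeats at a random phase
    (half reverse-complemented); background reads draw bases i.i.d. with
    the configured GC probability.
    """
    tel = config.telomere
    rng = stage_rng(config.seed, "telomere")
    n_tel = int(round(tel.n_reads * tel.telomeric_fraction))
    reads = []
    tandem = _MOTIF * (tel.read_length // 6 + 2)
    tandem_rc = _MOTIF_RC * (tel.read_length // 6 + 2)
    for i in range(n_tel):
        phase = int(rng.integers(0, 6))
        src = tandem if rng.random() < 0.5 else tandem_rc
        reads.append(src[phase:phase + tel.read_length])
    p_gc = tel.background_gc
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    bases = np.array(list("ATGC"))
    for i in range(tel.n_reads - n_tel):
        reads.append("".join(bases[rng.choice(4, size=tel.read_length, p=probs)]))
    order = rng.permutation(len(reads))
    truth = dict(
        n_reads=tel.n_reads, n_telomeric=n_tel,
        telomeric_fraction=tel.telomeric_fraction,
    )
    return [reads[i] for i in order], truth


def generate_cq_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Replicated Cq panel: truth + Gaussian(0, replicate_sd) noise per well."""
    q = config.qpcr
    rng = stage_rng(config.seed, "qpcr")
    rows = []
    for (target, condition), mu in q.true_cq.items():
        noise = rng.normal(0.0, q.replicate_sd, size=q.n_replicates)
        for r, eps in enumerate(noise, start=1):
            rows.append(dict(target=target, condition=condition,
                             replicate=r, cq=float(mu + eps)))
    panel = pd.DataFrame(rows)
    truth = dict(
        true_cq={f"{t}|{c}": mu for (t, c), mu in q.true_cq.items()},
        replicate_sd=q.replicate_sd,
        n_replicates=q.n_replicates,
    )
    return panel, truth
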