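"""Simulation studies that validate the pipeline end to end.

Each routine here regenerates synthetic data with known ground truth,
runs the corresponding analysis exactly as a user would, and summarises
how well the method behaves: type-I error calibration of the
random-region test, recovery of an injected pericentric susceptibility
gain, exactness of the Fisher and Benjamini-Hochberg machinery against
brute-force oracles, bootstrap CI coverage of the compartment
metaprofile, recovery of a planted mutation co-occurrence, the exact
counters, the closed-form qPCR identities, and byte-level determinism
of the full pipeline.  The routines are shared by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import re
import tempfile

import numpy as np
import pandas as pd

from . import lesion, metaprofile, mutations, repeats, resampling, telomere
from .pipeline import run_pipeline
from .simulate import (
    CohortModel,
    CompartmentModel,
    GenomeModel,
    LesionModel,
    PairSpec,
    QpcrModel,
    SimulationConfig,
    TelomereModel,
    generate_cohort,
    generate_compartment_track,
    generate_compartments,
    generate_cq_table,
    generate_layout,
    generate_lesion_fragments,
    generate_read_family_map,
    generate_telomere_reads,
    region_class_intervals,
)
from .stats import bh_adjust


def _null_lesion_config(seed: int) -> SimulationConfig:
    """Two 10-Mb chromosomes, 100-kb bins, Poisson rate 50, no multipliers."""
    return SimulationConfig(
        seed=seed,
        genome=GenomeModel(n_chromosomes=2, chrom_length=10_000_000),
        lesion=LesionModel(bin_size=100_000, base_rate=50.0,
                           multipliers={"WT": {}, "KO": {}}),
    )


# ---------------------------------------------------------------------------
# Random-region test calibration and power
# ---------------------------------------------------------------------------


def typeI_calibration(
    n_datasets: int = 500, n_groups: int = 200, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical-p rejection rate of the pericentric test under the null.

    Each dataset is a pair of homogeneous-Poisson lesion genomes (no
    region effects in either condition); the pericentric enrichment test
    runs on the log2(KO/WT) fold-change track — the statistic the
    landmark comparisons are made on — and should reject at close to the
    nominal rate.
    """
    rng_seeds = np.random.SeedSequence([seed, 101]).generate_state(n_datasets) % (2**31)
    rejections = 0
    for ds in range(n_datasets):
        cfg = _null_lesion_config(int(rng_seeds[ds]))
        layout = generate_layout(cfg)
        tracks = {}
        for cond in ("WT", "KO"):
            frags, _ = generate_lesion_fragments(cfg, layout, cond)
            tracks[cond] = lesion.bin_coverage(frags, layout, cfg.lesion.bin_size)
        fc = lesion.normalize_and_ratio(tracks["KO"], tracks["WT"],
                                        pseudocount=0.0, scale="none")
        peri = region_class_intervals(cfg, layout)["pericentric"]
        null = resampling.sample_random_groups(
            layout, peri, n_groups=n_groups, seed=int(rng_seeds[ds]),
        )
        res = resampling.region_enrichment_test(fc.track, peri, null, layout)
        if res.empirical_p <= alpha:
            rejections += 1
    return dict(rejection_rate=rejections / n_datasets, n=n_datasets)


def pericentric_recovery(n_reps: int = 50, n_groups: int = 200, seed: int = 0) -> dict:
    """Detection and effect recovery for a 1.5x pericentric gain in the KO.

    Per replicate: simulate WT and KO lesion genomes (KO pericentric
    rate x1.5), build the raw-count log2(KO/WT) track, and run the
    pericentric enrichment test.  Reports the fraction of replicates
    with empirical p <= 0.01 and the mean over replicates of the median
    pericentric log2 fold change (truth: log2 1.5 ~ 0.585).
    """
    rng_seeds = np.random.SeedSequence([seed, 102]).generate_state(n_reps) % (2**31)
    detected = 0
    medians = []
    for r in range(n_reps):
        cfg = _null_lesion_config(int(rng_seeds[r]))
        cfg.lesion.multipliers = {"WT": {}, "KO": {"pericentric": 1.5}}
        layout = generate_layout(cfg)
        tracks = {}
        for cond in ("WT", "KO"):
            frags, _ = generate_lesion_fragments(cfg, layout, cond)
            tracks[cond] = lesion.bin_coverage(frags, layout, cfg.lesion.bin_size)
        fc = lesion.normalize_and_ratio(tracks["KO"], tracks["WT"],
                                        pseudocount=0.0, scale="none")
        peri = region_class_intervals(cfg, layout)["pericentric"]
        null = resampling.sample_random_groups(
            layout, peri, n_groups=n_groups, seed=int(rng_seeds[r]),
        )
        res = resampling.region_enrichment_test(fc.track, peri, null, layout)
        if res.empirical_p <= 0.01:
            detected += 1
        medians.append(res.observed)
    return dict(
        detection_rate=detected / n_reps,
        median_log2fc=float(np.mean(medians)),
        true_log2fc=float(np.log2(1.5)),
        n=n_reps,
    )


# ---------------------------------------------------------------------------
# Exact-statistics oracles
# ---------------------------------------------------------------------------


def _fisher_enumeration_p(n11: int, r1: int, c1: int, n: int) -> float:
    """Brute-force two-sided Fisher p: sum hypergeometric probabilities of
    all tables with the observed margins whose probability does not
    exceed the observed table's (with the conventional tiny relative
    tolerance for floating-point comparability)."""
    from scipy.stats import hypergeom

    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == n11][0]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def fisher_exact_oracle(max_margin: int = 30) -> dict:
    """Max |implementation - enumeration| over all tables with margins <= max_margin."""
    worst = 0.0
    n_tables = 0
    for r1 in range(0, max_margin + 1):
        for c1 in range(0, max_margin + 1):
            n_lo = max(r1, c1, 1)
            n_hi = min(r1 + max_margin, c1 + max_margin)
            for n in range(n_lo, n_hi + 1):
                for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                    b, c = r1 - a, c1 - a
                    d = n - a - b - c
                    p_impl = mutations.fisher_two_sided_p(a, b, c, d)
                    p_oracle = _fisher_enumeration_p(a, r1, c1, n)
                    worst = max(worst, abs(p_impl - p_oracle))
                    n_tables += 1
    return dict(max_abs_error=worst, n=n_tables)


def bh_oracle(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Max |BH q - textbook step-up q| over random p-vectors."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 109]))
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 51))
        p = rng.random(m)
        q = bh_adjust(p)
        # step-up definition: q_(i) = min_{k >= i} m p_(k) / k at sorted ranks
        order = np.argsort(p, kind="stable")
        q_oracle = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, m * p[order[rank - 1]] / rank)
            q_oracle[order[rank - 1]] = min(running, 1.0)
        worst = max(worst, float(np.max(np.abs(q - q_oracle))))
    return dict(max_abs_error=worst, n=n_vectors)


# ---------------------------------------------------------------------------
# Co-occurrence recovery
# ---------------------------------------------------------------------------


def cooccurrence_recovery(
    n_reps: int = 100, n_donors: int = 1000, log2_or: float = 2.0, seed: int = 0
) -> dict:
    """Recovery of a planted pairwise odds ratio from generated cohorts.

    Per replicate: a cohort with marginals 0.2/0.2 and the target log2
    odds ratio is generated, the donor x gene matrix rebuilt from the
    records, and the pair scored.  Reports the fraction of replicates
    with BH q < 0.05, the mean estimated log2 OR across replicates, and
    (for reference) the per-replicate joint rate of q < 0.05 with the
    estimate inside +-0.5 of truth.
    """
    rng_seeds = np.random.SeedSequence([seed, 104]).generate_state(n_reps) % (2**31)
    successes = 0
    significant = 0
    estimates = []
    for r in range(n_reps):
        cfg = SimulationConfig(
            seed=int(rng_seeds[r]),
            cohort=CohortModel(
                n_donors=n_donors,
                pairs=[PairSpec("TERT", "TPTE", 0.2, 0.2, log2_or)],
                background_genes={},
            ),
        )
        records, truth = generate_cohort(cfg)
        cohort = mutations.CohortMatrix.from_records(records, donors=truth["donors"])
        res = mutations.cooccurrence(cohort, [("TERT", "TPTE")])
        est = float(res["log2or"].iloc[0])
        estimates.append(est)
        sig = float(res["q"].iloc[0]) < 0.05
        significant += sig
        if sig and abs(est - log2_or) <= 0.5:
            successes += 1
    return dict(
        significant_rate=significant / n_reps,
        mean_log2or=float(np.mean(estimates)),
        joint_success_rate=successes / n_reps,
        n=n_reps,
    )


# ---------------------------------------------------------------------------
# Metaprofile coverage and step recovery
# ---------------------------------------------------------------------------


def _metaprofile_config(seed: int, n_compartments: int = 61) -> SimulationConfig:
    comp = CompartmentModel(bin_size=10_000, compartment_length=500_000,
                            base_rate=50.0, b_over_a=1.5)
    return SimulationConfig(
        seed=seed,
        genome=GenomeModel(
            n_chromosomes=1,
            chrom_length=n_compartments * comp.compartment_length,
        ),
        compartment=comp,
    )


def bootstrap_coverage(n_datasets: int = 1000, R: int = 200, seed: int = 0) -> dict:
    """Positionwise coverage of the metaprofile bootstrap 95% CI.

    Compartments are exactly 50 track bins wide, so the generator's true
    positionwise mean is the Poisson rate itself (base in A, base x
    ratio in B).  Reports the fraction of (dataset, position) cells
    where the CI covers the truth; nominal 0.95.
    """
    rng_seeds = np.random.SeedSequence([seed, 105]).generate_state(n_datasets) % (2**31)
    covered = 0
    total = 0
    for ds in range(n_datasets):
        cfg = _metaprofile_config(int(rng_seeds[ds]))
        layout = generate_layout(cfg)
        comps = generate_compartments(cfg, layout)
        track, _ = generate_compartment_track(cfg, layout, comps)
        merged = metaprofile.merge_adjacent(comps)
        prof = metaprofile.build_metaprofile(
            track, merged, n_bins=50, R=R, seed=int(rng_seeds[ds]),
        )
        base, ratio = cfg.compartment.base_rate, cfg.compartment.b_over_a
        truth = np.concatenate([
            np.full(50, base), np.full(50, base * ratio), np.full(50, base),
        ])
        hit = (prof.ci_low <= truth) & (truth <= prof.ci_high)
        covered += int(hit.sum())
        total += len(hit)
    return dict(coverage=covered / total, n=n_datasets)


def metaprofile_step_recovery(seed: int = 0) -> dict:
    """Recovery of the closed/open (B/A) signal ratio from the metaprofile.

    The mean of the central 30 B positions over the mean of the outer 30
    A positions should estimate the generator's B/A rate ratio.
    """
    cfg = _metaprofile_config(seed)
    layout = generate_layout(cfg)
    comps = generate_compartments(cfg, layout)
    track, _ = generate_compartment_track(cfg, layout, comps)
    prof = metaprofile.build_metaprofile(
        track, metaprofile.merge_adjacent(comps), n_bins=50, R=200, seed=seed,
    )
    central_b = float(np.mean(prof.mean[60:90]))
    outer_a = float(np.mean(np.concatenate([prof.mean[:15], prof.mean[135:]])))
    return dict(
        step_ratio=central_b / outer_a,
        true_ratio=cfg.compartment.b_over_a,
        n=prof.n_triples,
    )


# ---------------------------------------------------------------------------
# Exact counters and closed forms
# ---------------------------------------------------------------------------

_TEL_RE = re.compile("(?:%s){7}|(?:%s){7}" % ("TTAGGG", "CCCTAA"))


def exact_counters(seed: int = 0) -> dict:
    """Exactness of the telomere, solar-signature and fractional counters.

    Each counter is compared against an independent exhaustive scan
    (regex for telomere repeats, row predicate for the solar filter) on
    10,000 generated reads/records, and fractional assignment is checked
    for read-mass conservation.
    """
    cfg = SimulationConfig(
        seed=seed,
        telomere=TelomereModel(n_reads=10_000, telomeric_fraction=0.01),
        cohort=CohortModel(
            n_donors=2800,
            pairs=[PairSpec("TERT", "TPTE", 0.2, 0.2, 2.0)],
            background_genes={g: 0.2 for g in (
                "RB1", "CCND1", "CCNE1", "CDKN1A", "CDKN1B", "CDKN2A",
                "CDKN2B", "BRAF", "NRAS", "NF1", "KIT", "PTEN", "TP53",
                "ARID2", "PPP6C", "RAC1", "IDH1", "MAP2K1",
            )},
            solar_fraction=0.7,
        ),
    )
    reads, _ = generate_telomere_reads(cfg)
    impl = telomere.count_telomeric_reads(reads).telomeric_read_count
    oracle = sum(1 for r in reads if _TEL_RE.search(r.upper()))
    telomere_exact = impl == oracle

    records, _ = generate_cohort(cfg)
    kept = mutations.filter_solar_signature(records)
    oracle_kept = records[
        [(r.ref, r.alt) in {("C", "T"), ("G", "A")} for r in records.itertuples()]
    ]
    solar_exact = len(kept) == len(oracle_kept) and (
        kept.reset_index(drop=True).equals(oracle_kept.reset_index(drop=True))
    )

    fam_map, _ = generate_read_family_map(cfg, "KO", "ip", 1)
    vec = repeats.assign_fractional(fam_map)
    mass_error = abs(sum(vec.counts.values()) + vec.unassigned - vec.total_reads)
    return dict(
        telomere_counter_exact=bool(telomere_exact),
        solar_filter_exact=bool(solar_exact),
        fractional_mass_error=float(mass_error),
        n_reads=len(reads),
        n_records=len(records),
    )


def _noiseless_panel(true_cq: dict[tuple[str, str], float]) -> pd.DataFrame:
    cfg = SimulationConfig(qpcr=QpcrModel(replicate_sd=0.0, true_cq=true_cq))
    panel, _ = generate_cq_table(cfg)
    return panel


def closed_form_checks(seed: int = 0, n_chi2_configs: int = 50) -> dict:
    """Closed-form identities of the qPCR calculators and the chi-square test.

    Percent inhibition at X = 0, 1, 2 must equal 0%, 50%, 75%; the
    telomere ratio of a sample against itself must be exactly 1; and the
    peak-overlap chi-square must equal the textbook Sum (O-E)^2/E on
    random peak/selection configurations.
    """
    inh_errors = []
    for x, expected in ((0.0, 0.0), (1.0, 50.0), (2.0, 75.0)):
        panel = _noiseless_panel({
            ("TERT", "-UV"): 20.0, ("GAPDH", "-UV"): 18.0,
            ("TERT", "+UV"): 20.0 + x, ("GAPDH", "+UV"): 18.0,
        })
        inh, _ = telomere.percent_inhibition(panel, "TERT")
        inh_errors.append(abs(inh - expected))

    panel = _noiseless_panel({("telo", "S"): 12.0, ("36B4", "S"): 15.0})
    fc, _ = telomere.qpcr_telomere_ratio(panel, "S", "S")
    self_ratio_error = abs(fc - 1.0)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 108]))
    cfg = _null_lesion_config(seed)
    layout = generate_layout(cfg)
    track = lesion.bin_coverage([], layout, cfg.lesion.bin_size)
    n_bins = {c: len(v) for c, v in track.values.items()}
    chi2_err = 0.0
    from .genome import GenomicInterval
    for _ in range(n_chi2_configs):
        sel = {
            c: np.sort(rng.choice(nb, size=int(rng.integers(5, nb // 2)), replace=False))
            for c, nb in n_bins.items()
        }
        peaks = []
        for _ in range(int(rng.integers(20, 200))):
            chrom = layout.names[int(rng.integers(len(layout.names)))]
            s = int(rng.integers(0, layout.length(chrom) - 1000))
            peaks.append(GenomicInterval(chrom, s, s + 1000))
        res = resampling.observed_expected_overlap(peaks, sel, track)
        # independent evaluation of Sum (O-E)^2/E from first principles
        sel_sets = {c: set(map(int, v)) for c, v in sel.items()}
        o_in = sum(
            1 for p in peaks
            if ((p.start + p.end) // 2) // track.bin_size in sel_sets[p.chrom]
        )
        frac = sum(len(v) for v in sel.values()) / sum(n_bins.values())
        e_in = len(peaks) * frac
        expected_chi2 = (o_in - e_in) ** 2 / e_in + \
            ((len(peaks) - o_in) - (len(peaks) - e_in)) ** 2 / (len(peaks) - e_in)
        chi2_err = max(chi2_err, abs(res.chi2 - expected_chi2))
    return dict(
        percent_inhibition_max_error=float(max(inh_errors)),
        self_ratio_error=float(self_ratio_error),
        chi2_max_error=float(chi2_err),
        n=n_chi2_configs,
    )


# ---------------------------------------------------------------------------
# Pipeline determinism
# ---------------------------------------------------------------------------


def pipeline_determinism(seed: int = 0, n_groups: int = 200, R: int = 200) -> dict:
    """Whether two runs of the full pipeline give byte-identical outputs."""
    digests = []
    for _ in range(2):
        with tempfile.TemporaryDirectory() as tmp:
            cfg = SimulationConfig(seed=seed)
            manifest = run_pipeline(cfg, tmp, n_groups=n_groups, metaprofile_R=R)
            digests.append(manifest.outputs)
    return dict(
        identical=digests[0] == digests[1],
        n=len(digests[0]),
    )
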