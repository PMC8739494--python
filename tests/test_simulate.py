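"""Ground-truth properties of the synthetic-data generators."""

import numpy as np
import pytest

from uvsuscept import lesion
from uvsuscept.simulate import (
    CohortModel,
    GenomeModel,
    PairSpec,
    QpcrModel,
    SimulationConfig,
    TelomereModel,
    bivariate_bernoulli_cells,
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
from uvsuscept.telomere import count_telomeric_reads, percent_inhibition


class TestLayoutGenerator:
    def test_centromere_placed_at_configured_fraction(self):
        cfg = SimulationConfig(genome=GenomeModel(
            n_chromosomes=2, chrom_length=10_000_000,
            centromere_fraction=0.5, centromere_width=200_000,
        ))
        lay = generate_layout(cfg)
        assert lay.centromeres["chr1"] == (4_900_000, 5_100_000)
        assert lay.centromeres["chr2"] == (4_900_000, 5_100_000)

    def test_deterministic(self):
        a = generate_layout(SimulationConfig(seed=5))
        b = generate_layout(SimulationConfig(seed=5))
        assert a.chromosomes == b.chromosomes and a.centromeres == b.centromeres

    def test_centromere_always_inside_chromosome(self, rng):
        for _ in range(100):
            cfg = SimulationConfig(genome=GenomeModel(
                n_chromosomes=1,
                chrom_length=int(rng.integers(1_000_000, 50_000_000)),
                centromere_fraction=float(rng.uniform(0.05, 0.95)),
                centromere_width=int(rng.integers(10_000, 500_000)),
            ))
            lay = generate_layout(cfg)
            s, e = lay.centromeres["chr1"]
            assert 0 <= s < e <= lay.length("chr1")


class TestLesionGenerator:
    def test_null_mean_close_to_base_rate(self):
        cfg = SimulationConfig(seed=3)
        cfg.lesion.multipliers = {"WT": {}}
        lay = generate_layout(cfg)
        frags, rates = generate_lesion_fragments(cfg, lay, "WT")
        track = lesion.bin_coverage(frags, lay, cfg.lesion.bin_size)
        vals = track.flat()
        se = np.sqrt(50.0 / len(vals))
        assert np.mean(vals) == pytest.approx(50.0, abs=3 * se)
        assert np.allclose(rates.flat(), 50.0)

    def test_pericentric_multiplier_realised_in_ko_wt_ratio(self):
        cfg = SimulationConfig(seed=4)
        lay = generate_layout(cfg)
        tracks = {}
        for cond in ("WT", "KO"):
            frags, _ = generate_lesion_fragments(cfg, lay, cond)
            tracks[cond] = lesion.bin_coverage(frags, lay, cfg.lesion.bin_size)
        from uvsuscept.genome import bins_overlapping, selected_values

        peri = region_class_intervals(cfg, lay)["pericentric"]
        sel = bins_overlapping(lay, cfg.lesion.bin_size, peri)
        ko = selected_values(tracks["KO"], sel).sum()
        wt = selected_values(tracks["WT"], sel).sum()
        assert ko / wt == pytest.approx(1.5, rel=0.1)

    def test_seed_determinism_of_fragments(self):
        cfg = SimulationConfig(seed=11)
        lay = generate_layout(cfg)
        a, _ = generate_lesion_fragments(cfg, lay, "KO")
        b, _ = generate_lesion_fragments(cfg, lay, "KO")
        assert a == b


class TestBivariateBernoulli:
    def test_independence_at_or_one(self):
        cells = bivariate_bernoulli_cells(0.3, 0.4, 1.0)
        assert cells[0] == pytest.approx(0.12)
        assert cells.sum() == pytest.approx(1.0)

    def test_marginals_always_recovered(self, rng):
        for _ in range(50):
            pa, pb = rng.uniform(0.05, 0.6, size=2)
            odds = float(np.exp(rng.uniform(-2, 3)))
            cells = bivariate_bernoulli_cells(pa, pb, odds)
            assert cells[0] + cells[1] == pytest.approx(pa)
            assert cells[0] + cells[2] == pytest.approx(pb)
            p11, p10, p01, p00 = cells
            if min(cells) > 0:
                assert (p11 * p00) / (p10 * p01) == pytest.approx(odds, rel=1e-6)

    def test_large_or_limit_discordant_cells_vanish(self):
        cells = bivariate_bernoulli_cells(0.3, 0.3, 1e8)
        assert cells[1] < 1e-3 and cells[2] < 1e-3

    def test_infeasible_combination_rejected(self):
        with pytest.raises(ValueError):
            bivariate_bernoulli_cells(0.0, 0.5, 2.0)

    def test_empirical_or_matches_target(self):
        cfg = SimulationConfig(seed=21, cohort=CohortModel(
            n_donors=10_000,
            pairs=[PairSpec("A", "B", 0.3, 0.3, np.log2(4.0))],
            background_genes={},
        ))
        records, truth = generate_cohort(cfg)
        from uvsuscept.mutations import CohortMatrix, cooccurrence

        cohort = CohortMatrix.from_records(records, donors=truth["donors"])
        res = cooccurrence(cohort, [("A", "B")])
        assert 2.0 ** res["log2or"].iloc[0] == pytest.approx(4.0, rel=0.15)


class TestCohortGenerator:
    def test_truth_sidecar_consistent_with_records(self):
        cfg = SimulationConfig(seed=8, cohort=CohortModel(n_donors=300))
        records, truth = generate_cohort(cfg)
        assert truth["n_donors"] == 300
        assert set(records["gene"]) <= set(truth["marginals"])
        # every record's position inside the gene's territory
        for r in records.itertuples():
            chrom, s, e = truth["territories"][r.gene]
            assert chrom == r.chrom and s <= r.pos < e

    def test_solar_fraction_approximately_respected(self):
        cfg = SimulationConfig(seed=9, cohort=CohortModel(n_donors=2000, solar_fraction=0.8))
        records, _ = generate_cohort(cfg)
        from uvsuscept.mutations import filter_solar_signature

        frac = len(filter_solar_signature(records)) / len(records)
        assert frac == pytest.approx(0.8, abs=0.03)

    def test_determinism(self):
        cfg = SimulationConfig(seed=10)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        assert a.equals(b)


class TestCompartmentGenerator:
    def test_flat_profile_when_ratio_one(self):
        from uvsuscept.metaprofile import build_metaprofile, merge_adjacent

        cfg = SimulationConfig(seed=12, genome=GenomeModel(n_chromosomes=1, chrom_length=15_500_000))
        cfg.compartment.b_over_a = 1.0
        lay = generate_layout(cfg)
        comps = generate_compartments(cfg, lay)
        track, truth = generate_compartment_track(cfg, lay, comps)
        assert np.allclose(truth.flat(), cfg.compartment.base_rate)
        prof = build_metaprofile(track, merge_adjacent(comps), R=300, seed=1)
        centre = prof.mean[60:90].mean()
        flank = np.r_[prof.mean[:15], prof.mean[135:]].mean()
        assert centre / flank == pytest.approx(1.0, abs=0.05)

    def test_alternating_labels(self):
        cfg = SimulationConfig(seed=13)
        lay = generate_layout(cfg)
        comps = generate_compartments(cfg, lay)
        for _chrom, pairs in comps.by_chrom().items():
            labs = [lab for _, lab in pairs]
            assert all(x != y for x, y in zip(labs, labs[1:]))


class TestTelomereGenerator:
    def test_zero_fraction_gives_zero_count(self):
        cfg = SimulationConfig(seed=14, telomere=TelomereModel(n_reads=500, telomeric_fraction=0.0))
        reads, truth = generate_telomere_reads(cfg)
        assert truth["n_telomeric"] == 0
        assert count_telomeric_reads(reads).telomeric_read_count == 0

    def test_configured_fraction_recovered_exactly(self):
        cfg = SimulationConfig(seed=15, telomere=TelomereModel(n_reads=2000, telomeric_fraction=0.05))
        reads, truth = generate_telomere_reads(cfg)
        assert count_telomeric_reads(reads).telomeric_read_count == truth["n_telomeric"] == 100


class TestCqGenerator:
    def test_noiseless_panel_reproduces_truth(self):
        cfg = SimulationConfig(qpcr=QpcrModel(replicate_sd=0.0))
        panel, truth = generate_cq_table(cfg)
        inh, se = percent_inhibition(panel, "TERT")
        assert inh == pytest.approx(50.0)  # default true X = 1
        assert se == 0.0

    def test_noisy_panel_recovers_truth_within_three_se(self):
        cfg = SimulationConfig(seed=16, qpcr=QpcrModel(replicate_sd=0.1, n_replicates=6))
        panel, _ = generate_cq_table(cfg)
        inh, se = percent_inhibition(panel, "TERT")
        assert abs(inh - 50.0) <= 3 * se


class TestReadFamilyMap:
    def test_deterministic_and_mass_structure(self):
        cfg = SimulationConfig(seed=17)
        a, truth = generate_read_family_map(cfg, "KO", "ip", 1)
        b, _ = generate_read_family_map(cfg, "KO", "ip", 1)
        assert a == b
        assert len(a) == cfg.repeat.n_reads
        assert sum(truth["true_counts"].values()) <= cfg.repeat.n_reads

    def test_ip_enrichment_shifts_family_share(self):
        cfg = SimulationConfig(seed=18)
        cfg.repeat.n_reads = 20_000
        ip, _ = generate_read_family_map(cfg, "KO", "ip", 1)
        inp, _ = generate_read_family_map(cfg, "KO", "input", 1)
        from uvsuscept.repeats import assign_fractional, family_log2fc

        fc = family_log2fc(assign_fractional(ip), assign_fractional(inp), pseudocount=0.5)
        assert fc["Satellite"] > 0.3  # configured 1.5x IP enrichment
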