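"""Cohort statistics: solar filter, rates, stratification, co-occurrence."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from uvsuscept.genome import GenomeLayout, GenomicInterval, LabeledSegmentation
from uvsuscept.mutations import (
    CohortMatrix,
    compare_rate_distributions,
    cooccurrence,
    distance_to_landmark,
    feature_mutation_fraction,
    filter_solar_signature,
    fisher_two_sided_p,
    gene_mutation_rate,
    log2_odds_ratio,
    stratify_by_pathway,
    validate_records,
)


def _records(rows):
    return pd.DataFrame(
        rows, columns=["donor_id", "gene", "chrom", "pos", "ref", "alt", "feature"]
    )


class TestSolarFilter:
    def test_keeps_only_ct_and_ga(self):
        recs = _records([
            ("d1", "g", "c", 1, "C", "T", "exon"),
            ("d1", "g", "c", 2, "G", "A", "exon"),
            ("d1", "g", "c", 3, "C", "A", "exon"),
            ("d1", "g", "c", 4, "T", "C", "exon"),
        ])
        kept = filter_solar_signature(recs)
        assert len(kept) == 2
        assert set(zip(kept["ref"], kept["alt"])) == {("C", "T"), ("G", "A")}

    def test_empty_input(self):
        assert len(filter_solar_signature(_records([]))) == 0

    def test_matches_predicate_scan(self, rng):
        bases = list("ACGT")
        rows = []
        for i in range(2000):
            ref = rng.choice(bases)
            alt = rng.choice([b for b in bases if b != ref])
            rows.append((f"d{i % 50}", "g", "c", i, ref, alt, "exon"))
        recs = validate_records(_records(rows))
        kept = filter_solar_signature(recs)
        want = [r for r in rows if (r[4], r[5]) in {("C", "T"), ("G", "A")}]
        assert len(kept) == len(want)

    def test_validation_rejects_identity_substitution(self):
        with pytest.raises(ValueError):
            validate_records(_records([("d", "g", "c", 1, "C", "C", "exon")]))


class TestGeneRate:
    def _cohort(self, n_donors, cg):
        mat = pd.DataFrame(0, index=[f"d{i}" for i in range(n_donors)], columns=list(cg))
        return CohortMatrix(matrix=mat, cg_content=pd.Series(cg, dtype=float))

    def test_rate_arithmetic(self):
        recs = _records([
            ("d0", "g", "c", 1, "C", "T", "exon"),
            ("d0", "g", "c", 2, "G", "A", "exon"),
        ])
        rate = gene_mutation_rate(recs, self._cohort(1, {"g": 10}), "g")
        assert rate == pytest.approx(0.2)

    def test_zero_mutations_zero_rate(self):
        assert gene_mutation_rate(_records([]), self._cohort(5, {"g": 10}), "g") == 0

    def test_zero_cg_gives_missing(self, caplog):
        with caplog.at_level("WARNING"):
            rate = gene_mutation_rate(_records([]), self._cohort(5, {"g": 0}), "g")
        assert np.isnan(rate)


class TestStratify:
    def _cohort(self, mat):
        return CohortMatrix(matrix=mat, cg_content=pd.Series(dtype=float))

    def test_any_pathway_gene_counts(self):
        mat = pd.DataFrame(
            {"CDKN2A": [1, 0], "TERT": [1, 1]}, index=["d1", "d2"]
        )
        mutated, not_mutated = stratify_by_pathway(self._cohort(mat))
        assert mutated == ["d1"] and not_mutated == ["d2"]

    def test_partition_matches_any_column_or_oracle(self, rng):
        genes = ["RB1", "CCND1", "CDKN2B", "TERT", "TPTE"]
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(200, 5)), columns=genes,
            index=[f"d{i}" for i in range(200)],
        )
        mutated, not_mutated = stratify_by_pathway(self._cohort(mat))
        pathway = ["RB1", "CCND1", "CDKN2B"]
        want = set(mat.index[mat[pathway].any(axis=1)])
        assert set(mutated) == want
        assert set(not_mutated) == set(mat.index) - want
        assert not set(mutated) & set(not_mutated)


class TestFeatureFractions:
    def test_fraction_and_identical_strata(self):
        rows = [(f"d{i}", "TERT", "c", i, "C", "T", "promoter") for i in range(3)]
        recs = _records(rows)
        cohort = CohortMatrix(
            matrix=pd.DataFrame({"TERT": [1] * 3 + [0] * 7}, index=[f"d{i}" for i in range(10)]),
            cg_content=pd.Series(dtype=float),
        )
        strata = {"s1": [f"d{i}" for i in range(10)], "s2": [f"d{i}" for i in range(10)]}
        df = feature_mutation_fraction(recs, cohort, "TERT", strata).set_index("feature")
        assert df.loc["promoter", "frac_s1"] == pytest.approx(0.3)
        assert df.loc["promoter", "fisher_p"] == pytest.approx(1.0)
        assert df.loc["exon", "frac_s1"] == 0.0

    def test_empty_stratum_rejected(self):
        cohort = CohortMatrix(
            matrix=pd.DataFrame({"g": [1]}, index=["d0"]), cg_content=pd.Series(dtype=float)
        )
        with pytest.raises(ValueError):
            feature_mutation_fraction(_records([]), cohort, "g", {"a": ["d0"], "b": []})


def brute_force_fisher(n11, n10, n01, n00):
    """Enumerate all tables with the observed margins; sum p(table) <= p(obs)."""
    n = n11 + n10 + n01 + n00
    r1, c1 = n11 + n10, n11 + n01
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {a: hypergeom.pmf(a, n, r1, c1) for a in support}
    p_obs = pmf[n11]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


class TestCooccurrence:
    def _cohort_from_table(self, n11, n10, n01, n00):
        a = [1] * (n11 + n10) + [0] * (n01 + n00)
        b = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
        mat = pd.DataFrame({"A": a, "B": b}, index=[f"d{i}" for i in range(len(a))])
        return CohortMatrix(matrix=mat, cg_content=pd.Series(dtype=float))

    def test_closed_form_odds_ratio(self):
        res = cooccurrence(self._cohort_from_table(30, 10, 10, 50), [("A", "B")])
        assert res["log2or"].iloc[0] == pytest.approx(np.log2(15), abs=1e-12)
        assert res[["n11", "n10", "n01", "n00"]].iloc[0].sum() == 100

    def test_zero_cell_gets_haldane_correction(self):
        res = cooccurrence(self._cohort_from_table(10, 0, 5, 30), [("A", "B")])
        assert bool(res["zero_cell_corrected"].iloc[0])
        assert res["log2or"].iloc[0] == pytest.approx(
            np.log2((10.5 * 30.5) / (0.5 * 5.5))
        )

    def test_degenerate_column_reported_not_crashed(self):
        mat = pd.DataFrame({"A": [1, 1, 1], "B": [1, 0, 1]}, index=["d0", "d1", "d2"])
        res = cooccurrence(CohortMatrix(matrix=mat, cg_content=pd.Series(dtype=float)), [("A", "B")])
        assert np.isnan(res["log2or"].iloc[0])
        assert res["p"].iloc[0] == 1.0
        assert res["call"].iloc[0] == "none"

    def test_null_symmetry_of_log2or(self, rng):
        vals = []
        for _ in range(200):
            a = rng.integers(0, 2, size=400)
            b = rng.integers(0, 2, size=400)
            mat = pd.DataFrame({"A": a, "B": b}, index=[f"d{i}" for i in range(400)])
            res = cooccurrence(CohortMatrix(matrix=mat, cg_content=pd.Series(dtype=float)), [("A", "B")])
            vals.append(res["log2or"].iloc[0])
        assert abs(np.mean(vals)) < 0.05

    def test_sign_flips_under_single_column_negation(self):
        l2, _ = log2_odds_ratio(30, 10, 10, 50)
        flipped, _ = log2_odds_ratio(10, 30, 50, 10)  # complement gene A
        assert flipped == pytest.approx(-l2)
        both, _ = log2_odds_ratio(50, 10, 10, 30)  # complement both
        assert both == pytest.approx(l2)

    def test_fisher_matches_enumeration_small_margins(self):
        for n11, n10, n01, n00 in itertools.product(range(0, 7, 2), repeat=4):
            if n11 + n10 + n01 + n00 == 0:
                continue
            p = fisher_two_sided_p(n11, n10, n01, n00)
            assert p == pytest.approx(brute_force_fisher(n11, n10, n01, n00), abs=1e-10)

    def test_calls_respect_q_threshold_and_direction(self):
        res = cooccurrence(self._cohort_from_table(40, 5, 5, 50), [("A", "B")])
        assert res["call"].iloc[0] == "co-occurring"
        res = cooccurrence(self._cohort_from_table(2, 40, 40, 2), [("A", "B")])
        assert res["call"].iloc[0] == "mutually_exclusive"


class TestDistanceToLandmark:
    def _genes(self, spans):
        return LabeledSegmentation(
            intervals=[GenomicInterval(c, s, e) for c, s, e in spans],
            labels=[f"g{i}" for i in range(len(spans))],
        )

    def test_nearest_is_p_telomere(self):
        lay = GenomeLayout([("c", 100_000_000)], {"c": (50_000_000, 51_000_000)})
        d = distance_to_landmark(self._genes([("c", 5_000_000, 5_010_000)]), lay)
        assert d["g0"] == 5_000_000

    def test_gene_overlapping_centromere_distance_zero(self):
        lay = GenomeLayout([("c", 100_000_000)], {"c": (50_000_000, 51_000_000)})
        d = distance_to_landmark(self._genes([("c", 50_500_000, 50_600_000)]), lay)
        assert d["g0"] == 0

    def test_matches_min_over_landmarks_oracle(self, rng):
        lay = GenomeLayout([("c", 100_000_000)], {"c": (47_300_000, 50_100_000)})
        spans = []
        for _ in range(200):
            s = int(rng.integers(0, 99_000_000))
            spans.append(("c", s, s + int(rng.integers(1_000, 1_000_000))))
        d = distance_to_landmark(self._genes(spans), lay)
        cs, ce = 47_300_000, 50_100_000
        for (c, s, e), lab in zip(spans, [f"g{i}" for i in range(len(spans))]):
            if e <= cs:
                cen = cs - e
            elif s >= ce:
                cen = s - ce
            else:
                cen = 0
            assert d[lab] == min(s, 100_000_000 - e, cen)


def brute_force_mannwhitney_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs_u = ranks[:n].sum() - n * (n + 1) / 2
    mean_u = n * len(y) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        us.append(u)
    us = np.array(us)
    return float(np.mean(np.abs(us - mean_u) >= abs(obs_u - mean_u) - 1e-12))


class TestRateComparison:
    def test_identical_samples(self):
        assert compare_rate_distributions([1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_complete_separation(self):
        p = compare_rate_distributions(np.arange(10), np.arange(100, 110))
        assert p < 1e-3

    def test_matches_exact_enumeration_small_n(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        p = compare_rate_distributions(x, y)
        assert p == pytest.approx(brute_force_mannwhitney_p(x, y), abs=1e-10)
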