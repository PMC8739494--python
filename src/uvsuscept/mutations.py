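"""Melanoma-cohort mutation statistics.

Works from MAF-like records (donor, gene, position, ref/alt, genic
feature).  Solar-signature filtering keeps C>T and G>A substitutions;
gene mutation rates are normalised by the gene's C+G base content and
cohort size; donors are stratified by RB1-pathway mutation status; and
pairwise co-occurrence is scored with the 2x2 log2 odds ratio, Fisher's
exact test and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout, LabeledSegmentation
from .stats import bh_adjust

logger = logging.getLogger(__name__)

RB1_PATHWAY = ("RB1", "CCND1", "CCNE1", "CDKN1A", "CDKN1B", "CDKN2A", "CDKN2B")

GENIC_FEATURES = (
    "promoter", "upstream", "downstream", "exon", "intron",
    "UTR5", "UTR3", "intergenic",
)

_BASES = {"A", "C", "G", "T"}


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    bad = records[
        ~records["ref"].isin(_BASES)
        | ~records["alt"].isin(_BASES)
        | (records["ref"] == records["alt"])
    ]
    if len(bad):
        raise ValueError(f"{len(bad)} records with invalid ref/alt")
    return records


def filter_solar_signature(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only C>T and G>A substitutions (the UV solar signature)."""
    keep = ((records["ref"] == "C") & (records["alt"] == "T")) | (
        (records["ref"] == "G") & (records["alt"] == "A")
    )
    return records[keep].reset_index(drop=True)


@dataclass
class CohortMatrix:
    """Binary donors x genes mutation indicator plus gene C+G content."""

    matrix: pd.DataFrame              # index donors, columns genes, values 0/1
    cg_content: pd.Series             # per-gene C+G base count

    @property
    def n_donors(self) -> int:
        return len(self.matrix)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        cg_content: pd.Series | dict[str, int] | None = None,
        donors: list[str] | None = None,
        genes: list[str] | None = None,
        exclude_donors: set[str] | None = None,
    ) -> "CohortMatrix":
        """Build the indicator matrix from mutation records.

        ``donors``/``genes`` extend the universe beyond what appears in
        the records (donors with no mutation are legitimate cohort
        members); ``exclude_donors`` drops donors (e.g. an acral-melanoma
        exclusion list) before tabulation.
        """
        recs = records
        if exclude_donors:
            recs = recs[~recs["donor_id"].isin(exclude_donors)]
        all_donors = sorted(set(recs["donor_id"]) | set(donors or []))
        if exclude_donors:
            all_donors = [d for d in all_donors if d not in exclude_donors]
        all_genes = sorted(set(recs["gene"]) | set(genes or []))
        mat = pd.DataFrame(0, index=all_donors, columns=all_genes, dtype=int)
        hit = recs[["donor_id", "gene"]].drop_duplicates()
        for d, g in hit.itertuples(index=False):
            mat.at[d, g] = 1
        cg = pd.Series(cg_content, dtype=float) if cg_content is not None else pd.Series(dtype=float)
        return cls(matrix=mat, cg_content=cg)


def gene_mutation_rate(
    records: pd.DataFrame, cohort: CohortMatrix, gene: str
) -> float:
    """Mutations per C+G base per donor for one gene.

    ``records`` should already be solar-signature filtered.  Returns NaN
    with a warning when the gene's C+G content is zero or unknown.
    """
    cg = float(cohort.cg_content.get(gene, 0.0))
    if cg <= 0:
        logger.warning("gene %s has no C+G content; rate undefined", gene)
        return float("nan")
    n_mut = int((records["gene"] == gene).sum())
    return n_mut / (cg * cohort.n_donors)


def gene_rates(records: pd.DataFrame, cohort: CohortMatrix, genes: list[str]) -> pd.Series:
    return pd.Series({g: gene_mutation_rate(records, cohort, g) for g in genes}, name="rate")


def stratify_by_pathway(
    cohort: CohortMatrix, pathway_genes: tuple[str, ...] = RB1_PATHWAY
) -> tuple[list[str], list[str]]:
    """Split donors by mutation status of any pathway gene.

    Returns ``(mutated, not_mutated)`` donor lists; the partition is
    exhaustive and disjoint.  Pathway genes absent from the matrix are
    treated as unmutated with a warning.
    """
    present = [g for g in pathway_genes if g in cohort.matrix.columns]
    missing = set(pathway_genes) - set(present)
    if missing:
        logger.warning("pathway genes absent from cohort: %s", sorted(missing))
    if present:
        hit = cohort.matrix[present].any(axis=1)
    else:
        hit = pd.Series(False, index=cohort.matrix.index)
    mutated = list(cohort.matrix.index[hit])
    not_mutated = list(cohort.matrix.index[~hit])
    return mutated, not_mutated


def feature_mutation_fraction(
    records: pd.DataFrame,
    cohort: CohortMatrix,
    gene: str,
    strata: dict[str, list[str]],
    features: tuple[str, ...] = GENIC_FEATURES,
) -> pd.DataFrame:
    """Fraction of donors mutated in each genic feature of ``gene``, per stratum.

    With exactly two strata a per-feature two-proportion Fisher exact
    p-value is added.
    """
    for name, members in strata.items():
        if len(members) == 0:
            raise ValueError(f"stratum {name!r} is empty")
    recs = records[records["gene"] == gene]
    rows = []
    for feature in features:
        frecs = recs[recs["feature"] == feature]
        mutated_donors = set(frecs["donor_id"])
        row: dict[str, object] = {"feature": feature}
        counts = {}
        for name, members in strata.items():
            k = sum(1 for d in members if d in mutated_donors)
            counts[name] = (k, len(members))
            row[f"frac_{name}"] = k / len(members)
            row[f"n_{name}"] = len(members)
        if len(strata) == 2:
            (k1, n1), (k2, n2) = counts.values()
            _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
            row["fisher_p"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def log2_odds_ratio(
    n11: int, n10: int, n01: int, n00: int, zero_cell: float = 0.5
) -> tuple[float, bool]:
    """log2 OR of a 2x2 table; Haldane-Anscombe correction iff any cell is 0.

    Returns ``(log2or, corrected)``.  NaN when a margin is degenerate
    even after correction is impossible to interpret (all counts zero).
    """
    cells = np.array([n11, n10, n01, n00], dtype=float)
    corrected = bool((cells == 0).any())
    if cells.sum() == 0:
        return float("nan"), corrected
    if corrected:
        cells = cells + zero_cell
    a, b, c, d = cells
    return float(np.log2((a * d) / (b * c))), corrected


def fisher_two_sided_p(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sums)."""
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return float(p)


def cooccurrence(
    cohort: CohortMatrix,
    gene_pairs: list[tuple[str, str]],
    q_threshold: float = 0.05,
    zero_cell: float = 0.5,
) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual exclusivity over the requested pairs.

    Per pair: the donor 2x2 table (both, A-only, B-only, neither), log2
    odds ratio (zero-cell corrected when needed), two-sided Fisher exact
    p, and BH q across the tested pairs.  The call is "co-occurring" for
    log2OR > 0 with q below threshold, "mutually_exclusive" for
    log2OR < 0 with q below threshold, else "none".  A degenerate column
    (gene mutated in all or no donors) yields a missing OR and p = 1.
    """
    n = cohort.n_donors
    rows = []
    for ga, gb in gene_pairs:
        for g in (ga, gb):
            if g not in cohort.matrix.columns:
                raise KeyError(f"gene {g} not in cohort matrix")
        a = cohort.matrix[ga].to_numpy()
        b = cohort.matrix[gb].to_numpy()
        n11 = int(np.sum((a == 1) & (b == 1)))
        n10 = int(np.sum((a == 1) & (b == 0)))
        n01 = int(np.sum((a == 0) & (b == 1)))
        n00 = n - n11 - n10 - n01
        degenerate = a.sum() in (0, n) or b.sum() in (0, n)
        if degenerate:
            l2or, corrected, p = float("nan"), False, 1.0
        else:
            l2or, corrected = log2_odds_ratio(n11, n10, n01, n00, zero_cell)
            p = fisher_two_sided_p(n11, n10, n01, n00)
        rows.append(dict(
            gene_a=ga, gene_b=gb, n11=n11, n10=n10, n01=n01, n00=n00,
            log2or=l2or, zero_cell_corrected=corrected, p=float(p),
        ))
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    def call(r):
        if np.isnan(r.log2or) or r.q >= q_threshold:
            return "none"
        return "co-occurring" if r.log2or > 0 else "mutually_exclusive"
    df["call"] = [call(r) for r in df.itertuples()]
    return df


def distance_to_landmark(
    genes: LabeledSegmentation, layout: GenomeLayout
) -> pd.Series:
    """Per-gene bp distance to the nearest centromere edge or telomere anchor.

    The distance is measured from the gene edge nearest each landmark:
    to the p-telomere it is ``start``, to the q-telomere ``length - end``,
    and to the centromere the gap to its closer boundary (0 when the gene
    overlaps the centromere).  The minimum over landmarks is returned.
    """
    out = {}
    for iv, lab in zip(genes.intervals, genes.labels):
        length = layout.length(iv.chrom)
        dists = [iv.start, length - iv.end]
        if iv.chrom in layout.centromeres:
            cs, ce = layout.centromeres[iv.chrom]
            if iv.end <= cs:
                dists.append(cs - iv.end)
            elif iv.start >= ce:
                dists.append(iv.start - ce)
            else:
                dists.append(0)
        out[lab] = min(dists)
    return pd.Series(out, name="distance_bp")


def compare_rate_distributions(rates_a, rates_b) -> float:
    """Two-sided Mann-Whitney U p between two sets of per-gene rates."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both rate sets must be nonempty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
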