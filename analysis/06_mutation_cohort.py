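"""Melanoma-cohort mutation statistics on the simulated cohort.

Solar-signature (C>T/G>A) filtering, C+G-normalised gene mutation
rates, RB1-pathway stratification with per-feature mutation fractions
for the focal genes, pairwise co-occurrence (log2 odds ratio + Fisher +
BH), and gene distance to the nearest centromere/telomere.
"""

import json
from pathlib import Path

import pandas as pd

from uvsuscept import io, mutations
from uvsuscept.genome import GenomicInterval, LabeledSegmentation

BASE = Path(__file__).resolve().parent.parent / "results"
IN, OUT = BASE / "synthetic", BASE / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout = io.read_layout(IN / "layout.tsv")
    records = mutations.validate_records(io.read_mutation_table(IN / "cohort.tsv"))
    truth = json.loads((IN / "truth.json").read_text())["cohort"]

    cohort = mutations.CohortMatrix.from_records(
        records, cg_content=pd.Series(truth["cg_content"], dtype=float),
        donors=truth["donors"],
    )
    solar = mutations.filter_solar_signature(records)
    print(f"{len(solar)}/{len(records)} records carry the solar signature")

    rates = mutations.gene_rates(solar, cohort, sorted(cohort.matrix.columns))
    rates.rename_axis("gene").reset_index().to_csv(OUT / "gene_rates.tsv", sep="\t", index=False)

    mutated, not_mutated = mutations.stratify_by_pathway(cohort)
    print(f"RB1-pathway mutated: {len(mutated)} donors; not mutated: {len(not_mutated)}")
    strata = {"mutated": mutated, "not_mutated": not_mutated}
    for gene in ("TERT", "TPTE"):
        feats = mutations.feature_mutation_fraction(records, cohort, gene, strata)
        feats.to_csv(OUT / f"feature_fractions_{gene}.tsv", sep="\t", index=False)

    pairs = [("TERT", "TPTE"), ("TERT", "RB1"), ("TPTE", "CDKN2A"), ("RB1", "CDKN2A")]
    cooc = mutations.cooccurrence(cohort, pairs)
    cooc.to_csv(OUT / "cooccurrence.tsv", sep="\t", index=False)
    for r in cooc.itertuples():
        print(f"{r.gene_a} x {r.gene_b}: log2OR={r.log2or:+.2f}, q={r.q:.3g} -> {r.call}")

    terr = truth["territories"]
    genes = LabeledSegmentation(
        intervals=[GenomicInterval(c, s, e) for c, s, e in terr.values()],
        labels=list(terr),
    )
    dist = mutations.distance_to_landmark(genes, layout)
    dist.rename_axis("gene").reset_index().to_csv(
        OUT / "gene_landmark_distance.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
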