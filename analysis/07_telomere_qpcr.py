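"""Telomere content from reads and the qPCR calculators.

Counts reads with seven or more consecutive TTAGGG/CCCTAA motifs,
GC-normalises the count, and evaluates the delta-delta-Cq telomere
ratio (KO vs WT) and UV-interference percent inhibition with
error-propagated standard errors.
"""

from pathlib import Path

import pandas as pd

from uvsuscept import io, telomere

BASE = Path(__file__).resolve().parent.parent / "results"
IN, OUT = BASE / "synthetic", BASE / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reads = io.read_sequences(IN / "reads.fasta")
    est = telomere.count_telomeric_reads(reads)
    gcn = telomere.gc_normalized_content(reads)
    print(f"{est.telomeric_read_count}/{est.total_reads} telomeric reads; "
          f"{gcn.content_per_million:.0f} per million GC-comparable reads")

    panel = io.read_cq_table(IN / "cq.tsv")
    fc, se_fc = telomere.qpcr_telomere_ratio(panel, "KO", "WT")
    inh, se_inh = telomere.percent_inhibition(panel, "TERT")
    print(f"qPCR telomere fold change KO/WT: {fc:.3f} +- {se_fc:.3f}")
    print(f"TERT percent inhibition: {inh:.1f}% +- {se_inh:.1f}")

    pd.DataFrame([
        dict(metric="telomeric_reads", value=est.telomeric_read_count),
        dict(metric="total_reads", value=est.total_reads),
        dict(metric="gc_window_reads", value=gcn.gc_window_read_count),
        dict(metric="content_per_million", value=gcn.content_per_million),
        dict(metric="qpcr_fold_change_KO_WT", value=fc),
        dict(metric="qpcr_fold_change_se", value=se_fc),
        dict(metric="percent_inhibition_TERT", value=inh),
        dict(metric="percent_inhibition_se", value=se_inh),
    ]).to_csv(OUT / "telomere_qpcr.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
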