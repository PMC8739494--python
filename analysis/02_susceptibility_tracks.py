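"""Build binned susceptibility tracks and chromatin summaries.

From the simulated inputs: midpoint-binned WT/KO lesion coverage at
100 kb, the knockout/wild-type log2 fold-change track, top/bottom 10%
quantile selections, per-chromatin-state aggregation of the histone
IP/input fold change (with Mann-Whitney tests against the genome
median), and the Spearman correlation between lesion and histone fold
changes.  Outputs under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from uvsuscept import io, lesion

BASE = Path(__file__).resolve().parent.parent / "results"
IN, OUT = BASE / "synthetic", BASE / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout = io.read_layout(IN / "layout.tsv")
    cov = {}
    for cond in ("WT", "KO"):
        frags = io.read_bed(IN / f"lesion_{cond}.bed")
        cov[cond] = lesion.bin_coverage(frags, layout, 100_000)
        io.write_bedgraph(cov[cond], OUT / f"lesion_{cond}_100kb.bedGraph")

    fc = lesion.normalize_and_ratio(cov["KO"], cov["WT"], pseudocount=1.0, scale="none")
    io.write_bedgraph(fc.track, OUT / "lesion_log2fc_KO_WT.bedGraph")

    rows = []
    for tail in ("top", "bottom"):
        sel = lesion.select_quantile_bins(fc.track, 0.10, tail)
        rows += [dict(tail=tail, chrom=c, bin=int(i)) for c, idx in sel.items() for i in idx]
    pd.DataFrame(rows).to_csv(OUT / "quantile_bins_10pct.tsv", sep="\t", index=False)
    print(f"selected {len(rows)} extreme-decile bins")

    states = io.read_bed4(IN / "states.bed")
    for mark in ("H3K9me3", "H3K27me3"):
        ip = lesion.bin_coverage(io.read_bed(IN / f"chip_{mark}_ip.bed"), layout, 100_000)
        inp = lesion.bin_coverage(io.read_bed(IN / f"chip_{mark}_input.bed"), layout, 100_000)
        chip_fc = lesion.normalize_and_ratio(ip, inp, pseudocount=1.0, scale="cpm")
        io.write_bedgraph(chip_fc.track, OUT / f"{mark}_log2fc_ip_input.bedGraph")
        agg = lesion.aggregate_by_state(chip_fc.track, states)
        agg.to_csv(OUT / f"{mark}_by_state.tsv", sep="\t", index=False)
        flagged = agg[agg["mw_p"] < 0.001]["label"].tolist()
        print(f"{mark}: states different from genome median (P<0.001): {flagged}")
        rho, p = lesion.correlate_tracks(fc.track, chip_fc.track)
        print(f"{mark} vs lesion log2FC: Spearman rho={rho:.3f} (p={p:.2e})")
        pd.DataFrame([dict(mark=mark, spearman_rho=rho, p=p)]).to_csv(
            OUT / f"corr_lesion_{mark}.tsv", sep="\t", index=False
        )


if __name__ == "__main__":
    main()
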