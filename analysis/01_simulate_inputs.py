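"""Generate the synthetic study inputs with known ground truth.

Writes every input the downstream analyses consume — genome layout,
WT/KO UV-lesion fragment BEDs, chromatin-state and A/B-compartment
segmentations, ChIP/input fragments for two histone marks, a melanoma-
like mutation cohort, telomere-read FASTA and qPCR Cq panels — plus a
truth sidecar, under results/synthetic/.
"""

import json
import sys
from pathlib import Path

from uvsuscept import io
from uvsuscept.simulate import (
    SimulationConfig,
    generate_chip_fragments,
    generate_cohort,
    generate_compartment_track,
    generate_compartments,
    generate_cq_table,
    generate_layout,
    generate_lesion_fragments,
    generate_states,
    generate_telomere_reads,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    layout = generate_layout(cfg)
    io.write_layout(layout, OUT / "layout.tsv")

    for cond in ("WT", "KO"):
        frags, _ = generate_lesion_fragments(cfg, layout, cond)
        io.write_bed(frags, OUT / f"lesion_{cond}.bed")
        print(f"{cond}: {len(frags)} lesion fragments")

    states = generate_states(cfg, layout)
    io.write_bed4(states, OUT / "states.bed")
    for mark in ("H3K9me3", "H3K27me3"):
        for role in ("ip", "input"):
            frags, _ = generate_chip_fragments(cfg, layout, states, mark, role)
            io.write_bed(frags, OUT / f"chip_{mark}_{role}.bed")

    comps = generate_compartments(cfg, layout)
    io.write_bed4(comps, OUT / "compartments.bed")
    track, _ = generate_compartment_track(cfg, layout, comps)
    io.write_bedgraph(track, OUT / "compartment_signal.bedGraph")

    records, truth = generate_cohort(cfg, layout)
    records.to_csv(OUT / "cohort.tsv", sep="\t", index=False)
    print(f"cohort: {truth['n_donors']} donors, {len(records)} mutation records")

    reads, tel_truth = generate_telomere_reads(cfg)
    with open(OUT / "reads.fasta", "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f">read_{i:06d}\n{r}\n")
    panel, qpcr_truth = generate_cq_table(cfg)
    panel.to_csv(OUT / "cq.tsv", sep="\t", index=False)

    with open(OUT / "truth.json", "w") as fh:
        json.dump({"cohort": truth, "telomere": tel_truth, "qpcr": qpcr_truth},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
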