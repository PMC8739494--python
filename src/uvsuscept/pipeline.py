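"""End-to-end synthetic reproduction pipeline with run provenance.

``run_pipeline`` chains simulate -> bin -> ratio -> region tests ->
metaprofile -> repeats -> mutations -> telomere/qPCR -> report, writing
every output under one directory together with a manifest (command
line, config hash, seed, per-file SHA-256 digests).  All randomness
derives from the single config seed via per-stage seed sequences, so a
rerun with the same config produces byte-identical outputs.

Files are written atomically (``.partial`` then rename), so an aborted
stage never leaves a truncated file masquerading as a result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, io, lesion, metaprofile, mutations, repeats, resampling, telomere
from .genome import GenomicInterval, LabeledSegmentation
from .simulate import (
    PairSpec,
    SimulationConfig,
    generate_compartment_track,
    generate_compartments,
    generate_cohort,
    generate_cq_table,
    generate_layout,
    generate_lesion_fragments,
    generate_read_family_map,
    generate_telomere_reads,
    region_class_intervals,
)

logger = logging.getLogger("uvsuscept.pipeline")


# ---------------------------------------------------------------------------
# Config (de)serialisation
# ---------------------------------------------------------------------------


def _apply_dict(obj: Any, d: dict, path: str = "") -> None:
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in d.items():
        here = f"{path}.{key}" if path else key
        if key not in names:
            raise ValueError(f"unknown config key: {here}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply_dict(current, value, here)
        elif key == "true_cq" and isinstance(value, dict):
            setattr(obj, key, {tuple(k.split("|", 1)): float(v) for k, v in value.items()})
        elif key == "pairs" and isinstance(value, list):
            setattr(obj, key, [PairSpec(**v) for v in value])
        else:
            setattr(obj, key, value)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a (possibly partial) nested dict; unknown keys raise."""
    cfg = SimulationConfig()
    _apply_dict(cfg, d)
    return cfg


def config_from_yaml(path: str | Path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must hold a mapping")
    return config_from_dict(data)


def config_to_dict(cfg: SimulationConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {
                ("|".join(k) if isinstance(k, tuple) else k): convert(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(cfg)


def config_hash(cfg: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Atomic writing and digests
# ---------------------------------------------------------------------------


def _finalize(partial: Path) -> Path:
    final = partial.with_name(partial.name[: -len(".partial")])
    os.replace(partial, final)
    return final


class _Writer:
    """Write files atomically and record them for the manifest."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: dict[str, list[Path]] = {}

    def path(self, stage: str, name: str) -> Path:
        p = self.out_dir / name
        self.files.setdefault(stage, []).append(p)
        return p

    def write(self, stage: str, name: str, writer) -> Path:
        final = self.path(stage, name)
        partial = final.with_name(final.name + ".partial")
        writer(partial)
        return _finalize(partial)

    def write_tsv(self, stage: str, name: str, df: pd.DataFrame, index: bool = False) -> Path:
        return self.write(stage, name, lambda p: df.to_csv(p, sep="\t", index=index))

    def write_json(self, stage: str, name: str, obj) -> Path:
        def w(p: Path):
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True, default=str)
                fh.write("\n")
        return self.write(stage, name, w)


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    command_line: str
    seed: int
    config_hash: str
    package_version: str
    started: str
    finished: str
    outputs: dict[str, str]          # relative path -> sha256
    stages: dict[str, list[str]]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _enrichment_row(name: str, res: resampling.EnrichmentResult) -> dict:
    return dict(
        region_set=name,
        observed_median=res.observed,
        null_mean=res.null_mean,
        null_sd=res.null_sd,
        mw_p=res.mw_p,
        empirical_p=res.empirical_p,
        direction=res.direction,
        n_selected_bins=res.n_selected_bins,
    )


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    n_groups: int = 1000,
    metaprofile_R: int = 1000,
    quantile_fraction: float = 0.10,
) -> RunManifest:
    """Run every stage on synthetic inputs and write outputs plus manifest.

    Stages run in dependency order; a failure aborts with the stage name
    while prior outputs remain intact.  Returns the manifest (also
    written as ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    w = _Writer(out_dir)
    stage = "simulate"
    try:
        # -- simulate -------------------------------------------------------
        logger.info("[%s] generating synthetic inputs", stage)
        layout = generate_layout(config)
        w.write(stage, "layout.tsv", lambda p: io.write_layout(layout, p))
        frags, truth_rates = {}, {}
        for cond in ("WT", "KO"):
            frags[cond], truth_rates[cond] = generate_lesion_fragments(config, layout, cond)
            w.write(stage, f"lesion_{cond}.bed", lambda p, c=cond: io.write_bed(frags[c], p))
        compartments = generate_compartments(config, layout)
        w.write(stage, "compartments.bed", lambda p: io.write_bed4(compartments, p))
        comp_track, comp_truth = generate_compartment_track(config, layout, compartments)
        records, cohort_truth = generate_cohort(config, layout)
        w.write_tsv(stage, "cohort.tsv", records)
        reads, telomere_truth = generate_telomere_reads(config)
        def write_reads(p: Path):
            with open(p, "w") as fh:
                for i, r in enumerate(reads):
                    fh.write(f">read_{i:06d}\n{r}\n")
        w.write(stage, "reads.fasta", write_reads)
        panel, qpcr_truth = generate_cq_table(config)
        w.write_tsv(stage, "cq.tsv", panel)
        w.write_json(stage, "truth.json", dict(
            cohort=cohort_truth, telomere=telomere_truth, qpcr=qpcr_truth,
        ))

        # -- bin + ratio ----------------------------------------------------
        stage = "tracks"
        logger.info("[%s] binning fragments and building the KO/WT ratio", stage)
        bin_size = config.lesion.bin_size
        cov = {c: lesion.bin_coverage(frags[c], layout, bin_size) for c in ("WT", "KO")}
        for cond in ("WT", "KO"):
            w.write(stage, f"coverage_{cond}.bedGraph",
                    lambda p, c=cond: io.write_bedgraph(cov[c], p))
        fc = lesion.normalize_and_ratio(cov["KO"], cov["WT"], pseudocount=1.0, scale="none")
        w.write(stage, "log2fc_KO_WT.bedGraph", lambda p: io.write_bedgraph(fc.track, p))
        top = lesion.select_quantile_bins(fc.track, quantile_fraction, "top")
        bottom = lesion.select_quantile_bins(fc.track, quantile_fraction, "bottom")
        sel_rows = [
            dict(tail=tail, chrom=c, bin=int(i))
            for tail, sel in (("top", top), ("bottom", bottom))
            for c, idx in sel.items() for i in idx
        ]
        w.write_tsv(stage, "quantile_bins.tsv", pd.DataFrame(sel_rows))

        # -- region enrichment ---------------------------------------------
        stage = "region-test"
        logger.info("[%s] landmark-region resampling tests (%d groups)", stage, n_groups)
        classes = region_class_intervals(config, layout)
        seed_region = int(np.random.SeedSequence([config.seed, 7001]).generate_state(1)[0] % (2**31))
        rows = []
        for name, regions in classes.items():
            null = resampling.sample_random_groups(
                layout, regions, n_groups=n_groups, seed=seed_region,
            )
            res = resampling.region_enrichment_test(fc.track, regions, null, layout)
            rows.append(_enrichment_row(name, res))
        enrich_df = pd.DataFrame(rows)
        w.write_tsv(stage, "region_enrichment.tsv", enrich_df)

        # -- metaprofile ----------------------------------------------------
        stage = "metaprofile"
        logger.info("[%s] A-B-A compartment metaprofile (R=%d)", stage, metaprofile_R)
        merged = metaprofile.merge_adjacent(compartments)
        seed_meta = int(np.random.SeedSequence([config.seed, 7002]).generate_state(1)[0] % (2**31))
        prof = metaprofile.build_metaprofile(
            comp_track, merged, n_bins=50, R=metaprofile_R, seed=seed_meta,
        )
        meta_df = pd.DataFrame(dict(
            position=np.arange(len(prof.mean)),
            mean=prof.mean, ci_low=prof.ci_low, ci_high=prof.ci_high,
        ))
        meta_df["n_triples"] = prof.n_triples
        w.write_tsv(stage, "metaprofile.tsv", meta_df)

        # -- repeats --------------------------------------------------------
        stage = "repeats"
        logger.info("[%s] repeat-family quantification and differential", stage)
        rep = config.repeat
        per_rep = {}
        for r in range(1, rep.n_replicates + 1):
            for cond in ("WT", "KO"):
                ip_map, _ = generate_read_family_map(config, cond, "ip", r)
                in_map, _ = generate_read_family_map(config, cond, "input", r)
                vec_ip = repeats.assign_fractional(ip_map)
                vec_in = repeats.assign_fractional(in_map)
                per_rep[(cond, r)] = repeats.family_log2fc(vec_ip, vec_in)
        fams = sorted(set().union(*[set(s.index) for s in per_rep.values()]))
        paired = pd.DataFrame(
            {("a", r): per_rep[("KO", r)].reindex(fams).fillna(0.0)
             for r in range(1, rep.n_replicates + 1)}
            | {("b", r): per_rep[("WT", r)].reindex(fams).fillna(0.0)
               for r in range(1, rep.n_replicates + 1)},
            index=fams,
        )
        seed_rep = int(np.random.SeedSequence([config.seed, 7003]).generate_state(1)[0] % (2**31))
        diff = repeats.family_differential(paired, seed=seed_rep)
        w.write_tsv(stage, "repeat_differential.tsv", diff, index=True)

        # -- mutations ------------------------------------------------------
        stage = "mutations"
        logger.info("[%s] cohort mutation statistics", stage)
        cg = pd.Series(cohort_truth["cg_content"], dtype=float)
        cohort = mutations.CohortMatrix.from_records(
            records, cg_content=cg, donors=cohort_truth["donors"],
        )
        solar = mutations.filter_solar_signature(mutations.validate_records(records))
        rates = mutations.gene_rates(solar, cohort, list(cohort.matrix.columns))
        w.write_tsv(stage, "gene_rates.tsv", rates.rename_axis("gene").reset_index())
        mutated, not_mutated = mutations.stratify_by_pathway(cohort)
        pairs = [(s.gene_a, s.gene_b) for s in config.cohort.pairs]
        bg = list(config.cohort.background_genes)
        if len(bg) >= 2:
            pairs.append((bg[0], bg[1]))
        cooc = mutations.cooccurrence(cohort, pairs)
        w.write_tsv(stage, "cooccurrence.tsv", cooc)
        # distances over the simulated gene territories
        terr = cohort_truth["territories"]
        seg = LabeledSegmentation(
            intervals=[GenomicInterval(c, s, e) for c, s, e in terr.values()],
            labels=list(terr.keys()),
        )
        dist = mutations.distance_to_landmark(seg, layout)
        w.write_tsv(stage, "gene_landmark_distance.tsv",
                    dist.rename_axis("gene").reset_index())

        # -- telomere + qPCR ------------------------------------------------
        stage = "telomere"
        logger.info("[%s] telomere content and qPCR calculators", stage)
        est = telomere.count_telomeric_reads(reads)
        gcn = telomere.gc_normalized_content(reads)
        fc_t, se_t = telomere.qpcr_telomere_ratio(panel, "KO", "WT")
        inh, se_i = telomere.percent_inhibition(panel, "TERT")
        telo_df = pd.DataFrame([
            dict(metric="telomeric_reads", value=est.telomeric_read_count),
            dict(metric="total_reads", value=est.total_reads),
            dict(metric="gc_window_reads", value=gcn.gc_window_read_count),
            dict(metric="content_per_million", value=gcn.content_per_million),
            dict(metric="qpcr_fold_change_KO_vs_WT", value=fc_t),
            dict(metric="qpcr_fold_change_se", value=se_t),
            dict(metric="percent_inhibition_TERT", value=inh),
            dict(metric="percent_inhibition_se", value=se_i),
        ])
        w.write_tsv(stage, "telomere_qpcr.tsv", telo_df)

        # -- report ---------------------------------------------------------
        stage = "report"
        report = pd.concat([
            enrich_df.assign(section="region_enrichment"),
            cooc.assign(section="cooccurrence"),
        ], axis=0, ignore_index=True)
        w.write_tsv(stage, "report.tsv", report)
    except Exception:
        logger.error("stage %r failed", stage)
        raise

    outputs = {}
    for paths in w.files.values():
        for p in paths:
            outputs[str(p.relative_to(out_dir))] = sha256_file(p)
    manifest = RunManifest(
        command_line=" ".join(sys.argv),
        seed=config.seed,
        config_hash=config_hash(config),
        package_version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs=outputs,
        stages={s: [str(p.relative_to(out_dir)) for p in ps] for s, ps in w.files.items()},
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
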