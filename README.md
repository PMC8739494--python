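# uvsuscept

Analysis toolkit for genome-wide UV-lesion susceptibility: how loss of a
chromatin regulator (modelled on *RB1* knockout in human fibroblasts)
redistributes the propensity to acquire cyclobutane pyrimidine dimers
(CPDs) across the genome, and what that implies for melanoma mutation
patterns.

It is written for computational genomicists who have binned lesion or
ChIP signal, genome annotations (centromeres/telomeres, chromatin
states, Hi-C A/B compartments, repeat families) and somatic-mutation
tables, and want the complete statistical chain from aligned fragments
to calibrated enrichment calls — together with synthetic-data
generators that emulate every input with known ground truth, so the
whole pipeline is testable without any external download.

## What it computes

* **Susceptibility tracks** — midpoint-binned fragment counts per
  100-kb bin; log2 knockout/wild-type (or IP/input) fold-change tracks
  with optional library-size (cpm) scaling; extreme-quantile bin
  selections; per-chromatin-state aggregation with Mann–Whitney U tests
  against the genome median; Spearman track–track correlation.
* **Landmark-region enrichment** — for pericentric (±1 Mb around each
  centromere) and subtelomeric (100 kb at each chromosome end) regions:
  the observed median over overlapped bins is compared with 1,000
  groups of length-matched random regions.  The primary p-value is the
  add-one empirical p from the null distribution of group medians,

      p = (1 + #{ |M_i − c| ≥ |obs − c| }) / (n_groups + 1),  c = median(M),

  with a pooled-bin Mann–Whitney p reported alongside.  The same
  machinery drives the observed/expected χ² for binding-site overlap
  with extreme deciles and cumulative excision-repair (XR-seq-style)
  time courses.
* **Compartment metaprofiles** — adjacent same-label A/B compartments
  merged, every A–B–A triple rescaled to 3×50 meta-bins (meta-bin =
  median of member bins), positionwise mean over triples with a
  percentile-bootstrap 95% CI (R = 1,000, order-statistic convention).
* **Repeat families** — multi-mapping reads divided equally amongst
  candidate families (a read hitting k families adds 1/k to each,
  conserving read mass), per-family cpm log2 fold changes, and a paired
  Wilcoxon + sign-flip permutation + Benjamini–Hochberg differential.
* **Mutation cohorts** — solar-signature filtering (C>T / G>A),
  mutation rates per C+G base per donor, RB1-pathway stratification
  (*RB1, CCND1, CCNE1, CDKN1A, CDKN1B, CDKN2A, CDKN2B*), per-genic-
  feature mutation fractions, pairwise co-occurrence with the 2×2 log2
  odds ratio OR = (n11·n00)/(n10·n01), two-sided Fisher exact p and BH
  q, and gene distance to the nearest centromere/telomere.
* **Telomere & qPCR** — reads containing ≥7 consecutive TTAGGG (or
  CCCTAA) motifs; GC-window-normalised content per million reads;
  ΔΔCq telomere ratio FC = 2^(−ΔΔCq) and UV-interference percent
  inhibition (1 − 2^(−X))·100, both with first-order error propagation.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (`python analysis/01_simulate_inputs.py` first, then the rest in
order; outputs land in `results/`).  With the default configuration —
two 10-Mb chromosomes, 100-kb bins, Poisson base rate 50 fragments per
bin, and a 1.5× pericentric/subtelomeric susceptibility gain in the
knockout — `analysis/03_landmark_enrichment.py` prints:

```
pericentric: median log2FC +0.681 vs null +0.154+-0.104 -> enriched, empirical p=0.000999
subtelomeric: median log2FC +0.431 vs null +0.145+-0.166 -> enriched, empirical p=0.06294
binding sites vs top decile: observed 10 vs expected 50.0, chi2=35.6, p=2.48e-09
```

The pericentric median log2 fold change (+0.68 over 44 bins) exceeds
every one of the 1,000 random-region group medians, giving the smallest
attainable empirical p (1/1001); the subtelomeric effect rests on only
4 bins and is not resolved at this genome size.  Binding sites
simulated 5× depleted from the top-decile bins are recovered as
strongly depleted by the χ² test.  `analysis/04_compartment_metaprofile.py`
reports the closed/open compartment step:

```
18 A-B-A triples; central-B mean 75.2, outer-A mean 50.1 (B/A ratio 1.50)
```

recovering the generator's 1.5× closed-compartment signal ratio, and
`analysis/06_mutation_cohort.py` recovers the planted co-occurrence in
a 1,000-donor cohort:

```
TERT x TPTE: log2OR=+1.78, q=1.17e-10 -> co-occurring
```

The same chain is available as a CLI (`suscept bin`, `suscept ratio`,
`suscept region-test`, `suscept metaprofile`, `suscept mutations
cooccur`, `suscept qpcr inhibition`, ... and `suscept
reproduce-synthetic` for the end-to-end run with a manifest of output
digests).

## Layout

```
src/uvsuscept/     library: genome model, io, lesion, resampling,
                   metaprofile, repeats, mutations, telomere,
                   simulate, pipeline, evaluation, cli
analysis/          numbered narrative drivers (01_simulate_inputs ...)
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    models, statistics, and design choices in detail
```
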