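# Methods

This note documents the models and statistics implemented in
`uvsuscept`, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical conventions and
design choices made where several reasonable options existed.

## Coordinate frame and tracks

All coordinates are 0-based half-open (BED convention), chosen because
every external format the pipeline touches is BED-family.  A
`GenomeLayout` carries ordered chromosome lengths, one centromere
interval per chromosome, and telomeres as the two end anchors
(positions 0 and *L*) rather than intervals — the subtelomeric
definition (the 100 kb adjacent to each end) needs only the ends.
Pericentric regions are the ±1 Mb flanks of the centromere, excluding
the centromere body itself; both flanks are clipped to chromosome
bounds.

A `BinnedTrack` holds one float array per chromosome with
`ceil(L / bin_size)` entries; NaN marks unmappable bins and propagates
through every ratio and correlation (pairwise-complete semantics).  The
last bin may be partial; it is retained, and anything rate-like uses
its actual covered width.  Fragments are point events for our purposes
(lesion immunoprecipitation marks a single dimer), so `bin_coverage`
assigns each fragment to the bin containing its midpoint — this gives
the exact conservation law Σ bins = n fragments, which the tests rely
on.  A bp-overlap weighting could be added but is not currently
implemented.

Fold-change tracks are `log2(a_scaled + pc) − log2(b_scaled + pc)`
computed as a *difference of logs* so that swapping numerator and
denominator negates every value bit-exactly.  `scale="cpm"` divides
each track by its total/1e6 first; the default pseudocount is 1.  For
knockout/wild-type lesion comparisons on simulated data the analysis
scripts use raw counts (`scale="none"`): the generator emits
depth-matched per-bin rates, and rescaling by library totals would
reintroduce composition bias (the enriched pericentric bins inflate
the knockout total and shrink the measured effect — the same reasoning
that leads RNA-seq methods away from total-count normalisation under
asymmetric change).  cpm remains the default for ChIP IP/input ratios,
where library-size differences are real and must be removed.

Quantile selections take exactly `round(f · n_nonmissing)` bins; ties
at the threshold break deterministically by genome order (chromosome
order, then bin index).  Bins meet sub-bin chromatin-state intervals by
majority coverage, ties going to the label whose covering interval
starts first.  State summaries report n, median, quartiles, a
two-sided Mann–Whitney U p against all nonmissing genome bins, and the
median scaled by the genome median for heatmap display.

## Dinucleotide content

CPDs form between adjacent pyrimidines on either strand, so
dipyrimidine frequencies are double-stranded: each plus-strand
occurrence of TT/TC/CT/CC *or of its reverse complement* (AA/GA/AG/GG)
counts, over a denominator of twice the number of valid dinucleotide
windows.  Windows containing N are excluded from numerator and
denominator alike; a region with no valid window yields a missing
value, not zero.

## Random-region enrichment

The landmark question — is signal elevated in pericentric/subtelomeric
bins? — is answered against `n_groups` (default 1,000) control groups,
each matching the query in region count and per-region lengths.  Three
conventions matter and each was validated by simulation:

* **Sampling.**  A chromosome is drawn with probability proportional
  to its feasible-start count net of the exclusion set, then a start
  uniform over the feasible positions.  This is implemented as an exact
  draw over the feasible-start runs (equivalent in distribution to
  rejection sampling, but a single feasible slot is found
  deterministically and only true infeasibility errors).
* **No exclusion by default.**  Control regions may land anywhere,
  including on the query.  Excluding the query from control placement
  looks natural but breaks exchangeability: the observed group is then
  never part of the null population, the control medians cluster
  relative to it, and the type-I error inflates (measured 0.09–0.12 at
  α = 0.05 on this package's calibration genomes).  With no exclusion
  the observed group is exchangeable with the controls under a
  homogeneous null.  An exclusion list (e.g. assembly gaps) can still
  be supplied.
* **Empirical p.**  The primary p-value is add-one and two-sided around
  the null centre: `p = (1 + #{|M_i − c| ≥ |obs − c|})/(n_groups + 1)`
  with `c` the median of the group medians.  It can never be 0, equals
  1 for a constant track, and reaches its floor `1/(n_groups+1)` when
  the observation is beyond every control.  A Mann–Whitney p of the
  selected bin values against the pooled control bin values is reported
  alongside but treated as secondary: pooling overstates the effective
  sample size.

Calibration, measured over 500 simulated null genome pairs (two 10-Mb
chromosomes, 100-kb bins, Poisson rate 50, 200 groups, the test run on
the log2 KO/WT track): rejection 0.034 at α = 0.05 and 0.078 at
α = 0.10 — slightly conservative, the residual being tie mass in
medians over small bin sets.  Note that calibration on a *raw count*
track is substantially more conservative because medians of integer
counts are half-integers and the ≥ tie convention counts every tie;
the fold-change track is the statistic the landmark comparisons
actually use.

The observed/expected binding-site test assigns peaks to bins by
midpoint (consistent with fragment counting); under no association the
expected in-selection count is `n_peaks · |selected|/|all|`, and a
one-degree-of-freedom χ² compares the (inside, outside) counts.  A
warning is raised when an expected cell drops below 1.

Excision-repair time courses average replicate/strand tracks within
each timepoint, prefix-sum across timepoints (each cumulative track is
the sum of itself and all earlier ones), and apply the region test per
cumulative track.

## Compartment metaprofile

Adjacent same-label compartments merge by run-length encoding per
chromosome (gaps between same-label neighbours are swallowed — this is
what makes the track dense and strictly alternating, which the triple
construction requires).  Every closed (B) compartment flanked by open
(A) compartments on both sides forms a triple; chromosome-terminal
compartments without both flanks are dropped.  Each member compartment
is rescaled to 50 meta-bins: 50 equal sub-intervals, meta-bin value =
median of the track bins whose midpoints fall inside, empty meta-bins
filled from the nearest nonempty neighbour.  The profile is the
positionwise mean over triples (median within meta-bins, mean across
triples — both statistics deliberately retained).

The 95% CI is a positionwise percentile bootstrap over R = 1,000
resamples of triples with replacement, using the order-statistic
convention (the ⌊(R+1)·0.025⌋-th and ⌈(R+1)·0.975⌉-th sorted resample
means).  Interpolated quantiles give intervals that are too narrow at
moderate R: with 30 triples and R = 200 the measured positionwise
coverage was 0.927 interpolated versus 0.939 with order statistics
(nominal 0.95; percentile bootstraps undercover slightly at small n —
BCa was deliberately not used, to stay with the plain bootstrap the
profile is defined with).  The coverage study uses 30 triples per
genome with compartments exactly 50 track bins wide, so the
generator's true positionwise mean is the Poisson rate itself; real
compartment tracks yield hundreds of triples, where coverage only
improves.

## Repeat families

The input is a read → candidate-family map (the product of a
two-pass pseudo-genome alignment, which is out of scope here).  A read
mapping to k families contributes 1/k to each — equal division, since
no weighting is defined — so family counts plus unassigned reads equal
total reads to 1e−9.  Family differentials between paired replicate
groups use the signed-rank statistic, a two-sided sign-flip
permutation p (exhaustive enumeration for ≤ 10 nonzero pairs, where
the p-value is the exact flip fraction; add-one Monte Carlo with
10,000 flips otherwise), and BH across families.  This chain is the
defined statistic here; it replaces, and is not numerically concordant
with, count-model dispersion estimation on repeat counts.

## Mutation cohort

Solar-signature filtering keeps C>T and G>A records.  The gene
mutation rate is (# qualifying records in the gene across the cohort)
/ (C+G base content × n donors); the C+G territory is an explicit
input because no window definition is imposed.  Donors split into
RB1-pathway mutated vs not by an any-gene OR over the seven pathway
genes.  Genic features (promoter, exon, ...) are taken from the input
annotation; no window sizes are imposed by this package.

Co-occurrence uses the 2×2 donor table per requested pair: log2 OR
with the Haldane–Anscombe 0.5 correction applied *only* when a cell is
0 (and flagged), two-sided Fisher exact p by hypergeometric
enumeration of tables at most as probable as the observed one, and BH
across the requested pair list only.  A degenerate column (gene
mutated in all or no donors) reports a missing OR with p = 1.  Calls:
co-occurring iff log2 OR > 0 with q below threshold; mutually
exclusive iff log2 OR < 0 with q below threshold.  Donor exclusions
(e.g. non-UV acral melanomas) are an input list, not a classifier.

Distance to the nearest landmark is the minimum over: gene start (to
the p-end anchor), chromosome length − gene end (q-end), and the gap
to the nearer centromere boundary (0 if the gene overlaps the
centromere).

## Telomere content and qPCR

A read is telomeric iff it contains ≥ k = 7 consecutive exact copies
of TTAGGG or of CCCTAA — no mismatch tolerance, and variant repeats
are out of scope.  GC normalisation divides the telomeric count by the
number of reads whose GC fraction (G+C over non-N length) lies in
[0.48, 0.52] — a configurable window, defaulting to the canonical
telomere-repeat GC content of 50% — and scales to per-million.

qPCR: ΔCq per sample = mean Cq(telo) − mean Cq(control); ΔΔCq =
ΔCq(test) − ΔCq(ref); FC = 2^(−ΔΔCq).  SE(ΔΔCq) is the quadrature sum
of the four cell SEMs (independent errors), pushed through the
exponential by the first-order delta method: SE(FC) = FC·ln2·SE(ΔΔCq).
The UV-interference assay computes D_c = mean Cq(control) − mean
Cq(target) within each of −UV/+UV, X = D(−UV) − D(+UV), and percent
inhibition (1 − 2^(−X))·100.  The sign convention makes
lesion-blocked target amplification (higher target Cq after UV) give
X > 0 and positive inhibition; X = 1 → 50%, X = 2 → 75%.

## Synthetic-data generators

Every generator is a pure function of (config, seed) — per-stage seed
sequences keyed on the stage name make stages independent and
byte-reproducible — and each emits a truth sidecar for recovery tests.
Defaults describe the emulated study:

* **Genome**: two 10-Mb chromosomes; centromere midpoint at fraction
  0.487 of the chromosome, width 150 kb.  The placement is
  deliberately *not* aligned to 100-kb bin boundaries: real assembly
  gap coordinates never align to analysis bins, and an aligned
  landmark covers systematically fewer bins than unaligned random
  controls, which distorts bin-overlap statistics.
* **Lesions**: Poisson counts per 100-kb bin, base rate 50, fragments
  uniform within the bin (optionally TpT-density-weighted against a
  generated sequence); knockout multipliers 1.5× in pericentric and
  subtelomeric bins.  Poisson rather than negative binomial by
  default, so calibration studies have a clean null; overdispersion
  would widen the null spread that the random-region test resamples,
  not bias it.
* **ChIP**: per-chromatin-state IP enrichment over a uniform input for
  two heterochromatin marks.
* **Compartments**: alternating fixed-length A/B segments (500 kb = 50
  × 10-kb bins) with a 1.5× closed/open rate ratio.
* **Cohort**: for each targeted gene pair the donor indicators come
  from the exact bivariate Bernoulli solved from (p_A, p_B, OR) via
  the Plackett quadratic — exact cell probabilities, so recovery
  tolerances can be tight; untargeted genes are independent Bernoulli;
  each mutated donor-gene yields one record, solar with probability
  0.8, placed uniformly in a deterministic gene territory.
* **Telomere reads**: pure tandem TTAGGG repeats at random phase (half
  reverse-complemented) against i.i.d. background bases at GC 0.5;
  default telomeric fraction 0.001.
* **qPCR**: truth Cq + Gaussian(0, 0.1) per replicate, 3 replicates
  (the emulated assays use 2–3 biological × 3 technical replicates).

What the generators do *not* emulate: sequencing error, mappability
and GC bias, alignment ambiguity beyond the read→family map,
overdispersion (available but off), correlated mutation signatures
beyond the targeted pairs, and telomere variant repeats.  Passing
tests therefore demonstrate correctness and calibration of the
statistical machinery under idealised counts — not robustness to the
artefacts real libraries carry.

## Validation studies and problem sizes

`uvsuscept.evaluation` (shared by the acceptance tests and
`scripts/acceptance.py`) runs: type-I calibration (500 null genome
pairs, 200 groups), pericentric recovery (50 replicates; detection at
empirical p ≤ 0.01 and median log2 FC vs log2 1.5), Fisher-vs-
enumeration over all 164,175 2×2 tables with margins ≤ 30, planted
co-occurrence recovery (100 cohorts of 1,000 donors), bootstrap
coverage (1,000 genomes at R = 200), the 1.5× metaprofile step, exact
counters on ≥10,000 reads/records, the closed-form qPCR identities,
the BH step-up oracle (1,000 vectors), and a byte-identity check of
two full pipeline runs.  These sizes complete in about four minutes on
one CPU while leaving Monte-Carlo error well inside the validation
bands.

## Known limitations

* The empirical p is slightly conservative on heavily tied statistics
  (medians of small integer-count bin sets); use fold-change or other
  near-continuous tracks where possible.
* Landmark queries covering a large fraction of a (small synthetic)
  genome weaken the exchangeability argument; on real genomes the
  landmark classes are a few percent of bins.
* The subtelomeric test on the default synthetic genome rests on 4
  bins and has little power — as the worked example shows honestly.
* No GC- or mappability-matched controls (plain shuffle-style nulls
  only), no MACS2-style background model, no liftover.
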