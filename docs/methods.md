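# Methods

This note documents the models, parameter choices and numerical decisions
behind `cnloh`, and what the synthetic-data studies do and do not show
about real arrays.

## Copy-number model

The per-probe statistic is the log2 ratio of the tumor's total allele
signal to the reference panel's total, `log2((S_a+S_b)/(R_a+R_b))`. The
ratio is invariant to probe-specific brightness as long as sample and
reference share normalization; all intensities are therefore taken as
already normalized (quantile normalization of raw arrays is upstream of
this package). Values below the floor (−4 log2 units, default) are set to
the floor so homozygous deletions at zero signal remain finite.

Smoothing uses a Gaussian kernel in physical distance, σ = 100 kb,
truncated at 3σ and never crossing chromosome boundaries:
`smoothed_i = Σ_j w_ij raw_j / Σ_j w_ij`, `w_ij = exp(−d_ij²/2σ²)`. With
~12 kb probe spacing the kernel averages ~17 effective probes, shrinking
per-probe noise of 0.2 to ~0.04 — which is what makes an attenuated loss
(e.g. −0.415 at 50 % contamination) reliably callable at the 0.3
threshold.

### Run calling and boundary placement

Losses and gains are maximal runs of **more than 20** contiguous probes
(≥ 21) whose smoothed value is at or beyond ±0.3; both bounds are
inclusive readings of the published rule, and a single sub-threshold probe
breaks a run (an optional merge of same-direction runs separated by ≤ 2
probes exists behind `CNParams.merge_gap_probes`, off by default).

Detection on the smoothed track has a known geometric artifact: the
smoothed value crosses the threshold where the kernel mass over the event
reaches τ/|depth|, i.e. ~Φ⁻¹(0.7)·σ ≈ 52 kb ≈ 4–5 probes *outside* a
deep-loss edge, regardless of noise. We therefore place boundaries with a
half-amplitude rule (`CNParams.refine_boundaries`, on by default): each
run end is trimmed to the first probe whose **raw** value lies beyond half
the run's mean smoothed amplitude. Inside a true event the raw values sit
near the full amplitude, so trimming stops at the true edge; outside, raw
values near zero are trimmed away. Measured on planted 50-probe losses
(noise sd 0.2), this places both boundaries within ±5 probes in the large
majority of seeded replicates, where unrefined runs carry the systematic
4–5 probe overshoot (the on/off comparison is part of the test suite),
while detection — and hence sensitivity to attenuated events — still
happens on the smoothed track. Calling on the raw track instead would fix
attenuated events entirely (a −0.415 loss at noise 0.2 essentially never
yields 21 consecutive raw values ≤ −0.3), which is why the hybrid is the
design.

Whole-chromosome calls use an inclusive ≥ 0.9 probe-coverage fraction.
Loss segments whose mean is ≤ −1.0 are annotated as candidate homozygous
deletions during integration; the published analyses report such events
without a numeric rule, so the threshold is a package parameter.

## LOH model

LOH is inferred without a matched normal. States are retention (0) and
LOH (1). Emissions use the het/hom dichotomy only: P(AB | LOH) = ε = 0.02
(the genotyping error), P(AB | retention) = h_i, the reference panel's
SNP-wise heterozygosity rate (a flat 0.3 is available via
`use_snp_het_rates=False`; SNP-specific rates are the default because the
panel carries them). Emissions are floored at 1e−12 so degenerate
h_i ∈ {0, 1} cannot produce zeros.

Transitions between adjacent SNPs at distance d are
`P(s→s') = π_{s'} + e^{−d/D}(1{s=s'} − π_{s'})` with decay D = 10 Mb: the
identity at d → 0 and the stationary vector at d → ∞. The stationary LOH
probability π_LOH defaults to 0.5 (uninformative) since no published
value exists; decoding of clearly heterozygous tracts is insensitive to it
across 0.1–0.9 (tested). Posteriors come from the scaled forward–backward
recursion; hard states are posterior > 0.5, with Viterbi available behind
a flag. Correctness is pinned to an exhaustive 2ⁿ path-enumeration oracle
(≤ 12 SNPs, 1e−9 agreement).

No-calls are removed before decoding; distances are computed between the
retained SNPs, which the distance-decay model absorbs naturally.

### Fragment gating

Maximal decoded LOH runs become reported segments only if all three hold:
≥ 20 markers, LOH score > 50, het rate < 0.07 (AB / all calls; strict).
The three gates are conjunctive. The LOH score multiplies reference
homozygosity rates over the *homozygous-called* SNPs of the fragment
(heterozygous calls, allowed up to the het-rate limit, do not
contribute), making the score exactly −log10 of the null probability that
the observed homozygous calls arise by chance; it is computed in log
space.

### LOH boundary refinement

Decoded state runs lag at boundaries: an erroneous AB call just inside a
region delays the switch, and homozygous runs just outside extend it.
With `LOHParams.refine_boundaries` (default on), each run end is
re-estimated as the maximum-likelihood changepoint of the per-SNP
log-likelihood ratios (CUSUM argmax in a 50-marker window), dropping the
transition penalty from the boundary estimate. This is the efficient
estimator for a single changepoint; the residual error is
information-limited, because stretches of low-MAF SNPs contribute only
~0.08 nats of boundary evidence per marker (log(0.98/(1−h)) at h ≈ 0.1),
so no estimator can localize a boundary to a fixed marker tolerance with
arbitrarily high reliability under a U(0.05, 0.5) MAF panel. Measured on
planted 400-marker CNN-LOH regions, both boundaries land within ±10
markers in roughly nine out of ten seeded replicates (the replicate study
is part of the test suite), and fully normal samples produce zero LOH
segments in every replicate.

## Event integration

CN and LOH segments of one tumor pair when their overlap covers ≥ 50 % of
the shorter interval — a reciprocal-overlap surrogate for the by-eye
pairing used in the original analyses; paired events take the union of
bounds. LOH without qualifying CN overlap is CNN_LOH. WCL/WCG flags
absorb same-direction interval segments (and, for WCL, the chromosome's
LOH segments) into a single chromosome-level event so cohort frequencies
never double-count; WCL becomes WCL_LOH when the absorbed LOH covers at
least half the chromosome's extent. Artifact flagging (mask overlap, or
median inter-probe gap > 500 kb inside a segment) marks segments in
regions of poor probe density or near centromeres but never removes them;
cohort counts exclude flagged events only on request.

## Cohort statistics

The minimal region of overlap generalizes pairwise interval intersection:
intervals are merged per tumor (so split intervals from one tumor count
once), a sweep line accumulates coverage over endpoints, and all regions
tied at maximal coverage are returned in coordinate order — for exactly
two intervals this is their intersection. Open-ended "qter" intervals
resolve through a chromosome-length table; without one, the last probe
position stands in for qter. Frequencies count a tumor once per
(region, event-type) regardless of multiplicity; stages accept arabic or
roman numerals but unknown labels are never silently merged. Without an
arm-boundary table, whole chromosomes are the aggregation unit.

## Synthetic data: what it emulates and what it does not

The generator emulates a 250K-style array: SNP positions from a Poisson
process with 12 kb mean spacing; MAF ~ U(0.05, 0.5) with Hardy–Weinberg
heterozygosity h = 2p(1−p); reference allele-signal means splitting a
constant total by allele frequency. Tumors mix event-bearing cells
(fraction (1−c)·f) with background cells; expected total signal scales by
the cell-mixture copy-number average, allele signals split by mixture
dosage, and independent log-normal noise (sd 0.2 on the log2 scale,
preserving positivity) multiplies each allele signal. Genotypes come from
a caller surrogate — AB when the minor-allele signal fraction exceeds
0.25, NC at zero total signal — followed by a 2 % hom↔AB error flip, so
contaminating normal cells can genuinely restore AB calls inside LOH, and
a tetraploid background (ploidy 4) attenuates both the CN signal
(single-copy loss → log2(3/4)) and the LOH signal (a (2,1) allele state
still reads AB), as observed in real heterogeneous tumors.

Not modeled: GC/wave intensity artifacts, allele cross-hybridization,
probe-level outliers, linkage disequilibrium between SNPs, and subclonal
mixtures of more than one event-bearing population. Passing recovery
tests therefore demonstrate the pipeline's statistical behaviour under
clean mixture assumptions, not robustness to array-specific systematics.

### Default study sizes

Replicate studies use one chromosome of 500 probes (CN recovery;
50-probe planted losses) or 1200 SNPs (LOH recovery; 400-marker planted
regions) per seed, 100 seeds — large enough that every planted event is
surrounded by ample normal territory while keeping a full replicate study
in seconds. Cohort sampling checks use hundreds of small-genome tumors.
All generators are `numpy` `default_rng`-seeded; a fixed seed reproduces
byte-identical TSV output.

## Known limitations

* Boundary precision of LOH calls is information-limited in low-MAF
  stretches (see above); reported bounds are marker positions, not
  breakpoint estimates.
* The unpaired LOH model cannot distinguish true LOH from long germline
  runs of homozygosity; the score gate (> 50) makes chance runs
  astronomically unlikely under the panel but consanguinity violates the
  panel model.
* Copy-number calling assumes a dominant clone; complex subclonal
  mixtures shift log ratios continuously and may fall below threshold.
* Chromosome lengths (for "qter") must be supplied for coordinates beyond
  the last probe; no genome build is assumed or bundled.
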