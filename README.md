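# cnloh

Copy-number and loss-of-heterozygosity (LOH) analysis for SNP genotyping
arrays of heterogeneous tumors, built for the classic unpaired 250K-array
workflow used in pediatric-tumor (e.g. Wilms tumor) genomics: no matched
normal DNA is required, and copy-neutral LOH — invisible to plain CGH — is
detected directly from the genotype calls.

## Who it is for

Anyone with per-SNP allele-signal summaries and genotype calls
(BRLMM-style output) for tumor samples, plus a reference panel of normal
individuals, who wants reproducible segment calls, typed per-tumor events,
and cohort-level recurrence statistics. A synthetic-data generator plants
fully known losses, gains, homozygous deletions, CNN-LOH and
whole-chromosome events in simulated heterogeneous tumors, so the whole
chain is testable without any array data.

## The method

**Copy number.** Per SNP *i*, with sample allele signals S and reference
panel means R,

    log2ratio_i = log2( (S_a,i + S_b,i) / (R_a,i + R_b,i) )

The track is smoothed along the genome with a Gaussian kernel
(σ = 0.1 Mb), and losses/gains are called as runs of more than 20
contiguous probes with smoothed |log2| ≥ 0.3. Run ends are then trimmed to
the first probe whose raw value passes half the run's mean amplitude
(half-amplitude edge placement), which removes the boundary overshoot that
kernel smoothing otherwise causes. Chromosomes with ≥ 90 % of probes in
same-direction segments are whole-chromosome losses/gains (WCL/WCG).

**LOH.** A two-state HMM (retention / LOH) runs over the genotype calls of
each chromosome. A heterozygous call has probability ε = 0.02 (genotyping
error) under LOH and probability h_i (the panel's SNP-wise heterozygosity
rate) under retention; transitions between SNPs at distance *d* relax
toward the stationary distribution as exp(−d/D) with D = 10 Mb. Decoded
LOH runs are reported only if they have ≥ 20 markers, observed het rate
(AB/all calls) < 0.07, and LOH score > 50, where

    LOH score = −log10 Π_i hom_rate_i   (over homozygous calls)

is the chance that the homozygous stretch arises by luck in the reference
population.

**Integration and cohorts.** CN and LOH segments pair by reciprocal
overlap (≥ 50 % of the shorter interval) into typed events — CNA_loss_LOH,
CNA_loss, CNN_LOH, CNA_gain(_LOH), WCL(_LOH), WCG, homozygous_deletion —
and cohorts aggregate into minimal regions of overlap (MRO, the
maximal-coverage interval of the per-tumor coverage function), event
frequencies by stage/histology, and karyotype-complexity summaries.

## Worked example

```
$ python examples/04_cohort_mro.py
chr11 MRO: 102077451-125002355  support=2 (GOS128, GOS370)
```

Intersecting an 11q deletion spanning 102,077,451–qter with one spanning
66,706,205–125,002,355 localizes the shared (candidate driver) interval to
chr11:102,077,451–125,002,355, carried by both tumors.

```
$ python examples/02_loh_hmm.py
planted: cnn_loh chr1:4359406-8720342 (400 markers)
called : LOH chr1:4373466-8769919  n_markers=399  score=78.7  het_rate=0.023
```

The planted 400-marker copy-neutral LOH region is recovered with its score
(78.7 ≫ 50: the homozygous stretch is wildly improbable by chance) and a
het rate of 0.023 (< 0.07), so it is reported as LOH.

The other examples (`examples/01_copy_number.py`,
`examples/03_event_integration.py`) demonstrate segment calling on a
planted 50-probe loss and the integration of CN with LOH into typed
events; each prints what it computed and what the numbers mean. The
`cnloh` console script exposes the same stages
(`simulate`/`cn`/`loh`/`integrate`/`cohort`/`run`/`mro`) for shell use.

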