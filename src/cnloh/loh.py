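"""Unpaired LOH detection from SNP genotype calls.

The method needs no matched normal.  A two-state hidden Markov model
(retention = 0, LOH = 1) runs along each chromosome over the called
genotypes.  Emissions compare the chance of a heterozygous call under each
state: in an LOH region a heterozygous call can only arise through genotyping
error (probability epsilon, default 0.02); in a retained region its
probability is the reference population's SNP-wise heterozygosity rate h_i
(or a flat 0.3 when SNP-specific rates are disabled).  Transitions relax
toward the stationary distribution with genomic distance d between adjacent
SNPs via exp(-d / D), D = 10 Mb by default, so the influence of a SNP's
state decays over about that scale.

Candidate LOH fragments (maximal runs of decoded LOH states) are then gated
by three conjunctive rules before being reported:

* at least 20 markers;
* LOH score > 50, where the score is -log10 of the probability that the
  observed homozygous calls arise by chance in the reference population
  (the product of the reference homozygosity rates);
* observed het rate (AB calls / all calls) < 0.07.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LOHSegment, ProbeMap, ReferencePanel, SampleArray

EMISSION_FLOOR = 1e-12


@dataclass(frozen=True)
class LOHParams:
    """Tunable parameters of the LOH caller (defaults are the method's
    published operating point).

    epsilon
        Genotyping error rate: probability of an AB call inside true LOH.
    decay_bp
        Transition decay distance D in bp (10 Mb).
    score_threshold
        Minimum LOH score; fragments must exceed it strictly (> 50).
    het_rate_threshold
        Maximum observed het rate; strict (< 0.07).
    normal_het_rate
        Flat heterozygosity rate used when ``use_snp_het_rates`` is False.
    min_markers
        Minimum markers per reported fragment (20, inclusive).
    pi_loh
        Stationary/initial probability of the LOH state (uninformative 0.5).
    use_snp_het_rates
        Use the panel's SNP-wise h_i in emissions (default) rather than the
        flat ``normal_het_rate``.
    viterbi
        Decode hard states with Viterbi instead of posterior > 0.5.
    refine_boundaries
        Decoded state runs place boundaries with a lag: an erroneous AB call
        just inside a true LOH region delays the switch, and homozygous runs
        just outside extend it.  When enabled (default), each end of a
        candidate fragment is re-estimated as the maximum-likelihood
        changepoint of the per-SNP log-likelihood ratios (a CUSUM argmax in
        a window of ``refine_window`` markers around the decoded end),
        which drops the transition penalty from the boundary estimate.
    refine_window
        Half-width, in markers, of the changepoint search window.
    """

    epsilon: float = 0.02
    decay_bp: float = 10_000_000.0
    score_threshold: float = 50.0
    het_rate_threshold: float = 0.07
    normal_het_rate: float = 0.3
    min_markers: int = 20
    pi_loh: float = 0.5
    use_snp_het_rates: bool = True
    viterbi: bool = False
    refine_boundaries: bool = True
    refine_window: int = 50

    def __post_init__(self):
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if self.decay_bp <= 0:
            raise ValueError("decay_bp must be > 0")
        if self.score_threshold <= 0 or self.het_rate_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0.0 < self.pi_loh < 1.0:
            raise ValueError("pi_loh must be in (0, 1)")


@dataclass
class LOHStateTrack:
    """Per-SNP posterior probability of LOH and decoded hard states
    (1 = LOH, 0 = retention), parallel to the input SNP order."""

    posterior_loh: np.ndarray
    hard_state: np.ndarray


def _emission_matrix(genotypes: np.ndarray, het_rates: np.ndarray,
                     params: LOHParams) -> np.ndarray:
    """Per-SNP emission likelihoods, shape (n, 2) for states
    (retention, LOH).  Only the het/hom dichotomy matters."""
    if np.any(genotypes == "NC"):
        raise ValueError("no-calls must be removed before decoding")
    is_ab = genotypes == "AB"
    h = het_rates if params.use_snp_het_rates else np.full(
        len(genotypes), params.normal_het_rate)
    e = np.empty((len(genotypes), 2))
    e[:, 0] = np.where(is_ab, h, 1.0 - h)
    e[:, 1] = np.where(is_ab, params.epsilon, 1.0 - params.epsilon)
    return np.maximum(e, EMISSION_FLOOR)


def _transition_matrices(positions: np.ndarray, params: LOHParams) -> np.ndarray:
    """Per-gap 2x2 transition matrices between adjacent SNPs.

    P(s -> s') = pi_{s'} + exp(-d/D) * (1{s = s'} - pi_{s'})

    At d -> 0 this is the identity; at d -> inf it collapses to the
    stationary vector (1 - pi_loh, pi_loh) in state order (retention, LOH).
    """
    d = np.diff(positions.astype(float))
    if np.any(d <= 0):
        raise ValueError("positions must be strictly increasing")
    pi = np.array([1.0 - params.pi_loh, params.pi_loh])
    decay = np.exp(-d / params.decay_bp)  # shape (n-1,)
    eye = np.eye(2)
    # T[k, s, s'] = pi[s'] + decay[k] * (eye[s, s'] - pi[s'])
    return pi[None, None, :] + decay[:, None, None] * (eye[None, :, :] - pi[None, None, :])


def hmm_decode(genotypes, positions, het_rates,
               params: LOHParams = LOHParams()) -> LOHStateTrack:
    """Decode LOH versus retention along one chromosome.

    Parameters are per-SNP arrays ordered by strictly increasing position;
    no-calls must already be removed.  Posteriors come from the scaled
    forward-backward recursion; hard states are posterior > 0.5 (or the
    Viterbi path when ``params.viterbi``).
    """
    genotypes = np.asarray(genotypes, dtype=object).astype(str)
    positions = np.asarray(positions)
    het_rates = np.asarray(het_rates, dtype=float)
    n = len(genotypes)
    if n == 0:
        raise ValueError("empty genotype vector")
    if not (len(positions) == len(het_rates) == n):
        raise ValueError("genotypes, positions and het_rates must align")

    e = _emission_matrix(genotypes, het_rates, params)
    pi = np.array([1.0 - params.pi_loh, params.pi_loh])
    if n == 1:
        post = pi * e[0]
        post /= post.sum()
        hard = (post[1] > 0.5).astype(int) if not params.viterbi else \
            np.array([int(np.argmax(pi * e[0]))])
        return LOHStateTrack(np.array([post[1]]),
                             np.atleast_1d(np.asarray(hard, int)))

    trans = _transition_matrices(positions, params)

    # scaled forward-backward
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    a = pi * e[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ trans[t - 1]) * e[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        b = trans[t] @ (e[t + 1] * beta[t + 1])
        beta[t] = b / scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    posterior_loh = post[:, 1]

    if params.viterbi:
        hard = _viterbi(e, trans, pi)
    else:
        hard = (posterior_loh > 0.5).astype(int)
    return LOHStateTrack(posterior_loh, hard)


def _viterbi(e: np.ndarray, trans: np.ndarray, pi: np.ndarray) -> np.ndarray:
    n = len(e)
    logv = np.log(pi) + np.log(e[0])
    back = np.zeros((n, 2), dtype=int)
    for t in range(1, n):
        cand = logv[:, None] + np.log(trans[t - 1])
        back[t] = np.argmax(cand, axis=0)
        logv = cand[back[t], [0, 1]] + np.log(e[t])
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(logv))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t][path[t]]
    return path


def loh_score(genotypes, hom_rates) -> float:
    """LOH score of a fragment: -log10 of the probability that its
    homozygous calls arise by chance given reference homozygosity rates.

    Computed in log space as the sum of -log10(hom_rate_i) over SNPs with
    homozygous calls (AA/BB); heterozygous calls inside the fragment do not
    contribute.  hom_rate = 0 contributes through the emission floor.
    """
    genotypes = np.asarray(genotypes, dtype=object).astype(str)
    hom_rates = np.asarray(hom_rates, dtype=float)
    if len(genotypes) == 0:
        raise ValueError("empty fragment")
    if np.any(hom_rates > 1) or np.any(hom_rates < 0):
        raise ValueError("hom rates must be in [0, 1]")
    is_hom = (genotypes == "AA") | (genotypes == "BB")
    rates = np.maximum(hom_rates[is_hom], EMISSION_FLOOR)
    return float(-np.log10(rates).sum())


def het_rate(genotypes) -> float:
    """Observed heterozygosity rate: AB calls / all calls (AA+AB+BB).
    No-calls are excluded from numerator and denominator."""
    genotypes = np.asarray(genotypes, dtype=object).astype(str)
    called = genotypes[genotypes != "NC"]
    if len(called) == 0:
        raise ValueError("fragment has no called genotypes")
    return float((called == "AB").sum() / len(called))


def call_loh_segments(track: LOHStateTrack, genotypes, positions, hom_rates,
                      params: LOHParams = LOHParams(), *,
                      sample_id: str = "", chromosome: str = ""
                      ) -> list[LOHSegment]:
    """Turn decoded hard states into reported LOH segments.

    Maximal runs of hard state 1 become candidate fragments; a fragment is
    reported iff (markers >= min_markers) AND (score > score_threshold) AND
    (het rate < het_rate_threshold).  Bounds are the first/last SNP
    positions of the (optionally boundary-refined) run.
    """
    genotypes = np.asarray(genotypes, dtype=object).astype(str)
    positions = np.asarray(positions)
    hom_rates = np.asarray(hom_rates, dtype=float)
    hard = np.asarray(track.hard_state)
    out: list[LOHSegment] = []
    idx = np.flatnonzero(hard == 1)
    if len(idx) == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    runs = [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]
    if params.refine_boundaries:
        runs = _refine_runs(runs, genotypes, hom_rates, len(genotypes), params)
    for i0, i1 in runs:
        n_markers = i1 - i0 + 1
        if n_markers < params.min_markers:
            continue
        frag_gt = genotypes[i0:i1 + 1]
        score = loh_score(frag_gt, hom_rates[i0:i1 + 1])
        hr = het_rate(frag_gt)
        if score > params.score_threshold and hr < params.het_rate_threshold:
            out.append(LOHSegment(
                sample_id=sample_id, chromosome=chromosome,
                start_bp=int(positions[i0]), end_bp=int(positions[i1]),
                n_markers=n_markers, loh_score=score, het_rate_obs=hr))
    return out


def _refine_runs(runs: list[tuple[int, int]], genotypes: np.ndarray,
                 hom_rates: np.ndarray, n: int,
                 params: LOHParams) -> list[tuple[int, int]]:
    """Re-place run boundaries at the ML changepoint of the per-SNP
    log-likelihood ratio log P(g|LOH) - log P(g|retention).

    With end fixed, the best start maximizes the fragment LLR sum, i.e. it
    follows the minimum of the LLR prefix sums (CUSUM); symmetrically for
    the end.  The search window is ``refine_window`` markers around the
    decoded boundary and never crosses a neighbouring run.
    """
    is_ab = genotypes == "AB"
    het = np.maximum(1.0 - hom_rates, EMISSION_FLOOR)
    hom = np.maximum(hom_rates, EMISSION_FLOOR)
    llr = np.where(is_ab,
                   np.log(params.epsilon) - np.log(het),
                   np.log(1.0 - params.epsilon) - np.log(hom))
    cum = np.concatenate(([0.0], np.cumsum(llr)))  # cum[k] = sum llr[0:k]
    w = params.refine_window
    refined = []
    for k, (i0, i1) in enumerate(runs):
        prev_end = runs[k - 1][1] if k else -1
        next_start = runs[k + 1][0] if k + 1 < len(runs) else n
        s_lo = max(0, i0 - w, prev_end + 1)
        s_hi = min(i0 + w, i1)
        e_lo = max(i1 - w, i0)
        e_hi = min(n - 1, i1 + w, next_start - 1)
        # start s maximizes cum[e+1]-cum[s]  ->  minimize cum[s]
        s = int(s_lo + np.argmin(cum[s_lo:s_hi + 1]))
        e = int(e_lo + np.argmax(cum[e_lo + 1:e_hi + 2]))
        if e >= s:
            refined.append((s, e))
    return refined


def loh_segments_for_sample(sample: SampleArray, panel: ReferencePanel,
                            probe_map: ProbeMap,
                            params: LOHParams = LOHParams()
                            ) -> list[LOHSegment]:
    """Run HMM decoding and fragment gating chromosome by chromosome.

    No-call genotypes are removed before decoding; inter-SNP distances are
    then taken between the retained SNPs (the distance-decay transition
    model absorbs the gaps)."""
    samp = sample.aligned_to(probe_map)
    ref = panel.aligned_to(probe_map)
    gt_all = samp["genotype"].to_numpy(object).astype(str)
    het_all = ref["het_rate"].to_numpy(float)
    hom_all = ref["hom_rate"].to_numpy(float)
    chroms = probe_map.table["chromosome"].to_numpy()
    pos_all = probe_map.table["position"].to_numpy()

    segments: list[LOHSegment] = []
    for chrom in probe_map.chromosomes:
        sel = chroms == chrom
        gt, pos = gt_all[sel], pos_all[sel]
        het, hom = het_all[sel], hom_all[sel]
        called = gt != "NC"
        if called.sum() == 0:
            continue
        gt, pos, het, hom = gt[called], pos[called], het[called], hom[called]
        track = hmm_decode(gt, pos, het, params)
        segments.extend(call_loh_segments(
            track, gt, pos, hom, params,
            sample_id=sample.sample_id, chromosome=str(chrom)))
    return segments


__all__ = [
    "LOHParams", "LOHStateTrack", "hmm_decode", "loh_score", "het_rate",
    "call_loh_segments", "loh_segments_for_sample", "EMISSION_FLOOR",
]
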