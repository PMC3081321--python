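"""Synthetic 250K-style genotyping arrays of heterogeneous tumors.

The generator plants fully known copy-number and LOH events so that every
downstream stage can be exercised and scored against ground truth without
any external data.

Model sketch
------------
*Reference panel.*  SNP positions follow a Poisson process with the array's
mean inter-probe spacing (12 kb).  Each SNP gets a minor-allele frequency
p ~ U(0.05, 0.5); the population heterozygosity rate is the Hardy-Weinberg
h = 2p(1-p).  Reference allele-signal means are R_a = T(1-p), R_b = Tp with
a constant total T per probe (intensities are taken as already normalized).

*Tumor sample.*  Each SNP draws a germline genotype from Hardy-Weinberg.
A planted event (loss, gain, homozygous deletion, CNN-LOH, or a
whole-chromosome version) alters the allele copy numbers carried by the
event-bearing cells.  With tumor fraction f and normal-cell contamination c,
the observed cell mixture is (1-c)f event cells and 1-(1-c)f background
cells, so the expected total signal is scaled by

    m = ( copies_in_tumor * (1-c) f  +  ploidy * (1 - (1-c) f) ) / ploidy

Allele signals split the total by mixture allele dosage, then receive
independent log-normal multiplicative noise (sd on the log2 scale).
Genotypes come from a simple caller surrogate: AB when the minor-allele
signal fraction exceeds 0.25, no-call when total signal vanishes, hom
otherwise; a genotyping-error step then flips calls with probability
epsilon, so pure LOH regions read hom with probability 1 - epsilon.

On a tetraploid background (ploidy = 4) the same normalization makes a
single-copy loss read log2(3/4) ~ -0.415 and leaves heterozygosity intact,
reproducing the attenuation of both CN and LOH signals that higher ploidy
causes in real tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ProbeMap, ReferencePanel, SampleArray

EVENT_KINDS = ("loss", "gain", "homozygous_deletion", "cnn_loh",
               "whole_chr_loss", "whole_chr_gain")
REFERENCE_TOTAL_SIGNAL = 2.0  # arbitrary intensity units per probe
GENOTYPE_ERROR = 0.02         # caller surrogate's flip probability
AB_MINOR_FRACTION = 0.25      # minor-allele fraction above which AB is called


@dataclass(frozen=True)
class PlantedEvent:
    """A ground-truth genomic event carried by a fraction of tumor cells."""

    chromosome: str
    start_bp: int
    end_bp: int
    kind: str
    tumor_fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0.0 < self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in (0, 1]")
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic arrays.

    Defaults emulate the 250K array setting: ~12 kb mean probe spacing,
    log2-scale signal noise of 0.2, a diploid background and no
    normal-cell contamination.  Chromosome count and SNPs per chromosome
    are kept modest (4 x 1000 probes = 48 Mb of genome) so that seeded
    replicate studies stay cheap; both scale freely.
    """

    n_snps: int = 1000
    n_chromosomes: int = 4
    spacing_bp: float = 12_000.0
    noise_sd: float = 0.2
    contamination: float = 0.0
    ploidy: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.spacing_bp <= 0:
            raise ValueError("spacing_bp must be > 0")
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must be in [0, 1)")
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.n_snps < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one SNP and one chromosome")


def simulate_reference_panel(config: SimulationConfig
                             ) -> tuple[ProbeMap, ReferencePanel]:
    """Generate probe coordinates and a HapMap-style reference panel."""
    rng = np.random.default_rng(config.seed)
    rows_pm, rows_rp = [], []
    for ci in range(1, config.n_chromosomes + 1):
        chrom = f"chr{ci}"
        gaps = np.maximum(1, rng.exponential(config.spacing_bp, config.n_snps)
                          .round().astype(np.int64))
        pos = np.cumsum(gaps)
        maf = rng.uniform(0.05, 0.5, config.n_snps)
        het = 2.0 * maf * (1.0 - maf)
        for j in range(config.n_snps):
            pid = f"SNP_{chrom}_{j:06d}"
            rows_pm.append((pid, chrom, int(pos[j])))
            rows_rp.append((pid,
                            REFERENCE_TOTAL_SIGNAL * (1.0 - maf[j]),
                            REFERENCE_TOTAL_SIGNAL * maf[j],
                            het[j]))
    probe_map = ProbeMap(pd.DataFrame(rows_pm,
                                      columns=["probe_id", "chromosome", "position"]))
    rp = pd.DataFrame(rows_rp, columns=["probe_id", "ref_a_signal",
                                        "ref_b_signal", "het_rate"])
    rp["hom_rate"] = 1.0 - rp["het_rate"]
    return probe_map, ReferencePanel(rp.set_index("probe_id"))


def _check_non_overlapping(events: Sequence[PlantedEvent]) -> None:
    by_chrom: dict[str, list[PlantedEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start_bp)
        for a, b in zip(evs, evs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(f"overlapping events on {chrom}: "
                                 f"{a.kind}@{a.start_bp}-{a.end_bp} and "
                                 f"{b.kind}@{b.start_bp}-{b.end_bp}")


def _expand_whole_chromosome(events: Sequence[PlantedEvent],
                             probe_map: ProbeMap) -> list[PlantedEvent]:
    out = []
    for ev in events:
        if ev.kind in ("whole_chr_loss", "whole_chr_gain"):
            pos = probe_map.positions(ev.chromosome)
            out.append(replace(ev, start_bp=int(pos[0]), end_bp=int(pos[-1])))
        else:
            out.append(ev)
    return out


def simulate_tumor(panel: ReferencePanel, probe_map: ProbeMap,
                   events: Sequence[PlantedEvent], config: SimulationConfig,
                   sample_id: str = "SIM", rng: np.random.Generator | None = None
                   ) -> tuple[SampleArray, pd.DataFrame]:
    """Simulate one tumor array carrying the planted events.

    Returns the sample and a truth table
    (sample_id, chromosome, start, end, kind, tumor_fraction).
    """
    events = _expand_whole_chromosome(list(events), probe_map)
    _check_non_overlapping(events)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bg = config.ploidy
    c = config.contamination
    ref = panel.aligned_to(probe_map)
    maf = (ref["ref_b_signal"].to_numpy(float) / REFERENCE_TOTAL_SIGNAL)
    n = len(maf)
    chroms = probe_map.table["chromosome"].to_numpy()
    pos = probe_map.table["position"].to_numpy()

    # germline genotype per SNP under Hardy-Weinberg (B = minor allele)
    u = rng.random(n)
    p = maf
    g_b_dosage = np.where(u < (1 - p) ** 2, 0, np.where(u < (1 - p) ** 2 + 2 * p * (1 - p), 1, 2))
    # background-cell allele copies at ploidy bg (germline scaled up)
    bgA = (2 - g_b_dosage) * (bg // 2)
    bgB = g_b_dosage * (bg // 2)

    # event-cell allele copies: start from background, apply events
    evA = bgA.astype(float).copy()
    evB = bgB.astype(float).copy()
    frac = np.zeros(n)  # tumor fraction of the covering event (0 outside)
    retain_b = rng.random(n) < 0.5  # which homolog survives a loss / duplicates in CNN-LOH

    for ev in events:
        sel = (chroms == ev.chromosome) & (pos >= ev.start_bp) & (pos <= ev.end_bp)
        frac[sel] = ev.tumor_fraction
        kind = {"whole_chr_loss": "loss", "whole_chr_gain": "gain"}.get(ev.kind, ev.kind)
        het = sel & (g_b_dosage == 1)
        if kind == "loss":
            # one homolog copy removed; at het SNPs this yields LOH only on
            # a diploid background (tetraploid keeps one copy of each)
            evA[het & retain_b] -= 1
            evB[het & ~retain_b] -= 1
            evA[sel & (g_b_dosage == 0)] -= 1
            evB[sel & (g_b_dosage == 2)] -= 1
        elif kind == "gain":
            evA[het & ~retain_b] += 1
            evB[het & retain_b] += 1
            evA[sel & (g_b_dosage == 0)] += 1
            evB[sel & (g_b_dosage == 2)] += 1
        elif kind == "homozygous_deletion":
            evA[sel] = 0.0
            evB[sel] = 0.0
        elif kind == "cnn_loh":
            # one homolog lost, the other duplicated: copy number unchanged
            evA[het & retain_b] = 0.0
            evB[het & retain_b] = bg
            evA[het & ~retain_b] = bg
            evB[het & ~retain_b] = 0.0

    # cell mixture: (1-c)f event cells + (1 - (1-c)f) background cells
    w_ev = (1.0 - c) * frac
    mixA = evA * w_ev + bgA * (1.0 - w_ev)
    mixB = evB * w_ev + bgB * (1.0 - w_ev)

    noiseA = np.exp2(rng.normal(0.0, config.noise_sd, n))
    noiseB = np.exp2(rng.normal(0.0, config.noise_sd, n))
    s_a = REFERENCE_TOTAL_SIGNAL * (mixA / bg) * noiseA
    s_b = REFERENCE_TOTAL_SIGNAL * (mixB / bg) * noiseB

    # genotype-caller surrogate
    total = mixA + mixB
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(mixA, mixB) / np.where(total > 0, total, np.nan)
    genotype = np.where(total <= 1e-9, "NC",
                        np.where(minor > AB_MINOR_FRACTION, "AB",
                                 np.where(mixA >= mixB, "AA", "BB")))
    # genotyping error: flip hom <-> AB with probability epsilon
    flip = rng.random(n) < GENOTYPE_ERROR
    hom_flip = flip & ((genotype == "AA") | (genotype == "BB"))
    ab_flip = flip & (genotype == "AB")
    genotype = genotype.astype(object)
    genotype[hom_flip] = "AB"
    genotype[ab_flip] = np.where(rng.random(int(ab_flip.sum())) < 0.5, "AA", "BB")

    table = pd.DataFrame({
        "a_signal": s_a, "b_signal": s_b, "genotype": genotype.astype(str),
    }, index=pd.Index(probe_map.table["probe_id"], name="probe_id"))
    truth = pd.DataFrame(
        [(sample_id, ev.chromosome, ev.start_bp, ev.end_bp, ev.kind,
          ev.tumor_fraction) for ev in events],
        columns=["sample_id", "chromosome", "start", "end", "kind",
                 "tumor_fraction"])
    return SampleArray(sample_id, table), truth


@dataclass(frozen=True)
class MenuItem:
    """One entry of a cohort event menu: a template event planted with the
    given per-tumor probability."""

    event: PlantedEvent
    probability: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass
class SimulatedCohort:
    probe_map: ProbeMap
    panel: ReferencePanel
    samples: list[SampleArray]
    truth: pd.DataFrame  # ground-truth analog of a per-tumor event summary


def simulate_cohort(n_tumors: int, menu: Sequence[MenuItem],
                    config: SimulationConfig) -> SimulatedCohort:
    """Simulate a cohort sharing one reference panel.

    Each tumor independently draws each menu item with its probability.
    Draws that would overlap an already-planted event on the same tumor are
    dropped (menu order decides precedence); the truth table records what
    was actually planted.
    """
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    probe_map, panel = simulate_reference_panel(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    samples, truths = [], []
    for t in range(n_tumors):
        sid = f"SIM{t + 1:03d}"
        chosen: list[PlantedEvent] = []
        for item in menu:
            if rng.random() >= item.probability:
                continue
            ev = item.event
            clash = any(e.chromosome == ev.chromosome
                        and not (ev.end_bp < e.start_bp or ev.start_bp > e.end_bp)
                        for e in chosen)
            if not clash:
                chosen.append(ev)
        sample, truth = simulate_tumor(panel, probe_map, chosen, config,
                                       sample_id=sid, rng=rng)
        samples.append(sample)
        truths.append(truth)
    truths = [t for t in truths if len(t)]
    truth_table = (pd.concat(truths, ignore_index=True) if truths else
                   pd.DataFrame(columns=["sample_id", "chromosome", "start",
                                         "end", "kind", "tumor_fraction"]))
    return SimulatedCohort(probe_map, panel, samples, truth_table)


# ---------------------------------------------------------------------------
# TSV export (same formats as cnloh.io reads)
# ---------------------------------------------------------------------------

def write_probe_map(probe_map: ProbeMap, path) -> None:
    probe_map.table.to_csv(path, sep="\t", index=False)


def write_reference_panel(panel: ReferencePanel, path) -> None:
    cols = ["ref_a_signal", "ref_b_signal", "het_rate"]
    panel.table[cols].to_csv(path, sep="\t", float_format="%.10g")


def write_sample_array(sample: SampleArray, path) -> None:
    sample.table.to_csv(path, sep="\t", float_format="%.10g")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")


__all__ = [
    "EVENT_KINDS", "PlantedEvent", "SimulationConfig", "MenuItem",
    "SimulatedCohort", "simulate_reference_panel", "simulate_tumor",
    "simulate_cohort", "write_probe_map", "write_reference_panel",
    "write_sample_array", "write_truth",
]
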