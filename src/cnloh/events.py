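"""Integrate copy-number and LOH segments of one tumor into typed events.

The combined vocabulary distinguishes how LOH arose: segmental loss with or
without LOH (``CNA_loss_LOH`` / ``CNA_loss``), copy-number-neutral LOH
(``CNN_LOH``), gains with or without accompanying LOH (``CNA_gain_LOH`` /
``CNA_gain``), whole-chromosome losses and gains (``WCL`` / ``WCL_LOH`` /
``WCG``) and deep losses annotated as ``homozygous_deletion``.

A CN segment and an LOH segment are paired when their overlap covers at
least half of the shorter of the two intervals (reciprocal-overlap rule).
Whole-chromosome flags absorb the interval events they contain so cohort
frequencies never double-count; absorbed segments remain reachable through
the event's ``segments`` list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LOHSegment, ProbeMap, Segment, chromosome_sort_key

EVENT_TYPES = ("CNA_loss_LOH", "CNA_loss", "CNN_LOH", "CNA_gain",
               "CNA_gain_LOH", "WCL", "WCL_LOH", "WCG", "homozygous_deletion")

DEFAULT_OVERLAP_FRACTION = 0.5
DEFAULT_DENSITY_GAP_BP = 500_000


@dataclass
class TumorEvent:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    event_type: str
    segments: list = field(default_factory=list)
    artifact_flag: bool = False

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")


@dataclass
class TumorProfile:
    """All typed events of one tumor plus its whole-chromosome flags."""

    sample_id: str
    events: list[TumorEvent]
    wc_flags: dict[str, str | None] = field(default_factory=dict)

    def events_on(self, chromosome: str) -> list[TumorEvent]:
        return [e for e in self.events if e.chromosome == chromosome]


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _qualifies(cn: Segment, loh: LOHSegment, frac: float) -> bool:
    ov = _overlap(cn.start_bp, cn.end_bp, loh.start_bp, loh.end_bp)
    shorter = min(cn.length, loh.length)
    return ov >= frac * shorter


def classify_events(cn_segments: list[Segment], loh_segments: list[LOHSegment],
                    wc_flags: dict[str, str | None] | None = None,
                    probe_map: ProbeMap | None = None, *,
                    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
                    deep_deletion_log2: float = -1.0) -> TumorProfile:
    """Combine one tumor's CN and LOH segments into a typed event profile.

    Every input segment contributes to exactly one event.  Pairing uses the
    reciprocal-overlap rule (overlap >= ``overlap_fraction`` of the shorter
    interval); paired loss+LOH events take the union of their bounds.  Loss
    segments at or below ``deep_deletion_log2`` become homozygous deletions.
    On chromosomes flagged WCL/WCG all same-direction segments (and, for
    WCL, the chromosome's LOH segments) are absorbed into a single
    whole-chromosome event; WCL becomes WCL_LOH when absorbed LOH covers at
    least half of the chromosome's spanned extent.
    """
    ids = {s.sample_id for s in cn_segments} | {s.sample_id for s in loh_segments}
    if len(ids) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(ids)}")
    sample_id = ids.pop() if ids else ""
    wc_flags = dict(wc_flags or {})

    events: list[TumorEvent] = []
    cn_left = sorted(cn_segments, key=lambda s: (chromosome_sort_key(s.chromosome), s.start_bp))
    loh_left = sorted(loh_segments, key=lambda s: (chromosome_sort_key(s.chromosome), s.start_bp))

    # whole-chromosome events first: they absorb contained interval calls
    for chrom, flag in sorted(wc_flags.items(), key=lambda kv: chromosome_sort_key(kv[0])):
        if flag not in ("WCL", "WCG"):
            continue
        direction = "loss" if flag == "WCL" else "gain"
        absorbed_cn = [s for s in cn_left if s.chromosome == chrom and s.direction == direction]
        cn_left = [s for s in cn_left if s not in absorbed_cn]
        absorbed_loh: list[LOHSegment] = []
        if flag == "WCL":
            absorbed_loh = [s for s in loh_left if s.chromosome == chrom]
            loh_left = [s for s in loh_left if s not in absorbed_loh]
        parts = absorbed_cn + absorbed_loh
        if probe_map is not None:
            pos = probe_map.positions(chrom)
            bounds = (int(pos[0]), int(pos[-1]))
        elif parts:
            bounds = (min(s.start_bp for s in parts), max(s.end_bp for s in parts))
        else:
            bounds = (1, 1)
        etype = flag
        if flag == "WCL" and absorbed_loh:
            span = bounds[1] - bounds[0] + 1
            loh_cov = sum(s.length for s in absorbed_loh)
            if loh_cov >= 0.5 * span:
                etype = "WCL_LOH"
        events.append(TumorEvent(sample_id, chrom, bounds[0], bounds[1], etype,
                                 segments=parts,
                                 artifact_flag=any(s.artifact_flag for s in parts)))

    # pair remaining CN segments with LOH segments
    used_loh: set[int] = set()
    for cn in cn_left:
        partners = [i for i, l in enumerate(loh_left)
                    if i not in used_loh and l.chromosome == cn.chromosome
                    and _qualifies(cn, l, overlap_fraction)]
        used_loh.update(partners)
        loh_parts = [loh_left[i] for i in partners]
        parts = [cn] + loh_parts
        start = min(s.start_bp for s in parts)
        end = max(s.end_bp for s in parts)
        if cn.direction == "loss":
            if cn.mean_log2 <= deep_deletion_log2:
                etype = "homozygous_deletion"
            else:
                etype = "CNA_loss_LOH" if loh_parts else "CNA_loss"
        else:
            etype = "CNA_gain_LOH" if loh_parts else "CNA_gain"
        events.append(TumorEvent(cn.sample_id, cn.chromosome, start, end, etype,
                                 segments=parts,
                                 artifact_flag=any(s.artifact_flag for s in parts)))

    # leftover LOH with no qualifying CN overlap is copy-number neutral
    for i, l in enumerate(loh_left):
        if i in used_loh:
            continue
        events.append(TumorEvent(l.sample_id, l.chromosome, l.start_bp, l.end_bp,
                                 "CNN_LOH", segments=[l],
                                 artifact_flag=l.artifact_flag))

    events.sort(key=lambda e: (chromosome_sort_key(e.chromosome), e.start_bp, e.event_type))
    return TumorProfile(sample_id, events, wc_flags)


def flag_artifact_regions(segments, probe_map: ProbeMap,
                          mask: list[tuple[str, int, int]] | None = None,
                          density_gap_bp: int = DEFAULT_DENSITY_GAP_BP):
    """Set ``artifact_flag`` on segments that look like array artifacts.

    A segment is flagged when it overlaps a declared mask interval (e.g.
    centromeric/heterochromatic regions) or when the median inter-probe gap
    inside it exceeds ``density_gap_bp`` (poor probe density).  Flagged
    segments are retained, never removed.  Returns the same segment objects.
    """
    mask = mask or []
    for seg in segments:
        flagged = any(m_chrom == seg.chromosome
                      and _overlap(seg.start_bp, seg.end_bp, m_start, m_end) > 0
                      for m_chrom, m_start, m_end in mask)
        if not flagged:
            try:
                pos = probe_map.positions(seg.chromosome)
            except KeyError:
                pos = np.array([], dtype=int)
            inside = pos[(pos >= seg.start_bp) & (pos <= seg.end_bp)]
            if len(inside) < 2:
                flagged = True  # cannot even measure density
            elif float(np.median(np.diff(inside))) > density_gap_bp:
                flagged = True
        seg.artifact_flag = bool(flagged)
    return segments


def write_events(profile: TumorProfile, path) -> None:
    """Write a profile as an events TSV:
    sample_id, chromosome, start, end, event_type, artifact_flag."""
    with open(path, "w") as fh:
        fh.write("sample_id\tchromosome\tstart\tend\tevent_type\tartifact_flag\n")
        for e in profile.events:
            fh.write(f"{e.sample_id}\t{e.chromosome}\t{e.start_bp}\t{e.end_bp}\t"
                     f"{e.event_type}\t{int(e.artifact_flag)}\n")


__all__ = [
    "EVENT_TYPES", "TumorEvent", "TumorProfile", "classify_events",
    "flag_artifact_regions", "write_events",
]
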