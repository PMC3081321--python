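"""Cohort-level aggregation: minimal regions of overlap, event frequencies,
and karyotype-complexity summaries.

The minimal region of overlap (MRO) on a chromosome is the region covered by
the largest number of tumors' event intervals — the sweep-line maximum of
the per-tumor coverage function.  When exactly two intervals contribute this
reduces to their plain intersection, e.g. two 11q deletions spanning
102077451-qter and 66706205-125002355 intersect to 102077451-125002355.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import ClinicalRecord, chromosome_sort_key
from .events import TumorProfile

LOSS_LOH_TYPES = ("CNA_loss_LOH", "CNA_loss", "CNN_LOH", "WCL", "WCL_LOH",
                  "homozygous_deletion")
GAIN_TYPES = ("CNA_gain", "CNA_gain_LOH", "WCG")


@dataclass(frozen=True)
class MRORegion:
    chromosome: str
    start_bp: int
    end_bp: int
    support: int
    sample_ids: tuple[str, ...]


@dataclass
class CohortTable:
    """Tumor profiles keyed by sample_id, with an optional clinical join."""

    profiles: dict[str, TumorProfile]
    clinical: dict[str, ClinicalRecord] = field(default_factory=dict)

    @classmethod
    def from_profiles(cls, profiles: Iterable[TumorProfile],
                      clinical: Iterable[ClinicalRecord] | None = None
                      ) -> "CohortTable":
        pmap: dict[str, TumorProfile] = {}
        for p in profiles:
            if p.sample_id in pmap:
                raise ValueError(f"duplicate profile for {p.sample_id}")
            pmap[p.sample_id] = p
        cmap = {c.sample_id: c for c in clinical or []}
        # clinical-only samples get empty profiles so group sizes are right
        for sid in cmap:
            pmap.setdefault(sid, TumorProfile(sid, []))
        return cls(pmap, cmap)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.profiles)


def _resolve(interval, chromosome_length: int | None):
    """Normalize one (sample_id, start, end) interval; end may be None or
    'qter', resolved via the chromosome length."""
    sid, start, end = interval
    if end is None or (isinstance(end, str) and end.lower() == "qter"):
        if chromosome_length is None:
            raise ValueError("open-ended 'qter' interval needs a chromosome length")
        end = chromosome_length
    start, end = int(start), int(end)
    if start > end:
        raise ValueError(f"interval start > end for {sid}")
    return str(sid), start, end


def compute_mro(intervals: Sequence[tuple], chromosome_length: int | None = None,
                chromosome: str = "") -> list[MRORegion]:
    """Maximal-coverage region(s) of a set of per-tumor intervals.

    ``intervals`` are (sample_id, start_bp, end_bp) with 1-based inclusive
    bounds; ``end_bp`` may be ``None``/"qter" for open-ended intervals.
    Intervals from the same tumor are merged first, so coverage counts
    distinct tumors.  All regions tied at maximal coverage are returned in
    coordinate order.
    """
    if not intervals:
        raise ValueError("no intervals")
    per_sample: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        sid, start, end = _resolve(iv, chromosome_length)
        per_sample.setdefault(sid, []).append((start, end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for sid, ivs in per_sample.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[sid] = [tuple(x) for x in out]

    # sweep-line over breakpoints: +1 at start, -1 just past end
    deltas: dict[int, int] = {}
    for ivs in merged.values():
        for s, e in ivs:
            deltas[s] = deltas.get(s, 0) + 1
            deltas[e + 1] = deltas.get(e + 1, 0) - 1
    points = sorted(deltas)
    cov = 0
    best = 0
    pieces: list[tuple[int, int, int]] = []  # (start, end, coverage)
    for p, nxt in zip(points, points[1:] + [None]):
        cov += deltas[p]
        if nxt is not None and cov > 0:
            pieces.append((p, nxt - 1, cov))
            best = max(best, cov)
    # merge adjacent pieces at maximal coverage
    regions: list[list[int]] = []
    for s, e, c in pieces:
        if c != best:
            continue
        if regions and s == regions[-1][1] + 1:
            regions[-1][1] = e
        else:
            regions.append([s, e])
    out_regions = []
    for s, e in regions:
        carriers = tuple(sorted(
            sid for sid, ivs in merged.items()
            if any(a <= s and e <= b for a, b in ivs)))
        out_regions.append(MRORegion(chromosome, s, e, best, carriers))
    return out_regions


def _normalize_group(cohort: CohortTable, sample_id: str, group_by: str) -> str:
    rec = cohort.clinical.get(sample_id)
    if group_by == "none":
        return "all"
    if group_by == "stage":
        return rec.stage if rec else "NA"
    if group_by == "histology":
        return rec.histology if rec else "NA"
    raise ValueError(f"unknown group key {group_by!r}")


def _event_regions(event, arm_boundaries: Mapping[str, int] | None):
    """Aggregation unit(s) an event counts toward: chromosome, or arm(s)
    when a p-arm/q-arm boundary table is supplied."""
    if arm_boundaries is None or event.chromosome not in arm_boundaries:
        return [event.chromosome]
    p_end = arm_boundaries[event.chromosome]
    regions = []
    if event.start_bp <= p_end:
        regions.append(f"{event.chromosome}p")
    if event.end_bp > p_end:
        regions.append(f"{event.chromosome}q")
    return regions


def frequency_table(cohort: CohortTable, group_by: str = "none",
                    include_flagged: bool = True,
                    arm_boundaries: Mapping[str, int] | None = None
                    ) -> pd.DataFrame:
    """Counts and proportions of each event type per chromosome (or arm)
    per clinical group.

    A tumor counts once per (region, event_type) regardless of how many
    events of that type it carries there.  Proportions are carriers divided
    by group size; empty groups report NA.  ``include_flagged=False`` drops
    artifact-flagged events before counting.
    """
    group_sizes: dict[str, int] = {}
    carriers: dict[tuple[str, str, str], set[str]] = {}
    for sid in cohort.sample_ids:
        group = _normalize_group(cohort, sid, group_by)
        group_sizes[group] = group_sizes.get(group, 0) + 1
        for ev in cohort.profiles[sid].events:
            if not include_flagged and ev.artifact_flag:
                continue
            for region in _event_regions(ev, arm_boundaries):
                carriers.setdefault((group, region, ev.event_type), set()).add(sid)
    rows = []
    for (group, region, etype), sids in carriers.items():
        size = group_sizes[group]
        rows.append((group, region, etype, len(sids), size,
                     len(sids) / size if size else float("nan")))
    df = pd.DataFrame(rows, columns=["group", "region", "event_type",
                                     "n_carriers", "group_size", "proportion"])
    if df.empty:
        return df
    df["_rk"] = df["region"].map(chromosome_sort_key)
    df = (df.sort_values(["group", "_rk", "event_type"], kind="mergesort")
            .drop(columns="_rk").reset_index(drop=True))
    return df


def complexity_summary(cohort: CohortTable,
                       include_flagged: bool = True) -> pd.DataFrame:
    """Per-tumor event counts and karyotype-complexity labels.

    Tumors with no events are ``normal``; tumors whose only events are
    copy-number-neutral LOH are ``cnn_loh_only``; the rest are
    ``cna_bearing``.
    """
    rows = []
    for sid in cohort.sample_ids:
        events = [e for e in cohort.profiles[sid].events
                  if include_flagged or not e.artifact_flag]
        if not events:
            label = "normal"
        elif all(e.event_type == "CNN_LOH" for e in events):
            label = "cnn_loh_only"
        else:
            label = "cna_bearing"
        rows.append((sid, len(events), label))
    return pd.DataFrame(rows, columns=["sample_id", "n_events", "label"])


def chromosome_carriers(cohort: CohortTable, chromosome: str,
                        event_types: Sequence[str] = LOSS_LOH_TYPES,
                        include_flagged: bool = True) -> list[str]:
    """Sample ids of tumors carrying any event of the given types on a
    chromosome (the 'n tumors showed X' tally)."""
    out = []
    for sid in cohort.sample_ids:
        for ev in cohort.profiles[sid].events_on(chromosome):
            if ev.event_type in event_types and (include_flagged or not ev.artifact_flag):
                out.append(sid)
                break
    return out


__all__ = [
    "MRORegion", "CohortTable", "compute_mro", "frequency_table",
    "complexity_summary", "chromosome_carriers", "LOSS_LOH_TYPES", "GAIN_TYPES",
]
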