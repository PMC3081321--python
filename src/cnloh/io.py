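"""Shared data model and tabular I/O for the SNP-array CN/LOH pipeline.

All genomic coordinates are 1-based and inclusive at both ends, matching the
``Chr11:102077451-125002355`` convention used throughout the field's array
literature.  Conversion to 0-based half-open happens only inside the BED
exporter.

Formats handled here:

* probe map TSV        — ``probe_id  chromosome  position``
* reference panel TSV  — ``probe_id  ref_a_signal  ref_b_signal  het_rate``
* sample array TSV     — ``probe_id  a_signal  b_signal  genotype``
* clinical TSV         — ``sample_id  stage  histology``
* chromosome sizes TSV — ``chromosome  length``
* SEG segment files    — see :func:`write_segments`
* BED export of LOH segments (0-based half-open)
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("AA", "AB", "BB", "NC")
STAGES = ("I", "II", "III", "IV", "V", "NA")
HISTOLOGIES = ("FH", "UH", "NA")


class FormatError(ValueError):
    """Raised when an input table violates its documented format."""


def chromosome_sort_key(chrom: str):
    """Natural ordering key: chr1 < chr2 < ... < chr10 < chrX."""
    m = re.match(r"(?:chr)?(\d+)$", str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic coordinates of the array's SNP probes.

    ``table`` has columns ``probe_id``, ``chromosome``, ``position`` and is
    sorted by (chromosome, position) with strictly increasing positions within
    each chromosome.
    """

    table: pd.DataFrame

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["chromosome"]:
            seen.setdefault(c)
        return list(seen)

    def for_chromosome(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chrom]
        if sub.empty:
            raise KeyError(f"no probes on chromosome {chrom!r}")
        return sub

    def positions(self, chrom: str) -> np.ndarray:
        return self.for_chromosome(chrom)["position"].to_numpy()

    def n_probes(self, chrom: str | None = None) -> int:
        if chrom is None:
            return len(self.table)
        return len(self.for_chromosome(chrom))

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ReferencePanel:
    """Per-SNP reference allele signal means and heterozygosity rates.

    The reference emulates a panel of phenotypically normal individuals: for
    each SNP it stores the mean A and B allele signals (R_a, R_b) and the
    population heterozygosity rate h (probability of an AB call), from which
    the homozygosity rate 1 - h follows.
    ``table`` is indexed by probe_id with columns ``ref_a_signal``,
    ``ref_b_signal``, ``het_rate``, ``hom_rate``.
    """

    table: pd.DataFrame

    def aligned_to(self, probe_map: ProbeMap) -> pd.DataFrame:
        missing = probe_map.table["probe_id"][
            ~probe_map.table["probe_id"].isin(self.table.index)
        ]
        if len(missing):
            raise FormatError(
                "probes absent from reference panel: "
                + ", ".join(missing.head(5)) + ("..." if len(missing) > 5 else "")
            )
        return self.table.loc[probe_map.table["probe_id"]]


@dataclass(frozen=True)
class SampleArray:
    """One tumor array: per-SNP allele signals and BRLMM-style genotype calls.

    ``table`` is indexed by probe_id with columns ``a_signal``, ``b_signal``,
    ``genotype`` (AA/AB/BB/NC).
    """

    sample_id: str
    table: pd.DataFrame

    def aligned_to(self, probe_map: ProbeMap) -> pd.DataFrame:
        missing = probe_map.table["probe_id"][
            ~probe_map.table["probe_id"].isin(self.table.index)
        ]
        if len(missing):
            raise FormatError(
                f"sample {self.sample_id}: probes absent from array: "
                + ", ".join(missing.head(5)) + ("..." if len(missing) > 5 else "")
            )
        return self.table.loc[probe_map.table["probe_id"]]


@dataclass
class Segment:
    """A called copy-number segment (run of probes beyond the log2 threshold)."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_probes: int
    mean_log2: float
    direction: str  # "loss" | "gain"
    artifact_flag: bool = False

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")
        if self.direction not in ("loss", "gain"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class LOHSegment:
    """A called LOH segment with its score and observed het rate."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    loh_score: float
    het_rate_obs: float
    artifact_flag: bool = False

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")
        if self.loh_score < 0:
            raise ValueError("loh_score must be non-negative")

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    stage: str = "NA"
    histology: str = "NA"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_probe_map(path) -> ProbeMap:
    """Read a probe annotation TSV and return a sorted :class:`ProbeMap`."""
    df = _read_tsv(path, ["probe_id", "chromosome", "position"])
    if df.empty:
        raise FormatError(f"{path}: no probes")
    dupes = df["probe_id"][df["probe_id"].duplicated()]
    if len(dupes):
        raise FormatError(f"{path}: duplicate probe_id(s): {sorted(set(dupes))[:5]}")
    try:
        df["position"] = df["position"].astype(np.int64)
    except (ValueError, TypeError):
        raise FormatError(f"{path}: non-integer position")
    df["_ck"] = df["chromosome"].map(chromosome_sort_key)
    df = df.sort_values(["_ck", "position"], kind="mergesort").drop(columns="_ck")
    df = df.reset_index(drop=True)
    for chrom, sub in df.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise FormatError(
                f"{path}: duplicate position on {chrom}; positions must be unique"
            )
    return ProbeMap(df)


def read_reference_panel(path) -> ReferencePanel:
    df = _read_tsv(path, ["probe_id", "ref_a_signal", "ref_b_signal", "het_rate"])
    for col in ("ref_a_signal", "ref_b_signal", "het_rate"):
        try:
            df[col] = df[col].astype(float)
        except (ValueError, TypeError):
            raise FormatError(f"{path}: non-numeric {col}")
    if (df["het_rate"].lt(0) | df["het_rate"].gt(1)).any():
        bad = df.loc[df["het_rate"].lt(0) | df["het_rate"].gt(1), "probe_id"]
        raise FormatError(f"{path}: het_rate outside [0,1] for {list(bad[:5])}")
    if ((df["ref_a_signal"] + df["ref_b_signal"]) <= 0).any():
        bad = df.loc[(df["ref_a_signal"] + df["ref_b_signal"]) <= 0, "probe_id"]
        raise FormatError(f"{path}: zero reference signal for {list(bad[:5])}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe_id in panel")
    df["hom_rate"] = 1.0 - df["het_rate"]
    return ReferencePanel(df.set_index("probe_id"))


def read_sample_array(path, sample_id: str | None = None) -> SampleArray:
    path = Path(path)
    df = _read_tsv(path, ["probe_id", "a_signal", "b_signal", "genotype"])
    for col in ("a_signal", "b_signal"):
        try:
            df[col] = df[col].astype(float)
        except (ValueError, TypeError):
            raise FormatError(f"{path}: non-numeric {col}")
    if (df[["a_signal", "b_signal"]] < 0).any().any():
        raise FormatError(f"{path}: negative allele signal")
    bad = set(df["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(f"{path}: unknown genotype symbol(s): {sorted(bad)}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe_id in sample")
    if sample_id is None:
        sample_id = path.stem
    return SampleArray(sample_id, df.set_index("probe_id"))


def read_clinical(path) -> list[ClinicalRecord]:
    """Read the clinical table; stage/histology values are lightly normalized.

    ``1``..``5`` (arabic) map onto roman stage labels; blanks map onto ``NA``.
    Anything else that is not a documented enumeration value is an error —
    unknowns are never silently merged into a named group.
    """
    df = _read_tsv(path, ["sample_id", "stage", "histology"])
    arabic = {"1": "I", "2": "II", "3": "III", "4": "IV", "5": "V"}
    records = []
    for _, row in df.iterrows():
        stage = str(row["stage"]).strip().upper()
        stage = arabic.get(stage, stage)
        if stage in ("", "NAN", "NONE"):
            stage = "NA"
        hist = str(row["histology"]).strip().upper()
        if hist in ("", "NAN", "NONE"):
            hist = "NA"
        records.append(ClinicalRecord(str(row["sample_id"]), stage, hist))
    ids = [r.sample_id for r in records]
    if len(ids) != len(set(ids)):
        raise FormatError(f"{path}: duplicate sample_id")
    return records


def read_chromosome_sizes(path) -> dict[str, int]:
    df = _read_tsv(path, ["chromosome", "length"])
    try:
        df["length"] = df["length"].astype(np.int64)
    except (ValueError, TypeError):
        raise FormatError(f"{path}: non-integer chromosome length")
    return dict(zip(df["chromosome"], df["length"]))


# ---------------------------------------------------------------------------
# Segment writer / reader (SEG format)
# ---------------------------------------------------------------------------

_SEG_COLUMNS = [
    "sample_id", "chromosome", "start", "end",
    "num_probes", "mean_log2", "event_type", "artifact_flag", "het_rate",
]


def _seg_sort_key(seg) -> tuple:
    return (seg.sample_id, chromosome_sort_key(seg.chromosome), seg.start_bp)


def write_segments(segments: Sequence[Segment | LOHSegment], path) -> None:
    """Write CN and/or LOH segments as a tab-separated SEG file.

    Input must already be sorted by (sample, chromosome, start); the writer
    refuses to sort silently.  CN segments store their direction in
    ``event_type`` and leave ``het_rate`` as NA; LOH segments use event_type
    ``LOH``, store the LOH score in ``mean_log2`` and their observed het rate
    in ``het_rate`` (the extra column keeps the round-trip lossless).
    """
    segments = list(segments)
    keys = [_seg_sort_key(s) for s in segments]
    if keys != sorted(keys):
        raise ValueError("segments must be sorted by (sample, chromosome, start)")
    rows = []
    for seg in segments:
        if isinstance(seg, LOHSegment):
            rows.append([seg.sample_id, seg.chromosome, seg.start_bp, seg.end_bp,
                         seg.n_markers, repr(float(seg.loh_score)), "LOH",
                         int(seg.artifact_flag), repr(float(seg.het_rate_obs))])
        else:
            rows.append([seg.sample_id, seg.chromosome, seg.start_bp, seg.end_bp,
                         seg.n_probes, repr(float(seg.mean_log2)), seg.direction,
                         int(seg.artifact_flag), "NA"])
    with open(path, "w") as fh:
        fh.write("\t".join(_SEG_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_segments(path) -> list[Segment | LOHSegment]:
    """Read a SEG file written by :func:`write_segments`."""
    df = _read_tsv(path, _SEG_COLUMNS[:8])
    out: list[Segment | LOHSegment] = []
    for _, row in df.iterrows():
        common = dict(
            sample_id=str(row["sample_id"]),
            chromosome=str(row["chromosome"]),
            start_bp=int(row["start"]),
            end_bp=int(row["end"]),
            artifact_flag=bool(int(row["artifact_flag"])),
        )
        if row["event_type"] == "LOH":
            out.append(LOHSegment(n_markers=int(row["num_probes"]),
                                  loh_score=float(row["mean_log2"]),
                                  het_rate_obs=float(row.get("het_rate", "nan")),
                                  **common))
        else:
            out.append(Segment(n_probes=int(row["num_probes"]),
                               mean_log2=float(row["mean_log2"]),
                               direction=str(row["event_type"]),
                               **common))
    return out


def write_bed(segments: Iterable[LOHSegment], path) -> None:
    """Export LOH segments as BED (0-based half-open): chrom, start, end,
    sample_id, loh_score."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chromosome}\t{seg.start_bp - 1}\t{seg.end_bp}\t"
                     f"{seg.sample_id}\t{seg.loh_score:.6g}\n")


def read_mask_bed(path) -> list[tuple[str, int, int]]:
    """Read a mask BED (e.g. centromere/heterochromatin intervals) into
    1-based inclusive (chromosome, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: malformed BED line: {line!r}")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


__all__ = [
    "FormatError", "GENOTYPES", "ProbeMap", "ReferencePanel", "SampleArray",
    "Segment", "LOHSegment", "ClinicalRecord", "chromosome_sort_key",
    "read_probe_map", "read_reference_panel", "read_sample_array",
    "read_clinical", "read_chromosome_sizes", "write_segments",
    "read_segments", "write_bed", "read_mask_bed",
]
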