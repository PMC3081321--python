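"""Bundled example data.

``load_synthetic_wt_cohort`` returns a synthetic per-tumor event summary of
a 56-tumor Wilms-tumor-like cohort.  It is a constructed stand-in (not
measured data): the per-tumor rows were designed to be jointly consistent
with the published cohort-level tallies for such a series — 8 fully normal
tumors, 5 tumors with copy-number-neutral LOH as their only abnormality,
37 tumors carrying chromosome-11 loss or LOH (7 whole-chromosome losses of
which 4 with LOH, 12 subregional losses of which 10 with LOH, 18 CNN-LOH),
22 tumors with 1q gain, and a stage/histology breakdown in which 4/6
unfavorable-histology and 6/22 favorable-histology tumors carry the 1q
gain.  Coordinates are plausible hg18-era values and carry no per-probe
information.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import CohortTable
from .events import TumorEvent, TumorProfile
from .io import ClinicalRecord


def _data_path(name: str):
    return resources.files("cnloh").joinpath("data", name)


def load_synthetic_wt_cohort() -> CohortTable:
    """Load the synthetic 56-tumor cohort summary as a :class:`CohortTable`."""
    with resources.as_file(_data_path("wt_cohort_events_synthetic.tsv")) as p:
        events = pd.read_csv(p, sep="\t")
    with resources.as_file(_data_path("wt_cohort_clinical_synthetic.tsv")) as p:
        clinical_df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)

    profiles: dict[str, TumorProfile] = {}
    for row in events.itertuples():
        sid = str(row.sample_id)
        profiles.setdefault(sid, TumorProfile(sid, []))
        profiles[sid].events.append(TumorEvent(
            sid, str(row.chromosome), int(row.start), int(row.end),
            str(row.event_type), artifact_flag=bool(int(row.artifact_flag))))
    clinical = [ClinicalRecord(str(r.sample_id), str(r.stage), str(r.histology))
                for r in clinical_df.itertuples()]
    return CohortTable.from_profiles(profiles.values(), clinical)


__all__ = ["load_synthetic_wt_cohort"]
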