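"""End-to-end pipeline runner: simulate -> CN -> LOH -> integrate -> cohort.

A run is driven by a :class:`RunConfig` (optionally loaded from YAML),
executes the stages in order into an output directory, and records a
manifest (parameters, seed, per-file SHA-256 checksums) so that identical
configs provably produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import simulate as sim
from .cohort import CohortTable, complexity_summary, frequency_table
from .copy_number import CNParams, cn_segments_for_sample
from .events import classify_events, flag_artifact_regions, write_events
from .io import read_clinical, read_mask_bed, write_segments
from .loh import LOHParams, loh_segments_for_sample


@dataclass
class RunConfig:
    out_dir: str = "cnloh_run"
    seed: int = 0
    n_tumors: int = 6
    include_flagged: bool = True
    group_by: str = "none"
    clinical_path: str | None = None
    mask_path: str | None = None
    cn: CNParams = field(default_factory=CNParams)
    loh: LOHParams = field(default_factory=LOHParams)
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    menu: list[sim.MenuItem] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("out_dir", "seed", "n_tumors", "include_flagged",
                    "group_by", "clinical_path", "mask_path"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cn" in raw:
            kwargs["cn"] = CNParams(**raw["cn"])
        if "loh" in raw:
            kwargs["loh"] = LOHParams(**raw["loh"])
        if "sim" in raw:
            kwargs["sim"] = sim.SimulationConfig(**raw["sim"])
        menu = []
        for item in raw.get("menu", []):
            prob = item.pop("probability", 1.0)
            menu.append(sim.MenuItem(sim.PlantedEvent(**item), prob))
        kwargs["menu"] = menu
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.clinical_path, self.mask_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.group_by not in ("none", "stage", "histology"):
            raise ValueError(f"unknown group_by {self.group_by!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    cohort_data = sim.simulate_cohort(config.n_tumors, config.menu, sim_cfg)
    sim.write_probe_map(cohort_data.probe_map, out / "probes.tsv")
    sim.write_reference_panel(cohort_data.panel, out / "panel.tsv")
    sim.write_truth(cohort_data.truth, out / "truth.tsv")

    mask = read_mask_bed(config.mask_path) if config.mask_path else None
    clinical = read_clinical(config.clinical_path) if config.clinical_path else []

    profiles = []
    for sample in cohort_data.samples:
        sim.write_sample_array(sample, out / f"{sample.sample_id}.tsv")
        cn_segs, wc_flags, _ = cn_segments_for_sample(
            sample, cohort_data.panel, cohort_data.probe_map, config.cn)
        loh_segs = loh_segments_for_sample(
            sample, cohort_data.panel, cohort_data.probe_map, config.loh)
        flag_artifact_regions(cn_segs + loh_segs, cohort_data.probe_map, mask)
        write_segments(cn_segs, out / f"{sample.sample_id}.cn.seg")
        write_segments(loh_segs, out / f"{sample.sample_id}.loh.seg")
        profile = classify_events(cn_segs, loh_segs, wc_flags,
                                  cohort_data.probe_map,
                                  deep_deletion_log2=config.cn.deep_deletion_log2)
        if not profile.sample_id:
            profile.sample_id = sample.sample_id
        write_events(profile, out / f"{sample.sample_id}.events.tsv")
        profiles.append(profile)

    cohort = CohortTable.from_profiles(profiles, clinical)
    freq = frequency_table(cohort, config.group_by,
                           include_flagged=config.include_flagged)
    freq.to_csv(out / "frequencies.csv", index=False, float_format="%.6g")
    complexity_summary(cohort).to_csv(out / "complexity.tsv", sep="\t",
                                      index=False)

    manifest = {
        "version": __import__("cnloh").__version__,
        "seed": config.seed,
        "parameters": {
            "cn": dataclasses.asdict(config.cn),
            "loh": dataclasses.asdict(config.loh),
            "sim": dataclasses.asdict(sim_cfg),
        },
        "outputs": {p.name: _sha256(p)
                    for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


__all__ = ["RunConfig", "run_pipeline"]
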