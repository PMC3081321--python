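"""Integrate CN and LOH calls of one tumor into typed events.

Simulates a tumor with a deletion-with-LOH and a separate CNN-LOH region,
runs both callers, and classifies the combined profile (CNA_loss_LOH vs
CNN_LOH vs gains, whole-chromosome events, homozygous deletions).
"""

from cnloh import classify_events, cn_segments_for_sample, loh_segments_for_sample
from cnloh.simulate import (PlantedEvent, SimulationConfig,
                            simulate_reference_panel, simulate_tumor)

config = SimulationConfig(n_snps=1000, n_chromosomes=2, noise_sd=0.2, seed=3)
probe_map, panel = simulate_reference_panel(config)
p1, p2 = probe_map.positions("chr1"), probe_map.positions("chr2")

events = [
    PlantedEvent("chr1", int(p1[100]), int(p1[399]), "loss"),      # loss + LOH
    PlantedEvent("chr2", int(p2[300]), int(p2[799]), "cnn_loh"),   # LOH only
]
sample, _ = simulate_tumor(panel, probe_map, events, config, "DEMO")

cn_segs, wc_flags, _ = cn_segments_for_sample(sample, panel, probe_map)
loh_segs = loh_segments_for_sample(sample, panel, probe_map)
profile = classify_events(cn_segs, loh_segs, wc_flags, probe_map)

for ev in profile.events:
    print(f"{ev.event_type:14s} {ev.chromosome}:{ev.start_bp}-{ev.end_bp}")
print("# a deletion on a diploid background exposes LOH (CNA_loss_LOH);")
print("# LOH with a flat copy-number track is copy-neutral LOH (CNN_LOH)")
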