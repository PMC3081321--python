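import numpy as np
import pandas as pd
import pytest

from cnloh.io import ProbeMap, ReferencePanel, SampleArray


def build_probe_map(chrom_positions: dict[str, list[int]]) -> ProbeMap:
    rows = []
    for chrom, positions in chrom_positions.items():
        for i, pos in enumerate(positions):
            rows.append((f"{chrom}_p{i:04d}", chrom, int(pos)))
    return ProbeMap(pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"]))


def build_panel(probe_map: ProbeMap, het: float = 0.3,
                ref_a: float = 2.0, ref_b: float = 2.0) -> ReferencePanel:
    ids = probe_map.table["probe_id"]
    df = pd.DataFrame({
        "ref_a_signal": ref_a, "ref_b_signal": ref_b,
        "het_rate": het, "hom_rate": 1.0 - het,
    }, index=pd.Index(ids, name="probe_id"))
    return ReferencePanel(df)


def build_sample(probe_map: ProbeMap, a: float = 2.0, b: float = 2.0,
                 genotype: str = "AB", sample_id: str = "S1") -> SampleArray:
    ids = probe_map.table["probe_id"]
    df = pd.DataFrame({
        "a_signal": float(a), "b_signal": float(b), "genotype": genotype,
    }, index=pd.Index(ids, name="probe_id"))
    return SampleArray(sample_id, df)


@pytest.fixture
def probe_map_1chr():
    """101 evenly spaced probes on one chromosome (12 kb spacing)."""
    return build_probe_map({"chr1": list(range(10_000, 10_000 + 101 * 12_000, 12_000))})
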