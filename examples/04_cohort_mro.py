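"""Cohort aggregation: the minimal region of overlap and event frequencies.

First reproduces the classic two-tumor worked example on chromosome 11 —
intersecting a 102,077,451-qter deletion with a 66,706,205-125,002,355
deletion — then tallies the bundled synthetic 56-tumor cohort summary.
"""

from cnloh.cohort import (GAIN_TYPES, LOSS_LOH_TYPES, chromosome_carriers,
                          complexity_summary, compute_mro)
from cnloh.datasets import load_synthetic_wt_cohort

regions = compute_mro(
    [("GOS128", 102_077_451, "qter"), ("GOS370", 66_706_205, 125_002_355)],
    chromosome_length=134_452_384, chromosome="chr11")
r = regions[0]
print(f"chr11 MRO: {r.start_bp}-{r.end_bp}  support={r.support} "
      f"({', '.join(r.sample_ids)})")
print("# the smallest interval shared by the most tumors: a candidate")
print("# tumor-suppressor locus on 11q\n")

cohort = load_synthetic_wt_cohort()
labels = complexity_summary(cohort)["label"].value_counts()
print(f"cohort size          : {len(cohort.profiles)}")
print(f"fully normal tumors  : {labels['normal']}")
print(f"CNN-LOH-only tumors  : {labels['cnn_loh_only']}")
print(f"chr11 loss/LOH       : {len(chromosome_carriers(cohort, 'chr11', LOSS_LOH_TYPES))}")
print(f"1q gain              : {len(chromosome_carriers(cohort, 'chr1', GAIN_TYPES))}")
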