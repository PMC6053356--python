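"""TCW count vs total mutation count as immunotherapy-response predictors.

Simulates a cohort whose durable-clinical-benefit labels depend on
APOBEC mutation load, then compares the two candidate biomarkers with
logistic regression and the Hosmer-Lemeshow goodness-of-fit test.
"""

import json
from tempfile import TemporaryDirectory

import pandas as pd
from pyfaidx import Fasta

from apobecsig import CohortSpec, compare_predictors, count_tcw, read_maf, simulate_cohort
from apobecsig.catalog import group_records_by_sample

with TemporaryDirectory() as tmp:
    cohort = simulate_cohort(CohortSpec(seed=4, n_samples=40, genome_length=40_000), tmp)
    reference = Fasta(str(cohort.fasta))
    rows = []
    for sid, recs in group_records_by_sample(read_maf(cohort.maf)).items():
        tc = count_tcw(recs, reference)
        rows.append({"sample_id": sid, "tcw_count": tc.tcw_count,
                     "total_count": tc.total_count})
    tcw = pd.DataFrame(rows).set_index("sample_id")
    labels = pd.read_csv(cohort.clinical, sep="\t", index_col=0, dtype=str)

report = compare_predictors(tcw, labels)
for name, stats in report["predictors"].items():
    print(f"{name}: DCB mean {stats['dcb_mean']:.1f} vs NDB mean "
          f"{stats['ndb_mean']:.1f} ({stats['fold_change']:.1f}-fold), "
          f"H-L p = {stats['hl_p_value']:.3f}")
print()
print("Labels were generated from APOBEC load, so the TCW count separates the")
print("groups sharply while total burden barely does; a larger H-L p-value")
print("means the logistic model's predicted probabilities are well calibrated.")
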