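"""Synthetic NSCLC cohort: schema, dose-outcome trend and the ZSV feature.

Generates a seeded cohort with the 5-feature patient state (IP10, GLSZM
zone-size variance, tumor/lung gEUD, cxcr1 genotype), shows that the
outcome rates rise with the clinical dose per fraction, and computes the
ZSV radiomics feature from a small gray-level size-zone matrix.
"""

import numpy as np

from qdrlart import CohortConfig, compute_zsv, generate_cohort
from qdrlart.cohort import records_to_frame

records = generate_cohort(CohortConfig(n_patients=2000, seed=5))
df = records_to_frame(records)
print(f"{len(records)} patients; columns: {', '.join(df.columns[:6])}, ...")

terc = df.clinical_dose.rank(pct=True).apply(lambda p: min(int(p * 3), 2))
print("P(LC=1)  by dose tercile:", df.groupby(terc).lc.mean().round(3).tolist())
print("P(RP2=1) by dose tercile:", df.groupby(terc).rp2.mean().round(3).tolist())
print("outcome classes (LC,RP2):",
      df.groupby(["lc", "rp2"]).size().to_dict())

# Zone-size variance of a GLSZM: zones of sizes {1,1,2,2} have variance 0.25.
glszm = np.array([[1, 1],
                  [1, 1]])
print("ZSV of a 2x2 GLSZM with equal 1- and 2-voxel zones:", compute_zsv(glszm))
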