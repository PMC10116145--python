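"""Screen a simulated MCI / healthy-control sample.

Draws a case-control sample with the published group score summaries,
converts raw scores to adjusted z-scores, applies the min-z impairment
rule at z < -0.4, and summarizes discrimination (confusion matrix,
sensitivity/specificity, Youden J, ROC/AUC, optimal cutoff).
"""

import numpy as np

from c3b import norms, screening, simulate

df = simulate.generate_case_control(simulate.CaseControlSpec(seed=5))
models = norms.builtin_models()

records = []
for _, row in df.iterrows():
    demo = norms.Demographics(row["age"], row["education"], int(row["sex"]), int(row["race"]))
    z_pst = norms.adjusted_z(row["pst_raw"], models["PST"], demo)
    z_vmt = norms.adjusted_z(row["vmt_raw"], models["VMT"], demo)
    records.append(
        screening.ScreeningRecord(
            subject_id=row["id"],
            z_pst=z_pst,
            z_vmt=z_vmt,
            call=screening.classify(z_pst, z_vmt),
            truth=row["group"],
        )
    )

cm = screening.confusion(records)
sens, spec, j = screening.diagnostics(cm)
print(f"confusion at z < -0.4: TP {cm.tp}  FP {cm.fp}  TN {cm.tn}  FN {cm.fn}")
print(f"sensitivity {sens:.2f}, specificity {spec:.2f}, Youden J {j:.2f}")

min_z = np.array([r.min_z for r in records])
truth = [r.truth for r in records]
curve = screening.roc(-min_z, truth)
cutoff, j_opt = screening.youden_optimal_z_cutoff(min_z, truth)
print(f"AUC {curve.auc:.3f}; Youden-optimal cutoff z < {cutoff:.2f} (J {j_opt:.2f})")
# Sensitivity lands near the published validation figure (0.90);
# specificity runs lower than the published 0.83 because the published
# cutoff was optimized in-sample on its own 30 controls, while this
# sample is a fresh draw from the group-level summaries.
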