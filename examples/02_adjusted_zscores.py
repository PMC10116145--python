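"""Demographically adjusted z-scores for two contrasting patients.

The same raw score means very different things for a 30-year-old with 16
years of education and a 60-year-old African-American man with 10 years:
the published regression norms predict each patient's expected score and
express the deficit in residual-SD units.
"""

from c3b import norms

models = norms.builtin_models()

patients = {
    "patient 1 (age 30, educ 16, F, non-AA)": norms.Demographics(30, 16, sex=0, race=0),
    "patient 2 (age 60, educ 10, M, AA)": norms.Demographics(60, 10, sex=1, race=1),
}

for label, demo in patients.items():
    print(label)
    for tid, raw in (("PST", 36), ("VMT", 33)):
        m = models[tid]
        pred = norms.predicted_score(m, demo)
        z = norms.adjusted_z(raw, m, demo)
        call = "impaired" if z < -0.4 else "WNL"
        print(f"  {tid}: raw {raw}, predicted {pred:5.1f}, z {z:+.2f} -> {call}")
# A z below the screening cutoff (-0.4) flags the score as impaired for
# that patient's demographic stratum; identical raw scores can be
# impaired for one patient and within normal limits for another.
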