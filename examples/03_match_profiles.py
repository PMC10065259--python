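"""Match normalized views into multiomic profiles.

A profile is one (mouse, group, week) key; a view that never measured a
profile is marked unobserved there rather than imputed.  Duplicate
samples for one key (e.g. two muscle preps of the same mouse) are
averaged on the normalized scale.
"""

import momfa
from momfa import pipeline
from momfa.matching import missingness_report

study = momfa.simulate_study(
    momfa.StudyDesign(n_mice_per_group=4, muscle_replicate_fraction=0.3),
    momfa.TruthModel(n_features={"muscle_rna": 300, "blood_rna": 300,
                                 "lipids": 100, "metabolites": 50}),
    seed=3,
)
views, reports = pipeline.preprocess_views(study["views"], momfa.RunConfig())
ps = pipeline.build_profiles(views, study["meta"])

print(f"profiles: {ps.n_profiles} (union of (mouse, group, week) keys)")
print("\nobserved profiles and data points per view:")
print(missingness_report(ps).to_string(index=False))
print("\nThe total row counts omic data points the way the study design "
      "does: one per (view, profile) actually measured.")
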