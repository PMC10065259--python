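"""Generate a synthetic longitudinal four-view study and look at its layout.

The generator emulates a 30-week dystrophic-mouse experiment: 4 genotype
groups, blood drawn every 6 weeks, muscle assayed only at sacrifice
(week 30), and each (mouse, week) blood draw assayed either by RNA-seq
or by the two plasma LC-MS views — never both.
"""

import momfa

design = momfa.StudyDesign(n_mice_per_group=5)
truth = momfa.TruthModel(
    n_features={"muscle_rna": 400, "blood_rna": 400, "lipids": 120,
                "metabolites": 60}
)
study = momfa.simulate_study(design, truth, seed=1)

print("views (features x samples):")
for name, view in study["views"].items():
    print(f"  {name:12s} {view.n_features:4d} x {view.n_samples}")
print(f"metadata rows: {len(study['meta'])}")
print(f"true factors:  {truth.n_factors_true} "
      "(disease offset, growth trend, early-disease interaction)")

# Every (mouse, week) pair goes to exactly one blood assay arm:
assays = study["assays"]
print("\nassay partition of (mouse, week) pairs:")
print(assays["assay"].value_counts().to_string())
print("\nThe muscle view only holds week-30 samples, and the plasma views "
      "are disjoint from blood RNA by design — this cross-view missingness "
      "is what the downstream factor model has to absorb.")
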