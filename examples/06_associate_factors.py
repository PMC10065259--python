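"""Relate latent factors to genotype group and time.

Runs the full workflow on a default-size synthetic study, then tests
each latent factor against mouse group and week with one-way F-tests
(BH-adjusted across factors) and the group-by-week interaction model.
The generator's first true factor is a disease signature (WT offset vs
dystrophic groups plus a week-6 spike), so its matched estimate should
come out significant for both group and week.
"""

import momfa
from momfa import pipeline
from momfa.gfa import match_factors

study = momfa.simulate_study(
    momfa.StudyDesign(n_mice_per_group=6),
    momfa.TruthModel(n_features={"muscle_rna": 600, "blood_rna": 600,
                                 "lipids": 200, "metabolites": 80}),
    seed=6,
)
cfg = momfa.RunConfig(thresholds=(0.02, 0.10), seeds_per_threshold=2,
                      k_init=8, top_k_genes=500)
views, _ = pipeline.preprocess_views(study["views"], cfg)
ps = pipeline.prepare_for_factors(
    pipeline.build_profiles(views, study["meta"]), cfg
)
ens = momfa.run_ensemble(ps, cfg)
best = momfa.select_best_per_k(ens)
curve = momfa.selection_curve(best, ps)
k, fit = momfa.select_model(curve, best)

assoc = momfa.lf_anova(fit.Z, ps.profiles)
cols = ["factor", "r2_group", "r2_week", "r2_interaction", "q_group", "q_week"]
print(assoc[cols].round(4).to_string(index=False))

truth = study["scores"].set_index(["mouse_id", "week"])
keys = list(zip(ps.profiles["mouse_id"], ps.profiles["week"]))
zcols = [c for c in truth.columns if c.startswith("Z")]
pairs = match_factors(truth.loc[keys, zcols].to_numpy(), fit.Z)
disease = next(j for i, j, _ in pairs if i == 0)
row = assoc.iloc[disease]
print(f"\nthe injected disease factor matched estimated LF{disease + 1} "
      f"(q_group = {row['q_group']:.2g}, q_week = {row['q_week']:.2g}).")
print("q_group < 0.05 marks it as a genotype-separating signature; its "
      "week-6 spike also drives a time association, though at this "
      "reduced study size the fit sometimes splits that part into a "
      "separate factor.")

top = momfa.top_loadings(fit, "muscle_rna", disease, 5)
print("\ntop-5 muscle features driving that factor (signed loadings):")
print(top.to_string(index=False))
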