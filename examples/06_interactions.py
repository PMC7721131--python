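"""Discover two-way interactions under strong hierarchy and refit with GxE.

Plants one real gene-environment product effect, runs the hierarchical
group-lasso over all candidate pairs, and re-introduces the discovered GxE
terms into the elastic net to test hold-out improvement.
"""

import geinterplay as gi

cfg = gi.calibrated_preset(
    seed=6, n_individuals=3000, gxe_effects=[(0, 0, 0.3)])
cohort = gi.simulate_score_cohort(cfg)
panel = gi.panel_from_cohort(cohort, seed=6)

cols = panel.columns(("gps", "environment"))
roles = [panel.roles[c] for c in cols]
cand = gi.build_candidates(roles)
print(f"{len(cols)} predictors -> {cand.n_candidates} candidate pairs "
      f"({sum(k == 'GxE' for k in cand.classes)} GxE)")

sel = gi.fit_hierarchical(panel.matrix(("gps", "environment"), train=True),
                          panel.outcome_vector(train=True),
                          roles=roles, n_lambda=20, seed=6)
print(f"selected {len(sel.main_effects)} mains and {len(sel.pairs)} pairs "
      f"at lambda = {sel.lam:.4f}; strong hierarchy holds: "
      f"{sel.satisfies_strong_hierarchy()}")
for p in sel.pairs:
    print(f"  {cols[p.i]} x {cols[p.j]}  [{p.klass}]  weight {p.weight:+.3f}")

gxe = [(cols[i], cols[j]) for i, j in sel.gxe_pairs()]
if gxe:
    config = gi.ElasticNetConfig(alpha_grid=(0.5, 1.0), n_lambda=40,
                                 repeats=3, seed=6)
    base = gi.fit_three_models(panel, config)["G+E"]
    aug = gi.refit_with_gxe(panel, gxe, config)
    print(f"\nhold-out R2: G+E = {base.holdout.r2:.3f}, "
          f"G+E+GxE = {aug.holdout.r2:.3f}")
    print("A planted product effect should lift the augmented model; on "
          "additive data\nthe difference stays within bootstrap noise.")
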