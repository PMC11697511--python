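"""A complete synthetic study: counts + surveys + growth -> causal ranking.

Generates a 40-genus study with a planted positive effect of the focal
symbiont on both disease susceptibility (beta = 0.8) and growth rate
(beta = 0.6), runs the whole pipeline, and prints the selected PGLS tests
and the CICc ranking of causal models.
"""

import phylosym as ps

bundle = ps.make_mini_gcmp(seed=7)
cfg = ps.RunConfig(compute_beta=False)
traits, comp, path = ps.run_all(bundle, cfg)

print(f"trait table: {traits.table.shape[0]} genera x {traits.table.shape[1]} traits")
print(f"genera with disease data: {traits.table['disease_prevalence'].notna().sum()}, "
      f"with growth data: {traits.table['growth_mm_yr'].notna().sum()}\n")

sel = comp.results[comp.results["selected"]]
focal = sel[sel["predictor"].str.startswith("endozoicomonas")]
print("selected PGLS fits for the focal taxon (AICc winners):")
print(
    focal[["response", "predictor", "model", "n", "coefficient", "r2", "p", "q"]]
    .round(4)
    .to_string(index=False)
)

print("\ntop causal models (Brownian):")
bm = path.ranking_table[path.ranking_table["evo_model"] == "BM"].head(4)
print(bm[["rank", "edges", "C", "p", "CICc", "delta_CICc"]].round(3).to_string(index=False))

print("\naveraged standardized path coefficients:")
print(path.averaged_table.round(3).to_string(index=False))
print(
    "\nThe tissue abundance-disease and abundance-growth tests should be"
    "\nsignificant (q < 0.05) and the models linking the symbiont to both"
    "\nhost traits should dominate the CICc ranking."
)
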