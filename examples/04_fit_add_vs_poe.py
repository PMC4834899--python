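"""Train the additive and parent-of-origin prediction models on simulated data.

Simulates a population, overlays a strongly imprinted trait (rho = 0,
s = 0.6, so 60% of QTL have one parental copy fully silenced), trains on
generation 2 with generation 3 masked, and compares predictive accuracy.
The POE model carries separate maternal and paternal substitution effects
per SNP plus a gametic pedigree term; the ADD model uses one additive
effect per SNP.
"""

import numpy as np

from poegp import (SimConfig, simulate_population, export_dataset,
                   draw_qtl_effects, assign_imprint_status, simulate_phenotypes,
                   Pedigree, relationship_matrices,
                   assemble_model, default_priors, run_gibbs, McmcConfig,
                   evaluate)

cfg = SimConfig(n_chrom=2, snps_per_chrom=150, n_qtl=20,
                founder_males=50, founder_females=50, hist_generations=300,
                recent_generations=3, recent_size=250, seed=7)
pop = simulate_population(cfg)
data = export_dataset(pop, pop.generations_present())

rng = np.random.default_rng(7)
effects = draw_qtl_effects(data.qtl_ids, data.qtl_maternal, data.qtl_paternal,
                           data.genotypes.ids, rng, h2=0.5)
scenario = assign_imprint_status(data.qtl_ids, s=0.6, rho=0.0, rng=rng)
pheno = simulate_phenotypes(data.qtl_maternal, data.qtl_paternal,
                            effects, scenario)

gen = data.pedigree["generation"].to_numpy()
keep = (gen == 2) | (gen == 3)
geno = data.genotypes.subset_individuals(keep)
y = pheno.phenotype[keep]
observed = (gen[keep] == 2)          # generation 3 is masked for prediction
rel = relationship_matrices(Pedigree.from_frame(data.pedigree))
mcmc = McmcConfig(iterations=4000, burn_in=1000, thin=5, seed=1)

for kind in ("ADD", "POE"):
    spec = assemble_model(kind, geno, kinship=rel, include_polygenic=True,
                          include_gametic=(kind == "POE"))
    priors = default_priors(y, spec, mask_observed=observed)
    fit = run_gibbs(spec, priors, mcmc, y, mask_observed=observed,
                    keep_effect_samples=False)
    m = evaluate(y[~observed], fit.linpred_mean[~observed])
    print(f"{kind}: {spec.n_marker_coefficients} marker coefficients; "
          f"test Pearson {m.pearson:.3f}, test MSE {m.mse:.3f}")
print("\nThe POE model can exploit the parental origin of each allele, which "
      "the additive coding discards — but it doubles the marker parameters, "
      "so on a single miniature replicate like this one either model may come "
      "out ahead.  The averaged scenario grid (example 06) shows the "
      "systematic pattern: POE wins under strong imprinting, ADD without it.")
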