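"""Test quantitative traits for sexual dimorphism across plantation sites.

Simulates sex-homomorphic traits (latitude effect, genotype effect, no sex
effect) plus one genuinely dimorphic trait, then runs the per-trait pipeline:
BIC covariate selection, interaction screen, sex LRT, omega-squared.
"""

import pandas as pd

from dioecy import (SimConfig, TraitSimConfig, simulate_population,
                    simulate_traits, run_battery, multi_site_battery)

cfg = SimConfig(n_individuals=300, n_background_snps=0, n_sdr_snps=1, seed=3)
_, samples, _ = simulate_population(cfg)

tables = []
for k in range(8):
    tc = TraitSimConfig(trait_name=f"null_trait_{k}", beta_lat=0.3,
                        delta_sex=0.0, sigma_G=0.5, sigma_E=1.0)
    tables.append(simulate_traits(tc, samples, seed=100 + k))
dimorphic = TraitSimConfig(trait_name="dimorphic_trait", beta_lat=0.3,
                           delta_sex=1.0, sigma_G=0.5, sigma_E=1.0)
tables.append(simulate_traits(dimorphic, samples, seed=200))
traits = pd.concat(tables, ignore_index=True)

battery = run_battery(traits)
print(battery[["trait", "engine", "covariates", "p_sex", "omega2_sex",
               "q_value"]].to_string(index=False))

# Repeatability of one null trait across three independent "sites"
tc = TraitSimConfig(trait_name="null_trait_0", beta_lat=0.3, delta_sex=0.0,
                    sigma_G=0.5, sigma_E=1.0)
tabs = {f"site{s}": simulate_traits(tc, samples, seed=300 + s)
        for s in range(3)}
ms = multi_site_battery(tabs, "null_trait_0")
print("\nper-site p_sex:", {k: round(v, 3) for k, v in ms["p_sex"].items()},
      "repeatable:", ms["repeatable"])

# Only the constructed dimorphic trait shows a small sex p-value and a
# non-trivial omega^2; null traits scatter around nominal significance and
# never replicate across sites, the signature of sexual homomorphism.
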