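"""Simulate a two-breed half-sib population with known trait architecture.

Builds 2 x 300 offspring from 15 sires per breed at 500 SNPs, plants a trait
with 40% additive and 10% dominance variance, and prints the realized
variance decomposition next to the configured targets.
"""

import pandas as pd

from hetvar import SimConfig, simulate_genotypes, simulate_phenotypes, truth_from_fractions

cfg = SimConfig(n_breeds=2, animals_per_breed=300, n_sires_per_breed=15,
                n_snps=500, seed=42)
G, ped = simulate_genotypes(cfg)
print(f"simulated {G.n_animals} genotyped offspring x {G.n_snps} SNPs")
print(f"pedigree holds {len(ped)} animals incl. founder sires/dams")

truth = truth_from_fractions(G, va_frac=0.4, vd_frac=0.1, seed=43)
y, components = simulate_phenotypes(G, ped, truth, seed=44)

print("\nrealized variance decomposition (trait units^2):")
print(components.var(ddof=1).round(4).to_string())
print("\nThe additive and dominance rows are calibrated to exactly 0.40 and")
print("0.10 of a unit phenotypic variance; the residual absorbs the rest.")
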