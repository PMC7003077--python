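"""Simulate a half-sib breeding panel with GBS genotypes and trial phenotypes.

Builds a scaled-down version of the study design (multi-population polycross,
2 locations x 3 replicates, low-coverage genotyping), then prints the realized
sequencing statistics next to their targets.
"""

import numpy as np

from ryegp import SimulationConfig, TraitModel, simulate_gbs_reads, simulate_population_set, simulate_trial

config = SimulationConfig(
    n_populations=5,
    families_per_population=(40, 42, 45, 44, 34),  # same proportions, 1/2.5 scale
    n_snps=2000,
    mean_depth=2.98,
    missing_rate=0.23,
    seed=1,
    traits={"Na": TraitModel(sigma2_g=2.32e-3, sigma2_gs=0.25e-3, sigma2_e=3.93e-3)},
)

founders = simulate_population_set(config)
reads = simulate_gbs_reads(founders)
trial = simulate_trial(founders)

depth = np.asarray(reads.depth)
print(f"families: {founders.n_parents} across {config.n_populations} populations")
print(f"plots:    {len(trial)} (= families x 2 locations x 3 replicates)")
print(f"mean read depth (covered cells): {depth[depth > 0].mean():.2f}  (target 2.98)")
print(f"missing genotype calls:          {(depth == 0).mean():.1%}   (target 23%)")
print(f"maternal breeding-value variance: {founders.breeding_values['Na'].var():.2e}"
      f"  (= 2 x family variance {2 * 2.32e-3:.2e})")
# Half of each maternal breeding value is passed to the family, so markers on
# the mothers can explain at most half of the family variance — the same
# ceiling a real polycross design imposes.
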