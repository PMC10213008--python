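"""Generate a synthetic twin-family GWAS dataset and inspect its structure.

Builds the reference design: 250 nuclear families (parents + MZ twins),
50 SNPs in five correlated blocks, four causal SNPs whose effect sizes are
set by the per-SNP heritability parameter h, and ACE phenotype noise with
variance components (4, 1, 1).
"""

import numpy as np

from snpevals import SimConfig, simulate_dataset

config = SimConfig(h=10.0)
dataset, truth = simulate_dataset(config, seed_or_rng=1)

y = np.concatenate([f.y for f in dataset.families])
print(f"families: {dataset.m}, individuals: {dataset.n}, SNPs: {dataset.p_g}")
print(f"causal SNPs (0-based indices): {list(truth.causal_indices)}")
print("causal effect sizes:", np.round(truth.beta_g[list(truth.causal_indices)], 3))
print(f"empirical trait variance: {np.var(y):.2f}  (error components sum to 6)")

twins = np.array([[f.y[2], f.y[3]] for f in dataset.families])
print(f"MZ-twin phenotype covariance: {np.cov(twins.T)[0, 1]:.2f}  (sigma_a^2 + sigma_c^2 = 5)")

# The four causal SNPs each add h/100 = 0.1 to the trait variance, i.e. each
# explains h/(sigma_a^2+sigma_c^2+sigma_e^2) percent (~1.7%) of the error
# variance - realistic single-variant effect sizes for a complex trait.
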