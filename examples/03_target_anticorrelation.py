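"""Bootstrap-KS test for target anticorrelation with an age-rising miRNA.

Simulates a 2000-gene x 25-sample (5 ages x 5 animals) expression matrix
where the miRNA rises 15-fold with age and represses its 200 targets, then
asks: are target-vs-miRNA Pearson correlations shifted left of a
size-matched bootstrap of non-target genes?
"""

import numpy as np

from mirage import AnticorrConfig, SimulationConfig, anticorrelation_test, simulate_expression

cfg = SimulationConfig(rng_seed=7)  # coupling=1, noise_sigma=0.3 defaults
expr, mirna, truth = simulate_expression(cfg)
by_age = mirna.groupby(expr.samples["age_weeks"]).mean()
print(f"miRNA mean by age (weeks): "
      + ", ".join(f"{a:g}w={v:.0f}" for a, v in by_age.items()))

res = anticorrelation_test(expr, mirna, truth.target_gene_ids,
                           AnticorrConfig(B=1000, rng_seed=7))
print(f"mean target r = {res.target_r.mean():.3f}  "
      f"mean bootstrap-null r = {np.mean(res.null_r):.3f}")
print(f"KS D = {res.D:.3f}, p = {res.p:.3g} "
      f"(effective null size {res.n_null_effective} non-target genes)")
# A D near 1 with a vanishing p says the target correlation distribution
# sits far left of the null: the hallmark of genuine miRNA repression.
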