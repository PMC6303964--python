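"""Partition genetic variance with the full GBLUP model by Gibbs sampling.

Fits y = Xb + f b + Z(g_A + g_D + g_AA + g_AD + g_DD) + Z pe + e on a small
simulated data set and reports posterior means of the variance components,
the heritability ratios, the inbreeding depression slope, DIC and the
effective sample sizes of the chains.
"""

import epiblup as eb

genotypes, records, truth = eb.scenario_sow_litter(seed=3, n_individuals=300,
                                                   m_snps=600)
freqs = eb.allele_frequencies(genotypes)
f = eb.genomic_inbreeding(genotypes)
grms = eb.build_grms(genotypes, freqs)

spec = eb.ModelSpec(terms=("A", "D", "AA", "AD", "DD"))
design = eb.build_design(records, spec, f, genotypes.individual_ids)
chain = eb.gibbs_sample(design, grms,
                        eb.ChainConfig(n_iter=5000, burn_in=1000, thin=5, seed=3))
summary = eb.variance_ratios(chain, spec)

print(f"model {summary.model}")
for comp, mean in summary.component_mean.items():
    sd = summary.component_sd[comp]
    print(f"  {comp:8s} {mean:6.3f} +/- {sd:.3f}   ESS {summary.ess[comp]:.0f}")
print(f"h2 = {summary.h2:.3f} +/- {summary.h2_sd:.3f}   "
      f"d2 = {summary.d2:.3f}   i2 = {summary.i2:.3f}")
print(f"inbreeding depression b = {summary.b_mean:.2f} +/- {summary.b_sd:.2f} "
      "piglets per unit homozygosity "
      f"({0.1 * summary.b_mean:.2f} per 10% inbreeding)")
print(f"DIC = {summary.dic:.1f} (pD = {summary.p_d:.1f})")
print("h2/d2/i2 are the additive, dominance and summed pairwise-epistatic "
      "variances as fractions of the total phenotypic variance per sample.")
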