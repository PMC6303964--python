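"""Build the orthogonal genomic relationship matrices.

The additive matrix uses VanRaden centering, the dominance matrix the
orthogonal NOIA coding, and the three pairwise epistatic matrices are
trace-normalized Hadamard products: G_AA = (G_A . G_A) / (tr(G_A . G_A)/n),
so that tr(G)/n = 1 for every epistatic component.
"""

import numpy as np

import epiblup as eb

genotypes, _, _ = eb.scenario_sow_litter(seed=2, n_individuals=200, m_snps=500)
freqs = eb.allele_frequencies(genotypes)

M = eb.additive_incidence(genotypes, freqs)
W = eb.dominance_incidence(genotypes, freqs)
print(f"M columns sum to zero (max |sum| = {np.abs(M.values.sum(0)).max():.2e})")

g_a = eb.grm_additive(M)
g_d = eb.grm_dominance(W)
g_aa = eb.epistatic_grm(g_a, g_a)
g_ad = eb.epistatic_grm(g_a, g_d)
g_dd = eb.epistatic_grm(g_d, g_d)

for g in (g_a, g_d, g_aa, g_ad, g_dd):
    print(f"G_{g.component:<2} trace/n = {np.trace(g.values)/g.n:.6f}  "
          f"norm constant = {g.norm_constant:.4f}")
print("trace/n = 1 puts every component's variance on a comparable scale;")
print("for unrelated HWE individuals the epistatic matrices are close to "
      "identity, which is why epistatic variance is hard to separate from "
      "permanent environmental variance.")
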