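"""Simulate a litter-size-like population and run genotype quality control.

Generates unlinked HWE genotypes with variable genomic homozygosity,
repeated litter records per sow, and known additive/dominance/epistatic
architecture, then applies the standard marker filters.
"""

import epiblup as eb

genotypes, records, truth = eb.scenario_sow_litter(seed=1, n_individuals=300,
                                                   m_snps=600)
print(f"simulated {genotypes.n_individuals} sows x {genotypes.n_snps} SNPs, "
      f"{len(records)} litter records")
print(f"phenotype mean {records.df['y'].mean():.2f}, SD {records.df['y'].std():.2f}"
      "  (litter-size scale: ~12.7 +/- 3.1)")

clean, report = eb.apply_qc(genotypes)
print(f"QC kept {report.n_snps_out}/{report.n_snps_in} SNPs "
      f"(MAF removed {report.removed_maf}, HWE removed {report.removed_hwe})")

f = eb.genomic_inbreeding(clean)
print(f"genomic homozygosity f: mean {f.mean():.3f}, SD {f.std():.3f}")
print("f is the proportion of homozygous SNPs per sow; its spread drives the "
      "inbreeding-depression covariate in the evaluation model.")
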