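"""Simulate a balanced case/control phenotype, then watermark the dataset.

The phenotype is a logit (liability) model over a random 10% causal-SNP
subset; exactly half the samples become cases. Watermark SNPs are
fabricated columns with alt-allele frequency z0 + eps among cases and
z0 - eps among controls, so a GWAS returning anything but an extreme
p-value on them signals a corrupted computation.
"""

import numpy as np

from genosynth import (
    FounderConfig,
    PhenoParams,
    WatermarkParams,
    association_test,
    generate_watermarks,
    select_causal_snps,
    simulate_founders,
    simulate_phenotype,
)

gm = simulate_founders(
    FounderConfig(group_sizes={"European": 4000}, n_snps=200, fst=0.05, seed=4)
)
rng = np.random.default_rng(5)
causal = select_causal_snps(gm.snp_ids, 0.10, rng)
pheno = simulate_phenotype(gm, causal, PhenoParams(effect_sd=0.5), rng)
print(f"causal SNPs: {len(causal)} of {gm.n_snps}")
print(f"cases/controls: {pheno.n_cases}/{len(pheno.sample_ids) - pheno.n_cases}")

p_causal = association_test(
    gm.genotypes[:, gm.snp_ids.index(causal[0])], pheno.values
)
print(f"association p of one causal SNP: {p_causal:.2e}")

block = generate_watermarks(pheno, WatermarkParams(), rng, set(gm.snp_ids))
print(f"watermarks: {len(block.snp_ids)}, mean p = {block.p_values.mean():.2e}, "
      f"max p = {block.p_values.max():.2e}")
# Watermark p-values are astronomically small by construction; causal-SNP
# p-values vary with the drawn effect size.
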