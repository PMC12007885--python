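# genosynth

Generate **balanced synthetic genotype datasets** from any ancestry-labelled,
additively-encoded SNP matrix — with privacy-perturbed samples, a simulated
case/control phenotype, watermark SNPs for verifying outsourced GWAS
computations, and Mendelian synthetic relatives with ground-truth kinship.

Real genotype cohorts are dominated by European-ancestry samples and are
hard to share. `genosynth` takes a founder matrix (real, or simulated by its
own Balding–Nichols module when the real data are access-restricted) and
produces a dataset with equal representation across six ancestry groups,
known gene–phenotype associations, and known family structure — a controlled
benchmark for GWAS methods, kinship inference, and cloud-computation
integrity checks.

## The core mechanisms

**Privacy perturbation.** Synthetic samples are perturbed copies of real
ones under a constrained three-state randomized response. With genotype
states d = 3 and privacy parameter ε:

- state 0 or 2 flips to 1 with probability q = 2/(e^ε + d − 1),
- state 1 flips to 0 or 2 with probability q = 1/(e^ε + d − 1) each,
- direct 0 ↔ 2 transitions never occur.

At the default ε = 6 the flip probabilities are ≈ 0.49% and 0.25%, so
synthetic samples keep allele-frequency and ancestry structure while never
being identical to their source. Candidates that are identical to their
source or fall outside their ancestry group's region in PC space (distance
to centroid > the group's 97.5th-percentile member radius) are rejected.

**Phenotype.** A random 10% of SNPs become causal with N(0, 0.5²)
coefficients; a logistic liability ℓᵢ = β₀ + Σₖ βₖ gᵢₖ + εᵢ is thresholded
at its median so cases and controls are exactly balanced.

**Watermarks.** Each watermark SNP has alternate-allele frequency
z₀ + eps among cases and z₀ − eps among controls (defaults z₀ = 0.49,
eps = 0.3), realised as Hardy–Weinberg genotype counts shuffled within each
arm. A likelihood-ratio logistic test gives each column its ground-truth
p-value.

**Relatives.** Per group, 400 synthetic samples are paired into 200
father–mother pairs producing 200 first-degree descendants; re-pairing
descendants yields 100 second- and 50 third-degree descendants
(350/group, 2,100 over six groups). Kinship is verified with the KING
coefficient φ(i,j) = (2n₁₁ − 4(n₀₂ + n₂₀) − n\*₁ + n₁\*) / (4 n₁\*).

Upstream of all of this sits PLINK-style QC (MAF ≥ 0.01, call-rate filters
at 5%, exact Hardy–Weinberg test at p ≥ 1e−6) and PCA stratification.

## Worked example

```python
from genosynth import DEFAULT_ANCESTRIES, FounderConfig, RunConfig, validate
from genosynth.ldp import SynthesisConfig
from genosynth.pedigree import GenerationSchedule
from genosynth.pipeline import run_pipeline

config = RunConfig(
    founder=FounderConfig(
        group_sizes={label: 80 for label in DEFAULT_ANCESTRIES},
        n_snps=400, fst=0.1, maf_range=(0.1, 0.5), missing_rate=0.01,
    ),
    synthesis=SynthesisConfig(per_group_target=200),
    schedule=GenerationSchedule(n_founders_selected=60, counts=(30, 15, 7)),
    seed=42,
    out_dir="bundle",
)
bundle = run_pipeline(config)
report = validate(bundle, bundle.samples)
```

Running this (it is `examples/06_full_pipeline.py`) prints:

```
samples:   1200 x 395 SNPs
relatives: 312
watermarks: 20, kinship pairs: 1488
kinship means by degree: {'first-degree': 0.249, 'second-degree': 0.12, 'third-degree': 0.063}
```

1,200 synthetic samples (6 × 200) over the 395 SNPs that survived QC, 312
relatives (6 × 52 from the 30/15/7 schedule), and mean KING coefficients at
the textbook values 0.25 / 0.125 / 0.0625 per relationship degree. Five CSV
files are written: the sample SNP matrix, the phenotype labels, the
watermark block (with a trailing p-value row), the kinship-relatedness
table, and the relatives' SNP matrix. The `examples/` directory has one
short script per capability; `genosynth --help` lists the equivalent CLI
subcommands (`simulate-base`, `qc`, `stratify`, `synthesize`, `phenotype`,
`watermark`, `relatives`, `kinship`, `run-all`, `validate`).

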