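# Methods

This note documents the models behind each stage, the defaults and why,
the numerical choices, and what the synthetic founder data do and do not
emulate.

## Founder simulation (`basepop`)

The founder module stands in for a real multi-ancestry cohort. Each SNP
gets an ancestral alternate-allele frequency p ~ Uniform(maf_range); each
ancestry group draws its own frequency from the Balding–Nichols
parameterisation Beta(p(1−F)/F, (1−p)(1−F)/F), whose mean is p and whose
variance is F·p(1−p); genotypes are Binomial(2, p_group) per sample, and
missingness is independent per call. Defaults: six groups of equal size,
F = 0.1 (continental-scale divergence, comfortably PCA-separable),
maf_range (0.05, 0.5), missing_rate 0.

What this emulates: group-differentiated allele frequencies, PCA-separable
population structure, additive encoding, missing calls. What it does not:
linkage disequilibrium (sites are independent), realistic site-frequency
spectra, relatedness among founders, genotyping-batch artefacts. Tests
passing on this generator therefore certify the *mechanisms* (perturbation
rates, Mendelian transmission, count arithmetic, estimator formulas), not
performance on real LD-structured genomes.

## Quality control (`qc`)

Filter order: samples with missing rate > 5% first (mirroring common
PLINK practice of --mind before the SNP filters), then SNPs by missing
rate > 5%, MAF < 0.01, and exact Hardy–Weinberg p < 1e−6. The HWE test is
the exact conditional test (Wigginton-style, standard p, not mid-p),
computed in log space with a 1e−9 relative tolerance when comparing
configuration probabilities so structurally tied configurations are
included regardless of round-off; it matches an exact-rational enumeration
oracle to 1e−12 for totals ≤ 50.

After filtering, residual missing calls are imputed to the per-SNP modal
genotype (ties to the lower value). This is a deliberate artifact choice:
every downstream stage (perturbation, PCA projection, phenotype,
watermarks, breeding, KING) assumes complete data. Mode imputation
slightly shrinks heterozygosity at high missingness; at the default ≤ 5%
missingness the effect is negligible.

Note that pooling diverged groups induces a real heterozygote deficit
(Wahlund effect), so on strongly structured input the HWE stage removes
the most diverged SNPs. This matches what the same filters do on real
mixed cohorts.

## Stratification (`stratify`)

PCA of the column-centered genotype matrix via thin SVD. Components
default to min(200, samples − 1, SNPs): 200 follows common practice for
large cohorts while the min() keeps desk-scale runs valid. Signs are fixed
by making the largest-magnitude loading of each component positive, so
scores are reproducible across runs and BLAS builds.

"Significantly deviates from the target ancestry group" is
operationalised as Euclidean distance in PC space from the group centroid
exceeding the group's 97.5th-percentile member radius (slack multiplier
configurable, default 1.0). The rule is scale-free and uses all fitted
components; with few components it tightens slightly because noise
dimensions are excluded.

## Privacy perturbation and synthesis (`ldp`)

The constrained randomized response over d = 3 genotype states:
q_extreme = 2/(e^ε + d − 1) from states 0/2 (always to 1) and
q_het = 1/(e^ε + d − 1) from state 1 to each homozygote. All states share
the stay-probability 1 − 2/(e^ε + 2); 0 ↔ 2 transitions are structurally
impossible, preserving biologically plausible single-allele steps. The
reported transition matrix is made row-stochastic to the last ulp by
compensating the round-off of the stay probability.

Default ε = 6 per group; because every sample belongs to exactly one
group, parallel composition keeps the overall budget at 6. The synthesis
loop draws source originals uniformly with replacement (so groups smaller
than the 5,000-per-group target can still fill it), perturbs whole rows,
and rejects candidates that are (a) genotype-identical to their source or
(b) ancestry-inconsistent. Identity is checked against the candidate's own
source by default — the cheapest rule satisfying the non-identity
requirement — with an `identity_filter="all"` mode for strict
dissimilarity to every original. The rejection loop is capped at 50× the
target to guarantee termination, reporting the acceptance rate on failure.
Rejected candidates are not counted against the privacy budget; whether
they should be is an open modelling question documented here rather than
resolved.

Sample IDs are unique random integers from [1,000,000, 9,999,999] assigned
across all groups after synthesis, and rows are re-ordered ascending by
ID, decoupling row order from group membership.

## Phenotype (`phenotype`)

Causal set: a uniform random round(0.10 × SNPs) subset (minimum 1).
Coefficients β ~ N(0, 0.5²) — at typical allele frequencies this yields
per-SNP odds ratios roughly in 1.1–3, a realistic GWAS range. Liability is
β₀ + Gβ + logistic noise; standard-logistic noise makes the model the
exact latent-variable form of logistic regression. Exact balance is
enforced by thresholding the liability at its case-fraction quantile
(default 0.5), ties broken by sample order; this guarantees the promised
case count for every input, unlike independent Bernoulli draws. The
intercept defaults to 0 and is immaterial under quantile thresholding.
Rounding is half-up for determinism. The causal set and coefficients are
exported as a sidecar JSON for benchmarking.

In the full pipeline the phenotype is simulated on the combined
original + synthetic matrix (configurable), but only synthetic-sample
labels are exported: in the intended use the originals are restricted
data. The exported subset is therefore balanced only approximately; exact
balance holds on the matrix the model was simulated on.

## Watermarks (`watermark`)

Target alternate-allele frequencies z₀ + eps (cases) and z₀ − eps
(controls), defaults z₀ = 0.49, eps = 0.3. Arm counts are Hardy–Weinberg
genotype expectations n(1−p)², 2np(1−p), np² rounded by largest remainder,
which conserves each arm's size exactly; remainders are rounded to 9
decimals before ranking so float noise cannot flip a tie (ties prefer the
lower genotype). The column is initialised as a copy of the phenotype
vector and then overwritten arm-by-arm with a uniform arrangement of the
planned counts.

The association test is a likelihood-ratio test of intercept + genotype
vs intercept-only logistic regression — more stable than a Wald test under
the near-separation these columns induce. The null log-likelihood is
closed-form; the alternative fit is iteration-capped with a
ridge-stabilised fallback under perfect separation. Constant columns
return p = 1 by convention; p-values are floored at 1e−320 to stay
strictly positive despite chi-square underflow. At study scale
(n ≈ 30,000 balanced) the 0.6 allele-frequency gap drives p far below
1e−100.

## Relatives and kinship (`pedigree`)

Per group, the schedule selects 400 founders, splits them uniformly into
father/mother halves, pairs them without replacement, and produces one
offspring per pair (200 first-degree); descendants are re-paired the same
way for 100 second- and 50 third-degree descendants. Transmission is per
SNP: genotype 0 transmits the reference allele, 2 the alternate, 1 either
with probability ½. Pairs sharing a parent are excluded; with one
offspring per pair such pairs cannot arise, so the constraint only binds
in unusual custom schedules.

Because each individual parents at most one child, the related pairs are
exactly the ancestor–descendant chains; each is recorded with its meiosis
count (1/2/3 → first/second/third-degree) and KING coefficient. The
default schedule yields 1,700 recorded pairs per group (200×2 + 100×6 +
50×14), i.e. 10,200 over six groups; pair totals depend on the counting
convention, so they are reported as computed rather than asserted against
any external figure. The KING formula is implemented exactly as printed,
including its asymmetry in n₁\* vs n\*₁ (the denominator uses the first
individual's heterozygosity, matching the within-family robust estimator);
it is undefined when the first individual has no heterozygous sites and
raises in that case. Relatives inherit the group label and receive fresh
random IDs disjoint from all existing ones.

## Pipeline, determinism and problem sizes

One global seed is expanded via `numpy.random.SeedSequence.spawn` into
independent per-stage streams, so any stage can be re-run in isolation and
two identical runs produce byte-identical CSVs. Output layouts are the
five-file scheme documented in `genodata`; the kinship file's second
column holds the related sample's ID. The watermark file appends one
p-value row after the sample rows.

The test and acceptance runs exercise the full-scale *counts*
(6 × 5,000 samples, 2,100 relatives, 718 causal of 7,180 SNPs, 20
watermarks) at reduced SNP width or reduced sample count — whichever axis
a given count does not depend on — because the count arithmetic is
invariant to the other axis; statistical properties (transition rates,
KING expectations, null-p uniformity, MAF preservation) use Monte-Carlo
sizes chosen so the assertion tolerance sits at ≥ 3 standard errors.
Memory stays desk-class: genotypes are int8 throughout, and the largest
full-width object (30,000 × 7,200 int8) is ~220 MB.

## Known limitations

- No LD, recombination maps, or sequence context; sites are exchangeable.
- Privacy is the mechanism's per-record ε only; no formal accounting for
  rejected candidates, and no membership-inference evaluation.
- The watermark count scheme is this package's concrete realisation of
  the frequency-gap idea; other realisations with the same (eps, z₀)
  parameters exist.
- Mode imputation biases rare-allele frequencies slightly downward at
  high missingness.
- t-SNE-style visual diagnostics are out of scope; validation is numeric
  (MAF gaps, KING summaries, watermark p-values).
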