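"""Quality-control a genotype matrix and stratify it by ancestry with PCA.

QC removes high-missingness samples, then SNPs failing missingness, minor
allele frequency (< 0.01) or the exact Hardy-Weinberg test (p < 1e-6),
and finally imputes residual missing calls so downstream stages see a
complete matrix.
"""

from genosynth import (
    DEFAULT_ANCESTRIES,
    FounderConfig,
    QCThresholds,
    apply_qc,
    fit_pca,
    group_geometry,
    simulate_founders,
)

founders = simulate_founders(
    FounderConfig(
        group_sizes={label: 80 for label in DEFAULT_ANCESTRIES},
        n_snps=400,
        fst=0.1,
        missing_rate=0.02,
        seed=1,
    )
)
clean, report = apply_qc(founders, QCThresholds())
print("QC report:", report.summary())
# SNPs removed at the HWE stage here reflect the Wahlund effect: pooling
# diverged groups produces a real heterozygote deficit at diverged sites.

model = fit_pca(clean)
print(f"PCA: {model.n_components} components")
print("top-5 explained variance ratios:", model.explained_variance_ratio_[:5].round(3))

for geom in group_geometry(model, clean, percentile=97.5):
    print(
        f"  {geom.label:12s}: centroid norm {float((geom.centroid**2).sum())**0.5:8.2f}, "
        f"97.5%-radius {geom.radius:6.2f}, members {geom.member_count}"
    )
# Each group's radius defines the ancestry-consistency filter used when
# accepting synthetic samples.
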