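"""Quality control: MAF, missingness, and exact Hardy-Weinberg filters.

Mirrors the common PLINK-style workflow: samples with excess missingness
are dropped first (--mind), then SNP filters (--geno, --maf, --hwe). The
Hardy-Weinberg test is the exact conditional test (Wigginton-style,
standard p, not mid-p). Residual missing genotypes are imputed to the
per-SNP most frequent genotype after filtering so downstream stages
receive a complete matrix; ties go to the lower genotype value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genodata import MISSING, GenotypeMatrix


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    hwe_p_min: float = 1e-6
    sample_missing_max: float = 0.05

    def validate(self) -> None:
        for name in ("maf_min", "snp_missing_max", "hwe_p_min", "sample_missing_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise QCError(f"{name} must be in [0, 1], got {v}")
        if self.maf_min > 0.5:
            raise QCError("maf_min cannot exceed 0.5")


@dataclass
class QCReport:
    """Which samples/SNPs each filter stage removed, plus dimensions."""

    samples_removed_missing: list[str] = field(default_factory=list)
    snps_removed_missing: list[str] = field(default_factory=list)
    snps_removed_maf: list[str] = field(default_factory=list)
    snps_removed_hwe: list[str] = field(default_factory=list)
    shape_before: tuple[int, int] = (0, 0)
    shape_after: tuple[int, int] = (0, 0)

    def summary(self) -> dict:
        return {
            "shape_before": list(self.shape_before),
            "shape_after": list(self.shape_after),
            "n_samples_removed_missing": len(self.samples_removed_missing),
            "n_snps_removed_missing": len(self.snps_removed_missing),
            "n_snps_removed_maf": len(self.snps_removed_maf),
            "n_snps_removed_hwe": len(self.snps_removed_hwe),
        }


def compute_maf(genotype_column: np.ndarray) -> float:
    """Minor allele frequency of one SNP: alt-allele fraction folded to <= 0.5."""
    g = np.asarray(genotype_column)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise QCError("cannot compute MAF of an all-missing column")
    freq = obs.sum() / (2.0 * obs.size)
    return float(min(freq, 1.0 - freq))


def _log_het_probabilities(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Log probabilities of each feasible heterozygote count.

    Conditional on ``n`` diploid genotypes carrying ``n_alt`` copies of the
    rarer allele, P(h hets) = n! 2^h na! nb! / (n0! h! n2! (2n)!) over
    heterozygote counts h with the parity of ``n_alt``.
    """
    n_ref = 2 * n - n_alt
    h_max = min(n_alt, n_ref)
    h = np.arange(n_alt % 2, h_max + 1, 2)
    n_hom_alt = (n_alt - h) // 2
    n_hom_ref = (n_ref - h) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_hom_ref + 1)
        - gammaln(h + 1)
        - gammaln(n_hom_alt + 1)
        + h * np.log(2.0)
        + gammaln(n_alt + 1)
        + gammaln(n_ref + 1)
        - gammaln(2 * n + 1)
    )
    return h, logp


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on the allele counts.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise QCError(f"negative genotype counts {counts}")
    n = sum(counts)
    if n == 0:
        raise QCError("empty genotype counts")
    n_alt = n_het + 2 * n_hom_alt
    n_alt = min(n_alt, 2 * n - n_alt)  # condition on the rarer allele
    h, logp = _log_het_probabilities(n, n_alt)
    probs = np.exp(logp - logp.max())
    obs = probs[np.searchsorted(h, n_het)]
    # tolerance absorbs round-off on structurally tied probabilities
    p = probs[probs <= obs * (1.0 + 1e-9)].sum() / probs.sum()
    return float(min(p, 1.0))


def genotype_counts(genotype_column: np.ndarray) -> tuple[int, int, int]:
    g = np.asarray(genotype_column)
    obs = g[g != MISSING]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def impute_mode(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the per-SNP most frequent genotype.

    Ties break toward the lower genotype value.
    """
    geno = gm.genotypes.copy()
    for j in np.flatnonzero((geno == MISSING).any(axis=0)):
        col = geno[:, j]
        counts = np.array([(col == v).sum() for v in (0, 1, 2)])
        if counts.sum() == 0:
            raise QCError(f"SNP {gm.snp_ids[j]!r} is entirely missing")
        mode = int(np.argmax(counts))  # argmax takes the first (lowest) tie
        col[col == MISSING] = mode
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        snp_ids=list(gm.snp_ids),
        ancestry=gm.ancestry.copy(),
        genotypes=geno,
    )


def apply_qc(
    gm: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC filters in a fixed order and impute residual missingness.

    Order: (1) samples by missing rate, (2) SNPs by missing rate, (3) SNPs
    by MAF, (4) SNPs by exact HWE p-value; then mode imputation.
    """
    thr = thresholds or QCThresholds()
    thr.validate()
    if gm.n_samples == 0 or gm.n_snps == 0:
        raise QCError("cannot QC an empty matrix")
    report = QCReport(shape_before=(gm.n_samples, gm.n_snps))

    miss = gm.missing_mask
    sample_rate = miss.mean(axis=1)
    keep_s = sample_rate <= thr.sample_missing_max
    report.samples_removed_missing = [
        gm.sample_ids[i] for i in np.flatnonzero(~keep_s)
    ]
    gm = gm.take_samples(np.flatnonzero(keep_s))
    if gm.n_samples == 0:
        raise QCError("all samples removed by missingness filter; review thresholds")

    miss = gm.missing_mask
    snp_rate = miss.mean(axis=0)
    keep_j = snp_rate <= thr.snp_missing_max
    report.snps_removed_missing = [gm.snp_ids[j] for j in np.flatnonzero(~keep_j)]
    gm = gm.take_snps(np.flatnonzero(keep_j))

    if gm.n_snps:
        mafs = np.array([compute_maf(gm.genotypes[:, j]) for j in range(gm.n_snps)])
        keep_j = mafs >= thr.maf_min
        report.snps_removed_maf = [gm.snp_ids[j] for j in np.flatnonzero(~keep_j)]
        gm = gm.take_snps(np.flatnonzero(keep_j))

    if gm.n_snps:
        pvals = np.array(
            [hwe_test(*genotype_counts(gm.genotypes[:, j])) for j in range(gm.n_snps)]
        )
        keep_j = pvals >= thr.hwe_p_min
        report.snps_removed_hwe = [gm.snp_ids[j] for j in np.flatnonzero(~keep_j)]
        gm = gm.take_snps(np.flatnonzero(keep_j))

    if gm.n_snps == 0:
        raise QCError("all SNPs removed by QC; review thresholds")
    gm = impute_mode(gm)
    report.shape_after = (gm.n_samples, gm.n_snps)
    return gm, report
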