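"""Watermark SNPs: fabricated variants engineered to associate strongly
with the simulated phenotype, used to verify outsourced GWAS computations.

Each watermark column is built in four steps: (1) initialise the column as
a copy of the phenotype vector; (2) split sample indices into the case set
and the control set; (3) decide how many 0/1/2 genotypes each set needs;
(4) overwrite the column with a uniformly random arrangement realising
those counts within each set. The counts target an alternate-allele
frequency of z0 + eps among cases and z0 - eps among controls, expanded to
genotype counts by Hardy-Weinberg proportions with largest-remainder
rounding (so counts sum exactly to each arm's size). With the defaults
(eps = 0.3, z0 = 0.49) the 0.6 allele-frequency gap makes every watermark
overwhelmingly significant in a single-SNP logistic test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .phenotype import PhenotypeSet

TINY_P = 1e-320  # floor keeping p-values strictly positive


class WatermarkError(ValueError):
    pass


@dataclass
class WatermarkParams:
    n_watermarks: int = 20
    eps: float = 0.3
    z0: float = 0.49

    def validate(self) -> None:
        if self.n_watermarks < 0:
            raise WatermarkError("n_watermarks must be >= 0")
        if not (0.0 <= self.z0 - self.eps and self.z0 + self.eps <= 1.0):
            raise WatermarkError(
                f"need 0 <= z0 - eps and z0 + eps <= 1; got z0={self.z0}, "
                f"eps={self.eps}"
            )


@dataclass
class WatermarkBlock:
    """Watermark columns, their random IDs, and ground-truth p-values."""

    snp_ids: list[str]
    genotypes: np.ndarray  # samples x n_watermarks, values in {0,1,2}
    p_values: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.snp_ids):
            raise WatermarkError("one genotype column required per watermark ID")
        if len(self.p_values) != len(self.snp_ids):
            raise WatermarkError("one p-value required per watermark ID")
        if len(self.snp_ids) and (
            (self.p_values <= 0).any() or (self.p_values > 1).any()
        ):
            raise WatermarkError("p-values must lie in (0, 1]")


def hwe_genotype_counts(n: int, p: float) -> np.ndarray:
    """Genotype counts [n0, n1, n2] for arm size n at alt-allele frequency p.

    Hardy-Weinberg expectations n(1-p)^2, 2np(1-p), np^2 rounded by largest
    remainder so the counts sum exactly to n.
    """
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    base = np.floor(expected).astype(int)
    short = n - base.sum()
    # round the remainders so float noise cannot flip a tie; stable sort
    # then prefers the lower genotype
    order = np.argsort(-np.round(expected - base, 9), kind="stable")
    base[order[:short]] += 1
    return base


def watermark_counts(
    n_cases: int, n_controls: int, params: WatermarkParams
) -> dict[str, np.ndarray]:
    """Per-arm genotype count plan for one watermark SNP."""
    params.validate()
    if n_cases <= 0 or n_controls <= 0:
        raise WatermarkError("both arms must be non-empty")
    return {
        "case": hwe_genotype_counts(n_cases, params.z0 + params.eps),
        "control": hwe_genotype_counts(n_controls, params.z0 - params.eps),
    }


def generate_watermark_snp(
    phenotype: PhenotypeSet,
    params: WatermarkParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one watermark genotype column for the phenotype's samples."""
    y = phenotype.values
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise WatermarkError("phenotype must contain both classes")
    plan = watermark_counts(case_idx.size, ctrl_idx.size, params)
    column = y.astype(np.int8).copy()  # step 1: duplicate the phenotype
    for idx, counts in ((case_idx, plan["case"]), (ctrl_idx, plan["control"])):
        arm = np.repeat(np.array([0, 1, 2], dtype=np.int8), counts)
        column[idx] = rng.permutation(arm)
    return column


def random_snp_ids(
    n: int, existing: set[str], rng: np.random.Generator
) -> list[str]:
    """Random watermark SNP IDs, disjoint from existing data SNP IDs."""
    ids: list[str] = []
    seen = set(existing)
    while len(ids) < n:
        candidate = f"rs{int(rng.integers(10_000_000, 100_000_000))}"
        if candidate not in seen:
            seen.add(candidate)
            ids.append(candidate)
    return ids


def association_test(
    genotype_column: np.ndarray, phenotype_values: np.ndarray
) -> float:
    """Likelihood-ratio p-value of a single-SNP additive logistic model.

    Compares intercept + genotype against intercept-only. A constant
    genotype column returns 1.0 by convention; under (near-)separation the
    fit is iteration-capped and the LRT p-value is still reported.
    """
    g = np.asarray(genotype_column, dtype=float)
    y = np.asarray(phenotype_values, dtype=float)
    if g.shape != y.shape:
        raise WatermarkError("genotype and phenotype lengths differ")
    if not (0 < y.sum() < y.size):
        raise WatermarkError("phenotype must contain both classes")
    if np.all(g == g[0]):
        return 1.0
    X = sm.add_constant(g)
    with np.errstate(all="ignore"):
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            llf_alt = fit.llf
        except Exception:
            # ridge-stabilised fallback for perfect separation
            fit = sm.Logit(y, X).fit_regularized(
                disp=0, alpha=1e-8, maxiter=500
            )
            llf_alt = sm.Logit(y, X).loglike(np.asarray(fit.params))
    pbar = y.mean()
    llf_null = y.size * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    lrt = max(0.0, 2.0 * (llf_alt - llf_null))
    p = stats.chi2.sf(lrt, df=1)
    return float(max(p, TINY_P))


def generate_watermarks(
    phenotype: PhenotypeSet,
    params: WatermarkParams,
    rng: np.random.Generator,
    existing_snp_ids: set[str] | None = None,
) -> WatermarkBlock:
    """Generate the full watermark block with ground-truth p-values."""
    params.validate()
    n = len(phenotype.sample_ids)
    if params.n_watermarks == 0:
        return WatermarkBlock(
            snp_ids=[],
            genotypes=np.empty((n, 0), dtype=np.int8),
            p_values=np.empty(0),
        )
    ids = random_snp_ids(params.n_watermarks, existing_snp_ids or set(), rng)
    columns = [
        generate_watermark_snp(phenotype, params, rng)
        for _ in range(params.n_watermarks)
    ]
    geno = np.stack(columns, axis=1)
    pvals = np.array(
        [association_test(geno[:, j], phenotype.values) for j in range(geno.shape[1])]
    )
    return WatermarkBlock(snp_ids=ids, genotypes=geno, p_values=pvals)
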