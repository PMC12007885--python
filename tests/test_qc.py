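"""MAF, exact Hardy-Weinberg test (vs an exact-rational enumeration
oracle), and the staged QC filter."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genosynth.genodata import GenotypeMatrix, MISSING
from genosynth.qc import (
    QCError,
    QCThresholds,
    apply_qc,
    compute_maf,
    genotype_counts,
    hwe_test,
    impute_mode,
)


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration of the conditional HWE test.

    P(h hets | n genotypes, na minor alleles) computed with integer
    combinatorics; the p-value sums probabilities <= the observed one.
    """
    from math import factorial

    n = n_hom_ref + n_het + n_hom_alt
    na = n_het + 2 * n_hom_alt
    na = min(na, 2 * n - na)
    nb = 2 * n - na
    probs = {}
    for h in range(na % 2, min(na, nb) + 1, 2):
        n2 = (na - h) // 2
        n0 = (nb - h) // 2
        # multinomial n!/(n0! h! n2!) * 2^h * na! nb! / (2n)!
        probs[h] = Fraction(
            factorial(n) * 2**h * factorial(na) * factorial(nb),
            factorial(n0) * factorial(h) * factorial(n2) * factorial(2 * n),
        )
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


# ---------------------------------------------------------------- MAF


@pytest.mark.parametrize(
    "column, expected",
    [
        ([0, 1, 2, 2], 0.375),
        ([0, 0, 0], 0.0),
        ([0, 1, MISSING, 2], 0.5),
        ([2, 2, 2], 0.0),
    ],
)
def test_compute_maf_examples(column, expected):
    assert compute_maf(np.array(column)) == pytest.approx(expected)


def test_compute_maf_all_missing_errors():
    with pytest.raises(QCError):
        compute_maf(np.array([MISSING, MISSING]))


@given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=40))
@settings(deadline=None, max_examples=200)
def test_compute_maf_always_folded(column):
    col = np.array(column)
    if (col == MISSING).all():
        return
    assert 0.0 <= compute_maf(col) <= 0.5


# ---------------------------------------------------------------- HWE


def test_hwe_extreme_het_excess_fails_threshold():
    assert hwe_test(0, 100, 0) < 1e-6


@pytest.mark.parametrize("n", [1, 5, 50])
def test_hwe_monomorphic_is_one(n):
    assert hwe_test(n, 0, 0) == 1.0
    assert hwe_test(0, 0, n) == 1.0


def test_hwe_negative_counts_error():
    with pytest.raises(QCError):
        hwe_test(-1, 2, 3)


def test_hwe_matches_enumeration_oracle_small_totals():
    rng = np.random.default_rng(0)
    cases = [(a, b, c) for a in range(8) for b in range(8) for c in range(8)
             if 0 < a + b + c]
    # plus random larger configurations up to total 50
    for _ in range(300):
        total = int(rng.integers(1, 51))
        split = rng.multinomial(total, [1 / 3] * 3)
        cases.append(tuple(split))
    for a, b, c in cases:
        assert hwe_test(a, b, c) == pytest.approx(hwe_oracle(a, b, c), abs=1e-12)


# ---------------------------------------------------------------- apply_qc


def _matrix(geno, labels=None):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(m)],
        ancestry=np.array(labels or ["African"] * n, dtype=object),
        genotypes=geno,
    )


def test_monomorphic_snp_removed_at_maf_stage():
    gm = _matrix(
        [
            [0, 0, 1],
            [1, 0, 0],
            [2, 0, 1],
            [1, 0, 2],
        ]
    )
    clean, report = apply_qc(gm, QCThresholds())
    assert report.snps_removed_maf == ["snp1"]
    assert clean.n_snps == 2
    assert not report.samples_removed_missing
    assert not report.snps_removed_hwe


def test_clean_single_group_matrix_passes_untouched():
    """One panmictic group, common alleles, no missingness -> identity.

    (A pooled multi-group matrix would legitimately fail HWE via the
    Wahlund effect, so the no-op check uses a single group.)
    """
    from genosynth.basepop import FounderConfig, simulate_founders

    gm = simulate_founders(
        FounderConfig(
            group_sizes={"European": 300},
            n_snps=200,
            fst=0.05,
            maf_range=(0.25, 0.5),
            missing_rate=0.0,
            seed=13,
        )
    )
    clean, report = apply_qc(gm, QCThresholds())
    assert clean.equals(gm)
    assert report.shape_before == report.shape_after


def test_high_missingness_sample_removed_first():
    geno = np.ones((4, 10), dtype=np.int8)
    geno[:, ::2] = 0  # keep SNPs polymorphic across samples
    geno[0, :2] = MISSING  # 20% missing > 5%
    gm = _matrix(geno)
    clean, report = apply_qc(
        gm, QCThresholds(maf_min=0.0, hwe_p_min=0.0, snp_missing_max=1.0)
    )
    assert report.samples_removed_missing == ["s0"]
    assert clean.n_samples == 3


def test_imputation_fills_to_mode_with_low_tie():
    geno = np.array([[0, 1], [2, 1], [MISSING, MISSING], [2, 0]], dtype=np.int8)
    gm = _matrix(geno)
    filled = impute_mode(gm)
    assert filled.genotypes[2, 0] == 2  # clear mode
    assert filled.genotypes[2, 1] == 1  # tie between 0/1 counts? 1 occurs twice
    assert not (filled.genotypes == MISSING).any()


def test_imputation_tie_breaks_low():
    geno = np.array([[0], [2], [MISSING]], dtype=np.int8)
    filled = impute_mode(_matrix(geno))
    assert filled.genotypes[2, 0] == 0


def test_apply_qc_idempotent(rng):
    from genosynth.basepop import FounderConfig, simulate_founders

    gm = simulate_founders(
        FounderConfig(
            group_sizes={"African": 150, "European": 150},
            n_snps=300,
            fst=0.1,
            maf_range=(0.1, 0.5),
            missing_rate=0.02,
            seed=9,
        )
    )
    once, _ = apply_qc(gm, QCThresholds())
    twice, report2 = apply_qc(once, QCThresholds())
    assert once.equals(twice)
    assert report2.shape_before == report2.shape_after


def test_empty_result_raises():
    gm = _matrix([[0, 0], [0, 0], [0, 0]])
    with pytest.raises(QCError, match="thresholds"):
        apply_qc(gm, QCThresholds())
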