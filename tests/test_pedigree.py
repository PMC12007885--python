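"""Mendelian inheritance, pedigree generation, and the KING estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genosynth.basepop import FounderConfig, simulate_founders
from genosynth.genodata import GenotypeMatrix
from genosynth.pedigree import (
    GenerationSchedule,
    PedigreeError,
    king_coefficient,
    king_counts,
    mendelian_offspring,
    simulate_generations,
)


# ------------------------------------------------------ Mendel's law


def test_fixed_transmissions(rng):
    zeros = np.zeros(1000, dtype=np.int8)
    twos = np.full(1000, 2, dtype=np.int8)
    assert (mendelian_offspring(zeros, zeros, rng) == 0).all()
    assert (mendelian_offspring(twos, twos, rng) == 2).all()
    assert (mendelian_offspring(zeros, twos, rng) == 1).all()


def test_het_by_hom_transmission_frequencies(rng):
    n = 100_000
    pa = np.zeros(n, dtype=np.int8)
    pb = np.ones(n, dtype=np.int8)
    child = mendelian_offspring(pa, pb, rng)
    freqs = np.array([(child == v).mean() for v in (0, 1, 2)])
    se = np.sqrt(0.5 * 0.5 / n)
    assert freqs[2] == 0.0
    assert abs(freqs[0] - 0.5) < 3 * se and abs(freqs[1] - 0.5) < 3 * se


def test_het_by_het_transmission_frequencies(rng):
    n = 100_000
    parents = np.ones(n, dtype=np.int8)
    child = mendelian_offspring(parents, parents, rng)
    expected = np.array([0.25, 0.5, 0.25])
    freqs = np.array([(child == v).mean() for v in (0, 1, 2)])
    se = np.sqrt(expected * (1 - expected) / n)
    assert (np.abs(freqs - expected) < 3 * se).all()


@given(st.integers(0, 2**32 - 1))
@settings(deadline=None, max_examples=50)
def test_offspring_always_mendel_consistent(seed):
    rng = np.random.default_rng(seed)
    pa = rng.integers(0, 3, size=200).astype(np.int8)
    pb = rng.integers(0, 3, size=200).astype(np.int8)
    child = mendelian_offspring(pa, pb, rng)
    lo = np.maximum(0, (pa == 2).astype(int) + (pb == 2).astype(int))
    hi = 2 - (pa == 0).astype(int) - (pb == 0).astype(int)
    assert ((child >= lo) & (child <= hi)).all()


def test_missing_parents_rejected(rng):
    with pytest.raises(PedigreeError):
        mendelian_offspring(np.array([0, -1]), np.array([1, 1]), rng)


# ------------------------------------------------------ KING


def test_king_self_is_half(rng):
    g = rng.integers(0, 3, size=500).astype(np.int8)
    g[0] = 1  # ensure at least one heterozygote
    assert king_coefficient(g, g) == pytest.approx(0.5)


def test_king_hand_example():
    gi = np.array([1, 1, 0, 2, 1], dtype=np.int8)
    gj = np.array([1, 0, 0, 2, 2], dtype=np.int8)
    c = king_counts(gi, gj)
    assert (c.n11, c.n02, c.n20, c.n1_star, c.star_1) == (1, 0, 0, 3, 1)
    assert king_coefficient(gi, gj) == pytest.approx(1 / 3)


def test_king_undefined_without_heterozygotes():
    with pytest.raises(PedigreeError, match="heterozygous"):
        king_coefficient(np.array([0, 2, 0]), np.array([1, 1, 0]))


def test_parent_offspring_king_expectation(rng):
    """Mean KING over 100 simulated parent-offspring pairs is ~0.25."""
    founders = simulate_founders(
        FounderConfig(
            group_sizes={"European": 200},
            n_snps=2000,
            fst=0.05,
            maf_range=(0.1, 0.5),
            missing_rate=0.0,
            seed=21,
        )
    )
    coeffs = []
    for k in range(100):
        pa = founders.genotypes[2 * k]
        pb = founders.genotypes[2 * k + 1]
        child = mendelian_offspring(pa, pb, rng)
        coeffs.append(king_coefficient(child, pa))
    mean = float(np.mean(coeffs))
    assert 0.20 <= mean <= 0.30


# ------------------------------------------------------ generations


def _group(n, m, seed, label="European"):
    cfg = FounderConfig(
        group_sizes={label: n},
        n_snps=m,
        fst=0.05,
        maf_range=(0.2, 0.5),
        missing_rate=0.0,
        seed=seed,
    )
    return simulate_founders(cfg)


def test_default_schedule_yields_350_relatives(rng):
    group = _group(450, 200, 30)
    rel, records = simulate_generations(group, GenerationSchedule(), rng)
    assert rel.n_samples == 200 + 100 + 50 == 350
    assert set(rel.ancestry.tolist()) == {"European"}
    # ancestor-descendant pair enumeration: 200*2 + 100*6 + 50*14
    assert len(records) == 400 + 600 + 700


def test_toy_schedule_pedigree_trace(rng):
    group = _group(4, 300, 31)
    sched = GenerationSchedule(n_founders_selected=4, counts=(2, 1))
    rel, records = simulate_generations(group, sched, rng)
    assert rel.n_samples == 3
    gen2_id = rel.sample_ids[-1]
    mine = [r for r in records if r.sample_id_a == gen2_id]
    first = [r for r in mine if r.degree == "first-degree"]
    second = [r for r in mine if r.degree == "second-degree"]
    assert len(first) == 2  # its two generation-1 parents
    assert len(second) == 4  # the four founders
    # parents of the generation-2 child are the generation-1 children
    assert {r.sample_id_b for r in first} == set(rel.sample_ids[:2])


def test_empty_schedule(rng):
    group = _group(10, 50, 32)
    rel, records = simulate_generations(
        group, GenerationSchedule(n_founders_selected=4, counts=()), rng
    )
    assert rel.n_samples == 0 and records == []


def test_infeasible_schedule_rejected(rng):
    group = _group(10, 50, 33)
    with pytest.raises(PedigreeError):
        simulate_generations(
            group, GenerationSchedule(n_founders_selected=4, counts=(3,)), rng
        )
    with pytest.raises(PedigreeError, match="founders"):
        simulate_generations(
            group, GenerationSchedule(n_founders_selected=40, counts=(2,)), rng
        )


def test_king_decreases_with_degree(rng):
    group = _group(450, 1500, 34)
    rel, records = simulate_generations(group, GenerationSchedule(), rng)
    by_degree = {}
    for r in records:
        by_degree.setdefault(r.degree, []).append(r.king)
    m1 = np.mean(by_degree["first-degree"])
    m2 = np.mean(by_degree["second-degree"])
    m3 = np.mean(by_degree["third-degree"])
    # unrelated founder pairs as baseline
    unrelated = [
        king_coefficient(group.genotypes[2 * k], group.genotypes[2 * k + 1])
        for k in range(100)
    ]
    m0 = np.mean(unrelated)
    assert m1 > m2 > m3 > m0
    assert m1 == pytest.approx(0.25, abs=0.05)


def test_relative_ids_fresh_and_unique(rng):
    group = _group(60, 100, 35)
    sched = GenerationSchedule(n_founders_selected=40, counts=(20, 10, 5))
    used = set(group.sample_ids)
    rel, _ = simulate_generations(group, sched, rng, used)
    assert len(set(rel.sample_ids)) == 35
    assert not set(rel.sample_ids) & set(group.sample_ids)
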