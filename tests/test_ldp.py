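"""Constrained randomized-response perturbation and the synthesis loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genosynth.ldp import (
    LDPParams,
    SynthesisConfig,
    SynthesisError,
    assign_sample_ids,
    perturb_genotype,
    perturb_matrix,
    synthesize_group,
)
from genosynth.qc import compute_maf
from genosynth.stratify import fit_pca, geometry_for, group_geometry


def test_flip_probability_formulas():
    p = LDPParams(epsilon=6.0)
    assert p.q_extreme == pytest.approx(2.0 / (math.e**6 + 2), rel=1e-12)
    assert p.q_het == pytest.approx(1.0 / (math.e**6 + 2), rel=1e-12)
    assert p.q_extreme == pytest.approx(2 * p.q_het, rel=1e-15)


@given(st.floats(min_value=0.1, max_value=30.0))
@settings(deadline=None, max_examples=100)
def test_transition_rows_sum_to_one(epsilon):
    T = LDPParams(epsilon=epsilon).transition_matrix()
    np.testing.assert_array_equal(T.sum(axis=1), np.ones(3))
    assert (T >= 0).all()
    assert T[0, 2] == 0.0 and T[2, 0] == 0.0


@pytest.mark.parametrize("epsilon", [1.0, 6.0])
def test_empirical_transition_frequencies(epsilon):
    n = 10**6
    params = LDPParams(epsilon=epsilon)
    for g in (0, 1, 2):
        rng = np.random.default_rng(np.random.SeedSequence([1, int(epsilon), g]))
        out = perturb_matrix(np.full((1, n), g, dtype=np.int8), params, rng)[0]
        counts = np.array([(out == v).sum() for v in (0, 1, 2)]) / n
        expected = params.transition_matrix()[g]
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(counts - expected) <= 3 * se + 1e-9).all()
        # forbidden direct transition between the homozygous states
        if g == 0:
            assert counts[2] == 0.0
        if g == 2:
            assert counts[0] == 0.0


def test_no_noise_limit(rng):
    params = LDPParams(epsilon=50.0)
    g = rng.integers(0, 3, size=(100, 100)).astype(np.int8)
    assert np.array_equal(perturb_matrix(g, params, rng), g)


def test_scalar_perturb_validates_state(rng):
    with pytest.raises(ValueError):
        perturb_genotype(3, LDPParams(), rng)


def test_expected_modified_fraction(rng):
    """Fraction of changed entries matches pi0*q_ext + pi1*2q_het + pi2*q_ext."""
    params = LDPParams(epsilon=3.0)
    probs = np.array([0.5, 0.3, 0.2])
    n = 400_000
    g = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=n, p=probs)
    out = perturb_matrix(g.reshape(1, -1), params, rng)[0]
    frac = (out != g).mean()
    pi = np.array([(g == v).mean() for v in (0, 1, 2)])
    expected = pi[0] * params.q_extreme + pi[1] * 2 * params.q_het + pi[2] * params.q_extreme
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(frac - expected) < 4 * se


# ------------------------------------------------------- synthesis loop


def _group_setup(two_group_founders):
    model = fit_pca(two_group_founders)
    geoms = group_geometry(model, two_group_founders)
    return model, geoms


def test_synthesize_more_than_group_size(two_group_founders, rng):
    model, geoms = _group_setup(two_group_founders)
    small = two_group_founders.for_ancestry("African").take_samples(range(5))
    cfg = SynthesisConfig(per_group_target=10)
    out = synthesize_group(
        small, model, geometry_for(geoms, "African"), cfg, LDPParams(3.0), rng
    )
    assert out.n_samples == 10
    assert set(out.ancestry.tolist()) == {"African"}


def test_synthesize_target_zero(two_group_founders, rng):
    model, geoms = _group_setup(two_group_founders)
    out = synthesize_group(
        two_group_founders.for_ancestry("African"),
        model,
        geometry_for(geoms, "African"),
        SynthesisConfig(per_group_target=0),
        LDPParams(),
        rng,
    )
    assert out.n_samples == 0 and out.n_snps == two_group_founders.n_snps


def test_synthetic_never_identical_to_source(two_group_founders, rng):
    model, geoms = _group_setup(two_group_founders)
    originals = two_group_founders.for_ancestry("European")
    cfg = SynthesisConfig(per_group_target=200, identity_filter="all")
    out = synthesize_group(
        originals, model, geometry_for(geoms, "European"), cfg, LDPParams(6.0), rng
    )
    rows = {originals.genotypes[i].tobytes() for i in range(originals.n_samples)}
    assert all(out.genotypes[i].tobytes() not in rows for i in range(out.n_samples))


def test_synthetic_maf_close_to_originals(two_group_founders, rng):
    model, geoms = _group_setup(two_group_founders)
    originals = two_group_founders.for_ancestry("African")
    out = synthesize_group(
        originals,
        model,
        geometry_for(geoms, "African"),
        SynthesisConfig(per_group_target=5000),
        LDPParams(6.0),
        rng,
    )
    orig_maf = np.array([compute_maf(originals.genotypes[:, j]) for j in range(originals.n_snps)])
    syn_maf = np.array([compute_maf(out.genotypes[:, j]) for j in range(out.n_snps)])
    assert np.abs(orig_maf - syn_maf).max() < 0.02


def test_impossible_acceptance_raises(two_group_founders, rng):
    model, geoms = _group_setup(two_group_founders)
    geom = geometry_for(geoms, "African")
    tight = type(geom)(label="African", centroid=geom.centroid, radius=0.0, member_count=geom.member_count)
    cfg = SynthesisConfig(per_group_target=5, max_attempts=2)
    with pytest.raises(SynthesisError, match="acceptance|accepted"):
        synthesize_group(
            two_group_founders.for_ancestry("African"),
            model,
            tight,
            cfg,
            LDPParams(6.0),
            rng,
        )


# ------------------------------------------------------- sample IDs


def test_assign_ids_sorted_unique(rng):
    cfg = SynthesisConfig(per_group_target=3)
    ids = assign_sample_ids(3, cfg, rng)
    assert len(ids) == 3 == len(set(ids))
    assert ids == sorted(ids)
    assert all(cfg.id_range[0] <= i <= cfg.id_range[1] for i in ids)


def test_assign_ids_deterministic():
    cfg = SynthesisConfig()
    a = assign_sample_ids(100, cfg, np.random.default_rng(5))
    b = assign_sample_ids(100, cfg, np.random.default_rng(5))
    assert a == b


def test_assign_ids_full_range(rng):
    cfg = SynthesisConfig(id_range=(10, 19))
    assert assign_sample_ids(10, cfg, rng) == list(range(10, 20))
    with pytest.raises(SynthesisError):
        assign_sample_ids(11, cfg, rng)
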