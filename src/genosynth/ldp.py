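"""Genotype perturbation under a constrained local-differential-privacy
randomized response, and the per-group synthetic-sample generation loop.

The mechanism acts on the three additive genotype states. The standard
d-state randomized response flips to each other state with probability
1/(e^eps + d - 1); the constrained variant used here forbids the
biologically implausible direct 0 <-> 2 transitions:

* state 0 -> 1 with probability q_extreme = 2/(e^eps + d - 1), else stays;
* state 2 -> 1 with probability q_extreme, else stays;
* state 1 -> 0 with probability q_het = 1/(e^eps + d - 1), -> 2 with
  probability q_het, else stays.

All three states therefore keep their value with the same probability
1 - 2*q_het. Larger epsilon means less noise; at the default epsilon = 6
the flip probabilities are ~0.49% and ~0.25%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeMatrix
from .stratify import GroupGeometry, PCModel, consistency_mask


class SynthesisError(RuntimeError):
    pass


@dataclass
class LDPParams:
    """Privacy parameters of the constrained randomized response."""

    epsilon: float = 6.0
    d: int = 3

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.d != 3:
            raise ValueError("the genotype mechanism is defined for d = 3 states")

    @property
    def q_het(self) -> float:
        """Per-target flip probability out of the heterozygous state."""
        return 1.0 / (math.exp(self.epsilon) + self.d - 1)

    @property
    def q_extreme(self) -> float:
        """Flip probability from a homozygous state (0 or 2) to 1."""
        return 2.0 * self.q_het

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 3x3 state transition matrix; rows sum to exactly 1."""
        q = self.q_het
        stay = 1.0 - 2.0 * q
        # compensate the round-off of 1 - 2q so each row sums to 1.0 exactly
        stay -= (q + stay + q) - 1.0
        return np.array(
            [
                [stay, 2.0 * q, 0.0],
                [q, stay, q],
                [0.0, 2.0 * q, stay],
            ]
        )


@dataclass
class SynthesisConfig:
    """Controls the per-group generation loop and sample-ID assignment."""

    per_group_target: int = 5000
    max_attempts: int = 50  # multiplier on the target before giving up
    slack: float = 1.0  # multiplier on the group radius
    id_range: tuple[int, int] = (1_000_000, 9_999_999)
    identity_filter: str = "source"  # or "all": reject matches to any original

    def validate(self, n_expected: int | None = None) -> None:
        if self.per_group_target < 0:
            raise ValueError("per_group_target must be >= 0")
        lo, hi = self.id_range
        width = hi - lo + 1
        if n_expected is not None and width < 100 * n_expected:
            raise ValueError(
                f"id_range of width {width} too narrow for {n_expected} samples"
            )
        if self.identity_filter not in ("source", "all"):
            raise ValueError("identity_filter must be 'source' or 'all'")


def perturb_matrix(
    genotypes: np.ndarray, params: LDPParams, rng: np.random.Generator
) -> np.ndarray:
    """Apply the constrained randomized response elementwise."""
    g = np.asarray(genotypes)
    if (g == MISSING).any() or not np.isin(g, (0, 1, 2)).all():
        raise ValueError("perturbation requires complete genotypes in {0,1,2}")
    out = g.astype(np.int8).copy()
    u = rng.random(g.shape)
    q = params.q_het
    out[(g == 0) & (u < 2.0 * q)] = 1
    out[(g == 2) & (u < 2.0 * q)] = 1
    het = g == 1
    out[het & (u < q)] = 0
    out[het & (u >= q) & (u < 2.0 * q)] = 2
    return out


def perturb_genotype(
    g: int, params: LDPParams, rng: np.random.Generator
) -> int:
    """Perturb a single genotype state; 0 <-> 2 transitions never occur."""
    return int(perturb_matrix(np.array([[g]]), params, rng)[0, 0])


def assign_sample_ids(
    n: int, cfg: SynthesisConfig, rng: np.random.Generator
) -> list[int]:
    """Draw n unique random integer IDs from cfg.id_range, sorted ascending."""
    lo, hi = cfg.id_range
    width = hi - lo + 1
    if n > width:
        raise SynthesisError(f"id_range of width {width} cannot supply {n} IDs")
    if n == width:
        return list(range(lo, hi + 1))
    chosen: set[int] = set()
    while len(chosen) < n:
        draws = rng.integers(lo, hi + 1, size=2 * (n - len(chosen)))
        for d in draws:
            chosen.add(int(d))
            if len(chosen) == n:
                break
    return sorted(chosen)


def synthesize_group(
    originals: GenotypeMatrix,
    model: PCModel,
    geometry: GroupGeometry,
    cfg: SynthesisConfig,
    params: LDPParams,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Generate synthetic samples for one ancestry group.

    Repeatedly draws a source original uniformly (with replacement, so small
    groups can exceed their own size), perturbs it, and accepts the result
    iff it is (a) not genotype-identical to its source and (b) ancestry-
    consistent with the group geometry. Accepted samples carry the group's
    ancestry label and placeholder IDs; final random IDs are assigned by the
    pipeline across all groups.
    """
    if originals.n_samples == 0:
        raise SynthesisError("cannot synthesize from an empty group")
    if (originals.genotypes == MISSING).any():
        raise SynthesisError("originals must be complete; run apply_qc first")
    labels = set(originals.ancestry.tolist())
    if labels != {geometry.label}:
        raise SynthesisError(
            f"originals carry ancestries {labels}, geometry is for "
            f"{geometry.label!r}"
        )
    cfg.validate()
    target = cfg.per_group_target
    label = geometry.label
    if target == 0:
        return GenotypeMatrix(
            sample_ids=[],
            snp_ids=list(originals.snp_ids),
            ancestry=np.empty(0, dtype=object),
            genotypes=np.empty((0, originals.n_snps), dtype=np.int8),
        )

    all_rows = (
        {originals.genotypes[i].tobytes() for i in range(originals.n_samples)}
        if cfg.identity_filter == "all"
        else None
    )
    accepted: list[np.ndarray] = []
    attempts = 0
    budget = cfg.max_attempts * target
    while len(accepted) < target:
        batch = min(max(target - len(accepted), 32), budget - attempts)
        if batch <= 0:
            rate = len(accepted) / max(attempts, 1)
            raise SynthesisError(
                f"group {label!r}: only {len(accepted)}/{target} accepted "
                f"after {attempts} attempts (rate {rate:.3f}); epsilon may be "
                "too small or the geometry too tight"
            )
        attempts += batch
        src = rng.integers(0, originals.n_samples, size=batch)
        pert = perturb_matrix(originals.genotypes[src], params, rng)
        not_identical = (pert != originals.genotypes[src]).any(axis=1)
        if all_rows is not None:
            not_identical &= np.fromiter(
                (row.tobytes() not in all_rows for row in pert),
                dtype=bool,
                count=batch,
            )
        ok = not_identical & consistency_mask(
            model.transform(pert), geometry, cfg.slack
        )
        for row in pert[ok]:
            accepted.append(row)
            if len(accepted) == target:
                break

    tag = label.replace(" ", "")
    return GenotypeMatrix(
        sample_ids=[f"syn_{tag}_{i:06d}" for i in range(target)],
        snp_ids=list(originals.snp_ids),
        ancestry=np.full(target, label, dtype=object),
        genotypes=np.vstack(accepted),
    )
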