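"""Founder-population simulator (Balding-Nichols model).

Stands in for a real, access-restricted foundation cohort: several ancestry
groups whose per-SNP allele frequencies diverge from a shared ancestral
frequency with variance governed by each group's FST. Produces the
PCA-separable population structure every downstream stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genodata import DEFAULT_ANCESTRIES, MISSING, GenotypeMatrix


def _default_group_sizes() -> dict[str, int]:
    return {label: 100 for label in DEFAULT_ANCESTRIES}


@dataclass
class FounderConfig:
    """Configuration for the founder simulation.

    Parameters
    ----------
    group_sizes : dict
        Ancestry label -> number of founder samples.
    n_snps : int
        Number of independent biallelic sites.
    fst : float or dict
        Divergence parameter in (0, 1), either shared or per group.
    maf_range : (low, high)
        Ancestral alternate-allele frequencies are drawn uniformly from
        this interval; must lie within (0, 0.5].
    missing_rate : float
        Independent per-call missingness probability in [0, 1).
    seed : int or None
        Seed for the simulation's random stream.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    n_snps: int = 1000
    fst: float | dict[str, float] = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int | None = None

    def fst_for(self, label: str) -> float:
        if isinstance(self.fst, dict):
            return float(self.fst[label])
        return float(self.fst)

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not self.group_sizes or any(
            v < 0 for v in self.group_sizes.values()
        ):
            raise ValueError("group sizes must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"degenerate maf_range {self.maf_range}; need 0 < low <= "
                "high <= 0.5"
            )
        for label in self.group_sizes:
            f = self.fst_for(label)
            if not (0.0 < f < 1.0):
                raise ValueError(f"fst for {label!r} must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def balding_nichols_frequencies(
    ancestral: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-group allele frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    scale = (1.0 - fst) / fst
    return rng.beta(ancestral * scale, (1.0 - ancestral) * scale)


def simulate_founders(
    config: FounderConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Simulate a multi-ancestry founder genotype matrix.

    Ancestral frequencies are uniform on ``maf_range``; each group's
    frequencies are Balding-Nichols draws around them; genotypes are
    Binomial(2, p_group); missingness is applied independently per call.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    ancestral = rng.uniform(lo, hi, size=config.n_snps)

    sample_ids: list[str] = []
    ancestry: list[str] = []
    blocks: list[np.ndarray] = []
    for label in sorted(config.group_sizes):
        n = config.group_sizes[label]
        if n == 0:
            continue
        p_group = balding_nichols_frequencies(
            ancestral, config.fst_for(label), rng
        )
        geno = rng.binomial(2, p_group, size=(n, config.n_snps)).astype(np.int8)
        if config.missing_rate > 0:
            mask = rng.random(geno.shape) < config.missing_rate
            geno[mask] = MISSING
        blocks.append(geno)
        tag = label.replace(" ", "")
        sample_ids.extend(f"{tag}_{i:05d}" for i in range(n))
        ancestry.extend([label] * n)

    if not blocks:
        raise ValueError("no samples requested")
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=[f"snp{j:05d}" for j in range(config.n_snps)],
        ancestry=np.asarray(ancestry, dtype=object),
        genotypes=np.vstack(blocks),
    )
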