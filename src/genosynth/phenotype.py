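"""Binary phenotype simulation via a logit (liability) model.

A random subset of SNPs is declared causal; each gets a coefficient drawn
from N(0, effect_sd^2). A per-sample liability is the genetic score plus
standard logistic noise (so thresholding reproduces logistic-regression
case probabilities). Exact case/control balance is enforced by thresholding
the liability at its case-fraction quantile rather than by independent
Bernoulli draws, so the promised case count holds for every input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genodata import MISSING, GenotypeMatrix


class PhenotypeError(ValueError):
    pass


@dataclass
class PhenoParams:
    causal_fraction: float = 0.10
    effect_sd: float = 0.5
    case_fraction: float = 0.5
    intercept: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.causal_fraction <= 1.0):
            raise PhenotypeError("causal_fraction must be in (0, 1]")
        if not (0.0 < self.case_fraction < 1.0):
            raise PhenotypeError("case_fraction must be in (0, 1)")
        if self.effect_sd < 0:
            raise PhenotypeError("effect_sd must be >= 0")


@dataclass
class PhenotypeSet:
    """Binary labels plus the causal ground truth that generated them."""

    sample_ids: list[str]
    values: np.ndarray  # int8, 0 control / 1 case
    causal_snp_ids: list[str] = field(default_factory=list)
    coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids),):
            raise PhenotypeError("one phenotype value required per sample")
        if not np.isin(self.values, (0, 1)).all():
            raise PhenotypeError("phenotype values must be 0 or 1")

    @property
    def n_cases(self) -> int:
        return int(self.values.sum())

    def subset(self, sample_ids: list[str]) -> "PhenotypeSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return PhenotypeSet(
            sample_ids=list(sample_ids),
            values=self.values[idx],
            causal_snp_ids=list(self.causal_snp_ids),
            coefficients=np.asarray(self.coefficients).copy(),
            intercept=self.intercept,
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_causal_snps(
    snp_ids: list[str], fraction: float, rng: np.random.Generator
) -> list[str]:
    """Uniform random causal subset of size round(fraction * count), min 1."""
    if not snp_ids:
        raise PhenotypeError("no SNP IDs to select from")
    if not (0.0 < fraction <= 1.0):
        raise PhenotypeError("fraction must be in (0, 1]")
    k = max(1, _round_half_up(fraction * len(snp_ids)))
    idx = rng.choice(len(snp_ids), size=k, replace=False)
    return [snp_ids[i] for i in sorted(idx)]


def simulate_phenotype(
    gm: GenotypeMatrix,
    causal_snp_ids: list[str],
    params: PhenoParams,
    rng: np.random.Generator,
) -> PhenotypeSet:
    """Simulate exactly balanced binary labels from the causal SNPs.

    liability_i = intercept + sum_k beta_k g_ik + logistic noise; the top
    round(case_fraction * n) liabilities become cases (liability ties broken
    by sample order).
    """
    params.validate()
    if gm.n_samples < 2:
        raise PhenotypeError("phenotype simulation needs at least 2 samples")
    if (gm.genotypes == MISSING).any():
        raise PhenotypeError("genotype matrix must be complete")
    pos = {s: j for j, s in enumerate(gm.snp_ids)}
    try:
        cols = np.array([pos[s] for s in causal_snp_ids], dtype=int)
    except KeyError as exc:
        raise PhenotypeError(f"causal SNP {exc.args[0]!r} not in matrix") from exc

    beta = rng.normal(0.0, params.effect_sd, size=len(causal_snp_ids))
    noise = rng.logistic(size=gm.n_samples)
    liability = (
        params.intercept + gm.genotypes[:, cols].astype(float) @ beta + noise
    )
    n_cases = _round_half_up(params.case_fraction * gm.n_samples)
    order = np.argsort(-liability, kind="stable")
    values = np.zeros(gm.n_samples, dtype=np.int8)
    values[order[:n_cases]] = 1
    return PhenotypeSet(
        sample_ids=list(gm.sample_ids),
        values=values,
        causal_snp_ids=list(causal_snp_ids),
        coefficients=beta,
        intercept=params.intercept,
    )


def save_ground_truth(phenotype: PhenotypeSet, path: str | Path) -> Path:
    """Write the causal-SNP ground truth as a sidecar JSON."""
    path = Path(path)
    payload = {
        "intercept": phenotype.intercept,
        "causal_snp_ids": list(phenotype.causal_snp_ids),
        "coefficients": [float(b) for b in phenotype.coefficients],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
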