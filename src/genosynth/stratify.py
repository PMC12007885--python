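"""PCA population stratification and the ancestry-deviation filter.

Principal components are computed from the column-centered genotype matrix
via SVD, with a deterministic sign convention: the largest-magnitude
loading of every component is made positive, so results are reproducible
across runs and platforms. Each ancestry group gets a simple geometry in
PC space (centroid + percentile radius of member distances), which
operationalises "significantly deviates from the target ancestry group" as
a scale-free distance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeMatrix


class StratifyError(ValueError):
    pass


@dataclass
class PCModel:
    """Fitted principal components of a complete genotype matrix."""

    n_components: int
    mean_: np.ndarray  # per-SNP centering means, shape (m,)
    components_: np.ndarray  # loadings, shape (k, m), rows orthonormal
    eigenvalues_: np.ndarray  # explained variances, non-increasing
    scores_: np.ndarray  # per-sample scores, shape (n, k)
    sample_ids: list[str]

    def transform(self, genotypes: np.ndarray) -> np.ndarray:
        """Project (rows of) an additive genotype array into PC space."""
        X = np.atleast_2d(np.asarray(genotypes, dtype=float))
        return (X - self.mean_) @ self.components_.T

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        total = self._total_variance
        return self.eigenvalues_ / total if total > 0 else self.eigenvalues_

    _total_variance: float = 0.0


@dataclass
class GroupGeometry:
    """Centroid and percentile radius of one ancestry group in PC space."""

    label: str
    centroid: np.ndarray
    radius: float
    member_count: int


def default_n_components(n_samples: int, n_snps: int, requested: int = 200) -> int:
    return max(1, min(requested, n_samples - 1, n_snps))


def fit_pca(gm: GenotypeMatrix, n_components: int | None = None) -> PCModel:
    """Fit the top principal components of a complete genotype matrix.

    ``n_components`` defaults to min(200, samples - 1, SNPs) so small
    matrices remain valid.
    """
    if (gm.genotypes == MISSING).any():
        raise StratifyError(
            "genotype matrix contains missing values; run apply_qc first"
        )
    n, m = gm.genotypes.shape
    if n < 2:
        raise StratifyError("PCA needs at least 2 samples")
    k = (
        default_n_components(n, m)
        if n_components is None
        else max(1, min(int(n_components), n - 1, m))
    )
    X = gm.genotypes.astype(float)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    components = Vt[:k]
    scores = U[:, :k] * S[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(k):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    eigenvalues = (S[:k] ** 2) / (n - 1)
    model = PCModel(
        n_components=k,
        mean_=mean,
        components_=components,
        eigenvalues_=eigenvalues,
        scores_=scores,
        sample_ids=list(gm.sample_ids),
    )
    model._total_variance = float((S**2).sum() / (n - 1))
    return model


def group_geometry(
    model: PCModel, gm: GenotypeMatrix, percentile: float = 97.5
) -> list[GroupGeometry]:
    """Centroid + distance-percentile radius for every ancestry group."""
    if model.scores_.shape[0] != gm.n_samples or model.sample_ids != gm.sample_ids:
        raise StratifyError("PC model does not cover this matrix's samples")
    geometries = []
    for label in gm.ancestry_labels():
        idx = np.flatnonzero(gm.ancestry == label)
        if idx.size < 2:
            raise StratifyError(
                f"ancestry group {label!r} has fewer than 2 members"
            )
        member_scores = model.scores_[idx]
        centroid = member_scores.mean(axis=0)
        dist = np.linalg.norm(member_scores - centroid, axis=1)
        radius = float(np.percentile(dist, percentile))
        geometries.append(
            GroupGeometry(
                label=label,
                centroid=centroid,
                radius=radius,
                member_count=int(idx.size),
            )
        )
    return geometries


def geometry_for(geometries: list[GroupGeometry], label: str) -> GroupGeometry:
    for g in geometries:
        if g.label == label:
            return g
    raise StratifyError(f"no geometry for ancestry {label!r}")


def consistency_mask(
    scores: np.ndarray, geom: GroupGeometry, slack: float = 1.0
) -> np.ndarray:
    """Vectorised ancestry-consistency test for rows of PC scores."""
    scores = np.atleast_2d(scores)
    if scores.shape[1] != geom.centroid.shape[0]:
        raise StratifyError("score dimensionality does not match geometry")
    dist = np.linalg.norm(scores - geom.centroid, axis=1)
    return dist <= slack * geom.radius


def is_ancestry_consistent(
    sample_scores: np.ndarray, geom: GroupGeometry, slack: float = 1.0
) -> bool:
    """True iff the sample lies within slack x radius of the group centroid."""
    return bool(consistency_mask(sample_scores, geom, slack)[0])
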