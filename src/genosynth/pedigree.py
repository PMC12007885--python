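"""Mendelian synthetic relatives and the KING kinship coefficient.

Relatives are bred over up to three descendant generations: founders are
split at random into father/mother halves and paired without replacement;
each pair contributes one offspring whose genotype is formed per SNP by
independent allele transmission (genotype 0 transmits the reference
allele, 2 the alternate, 1 either with probability 1/2). Descendant
generations are re-paired the same way; since every pair has a single
offspring, no two individuals of a generation share a parent, so the only
related pairs are ancestor-descendant chains, labelled by their meiosis
count (1 = first-degree, parent-child; 2 = grandparent; 3 =
great-grandparent).

Kinship is estimated with the heterozygosity-based KING coefficient

    phi(i, j) = (2*n11 - 4*(n02 + n20) - n*1 + n1*) / (4 * n1*)

where n11 counts SNPs heterozygous in both, n02/n20 count opposite
homozygotes, and n1* / n*1 count heterozygous SNPs in i and j. It is 0.5
for identical genotypes, ~0.25 for parent-offspring, halving per degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genodata import MISSING, GenotypeMatrix


class PedigreeError(ValueError):
    pass


DEGREE_LABELS = {1: "first-degree", 2: "second-degree", 3: "third-degree"}


def degree_label(meioses: int) -> str:
    return DEGREE_LABELS.get(meioses, f"{meioses}-meioses")


@dataclass
class GenerationSchedule:
    """How many founders to breed from and how many offspring per generation."""

    n_founders_selected: int = 400
    counts: tuple[int, ...] = (200, 100, 50)

    def validate(self) -> None:
        if self.n_founders_selected < 2 and self.counts:
            raise PedigreeError("need at least 2 founders to breed")
        available = self.n_founders_selected
        for depth, c in enumerate(self.counts, start=1):
            if c < 1:
                raise PedigreeError("generation counts must be >= 1")
            if c > available // 2:
                raise PedigreeError(
                    f"generation {depth} asks for {c} offspring but only "
                    f"{available} parents are available"
                )
            available = c

    @property
    def total_relatives(self) -> int:
        return sum(self.counts)


@dataclass
class KinshipRecord:
    sample_id_a: str  # the descendant (synthetic relative)
    sample_id_b: str  # the sample it is related to
    degree: str
    king: float

    def __post_init__(self) -> None:
        if self.sample_id_a == self.sample_id_b:
            raise PedigreeError("kinship record must relate two distinct samples")


@dataclass
class KingCounts:
    n11: int
    n02: int
    n20: int
    n1_star: int
    star_1: int


def king_counts(geno_i: np.ndarray, geno_j: np.ndarray) -> KingCounts:
    gi = np.asarray(geno_i)
    gj = np.asarray(geno_j)
    if gi.shape != gj.shape:
        raise PedigreeError("sequences must have equal length")
    if (gi == MISSING).any() or (gj == MISSING).any():
        raise PedigreeError("KING counts require complete sequences")
    het_i = gi == 1
    het_j = gj == 1
    return KingCounts(
        n11=int((het_i & het_j).sum()),
        n02=int(((gi == 0) & (gj == 2)).sum()),
        n20=int(((gi == 2) & (gj == 0)).sum()),
        n1_star=int(het_i.sum()),
        star_1=int(het_j.sum()),
    )


def king_coefficient(geno_i: np.ndarray, geno_j: np.ndarray) -> float:
    """KING kinship coefficient between two complete genotype sequences."""
    c = king_counts(geno_i, geno_j)
    if c.n1_star == 0:
        raise PedigreeError(
            "KING coefficient undefined: first individual has no heterozygous sites"
        )
    return (2 * c.n11 - 4 * (c.n02 + c.n20) - c.star_1 + c.n1_star) / (
        4 * c.n1_star
    )


def mendelian_offspring(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Offspring genotype: one allele transmitted per parent per SNP."""
    pa = np.asarray(parent_a)
    pb = np.asarray(parent_b)
    if pa.shape != pb.shape:
        raise PedigreeError("parent sequences must have equal length")
    for g in (pa, pb):
        if (g == MISSING).any() or not np.isin(g, (0, 1, 2)).all():
            raise PedigreeError("parent genotypes must be complete, in {0,1,2}")

    def transmit(g: np.ndarray) -> np.ndarray:
        allele = (g == 2).astype(np.int8)  # 0 -> ref, 2 -> alt
        het = g == 1
        allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        return allele

    return (transmit(pa) + transmit(pb)).astype(np.int8)


def _draw_ids(
    n: int,
    rng: np.random.Generator,
    used: set[str],
    id_range: tuple[int, int] = (1_000_000, 9_999_999),
) -> list[str]:
    lo, hi = id_range
    ids: list[str] = []
    while len(ids) < n:
        candidate = str(int(rng.integers(lo, hi + 1)))
        if candidate not in used:
            used.add(candidate)
            ids.append(candidate)
    return ids


def _pair_halves(
    members: list[int],
    parents_of: dict[int, tuple[int, int] | None],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Split into father/mother halves and pair without replacement,
    avoiding pairs that share a parent."""
    for _ in range(100):
        order = rng.permutation(len(members))
        half = len(members) // 2
        fathers = [members[i] for i in order[:half]]
        mothers = [members[i] for i in order[half : 2 * half]]
        pairs = list(zip(fathers, mothers))
        ok = True
        for a, b in pairs:
            pa, pb = parents_of.get(a), parents_of.get(b)
            if pa is not None and pb is not None and set(pa) & set(pb):
                ok = False
                break
        if ok:
            return pairs
    raise PedigreeError("could not pair parents without sibling matings")


def simulate_generations(
    group: GenotypeMatrix,
    schedule: GenerationSchedule,
    rng: np.random.Generator,
    used_ids: set[str] | None = None,
) -> tuple[GenotypeMatrix, list[KinshipRecord]]:
    """Breed the scheduled descendant generations from one ancestry group.

    Returns the relatives' genotype matrix (founder order preserved within
    generations) and one kinship record per ancestor-descendant pair at
    meiosis distance 1..len(schedule.counts).
    """
    schedule.validate()
    if not schedule.counts:
        empty = GenotypeMatrix(
            sample_ids=[],
            snp_ids=list(group.snp_ids),
            ancestry=np.empty(0, dtype=object),
            genotypes=np.empty((0, group.n_snps), dtype=np.int8),
        )
        return empty, []
    if group.n_samples < schedule.n_founders_selected:
        raise PedigreeError(
            f"group of {group.n_samples} cannot supply "
            f"{schedule.n_founders_selected} founders"
        )
    labels = set(group.ancestry.tolist())
    if len(labels) != 1:
        raise PedigreeError("relatives are bred within a single ancestry group")
    label = labels.pop()
    if used_ids is None:
        used_ids = set(group.sample_ids)

    founders = rng.choice(
        group.n_samples, size=schedule.n_founders_selected, replace=False
    )
    # node bookkeeping: founders are negative-free indices into `genomes`
    genomes: list[np.ndarray] = [group.genotypes[i] for i in founders]
    node_ids: list[str] = [group.sample_ids[i] for i in founders]
    parents_of: dict[int, tuple[int, int] | None] = {
        i: None for i in range(len(founders))
    }
    is_relative: list[bool] = [False] * len(founders)

    current = list(range(len(founders)))
    for count in schedule.counts:
        pairs = _pair_halves(current, parents_of, rng)[:count]
        children = []
        child_ids = _draw_ids(count, rng, used_ids)
        for (fa, mo), cid in zip(pairs, child_ids):
            child = len(genomes)
            genomes.append(mendelian_offspring(genomes[fa], genomes[mo], rng))
            node_ids.append(cid)
            parents_of[child] = (fa, mo)
            is_relative.append(True)
            children.append(child)
        current = children

    # ancestor enumeration by meiosis distance
    ancestors: dict[int, dict[int, int]] = {}
    for node in range(len(genomes)):
        par = parents_of[node]
        if par is None:
            ancestors[node] = {}
            continue
        amap: dict[int, int] = {}
        for p in par:
            amap[p] = min(amap.get(p, 99), 1)
            for a, d in ancestors[p].items():
                amap[a] = min(amap.get(a, 99), d + 1)
        ancestors[node] = amap

    records: list[KinshipRecord] = []
    rel_nodes = [i for i, r in enumerate(is_relative) if r]
    for node in rel_nodes:
        for anc, dist in sorted(ancestors[node].items()):
            records.append(
                KinshipRecord(
                    sample_id_a=node_ids[node],
                    sample_id_b=node_ids[anc],
                    degree=degree_label(dist),
                    king=king_coefficient(genomes[node], genomes[anc]),
                )
            )

    relatives = GenotypeMatrix(
        sample_ids=[node_ids[i] for i in rel_nodes],
        snp_ids=list(group.snp_ids),
        ancestry=np.full(len(rel_nodes), label, dtype=object),
        genotypes=np.vstack([genomes[i] for i in rel_nodes]),
    )
    return relatives, records
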