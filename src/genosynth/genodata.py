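"""Genotype containers and the dataset's CSV file layouts.

Genotypes use additive encoding: 0 = homozygous reference (dominant),
1 = heterozygous, 2 = homozygous alternate (recessive). Missing genotypes
are stored internally as ``MISSING`` (-1) and written to CSV as a
configurable token (default ``"NA"``).

The five on-disk layouts are:

* Sample SNP Data — sample ID, ancestry, then one column per SNP.
* Phenotype Condition Data — sample ID, binary phenotype.
* Watermark SNP Data — sample ID, one column per watermark SNP; a final
  extra row holds the per-SNP association p-values.
* Kinship-Relatedness Data — sample ID, related sample ID, relatedness
  degree, kinship coefficient.
* Synthetic Relatives SNP Data — sample ID, then one column per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

MISSING = -1

DEFAULT_ANCESTRIES = (
    "African",
    "American",
    "East Asian",
    "European",
    "South Asian",
    "West Asian",
)

SAMPLE_ID_COL = "Sample ID"
ANCESTRY_COL = "Ancestry"
PHENOTYPE_COL = "Phenotype Condition"
RELATED_ID_COL = "Related Sample ID"
RELATEDNESS_COL = "Relatedness"
KINSHIP_COL = "Kinship Coefficient"
P_VALUE_ROW_ID = "p-value"


class GenotypeDataError(ValueError):
    """Raised when genotype data violate the container invariants."""


@dataclass
class GenotypeMatrix:
    """A samples x SNPs additive genotype matrix with ancestry labels.

    Attributes
    ----------
    sample_ids : list of str
        Unique per-sample identifiers (row labels).
    snp_ids : list of str
        Unique per-SNP identifiers (column labels).
    ancestry : ndarray of str
        One ancestry label per sample.
    genotypes : ndarray of int8
        Values in {0, 1, 2} or ``MISSING``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    ancestry: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.ancestry = np.asarray(self.ancestry, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise GenotypeDataError("genotypes must be a 2-D array")
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise GenotypeDataError(
                f"{len(self.sample_ids)} sample IDs for {n} genotype rows"
            )
        if len(self.snp_ids) != m:
            raise GenotypeDataError(
                f"{len(self.snp_ids)} SNP IDs for {m} genotype columns"
            )
        if len(set(self.sample_ids)) != n:
            raise GenotypeDataError("duplicate sample IDs")
        if len(set(self.snp_ids)) != m:
            raise GenotypeDataError("duplicate SNP IDs")
        if self.ancestry.shape != (n,):
            raise GenotypeDataError("one ancestry label required per sample")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeDataError(
                f"invalid genotype value {self.genotypes[i, j]} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def ancestry_labels(self) -> list[str]:
        """Distinct ancestry labels, in sorted order."""
        return sorted(set(self.ancestry.tolist()))

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            snp_ids=list(self.snp_ids),
            ancestry=self.ancestry[index],
            genotypes=self.genotypes[index],
        )

    def take_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[j] for j in index],
            ancestry=self.ancestry.copy(),
            genotypes=self.genotypes[:, index],
        )

    def for_ancestry(self, label: str) -> "GenotypeMatrix":
        idx = np.flatnonzero(self.ancestry == label)
        if idx.size == 0:
            raise GenotypeDataError(f"no samples with ancestry {label!r}")
        return self.take_samples(idx)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and self.ancestry.tolist() == other.ancestry.tolist()
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class DatasetBundle:
    """The full generated dataset: samples plus all derived artefacts.

    ``relatives`` must share the SNP axis with ``samples``; every kinship
    record must reference sample IDs present in ``samples`` or
    ``relatives``.
    """

    samples: GenotypeMatrix
    relatives: GenotypeMatrix
    phenotype: Any  # PhenotypeSet
    watermark: Any  # WatermarkBlock
    kinship: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.relatives.snp_ids != self.samples.snp_ids:
            raise GenotypeDataError(
                "relatives' SNP axis must equal the samples' SNP axis"
            )
        known = set(self.samples.sample_ids) | set(self.relatives.sample_ids)
        for rec in self.kinship:
            for sid in (rec.sample_id_a, rec.sample_id_b):
                if sid not in known:
                    raise GenotypeDataError(
                        f"kinship record references unknown sample {sid!r}"
                    )


def _parse_genotype_table(
    raw: pd.DataFrame, snp_cols: list[str], missing_token: str
) -> np.ndarray:
    block = raw[snp_cols].astype(str).to_numpy()
    block = np.char.strip(block.astype(str))
    geno = np.full(block.shape, MISSING, dtype=np.int8)
    is_missing = block == missing_token
    for val in ("0", "1", "2"):
        geno[block == val] = int(val)
    bad = (geno == MISSING) & ~is_missing
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeDataError(
            f"unparseable genotype {block[i, j]!r} at data row {i + 1}, "
            f"column {snp_cols[j]!r}"
        )
    return geno


def read_sample_snp_csv(
    path: str | Path, missing_token: str = "NA"
) -> GenotypeMatrix:
    """Read a Sample SNP Data CSV (sample ID, ancestry, SNP columns)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise GenotypeDataError(
            "Sample SNP Data needs sample ID, ancestry and >=1 SNP column"
        )
    id_col, anc_col = raw.columns[0], raw.columns[1]
    snp_cols = list(raw.columns[2:])
    sample_ids = raw[id_col].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dupes = raw[id_col][raw[id_col].duplicated()].tolist()
        raise GenotypeDataError(f"duplicate sample IDs in {path}: {dupes[:5]}")
    geno = _parse_genotype_table(raw, snp_cols, missing_token)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_cols,
        ancestry=raw[anc_col].to_numpy(dtype=object),
        genotypes=geno,
    )


def _genotype_strings(geno: np.ndarray, missing_token: str) -> np.ndarray:
    out = geno.astype(object).astype(str)
    out[geno == MISSING] = missing_token
    return out


def write_sample_snp_csv(
    gm: GenotypeMatrix, path: str | Path, missing_token: str = "NA"
) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        _genotype_strings(gm.genotypes, missing_token), columns=gm.snp_ids
    )
    df.insert(0, ANCESTRY_COL, gm.ancestry)
    df.insert(0, SAMPLE_ID_COL, gm.sample_ids)
    df.to_csv(path, index=False)
    return path


def write_relatives_snp_csv(
    gm: GenotypeMatrix, path: str | Path, missing_token: str = "NA"
) -> Path:
    """Synthetic Relatives SNP Data: sample ID then SNP columns (no ancestry)."""
    path = Path(path)
    df = pd.DataFrame(
        _genotype_strings(gm.genotypes, missing_token), columns=gm.snp_ids
    )
    df.insert(0, SAMPLE_ID_COL, gm.sample_ids)
    df.to_csv(path, index=False)
    return path


def read_relatives_snp_csv(
    path: str | Path,
    missing_token: str = "NA",
    ancestry_label: str = "unknown",
) -> GenotypeMatrix:
    """Read a Synthetic Relatives SNP Data CSV (sample ID, SNP columns).

    The on-disk layout carries no ancestry column; rows get
    ``ancestry_label``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise GenotypeDataError(
            "Relatives SNP Data needs a sample ID and >=1 SNP column"
        )
    snp_cols = list(raw.columns[1:])
    geno = _parse_genotype_table(raw, snp_cols, missing_token)
    return GenotypeMatrix(
        sample_ids=raw.iloc[:, 0].tolist(),
        snp_ids=snp_cols,
        ancestry=np.full(len(raw), ancestry_label, dtype=object),
        genotypes=geno,
    )


def write_phenotype_csv(phenotype: Any, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            SAMPLE_ID_COL: phenotype.sample_ids,
            PHENOTYPE_COL: np.asarray(phenotype.values, dtype=int),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_phenotype_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Return (sample_ids, 0/1 labels) from a Phenotype Condition CSV."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] != 2:
        raise GenotypeDataError("Phenotype Condition Data must have 2 columns")
    values = raw.iloc[:, 1].astype(int).to_numpy(dtype=np.int8)
    if not np.isin(values, (0, 1)).all():
        raise GenotypeDataError("phenotype values must be 0 or 1")
    return raw.iloc[:, 0].tolist(), values


def write_watermark_csv(
    watermark: Any, sample_ids: Sequence[str], path: str | Path
) -> Path:
    """Watermark SNP Data: one row per sample plus a final p-value row."""
    path = Path(path)
    geno = np.asarray(watermark.genotypes)
    if geno.shape[0] != len(sample_ids):
        raise GenotypeDataError("watermark rows do not match sample IDs")
    df = pd.DataFrame(geno.astype(int).astype(str), columns=watermark.snp_ids)
    df.insert(0, SAMPLE_ID_COL, list(sample_ids))
    tail = pd.DataFrame(
        [[P_VALUE_ROW_ID] + [repr(float(p)) for p in watermark.p_values]],
        columns=df.columns,
    )
    pd.concat([df, tail], ignore_index=True).to_csv(path, index=False)
    return path


def read_watermark_csv(
    path: str | Path,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Return (sample_ids, watermark_snp_ids, genotypes, p_values)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.iloc[-1, 0] != P_VALUE_ROW_ID:
        raise GenotypeDataError("watermark file lacks the final p-value row")
    snp_ids = list(raw.columns[1:])
    body = raw.iloc[:-1]
    geno = body[snp_ids].astype(int).to_numpy(dtype=np.int8)
    p_values = raw.iloc[-1, 1:].astype(float).to_numpy()
    return body.iloc[:, 0].tolist(), snp_ids, geno, p_values


def write_kinship_csv(kinship: Sequence[Any], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            SAMPLE_ID_COL: [r.sample_id_a for r in kinship],
            RELATED_ID_COL: [r.sample_id_b for r in kinship],
            RELATEDNESS_COL: [r.degree for r in kinship],
            KINSHIP_COL: [repr(float(r.king)) for r in kinship],
        }
    )
    df.to_csv(path, index=False)
    return path


BUNDLE_FILES = {
    "samples": "sample_snp_data.csv",
    "phenotype": "phenotype_condition_data.csv",
    "watermark": "watermark_snp_data.csv",
    "kinship": "kinship_relatedness_data.csv",
    "relatives": "synthetic_relatives_snp_data.csv",
}


def write_bundle(
    bundle: DatasetBundle, directory: str | Path, missing_token: str = "NA"
) -> list[Path]:
    """Write the five dataset CSV files; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if list(bundle.phenotype.sample_ids) != list(bundle.samples.sample_ids):
        raise GenotypeDataError(
            "phenotype sample IDs do not match the sample matrix"
        )
    paths = [
        write_sample_snp_csv(
            bundle.samples, directory / BUNDLE_FILES["samples"], missing_token
        ),
        write_phenotype_csv(
            bundle.phenotype, directory / BUNDLE_FILES["phenotype"]
        ),
        write_watermark_csv(
            bundle.watermark,
            bundle.samples.sample_ids,
            directory / BUNDLE_FILES["watermark"],
        ),
        write_kinship_csv(bundle.kinship, directory / BUNDLE_FILES["kinship"]),
        write_relatives_snp_csv(
            bundle.relatives,
            directory / BUNDLE_FILES["relatives"],
            missing_token,
        ),
    ]
    return paths


def read_vcf(path: str | Path, ancestry_label: str = "unknown") -> GenotypeMatrix:
    """Optional VCF import: GT fields collapsed to additive coding.

    Counts copies of the first ALT allele per genotype; any missing allele
    marks the genotype missing. Requires cyvcf2.
    """
    from cyvcf2 import VCF  # local import: optional dependency

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for k, variant in enumerate(vcf):
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snp_ids.append(vid)
        # gts012=True encodes genotypes as 0/1/2 with 3 = unknown
        g = np.asarray(variant.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    geno = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        ancestry=np.full(len(sample_ids), ancestry_label, dtype=object),
        genotypes=geno,
    )
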