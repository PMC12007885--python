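"""End-to-end orchestration: QC -> stratify -> per-group synthesis ->
phenotype -> watermark -> relatives -> kinship, plus validation statistics.

One global seed deterministically derives every stage's random stream (via
numpy SeedSequence spawning), so two runs with the same configuration and
seed produce byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .basepop import FounderConfig, simulate_founders
from .genodata import DatasetBundle, GenotypeMatrix, write_bundle
from .ldp import LDPParams, SynthesisConfig, assign_sample_ids, synthesize_group
from .pedigree import GenerationSchedule, KinshipRecord, simulate_generations
from .phenotype import PhenoParams, PhenotypeSet, select_causal_snps, simulate_phenotype
from .qc import QCThresholds, apply_qc, compute_maf
from .stratify import fit_pca, geometry_for, group_geometry
from .watermark import WatermarkParams, association_test, generate_watermarks

logger = logging.getLogger("genosynth")

STAGES = (
    "founders",
    "qc",
    "stratify",
    "synthesize",
    "ids",
    "phenotype",
    "watermark",
    "relatives",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All stage parameter blocks plus the global seed."""

    founder: FounderConfig = field(default_factory=FounderConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_components: int | None = None  # default min(200, samples-1, SNPs)
    geometry_percentile: float = 97.5
    ldp: LDPParams = field(default_factory=LDPParams)
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    pheno: PhenoParams = field(default_factory=PhenoParams)
    watermark: WatermarkParams = field(default_factory=WatermarkParams)
    schedule: GenerationSchedule = field(default_factory=GenerationSchedule)
    phenotype_on_combined: bool = True
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        builders = {
            "founder": FounderConfig,
            "qc": QCThresholds,
            "ldp": LDPParams,
            "synthesis": SynthesisConfig,
            "pheno": PhenoParams,
            "watermark": WatermarkParams,
            "schedule": GenerationSchedule,
        }
        kwargs = {}
        for key, value in data.items():
            if key in builders and isinstance(value, dict):
                value = dict(value)
                for tup_key in ("maf_range", "id_range", "counts"):
                    if tup_key in value and isinstance(value[tup_key], list):
                        value[tup_key] = tuple(value[tup_key])
                kwargs[key] = builders[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


@dataclass
class ValidationReport:
    """Summary statistics the dataset is validated with."""

    maf_pairs: np.ndarray  # (n_snps, 2): original vs synthetic MAF
    maf_mean_abs_gap: float
    maf_max_abs_gap: float
    watermark_p_mean: float | None
    watermark_p_sd: float | None
    watermark_p_max: float | None
    kinship_by_degree: dict
    counts: dict

    def summary(self) -> dict:
        return {
            "maf_mean_abs_gap": self.maf_mean_abs_gap,
            "maf_max_abs_gap": self.maf_max_abs_gap,
            "watermark_p_mean": self.watermark_p_mean,
            "watermark_p_sd": self.watermark_p_sd,
            "watermark_p_max": self.watermark_p_max,
            "kinship_by_degree": self.kinship_by_degree,
            "counts": self.counts,
        }


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    streams = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(STAGES, streams)}


def run_pipeline(
    config: RunConfig, originals: GenotypeMatrix | None = None
) -> DatasetBundle:
    """Run the full generation flow and return the dataset bundle.

    ``originals`` defaults to a simulated founder population. Phenotypes
    are simulated on the combined original + synthetic matrix (the default)
    but only synthetic-sample labels are exported in the bundle.
    """
    rngs = _stage_rngs(config.seed)

    if originals is None:
        originals = simulate_founders(config.founder, rngs["founders"])
    logger.info("input: %d samples x %d SNPs", originals.n_samples, originals.n_snps)

    try:
        clean, qc_report = apply_qc(originals, config.qc)
    except Exception as exc:
        raise PipelineError(f"qc stage failed: {exc}") from exc
    logger.info("qc: %s -> %s", qc_report.shape_before, qc_report.shape_after)

    try:
        model = fit_pca(clean, config.n_components)
        geometries = group_geometry(model, clean, config.geometry_percentile)
    except Exception as exc:
        raise PipelineError(f"stratify stage failed: {exc}") from exc
    logger.info("stratify: %d components, %d groups", model.n_components, len(geometries))

    groups = clean.ancestry_labels()
    blocks = []
    for label in groups:
        try:
            blocks.append(
                synthesize_group(
                    clean.for_ancestry(label),
                    model,
                    geometry_for(geometries, label),
                    config.synthesis,
                    config.ldp,
                    rngs["synthesize"],
                )
            )
        except Exception as exc:
            raise PipelineError(
                f"synthesize stage failed for group {label!r}: {exc}"
            ) from exc

    synthetic = GenotypeMatrix(
        sample_ids=[s for b in blocks for s in b.sample_ids],
        snp_ids=list(clean.snp_ids),
        ancestry=np.concatenate([b.ancestry for b in blocks])
        if blocks
        else np.empty(0, dtype=object),
        genotypes=np.vstack([b.genotypes for b in blocks])
        if blocks
        else np.empty((0, clean.n_snps), dtype=np.int8),
    )
    # random IDs over all synthetic samples, rows re-ordered ascending by ID
    ids = assign_sample_ids(synthetic.n_samples, config.synthesis, rngs["ids"])
    shuffle = rngs["ids"].permutation(synthetic.n_samples)
    synthetic = GenotypeMatrix(
        sample_ids=[str(i) for i in ids],
        snp_ids=synthetic.snp_ids,
        ancestry=synthetic.ancestry[shuffle],
        genotypes=synthetic.genotypes[shuffle],
    )
    logger.info("synthesize: %d synthetic samples", synthetic.n_samples)

    pheno_matrix = synthetic
    if config.phenotype_on_combined:
        pheno_matrix = GenotypeMatrix(
            sample_ids=list(clean.sample_ids) + list(synthetic.sample_ids),
            snp_ids=list(clean.snp_ids),
            ancestry=np.concatenate([clean.ancestry, synthetic.ancestry]),
            genotypes=np.vstack([clean.genotypes, synthetic.genotypes]),
        )
    try:
        causal = select_causal_snps(
            pheno_matrix.snp_ids, config.pheno.causal_fraction, rngs["phenotype"]
        )
        pheno_full = simulate_phenotype(
            pheno_matrix, causal, config.pheno, rngs["phenotype"]
        )
    except Exception as exc:
        raise PipelineError(f"phenotype stage failed: {exc}") from exc
    pheno = pheno_full.subset(synthetic.sample_ids)
    logger.info(
        "phenotype: %d causal SNPs, %d/%d cases (exported subset)",
        len(causal),
        pheno.n_cases,
        len(pheno.sample_ids),
    )

    try:
        wm = generate_watermarks(
            pheno, config.watermark, rngs["watermark"], set(synthetic.snp_ids)
        )
    except Exception as exc:
        raise PipelineError(f"watermark stage failed: {exc}") from exc
    logger.info("watermark: %d columns", len(wm.snp_ids))

    relatives_blocks: list[GenotypeMatrix] = []
    kinship: list[KinshipRecord] = []
    used_ids = set(synthetic.sample_ids)
    for label in groups:
        try:
            rel, recs = simulate_generations(
                synthetic.for_ancestry(label),
                config.schedule,
                rngs["relatives"],
                used_ids,
            )
        except Exception as exc:
            raise PipelineError(
                f"relatives stage failed for group {label!r}: {exc}"
            ) from exc
        relatives_blocks.append(rel)
        kinship.extend(recs)
    relatives = GenotypeMatrix(
        sample_ids=[s for b in relatives_blocks for s in b.sample_ids],
        snp_ids=list(clean.snp_ids),
        ancestry=np.concatenate([b.ancestry for b in relatives_blocks])
        if relatives_blocks
        else np.empty(0, dtype=object),
        genotypes=np.vstack([b.genotypes for b in relatives_blocks])
        if relatives_blocks
        else np.empty((0, clean.n_snps), dtype=np.int8),
    )
    logger.info(
        "relatives: %d relatives, %d kinship pairs", relatives.n_samples, len(kinship)
    )

    bundle = DatasetBundle(
        samples=synthetic,
        relatives=relatives,
        phenotype=pheno,
        watermark=wm,
        kinship=kinship,
        provenance={"config": config.to_dict(), "qc": qc_report.summary()},
    )
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
        logger.info("wrote bundle to %s", config.out_dir)
    return bundle


def validate(bundle: DatasetBundle, originals: GenotypeMatrix) -> ValidationReport:
    """Compare the bundle against the (QC'd) originals it was built from."""
    if originals.snp_ids != bundle.samples.snp_ids:
        raise PipelineError("original and synthetic SNP axes differ")
    orig_maf = np.array(
        [compute_maf(originals.genotypes[:, j]) for j in range(originals.n_snps)]
    )
    syn_maf = np.array(
        [
            compute_maf(bundle.samples.genotypes[:, j])
            for j in range(bundle.samples.n_snps)
        ]
    )
    gaps = np.abs(orig_maf - syn_maf)

    wm = bundle.watermark
    if len(wm.snp_ids):
        recomputed = np.array(
            [
                association_test(wm.genotypes[:, j], bundle.phenotype.values)
                for j in range(len(wm.snp_ids))
            ]
        )
        p_mean = float(recomputed.mean())
        p_sd = float(recomputed.std(ddof=1)) if len(recomputed) > 1 else 0.0
        p_max = float(recomputed.max())
    else:
        p_mean = p_sd = p_max = None

    by_degree: dict[str, dict] = {}
    for rec in bundle.kinship:
        by_degree.setdefault(rec.degree, []).append(rec.king)
    kin_summary = {
        deg: {
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
        }
        for deg, vals in by_degree.items()
    }

    counts = {
        "n_synthetic_samples": bundle.samples.n_samples,
        "n_relatives": bundle.relatives.n_samples,
        "n_total_samples": bundle.samples.n_samples + bundle.relatives.n_samples,
        "n_data_snps": bundle.samples.n_snps,
        "n_watermarks": len(wm.snp_ids),
        "n_total_snp_columns": bundle.samples.n_snps + len(wm.snp_ids),
        "n_kinship_pairs": len(bundle.kinship),
        "n_cases": bundle.phenotype.n_cases,
    }
    return ValidationReport(
        maf_pairs=np.column_stack([orig_maf, syn_maf]),
        maf_mean_abs_gap=float(gaps.mean()),
        maf_max_abs_gap=float(gaps.max()),
        watermark_p_mean=p_mean,
        watermark_p_sd=p_sd,
        watermark_p_max=p_max,
        kinship_by_degree=kin_summary,
        counts=counts,
    )
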