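"""End-to-end pipeline: synth -> qc -> rank -> assoc -> enrich, plus a
calibration harness that measures type-I error and power of the enrichment
call over replicated synthetic cohorts.

Every random stage derives its seed from the master seed through
``numpy.random.SeedSequence`` spawn keys, so a stage can be re-run in
isolation and a full re-run under the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .association import ModelSpec, run_scan
from .cohort import (
    Cohort,
    CohortDesign,
    PlantedEffect,
    default_design,
    generate_cohort,
)
from .enrichment import (
    EnrichmentResult,
    build_epochs,
    results_frame,
    run_enrichment_curve,
)
from .qc import QCThresholds, ancestry_pca, compute_maf, filter_variants, pairwise_ibs
from .ranking import rank_case_genes, term_enrichment

STAGES = ("synth", "qc", "rank", "assoc", "enrich")


@dataclass
class PipelineConfig:
    """Everything needed to run (and exactly reproduce) a pipeline pass."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # synthetic design (ignored when input_dir is given)
    n_samples: int = 140
    n_case_genes: int = 120
    n_control_genes: int = 600
    snps_per_gene: int = 4
    missing_rate: float = 0.002
    planted_interaction_beta: float = 0.0
    planted_main_beta_long: float = 0.0
    n_planted_genes: int = 0
    snps_per_planted_gene: int = 1  # one causal variant per planted gene
    input_dir: str | None = None
    # QC
    hwe_alpha: float = 1e-4
    maf_min: float = 0.10
    snp_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.99
    # association
    trim_alpha: float = 0.05
    # enrichment
    alpha: float = 0.05
    R: int = 10_000
    step: int = 5
    ibs_flag_threshold: float = 0.90
    figures: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def thresholds(self) -> QCThresholds:
        return QCThresholds(
            hwe_alpha=self.hwe_alpha,
            maf_min=self.maf_min,
            snp_call_rate_min=self.snp_call_rate_min,
            sample_call_rate_min=self.sample_call_rate_min,
        )


def _stage_seed(master: int, stage: str) -> int:
    key = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
    return int(np.random.SeedSequence(master, spawn_key=(key,)).generate_state(1)[0] % (2**31))


def _build_design(config: PipelineConfig) -> CohortDesign:
    design = default_design(
        n_case_genes=config.n_case_genes,
        n_control_genes=config.n_control_genes,
        snps_per_gene=config.snps_per_gene,
        seed=_stage_seed(config.seed, "synth"),
        missing_rate=config.missing_rate,
    )
    if config.n_planted_genes > 0:
        planted_genes = [f"CASE{i:04d}" for i in range(1, config.n_planted_genes + 1)]
        snps = [
            f"{gene}_snp{k}"
            for gene in planted_genes
            for k in range(min(config.snps_per_planted_gene, config.snps_per_gene))
        ]
        effects_short = [
            PlantedEffect(s, 0.0, config.planted_interaction_beta) for s in snps
        ] if config.planted_interaction_beta else []
        effects_long = [
            PlantedEffect(s, config.planted_main_beta_long, 0.0) for s in snps
        ] if config.planted_main_beta_long else []
        design = replace(design, planted_effects=effects_short, planted_effects_long=effects_long)
    return design


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write the report bundle.

    Outputs land under ``config.outdir``: cohort files, ``qc_report.json``/
    ``.tsv``, ``ranked_genes.tsv``, ``assoc_<outcome>.tsv``,
    ``enrichment.tsv``/``.json`` and optional figures. Returns a dict with
    the in-memory results. A stage failure raises with the stage name;
    earlier outputs remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"seed": config.seed, "stages": list(config.stages)}

    cohort: Cohort | None = None
    try:
        if "synth" in config.stages:
            design = _build_design(config)
            cohort = generate_cohort(design)
            cio.write_cohort(cohort, outdir / "cohort")
            report["synth"] = {
                "n_samples": cohort.genotypes.n_samples,
                "n_snps": cohort.genotypes.n_snps,
                "seed": design.seed,
            }
        elif config.input_dir:
            cohort = cio.read_cohort(config.input_dir)
        else:
            raise ValueError("no synth stage and no input_dir to load a cohort from")
    except Exception as exc:
        raise RuntimeError(f"stage 'synth' failed: {exc}") from exc

    geno, variants, phenos = cohort.genotypes, cohort.variants, cohort.phenotypes
    qc_geno = geno
    pcs = None
    if "qc" in config.stages:
        try:
            qc_report, qc_geno = filter_variants(geno, variants, config.thresholds())
            (outdir / "qc_report.json").write_text(qc_report.to_json())
            qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
            pcs = ancestry_pca(qc_geno)
            pcs.to_csv(outdir / "ancestry_pcs.tsv", sep="\t")
            ibs = pairwise_ibs(qc_geno, flag_threshold=config.ibs_flag_threshold)
            ibs[ibs["flagged"]].to_csv(outdir / "related_pairs.tsv", sep="\t", index=False)
            report["qc"] = qc_report.counts
            report["qc"]["n_flagged_pairs"] = int(ibs["flagged"].sum())
        except Exception as exc:
            raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    ranked = None
    if "rank" in config.stages:
        try:
            if cohort.catalog is None:
                raise ValueError("no gene catalog available for ranking")
            ranked = rank_case_genes(cohort.catalog)
            ranked.to_csv(outdir / "ranked_genes.tsv", sep="\t", index=False)
            top10 = set(ranked["gene"].head(max(1, len(ranked) // 10)))
            enr = term_enrichment(
                set(cohort.catalog.genes_with("training")) | top10, cohort.catalog
            )
            enr[enr["significant"]].to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)
            report["rank"] = {"n_ranked": len(ranked), "n_enriched_terms": int(enr["significant"].sum())}
        except Exception as exc:
            raise RuntimeError(f"stage 'rank' failed: {exc}") from exc

    assoc_tables: dict[str, pd.DataFrame] = {}
    mafs: dict[str, float] = {}
    if "assoc" in config.stages:
        try:
            for outcome in ("short_term", "long_term"):
                spec = ModelSpec(outcome=outcome, trim_alpha=config.trim_alpha, use_pc1=pcs is not None)
                table = run_scan(qc_geno, phenos, spec, pcs=pcs, variants=variants)
                table.to_csv(outdir / f"assoc_{outcome}.tsv", sep="\t", index=False)
                assoc_tables[outcome] = table
                report.setdefault("assoc", {})[outcome] = {
                    "n_snps": len(table),
                    "n_valid": int(table["valid"].sum()),
                    "retained_covariates": table.attrs["retained_covariates"],
                }
            mafs = {
                snp: compute_maf(qc_geno.dosages[:, j])
                for j, snp in enumerate(qc_geno.snp_ids)
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'assoc' failed: {exc}") from exc

    if "enrich" in config.stages:
        try:
            if ranked is None or not assoc_tables:
                raise ValueError("enrichment needs the rank and assoc stages")
            training = cohort.catalog.genes_with("training")
            controls = cohort.catalog.genes_with("control")
            epochs = build_epochs(ranked["gene"].tolist(), training, step=config.step)
            results = run_enrichment_curve(
                epochs,
                assoc_tables,
                variants[variants["snp_id"].isin(set(qc_geno.snp_ids))],
                controls,
                mafs,
                alpha=config.alpha,
                R=config.R,
                seed=_stage_seed(config.seed, "enrich"),
            )
            frame = results_frame(results)
            frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            (outdir / "enrichment.json").write_text(
                json.dumps(frame.to_dict(orient="records"), indent=2, default=str)
            )
            report["enrich"] = {
                "n_cells": len(frame),
                "n_enriched": int(frame["enriched"].sum()),
            }
            if config.figures:
                _write_figures(results, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc
        report["enrichment_results"] = results

    report["assoc_tables"] = assoc_tables
    report["ranked"] = ranked
    report["cohort"] = cohort
    (outdir / "report.json").write_text(
        json.dumps({k: v for k, v in report.items() if _jsonable(v)}, indent=2, sort_keys=True)
    )
    return report


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _write_figures(results: Sequence[EnrichmentResult], outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    from .enrichment import plot_enrichment_curve

    combos = sorted({(r.family, r.outcome) for r in results})
    for family, outcome in combos:
        fig, ax = plt.subplots(figsize=(8, 4))
        plot_enrichment_curve(results, family, outcome, ax=ax)
        fig.tight_layout()
        fig.savefig(outdir / f"enrichment_{family}_{outcome}.png", dpi=100, metadata={"Software": ""})
        plt.close(fig)


def calibration_harness(
    n_replicates: int,
    scenario: str = "null",
    seed: int = 0,
    n_samples: int = 140,
    n_case_genes: int = 75,
    n_control_genes: int = 750,
    snps_per_gene: int = 4,
    n_planted_genes: int = 8,
    snps_per_planted_gene: int = 1,
    beta_interaction: float = 0.0,
    R: int = 500,
    step: int = 25,
    alpha: float = 0.05,
    outcome: str = "short_term",
    families: Sequence[str] = ("interaction",),
) -> pd.DataFrame:
    """Replicate cohort generation + scan + enrichment; tabulate flag rates.

    ``scenario="null"`` plants no effects, so the enriched flag should fire
    at roughly its nominal 5% rate per epoch. ``scenario="planted"`` plants
    ``beta_interaction`` (T-score units per minor allele, TBI group only) on
    ``snps_per_planted_gene`` SNP(s) of each of the ``n_planted_genes``
    top-ranked case genes — one causal variant per gene by default, so the
    aggregate genetic variance stays realistic as effects scale. The epochs
    use the generator's ground-truth ranking — the harness calibrates the
    enrichment statistic, not the ranker. QC is skipped: the generator's
    SNPs satisfy the QC conditions by design, and the design MAF (which is
    what control matching bands on) is known exactly.

    Returns one row per replicate x outcome-family x epoch with observed
    count, q95, empirical p and the enriched flag. Zero replicates yield an
    empty table.
    """
    if scenario not in ("null", "planted"):
        raise ValueError("scenario must be 'null' or 'planted'")
    rows = []
    master = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(max(n_replicates, 0))]
    for rep, rep_seed in enumerate(rep_seeds):
        design = default_design(
            n_case_genes=n_case_genes,
            n_control_genes=n_control_genes,
            snps_per_gene=snps_per_gene,
            seed=rep_seed,
            n_samples=n_samples,
            missing_rate=0.0,
        )
        if scenario == "planted" and beta_interaction != 0.0:
            planted_genes = [f"CASE{i:04d}" for i in range(1, n_planted_genes + 1)]
            snps = [
                f"{gene}_snp{k}"
                for gene in planted_genes
                for k in range(min(snps_per_planted_gene, snps_per_gene))
            ]
            design = replace(
                design,
                planted_effects=[PlantedEffect(s, 0.0, beta_interaction) for s in snps],
            )
        cohort = generate_cohort(design, n_case_genes=n_case_genes, n_control_genes=n_control_genes)
        spec = ModelSpec(outcome=outcome, use_pc1=False)
        assoc = run_scan(cohort.genotypes, cohort.phenotypes, spec, variants=cohort.variants)
        mafs = dict(zip(cohort.variants["snp_id"], cohort.variants["design_maf"]))
        training = [f"TRAIN{i:03d}" for i in range(1, 19)]
        true_order = [f"CASE{i:04d}" for i in range(1, n_case_genes + 1)]
        epochs = build_epochs(true_order, training, step=step)
        controls = sorted({g for g in cohort.variants["gene"] if g.startswith("CTRL")})
        results = run_enrichment_curve(
            epochs,
            {outcome: assoc},
            cohort.variants,
            controls,
            mafs,
            alpha=alpha,
            R=R,
            seed=rep_seed,
            families=families,
        )
        for r in results:
            row = r.to_row()
            row["replicate"] = rep
            row["scenario"] = scenario
            row["beta_interaction"] = beta_interaction if scenario == "planted" else 0.0
            rows.append(row)
    columns = [
        "replicate", "scenario", "beta_interaction", "epoch", "family", "outcome",
        "n_case_snps", "observed", "q95", "empirical_p", "enriched", "R", "seed",
    ]
    return pd.DataFrame(rows, columns=columns)


def flag_rates(calibration: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch (and family) enriched-flag rate across replicates."""
    if calibration.empty:
        return pd.DataFrame(columns=["epoch", "family", "rate", "n"])
    grouped = calibration.groupby(["epoch", "family"], as_index=False).agg(
        rate=("enriched", "mean"), n=("enriched", "size")
    )
    return grouped
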