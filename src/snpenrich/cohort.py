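"""Synthetic injured-cohort generator.

Emulates the statistical structure of an exome-chip study of behavioral
outcomes after early-childhood traumatic brain injury (TBI) versus
orthopedic injury (OI): biallelic autosomal SNPs in Hardy-Weinberg
equilibrium, a two-group cohort of ~140 children, CBCL-like Total Problems
T scores (normative mean 50, SD 10) with group shifts, pre-injury and
socioeconomic covariate effects, and optional planted per-allele main and
group-interaction effects used for power and calibration studies.

Every generator is deterministic given ``design.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .ranking import GeneCatalog

MISSING = -1  # dosage code for a missing genotype call

AUTOSOMES = tuple(str(c) for c in range(1, 23))


class VariantSpec(NamedTuple):
    """Design-time description of one biallelic SNP."""

    snp_id: str
    maf: float
    gene: str
    chrom: str
    variant_class: str = "missense"


class PlantedEffect(NamedTuple):
    """Additive effect of one SNP on an outcome, in T-score units per minor allele.

    ``beta_interaction`` acts only in the TBI group (SNP x group term).
    """

    snp_id: str
    beta_main: float = 0.0
    beta_interaction: float = 0.0


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage codes with an explicit missing marker.

    Dosages are stored as int8 in {0, 1, 2} with ``MISSING`` (-1) for no-calls.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # shape (n_samples, n_snps), int8

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        allowed = {0, 1, 2, MISSING}
        seen = set(np.unique(self.dosages).tolist())
        if not seen <= allowed:
            raise ValueError(f"illegal dosage codes present: {sorted(seen - allowed)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage column as float with NaN for missing calls."""
        col = self.dosages[:, self.snp_index(snp_id)].astype(float)
        col[col == MISSING] = np.nan
        return col

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        snp_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            np.arange(self.n_samples)
            if sample_ids is None
            else np.array([self.sample_ids.index(s) for s in sample_ids])
        )
        cols = (
            np.arange(self.n_snps)
            if snp_ids is None
            else np.array([self.snp_index(s) for s in snp_ids])
        )
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            snp_ids=[self.snp_ids[j] for j in cols],
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
        )


@dataclass
class CohortDesign:
    """Generative parameters for a synthetic two-group injured cohort.

    Outcome means default to the observed group means of the CBCL Total
    Problems T score in the study cohort this generator emulates (short-term
    43.76 OI / 52.80 TBI; long-term 45.12 / 55.79). ``outcome_sd`` is the
    residual noise SD, defaulting to the CBCL normative SD of 10.
    """

    n_samples: int = 140
    group_fraction_tbi: float = 69 / 140
    variant_specs: list[VariantSpec] = field(default_factory=list)
    missing_rate: float = 0.002
    outcome_mean_oi: float = 43.76
    outcome_mean_tbi: float = 52.80
    outcome_mean_oi_long: float = 45.12
    outcome_mean_tbi_long: float = 55.79
    outcome_sd: float = 10.0
    # covariate generation (pre-injury CBCL and SES z-score, Table-1-like)
    preinjury_mean_oi: float = 45.62
    preinjury_mean_tbi: float = 50.43
    preinjury_sd: float = 12.5
    ses_mean_oi: float = 0.11
    ses_mean_tbi: float = -0.14
    ses_sd: float = 0.97
    # outcome-model coefficients: T per T for pre-injury, T per SD for SES
    beta_preinjury: float = 0.40
    beta_ses: float = -1.5
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    planted_effects_long: list[PlantedEffect] = field(default_factory=list)
    # optional population structure: (n_subpops, Fst-like divergence)
    structure: tuple[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 < self.group_fraction_tbi < 1.0:
            raise ValueError("group_fraction_tbi must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.outcome_sd <= 0:
            raise ValueError("outcome_sd must be positive")
        for spec in self.variant_specs:
            if not 0.0 < spec.maf <= 0.5:
                raise ValueError(f"MAF for {spec.snp_id} must lie in (0, 0.5]")
            if spec.chrom not in AUTOSOMES + ("X", "Y", "MT", "XY"):
                raise ValueError(f"unknown chromosome {spec.chrom!r} for {spec.snp_id}")
        known = {s.snp_id for s in self.variant_specs}
        for eff in list(self.planted_effects) + list(self.planted_effects_long):
            if eff.snp_id not in known:
                raise ValueError(f"planted effect references unknown SNP {eff.snp_id!r}")
        if self.structure is not None:
            k, fst = self.structure
            if k < 2:
                raise ValueError("structure requires >= 2 subpopulations")
            if not 0.0 < fst < 1.0:
                raise ValueError("divergence parameter must lie in (0, 1)")


def _rng(design: CohortDesign, stream: str) -> np.random.Generator:
    """Independent, reproducible substream per generator stage."""
    key = zlib.crc32(stream.encode("utf-8"))  # stable across processes
    ss = np.random.SeedSequence(design.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def design_variants(
    gene_ids: Sequence[str],
    snps_per_gene: int = 4,
    maf_range: tuple[float, float] = (0.10, 0.50),
    variant_class: str = "missense",
    seed: int = 0,
) -> list[VariantSpec]:
    """Lay out a SNP panel with `snps_per_gene` SNPs per gene.

    MAFs are drawn uniformly over ``maf_range`` (the post-QC chip spectrum is
    modeled as flat on [0.10, 0.50] by default); genes are distributed across
    the 22 autosomes in order.
    """
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    specs: list[VariantSpec] = []
    for gi, gene in enumerate(gene_ids):
        chrom = AUTOSOMES[gi % len(AUTOSOMES)]
        for k in range(snps_per_gene):
            specs.append(
                VariantSpec(
                    snp_id=f"{gene}_snp{k}",
                    maf=float(rng.uniform(lo, hi)),
                    gene=gene,
                    chrom=chrom,
                    variant_class=variant_class,
                )
            )
    return specs


def variant_table(design: CohortDesign) -> pd.DataFrame:
    """Per-SNP metadata table: chrom, position, alleles, gene, class, design MAF."""
    rows = []
    pos_counter: dict[str, int] = {}
    for spec in design.variant_specs:
        pos_counter[spec.chrom] = pos_counter.get(spec.chrom, 0) + 1
        rows.append(
            {
                "snp_id": spec.snp_id,
                "chrom": spec.chrom,
                "pos": 10_000 + 1_000 * pos_counter[spec.chrom],
                "ref": "A",
                "alt": "G",
                "gene": spec.gene,
                "variant_class": spec.variant_class,
                "design_maf": spec.maf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "ref", "alt", "gene", "variant_class", "design_maf",
        ],
    )


def generate_genotypes(design: CohortDesign) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw dosages under HWE at each SNP's design MAF.

    Each dosage is the sum of two Bernoulli(maf) allele draws. If
    ``design.structure`` is set, subpopulation allele frequencies are
    perturbed around the design MAF with a Balding-Nichols Beta model at the
    given divergence, inducing genuine principal-component structure.
    Missing calls are planted independently at ``missing_rate``.
    """
    if not design.variant_specs:
        raise ValueError("design has no variant_specs")
    rng = _rng(design, "genotypes")
    n, m = design.n_samples, len(design.variant_specs)
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    mafs = np.array([s.maf for s in design.variant_specs])

    if design.structure is None:
        dose = rng.binomial(2, mafs[None, :], size=(n, m))
        subpop = None
    else:
        k, fst = design.structure
        a = mafs * (1 - fst) / fst
        b = (1 - mafs) * (1 - fst) / fst
        # subpop-specific frequencies, clipped away from fixation
        freqs = np.clip(rng.beta(a[None, :], b[None, :], size=(k, m)), 1e-4, 1 - 1e-4)
        subpop = rng.integers(0, k, size=n)
        dose = rng.binomial(2, freqs[subpop, :])
    dose = dose.astype(np.int8)
    if design.missing_rate > 0:
        miss = rng.random(size=(n, m)) < design.missing_rate
        dose[miss] = MISSING

    geno = GenotypeMatrix(sample_ids=sample_ids, snp_ids=[s.snp_id for s in design.variant_specs], dosages=dose)
    variants = variant_table(design)
    if subpop is not None:
        geno.subpop = subpop  # type: ignore[attr-defined]  # carried for phenotype stage
    return geno, variants


def _planted_dosage(geno: GenotypeMatrix, snp_id: str) -> np.ndarray:
    """Mean-centered dosage for effect construction.

    Centering keeps the group outcome means at their design values whatever
    effects are planted (the per-allele slope is unchanged by the shift);
    missing calls are mean-imputed here only.
    """
    col = geno.column(snp_id)
    called = ~np.isnan(col)
    if not called.any():
        raise ValueError(f"planted SNP {snp_id!r} has all-missing genotypes")
    mean = col[called].mean()
    col[~called] = mean
    return col - mean


def generate_phenotypes(geno: GenotypeMatrix, design: CohortDesign) -> pd.DataFrame:
    """Simulate phenotype/covariate table for the generated cohort.

    Outcome model per sample i (short-term shown; long-term analogous with its
    own group means and effect list)::

        cbcl_short_i = mean(group_i) + b_ses * ses_i + b_pre * (pre_i - mean(pre))
                       + sum_j beta_main_j * dose_ij
                       + sum_j beta_int_j * dose_ij * 1[group_i = TBI]
                       + N(0, outcome_sd)
    """
    if geno.n_samples != design.n_samples:
        raise ValueError("genotype matrix and design disagree on sample count")
    rng = _rng(design, "phenotypes")
    n = design.n_samples
    n_tbi = int(round(n * design.group_fraction_tbi))
    if n_tbi in (0, n):
        raise ValueError("group_fraction_tbi leaves one group empty at this n")
    is_tbi = np.zeros(n, dtype=bool)
    is_tbi[rng.permutation(n)[:n_tbi]] = True

    pre_mean = np.where(is_tbi, design.preinjury_mean_tbi, design.preinjury_mean_oi)
    pre = rng.normal(pre_mean, design.preinjury_sd)
    ses_mean = np.where(is_tbi, design.ses_mean_tbi, design.ses_mean_oi)
    ses = rng.normal(ses_mean, design.ses_sd)

    def outcome(mean_oi: float, mean_tbi: float, effects: list[PlantedEffect]) -> np.ndarray:
        y = np.where(is_tbi, mean_tbi, mean_oi).astype(float)
        y += design.beta_ses * ses + design.beta_preinjury * (pre - pre.mean())
        for eff in effects:
            d = _planted_dosage(geno, eff.snp_id)
            y += eff.beta_main * d + eff.beta_interaction * d * is_tbi
        return y + rng.normal(0.0, design.outcome_sd, size=n)

    phenos = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "group": np.where(is_tbi, "TBI", "OI"),
            "cbcl_preinjury": pre,
            "cbcl_short": outcome(design.outcome_mean_oi, design.outcome_mean_tbi, design.planted_effects),
            "cbcl_long": outcome(
                design.outcome_mean_oi_long, design.outcome_mean_tbi_long, design.planted_effects_long
            ),
            "ses_z": ses,
        }
    )
    subpop = getattr(geno, "subpop", None)
    if subpop is not None:
        phenos["ancestry_subpop"] = subpop
    return phenos


def generate_gene_catalog(
    n_case: int,
    n_control: int,
    n_terms_per_category: int = 200,
    similarity_gradient: Sequence[float] | None = None,
    n_training: int = 18,
    categories: Sequence[str] = (
        "pathway",
        "biological_process",
        "phenotype",
        "literature",
        "protein_interaction",
        "coexpression",
    ),
    core_size: int = 20,
    terms_per_gene: int = 12,
    seed: int = 0,
) -> GeneCatalog:
    """Build an annotation catalog with known ground-truth similarity order.

    Training genes share a core term set in every category. Case gene ``i``
    receives a fraction ``similarity_gradient[i]`` of the core terms (topped
    up with background terms), so the true similarity ranking equals the
    generation order. Control genes draw from background terms only. The
    default gradient decays linearly from 0.9 to 0.05.

    The default of 18 training genes mirrors the size of the
    literature-derived seed list of TBI-outcome genes this catalog stands in
    for.
    """
    if min(n_case, n_control, n_training, n_terms_per_category) <= 0:
        raise ValueError("all catalog counts must be positive")
    if core_size >= n_terms_per_category:
        raise ValueError("core_size must be smaller than n_terms_per_category")
    if similarity_gradient is None:
        similarity_gradient = np.linspace(0.9, 0.05, n_case)
    if len(similarity_gradient) != n_case:
        raise ValueError("similarity_gradient must have one entry per case gene")
    rng = np.random.default_rng(seed)

    training = [f"TRAIN{i:03d}" for i in range(1, n_training + 1)]
    case = [f"CASE{i:04d}" for i in range(1, n_case + 1)]
    control = [f"CTRL{i:05d}" for i in range(1, n_control + 1)]

    terms: dict[str, dict[str, frozenset[str]]] = {g: {} for g in training + case + control}
    for cat in categories:
        universe = [f"{cat}:T{t:04d}" for t in range(n_terms_per_category)]
        core = universe[:core_size]
        background = universe[core_size:]
        for g in training:
            # full core plus a little background noise
            extra = rng.choice(background, size=max(1, terms_per_gene - core_size), replace=False)
            terms[g][cat] = frozenset(core) | frozenset(extra.tolist())
        for g, frac in zip(case, similarity_gradient):
            k_core = int(round(frac * core_size))
            chosen_core = rng.choice(core, size=k_core, replace=False) if k_core else np.array([], dtype=object)
            k_bg = max(1, terms_per_gene - k_core)
            chosen_bg = rng.choice(background, size=k_bg, replace=False)
            terms[g][cat] = frozenset(chosen_core.tolist()) | frozenset(chosen_bg.tolist())
        for g in control:
            # uniform over the whole universe: expected core overlap equals
            # the chance rate terms_per_gene * core_size / n_terms
            chosen = rng.choice(universe, size=terms_per_gene, replace=False)
            terms[g][cat] = frozenset(chosen.tolist())

    designation = {g: "training" for g in training}
    designation.update({g: "case" for g in case})
    designation.update({g: "control" for g in control})
    return GeneCatalog(categories=list(categories), terms=terms, designation=designation)


@dataclass
class Cohort:
    """Bundle of the generated (or loaded) study objects."""

    design: CohortDesign | None
    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    phenotypes: pd.DataFrame
    catalog: GeneCatalog | None = None


def default_design(
    n_case_genes: int = 120,
    n_control_genes: int = 600,
    snps_per_gene: int = 4,
    seed: int = 0,
    **overrides,
) -> CohortDesign:
    """Study-scale default: n=140 cohort over training/case/control gene SNPs."""
    n_training = overrides.pop("n_training", 18)
    genes = (
        [f"TRAIN{i:03d}" for i in range(1, n_training + 1)]
        + [f"CASE{i:04d}" for i in range(1, n_case_genes + 1)]
        + [f"CTRL{i:05d}" for i in range(1, n_control_genes + 1)]
    )
    specs = design_variants(genes, snps_per_gene=snps_per_gene, seed=seed)
    return CohortDesign(variant_specs=specs, seed=seed, **overrides)


def generate_cohort(
    design: CohortDesign,
    n_case_genes: int | None = None,
    n_control_genes: int | None = None,
    catalog_seed: int | None = None,
) -> Cohort:
    """Generate genotypes, phenotypes and (when gene counts are known) a catalog."""
    geno, variants = generate_genotypes(design)
    phenos = generate_phenotypes(geno, design)
    catalog = None
    genes = variants["gene"]
    n_case = n_case_genes or int(genes.str.startswith("CASE").groupby(genes).first().sum())
    n_control = n_control_genes or int(genes.str.startswith("CTRL").groupby(genes).first().sum())
    if n_case and n_control:
        catalog = generate_gene_catalog(
            n_case=n_case,
            n_control=n_control,
            seed=design.seed if catalog_seed is None else catalog_seed,
        )
    return Cohort(design=design, genotypes=geno, variants=variants, phenotypes=phenos, catalog=catalog)


def with_planted_interactions(
    design: CohortDesign,
    snp_ids: Sequence[str],
    beta_interaction: float,
    outcome: str = "short",
) -> CohortDesign:
    """Copy of ``design`` with interaction effects planted on the given SNPs."""
    effects = [PlantedEffect(s, 0.0, beta_interaction) for s in snp_ids]
    if outcome == "short":
        return replace(design, planted_effects=effects)
    return replace(design, planted_effects_long=effects)
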