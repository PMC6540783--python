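"""Variant- and sample-level quality control, ancestry PCA, relatedness screen.

Mirrors a standard exome-chip QC flow: exclusion of non-autosomal and
mitochondrial variants and indels, of intergenic variants with no gene
assignment, and of SNPs failing call-rate, Hardy-Weinberg or minor-allele-
frequency thresholds; sample-level call-rate filtering; principal-component
ancestry scores from standardized dosages; and a pairwise identity-by-state
screen for cryptic relatedness.

Default thresholds: HWE exact p < 1e-4, MAF < 10%, SNP call rate < 90%,
sample call rate < 99%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import AUTOSOMES, MISSING, GenotypeMatrix

NON_AUTOSOMAL = {"X", "Y", "XY", "MT", "M", "MITO", "CHRX", "CHRY", "CHRM", "CHRMT"}

RULE_ORDER = (
    "non_autosomal",
    "indel",
    "intergenic",
    "snp_call_rate",
    "hwe",
    "maf",
)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Two-sided by probability ordering: conditional on the observed allele
    counts, the p-value sums the probabilities of all heterozygote counts
    whose conditional probability does not exceed that of the observed
    count. Probabilities are handled as exact integer weights, so ties are
    resolved exactly. Returns a p-value in (0, 1].
    """
    a, h, b = int(n_hom_major), int(n_het), int(n_hom_minor)
    if min(a, h, b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = a + h + b
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = min(2 * a + h, 2 * b + h)
    if n_minor == 0:
        return 1.0  # monomorphic: no variation to test

    def weight(het: int) -> int:
        hom_minor = (n_minor - het) // 2
        # exact multinomial weight (up to the shared normalizer): the number
        # of genotype assignments with this het count, doubled per het.
        return comb(n, het) * comb(n - het, hom_minor) * 2**het

    support = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    weights = {het: weight(het) for het in support}
    w_obs = weights[h]
    total = sum(weights.values())
    p_num = sum(w for w in weights.values() if w <= w_obs)
    return p_num / total


def compute_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency of one SNP from dosage codes.

    Accepts int codes with -1 for missing, or float with NaN. Returns
    min(f, 1-f) for f = sum(dosage) / (2 * n_called).
    """
    d = np.asarray(dosages, dtype=float)
    d[d == MISSING] = np.nan
    called = ~np.isnan(d)
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    f = float(d[called].sum()) / (2.0 * n_called)
    return min(f, 1.0 - f)


@dataclass
class QCThresholds:
    hwe_alpha: float = 1e-4
    maf_min: float = 0.10
    snp_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.99

    def __post_init__(self) -> None:
        for name in ("hwe_alpha", "maf_min", "snp_call_rate_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts plus the retained variant and sample sets.

    Conservation invariant: sum of per-rule SNP removals + retained SNPs
    equals the input SNP count, and likewise for samples.
    """

    n_snps_in: int
    n_samples_in: int
    removed_snps: dict[str, list[str]] = field(default_factory=dict)
    removed_samples: list[str] = field(default_factory=list)
    retained_snp_ids: list[str] = field(default_factory=list)
    retained_sample_ids: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {rule: len(self.removed_snps.get(rule, [])) for rule in RULE_ORDER}
        out["sample_call_rate"] = len(self.removed_samples)
        out["retained_snps"] = len(self.retained_snp_ids)
        out["retained_samples"] = len(self.retained_sample_ids)
        return out

    def check_conservation(self) -> None:
        removed = sum(len(v) for v in self.removed_snps.values())
        if removed + len(self.retained_snp_ids) != self.n_snps_in:
            raise AssertionError("QC report violates SNP conservation")
        if len(self.removed_samples) + len(self.retained_sample_ids) != self.n_samples_in:
            raise AssertionError("QC report violates sample conservation")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_snps_in": self.n_snps_in,
                "n_samples_in": self.n_samples_in,
                "counts": self.counts,
                "removed_samples": self.removed_samples,
            },
            indent=2,
        )

    def to_frame(self) -> pd.DataFrame:
        counts = self.counts
        return pd.DataFrame({"rule": list(counts), "count": list(counts.values())})


def sample_call_rates(geno: GenotypeMatrix) -> np.ndarray:
    return 1.0 - geno.missing_mask().mean(axis=1)


def snp_call_rates(geno: GenotypeMatrix) -> np.ndarray:
    return 1.0 - geno.missing_mask().mean(axis=0)


def filter_samples(geno: GenotypeMatrix, thresholds: QCThresholds) -> list[str]:
    """Sample ids whose genotype call rate meets the threshold."""
    rates = sample_call_rates(geno)
    keep = [s for s, r in zip(geno.sample_ids, rates) if r >= thresholds.sample_call_rate_min]
    if not keep:
        raise ValueError("sample call-rate filter removed every sample")
    return keep


def filter_variants(
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[QCReport, GenotypeMatrix]:
    """Apply the full QC flow and return the report plus the filtered matrix.

    Sample-level call-rate filtering runs first; SNP rules then apply in
    fixed order (non-autosomal/mito -> indel -> intergenic -> SNP call rate
    -> HWE -> MAF), each SNP attributed to the first rule it triggers, so
    per-rule counts are reproducible. Filtering is idempotent.
    """
    thresholds = thresholds or QCThresholds()
    vmeta = variants.set_index("snp_id")
    missing_meta = [s for s in geno.snp_ids if s not in vmeta.index]
    if missing_meta:
        raise ValueError(f"variant metadata missing for SNPs: {missing_meta[:5]}")

    retained_samples = filter_samples(geno, thresholds)
    removed_samples = [s for s in geno.sample_ids if s not in set(retained_samples)]
    sub = geno.subset(sample_ids=retained_samples) if removed_samples else geno

    removed: dict[str, list[str]] = {rule: [] for rule in RULE_ORDER}
    retained: list[str] = []
    call_rates = snp_call_rates(sub)
    for j, snp in enumerate(sub.snp_ids):
        chrom = str(vmeta.at[snp, "chrom"]).upper().removeprefix("CHR")
        vclass = str(vmeta.at[snp, "variant_class"]).lower()
        gene = vmeta.at[snp, "gene"]
        if chrom in {c.upper() for c in NON_AUTOSOMAL}:
            removed["non_autosomal"].append(snp)
            continue
        if chrom not in AUTOSOMES:
            raise ValueError(f"unknown chromosome label {chrom!r} for SNP {snp!r}")
        if vclass == "indel":
            removed["indel"].append(snp)
            continue
        if vclass == "intergenic" or gene is None or (isinstance(gene, float) and np.isnan(gene)) or gene == "":
            removed["intergenic"].append(snp)
            continue
        if call_rates[j] < thresholds.snp_call_rate_min:
            removed["snp_call_rate"].append(snp)
            continue
        col = sub.dosages[:, j]
        called = col[col != MISSING]
        if called.size == 0:
            removed["snp_call_rate"].append(snp)
            continue
        counts = np.bincount(called, minlength=3)
        n_minor_allele = 2 * counts[2] + counts[1]
        if n_minor_allele > counts.sum():  # coded allele is the major one
            counts = counts[::-1]
        if hwe_exact_test(counts[0], counts[1], counts[2]) < thresholds.hwe_alpha:
            removed["hwe"].append(snp)
            continue
        if compute_maf(col) < thresholds.maf_min:
            removed["maf"].append(snp)
            continue
        retained.append(snp)

    report = QCReport(
        n_snps_in=geno.n_snps,
        n_samples_in=geno.n_samples,
        removed_snps=removed,
        removed_samples=removed_samples,
        retained_snp_ids=retained,
        retained_sample_ids=retained_samples,
    )
    report.check_conservation()
    filtered = sub.subset(snp_ids=retained)
    return report, filtered


def ancestry_pca(
    geno: GenotypeMatrix,
    marker_ids: Sequence[str] | None = None,
    n_components: int = 10,
) -> pd.DataFrame:
    """Principal-component ancestry scores from standardized dosages.

    Missing dosages are mean-imputed per SNP (for PCA only). Each column is
    centered by twice the sample allele frequency and scaled by
    sqrt(2 f (1-f)); scores are left singular vectors times singular
    values. Monomorphic markers are excluded with a warning. Each PC is
    oriented so the sample with the lexicographically smallest id has a
    non-negative score; the result carries the explained-variance ratio in
    ``.attrs["explained_variance_ratio"]``.
    """
    sub = geno if marker_ids is None else geno.subset(snp_ids=list(marker_ids))
    X = sub.dosages.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    f = col_mean / 2.0
    poly = (f > 0) & (f < 1)
    if not poly.all():
        warnings.warn(f"excluded {int((~poly).sum())} monomorphic marker(s) from PCA", stacklevel=2)
    X = X[:, poly]
    f = f[poly]
    inds = np.where(np.isnan(X))
    X[inds] = (2 * f)[inds[1]]
    Z = (X - 2 * f) / np.sqrt(2 * f * (1 - f))
    Z -= Z.mean(axis=0)  # exact column centering after imputation
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, S.size)
    scores = U[:, :k] * S[:k]
    anchor = int(np.argmin(np.array(sub.sample_ids, dtype=object)))
    for j in range(k):
        if scores[anchor, j] < 0:
            scores[:, j] = -scores[:, j]
    out = pd.DataFrame(
        scores, index=pd.Index(sub.sample_ids, name="sample_id"),
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    total_var = float((S**2).sum())
    out.attrs["explained_variance_ratio"] = (S[:k] ** 2 / total_var).tolist()
    return out


def pairwise_ibs(geno: GenotypeMatrix, flag_threshold: float | None = None) -> pd.DataFrame:
    """Mean and SD of identity-by-state sharing for every sample pair.

    Per pair, over SNPs called in both samples: IBS = (2 - |d_i - d_j|) / 2.
    Pairs with no shared called SNP get NaN. When ``flag_threshold`` is
    given, pairs with mean IBS above it are flagged (possible cryptic
    relatedness).
    """
    if geno.n_samples < 2:
        raise ValueError("need >= 2 samples for a relatedness screen")
    D = geno.dosages.astype(float)
    D[D == MISSING] = np.nan
    rows = []
    for i in range(geno.n_samples - 1):
        di = D[i]
        diff = np.abs(D[i + 1:] - di)  # NaN propagates through missing pairs
        ibs = (2.0 - diff) / 2.0
        shared = ~np.isnan(ibs)
        n_shared = shared.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(ibs, axis=1)
            sds = np.nanstd(ibs, axis=1, ddof=0)
        for off, j in enumerate(range(i + 1, geno.n_samples)):
            mean_ij = means[off] if n_shared[off] > 0 else np.nan
            sd_ij = sds[off] if n_shared[off] > 0 else np.nan
            rows.append(
                {
                    "sample_i": geno.sample_ids[i],
                    "sample_j": geno.sample_ids[j],
                    "mean_ibs": mean_ij,
                    "sd_ibs": sd_ij,
                    "n_shared": int(n_shared[off]),
                }
            )
    out = pd.DataFrame(rows)
    if flag_threshold is not None:
        out["flagged"] = out["mean_ibs"] > flag_threshold
    return out
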