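"""Empirical gene-set enrichment by MAF-matched control resampling.

The core statistic: nested percentile "epochs" of ranked case genes
(training set plus the top p% of ranked candidates), the count of nominal
(p < 0.05) SNP associations inside each epoch, and an empirical null built
from R draws of control-gene SNPs matched exactly to the case set's
minor-allele-frequency band profile (bands 10-15%, 15-20%, 20-30%,
30-50%). An epoch is called enriched when its observed count exceeds the
95th percentile of the null counts; the empirical p-value uses the +1
correction, p = (1 + #{null >= observed}) / (1 + R), so it is never zero.

No multiplicity correction is applied across epochs: the nested subsets are
not mutually exclusive, and the matched-resampling null already accounts
for the number of variants tested within an epoch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MAF_BANDS: tuple[tuple[float, float, str], ...] = (
    (0.10, 0.15, "10-15"),
    (0.15, 0.20, "15-20"),
    (0.20, 0.30, "20-30"),
    (0.30, 0.50, "30-50"),
)
BAND_LABELS = tuple(label for _, _, label in MAF_BANDS)


def maf_band(maf: float) -> str:
    """Band label for a post-QC MAF. Half-open on the left, closed at 0.50."""
    if not 0.10 <= maf <= 0.50:
        raise ValueError(f"MAF {maf} outside the post-QC range [0.10, 0.50]")
    for lo, hi, label in MAF_BANDS:
        if lo <= maf < hi:
            return label
    return BAND_LABELS[-1]  # maf == 0.50, closed upper edge


def band_profile(snp_ids: Sequence[str], mafs: Mapping[str, float]) -> dict[str, int]:
    """Counts of SNPs per MAF band (the matching target for control draws)."""
    profile = {label: 0 for label in BAND_LABELS}
    for snp in snp_ids:
        profile[maf_band(mafs[snp])] += 1
    return profile


@dataclass(frozen=True)
class EpochSet:
    """One nested case-gene subset: training genes plus the top p% of ranked genes."""

    percentile: int
    gene_ids: frozenset[str]
    n_case_genes: int

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids


def build_epochs(
    ranked_genes: Sequence[str],
    training_ids: Sequence[str],
    step: int = 5,
) -> list[EpochSet]:
    """Nested epochs at percentiles 0, step, ..., 100 of the ranked case genes.

    The epoch at percentile p holds the training genes plus the top
    ceil(p/100 * N) ranked case genes, so with N = 847 the 10% epoch holds
    exactly 85 case genes. EpochSet(0) is the training set alone, and
    EpochSet(p) is a subset of EpochSet(q) whenever p < q.
    """
    if not ranked_genes:
        raise ValueError("ranked gene list is empty")
    if step <= 0 or 100 % step != 0:
        raise ValueError("step must be a positive divisor of 100")
    training = frozenset(training_ids)
    N = len(ranked_genes)
    epochs = []
    for p in range(0, 101, step):
        k = math.ceil(p / 100 * N)
        epochs.append(
            EpochSet(percentile=p, gene_ids=training | frozenset(ranked_genes[:k]), n_case_genes=k)
        )
    return epochs


def genes_to_snps(gene_ids: frozenset[str] | set[str], variants: pd.DataFrame) -> list[str]:
    """SNP ids whose assigned gene lies in the set, in variant-table order."""
    hit = variants["gene"].isin(gene_ids)
    return variants.loc[hit, "snp_id"].tolist()


def draw_control_set(
    pool_by_band: Mapping[str, np.ndarray],
    profile: Mapping[str, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample, without replacement, exactly the profile's count per MAF band.

    ``pool_by_band`` maps band label to an array of control-SNP ids (or
    integer indices). Raises when any band's pool is smaller than the
    requested count, naming the band and the deficit.
    """
    parts = []
    for label in BAND_LABELS:
        need = int(profile.get(label, 0))
        if need == 0:
            continue
        pool = pool_by_band.get(label, np.array([]))
        if len(pool) < need:
            raise ValueError(
                f"control pool exhausted in MAF band {label}%: need {need}, have {len(pool)} "
                f"(deficit {need - len(pool)})"
            )
        parts.append(rng.choice(pool, size=need, replace=False))
    if not parts:
        return np.array([], dtype=object)
    return np.concatenate(parts)


def count_nominal(
    assoc: pd.DataFrame,
    snp_set: Sequence[str],
    alpha: float = 0.05,
    which: str = "main",
) -> int:
    """Count SNPs in the set with the selected model p-value below alpha.

    Invalid association rows are excluded from the count (and from the
    denominator of any matched comparison).
    """
    if which not in ("main", "interaction"):
        raise ValueError("which must be 'main' or 'interaction'")
    if len(snp_set) == 0:
        warnings.warn("count_nominal called on an empty SNP set", stacklevel=2)
        return 0
    pcol = "p_main" if which == "main" else "p_int"
    sub = assoc[assoc["snp_id"].isin(set(snp_set)) & assoc["valid"]]
    return int((sub[pcol] < alpha).sum())


@dataclass
class EnrichmentResult:
    """Observed vs. resampled-null association counts for one epoch."""

    epoch: int
    family: str  # "main" or "interaction"
    outcome: str
    observed: int
    null_counts: np.ndarray
    q95: float
    empirical_p: float
    enriched: bool
    R: int
    seed: int
    n_case_snps: int

    def to_row(self) -> dict:
        return {
            "epoch": self.epoch,
            "family": self.family,
            "outcome": self.outcome,
            "n_case_snps": self.n_case_snps,
            "observed": self.observed,
            "q95": self.q95,
            "empirical_p": self.empirical_p,
            "enriched": self.enriched,
            "R": self.R,
            "seed": self.seed,
        }


def _valid_with_maf(
    assoc: pd.DataFrame, snp_ids: Sequence[str], mafs: Mapping[str, float]
) -> list[str]:
    valid = set(assoc.loc[assoc["valid"], "snp_id"])
    return [s for s in snp_ids if s in valid and s in mafs]


def enrichment_test(
    case_snps: Sequence[str],
    control_pool: Sequence[str],
    assoc: pd.DataFrame,
    mafs: Mapping[str, float],
    alpha: float = 0.05,
    R: int = 10_000,
    seed: int = 0,
    which: str = "main",
    outcome: str = "",
    epoch: int = -1,
) -> EnrichmentResult:
    """Empirical enrichment call for one case SNP set.

    observed = nominal-association count among the (valid) case SNPs;
    null_j = the same count in R control draws matched exactly to the case
    set's MAF-band profile; q95 = 95th percentile of the null counts
    (linear/type-7 interpolation); empirical p = (1 + #{null >= observed})
    / (1 + R); enriched iff observed > q95. Fully reproducible from seed.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    case_valid = _valid_with_maf(assoc, case_snps, mafs)
    pool_valid = _valid_with_maf(assoc, control_pool, mafs)
    profile = band_profile(case_valid, mafs)

    pcol = "p_main" if which == "main" else "p_int"
    sig = dict(zip(assoc["snp_id"], (assoc[pcol] < alpha) & assoc["valid"]))
    observed = count_nominal(assoc, case_valid, alpha=alpha, which=which) if case_valid else 0

    # index the pool per band once; draws then work on integer positions
    pool_bands: dict[str, list[str]] = {label: [] for label in BAND_LABELS}
    for snp in pool_valid:
        pool_bands[maf_band(mafs[snp])].append(snp)
    pool_by_band = {k: np.array(v, dtype=object) for k, v in pool_bands.items()}
    sig_by_band = {
        k: np.array([sig[s] for s in v], dtype=bool) for k, v in pool_bands.items()
    }

    null_counts = np.empty(R, dtype=np.int64)
    for j in range(R):
        total = 0
        for label in BAND_LABELS:
            need = profile[label]
            if need == 0:
                continue
            pool = pool_by_band[label]
            if len(pool) < need:
                raise ValueError(
                    f"control pool exhausted in MAF band {label}%: need {need}, "
                    f"have {len(pool)} (deficit {need - len(pool)})"
                )
            idx = rng.choice(len(pool), size=need, replace=False)
            total += int(sig_by_band[label][idx].sum())
            # matching exactness holds by construction: `need` SNPs from band `label`
        null_counts[j] = total

    q95 = float(np.percentile(null_counts, 95))  # type-7 / linear interpolation
    empirical_p = (1 + int((null_counts >= observed).sum())) / (1 + R)
    return EnrichmentResult(
        epoch=epoch,
        family=which,
        outcome=outcome,
        observed=observed,
        null_counts=null_counts,
        q95=q95,
        empirical_p=empirical_p,
        enriched=observed > q95,
        R=R,
        seed=seed,
        n_case_snps=len(case_valid),
    )


def run_enrichment_curve(
    epochs: Sequence[EpochSet],
    assoc_tables: Mapping[str, pd.DataFrame],
    variants: pd.DataFrame,
    control_genes: Sequence[str],
    mafs: Mapping[str, float],
    alpha: float = 0.05,
    R: int = 10_000,
    seed: int = 0,
    families: Sequence[str] = ("main", "interaction"),
) -> list[EnrichmentResult]:
    """Enrichment calls for every epoch x family x outcome cell.

    ``assoc_tables`` maps outcome name to its association table. Per-cell
    seeds are derived deterministically from the master seed with
    ``numpy.random.SeedSequence`` spawn keys, so any cell can be re-run in
    isolation. No correction across epochs (nested subsets).
    """
    control_pool = genes_to_snps(set(control_genes), variants)
    results = []
    cell = 0
    for outcome, assoc in assoc_tables.items():
        for family in families:
            for ep in epochs:
                case_snps = genes_to_snps(ep.gene_ids, variants)
                cell_seed = int(
                    np.random.SeedSequence(seed, spawn_key=(cell,)).generate_state(1)[0] % (2**31)
                )
                results.append(
                    enrichment_test(
                        case_snps,
                        control_pool,
                        assoc,
                        mafs,
                        alpha=alpha,
                        R=R,
                        seed=cell_seed,
                        which=family,
                        outcome=outcome,
                        epoch=ep.percentile,
                    )
                )
                cell += 1
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def plot_enrichment_curve(
    results: Sequence[EnrichmentResult],
    family: str,
    outcome: str,
    ax=None,
):
    """Box plots of null counts per epoch with the observed count as a dot."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(8, 4))
    sel = [r for r in results if r.family == family and r.outcome == outcome]
    sel.sort(key=lambda r: r.epoch)
    if not sel:
        raise ValueError(f"no results for family={family!r}, outcome={outcome!r}")
    ax.boxplot([r.null_counts for r in sel], positions=range(len(sel)), widths=0.6)
    ax.plot(
        range(len(sel)), [r.observed for r in sel], "o", color="crimson",
        label="observed (case genes)", zorder=3,
    )
    ax.set_xticks(range(len(sel)))
    ax.set_xticklabels([f"{r.epoch}" for r in sel])
    ax.set_xlabel("case-gene percentile epoch")
    ax.set_ylabel(f"nominal associations (p < 0.05), {family}")
    ax.set_title(f"{outcome}: case counts vs. matched control null")
    ax.legend(loc="upper left")
    return ax
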