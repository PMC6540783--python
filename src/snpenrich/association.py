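"""Per-SNP additive linear-model association scans.

Outcome preprocessing (change-score outlier exclusion and Winsorization of
extreme T scores), additive minor-allele coding, data-driven covariate
trimming, and ordinary-least-squares fits of

    outcome ~ snp + group + covariates            (main-effect model)
    outcome ~ snp + group + covariates + snp:group (interaction model)

with two-sided t-test p-values on the SNP and interaction coefficients.
The injury-group indicator is coded OI = 0, TBI = 1. Missing genotypes are
dropped listwise per SNP; degenerate fits (monomorphic in-sample, rank
deficiency, too few samples) yield rows flagged invalid that downstream
enrichment counting excludes from its denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as student_t

from .cohort import GenotypeMatrix

OUTCOME_COLUMNS = {"short_term": "cbcl_short", "long_term": "cbcl_long"}
WINSOR_CAP = 90.0  # 4 normative SDs above the CBCL mean of 50


@dataclass
class ModelSpec:
    outcome: str = "short_term"
    covariate_candidates: tuple[str, ...] = ("cbcl_preinjury", "ses_z")
    include_interaction: bool = True
    trim_alpha: float = 0.05
    use_pc1: bool = True  # ancestry PC1 is never trimmed

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
        if not 0.0 < self.trim_alpha < 1.0:
            raise ValueError("trim_alpha must lie in (0, 1)")


def preprocess_outcome(
    phenos: pd.DataFrame,
    timepoints: tuple[str, str] = ("cbcl_short", "cbcl_long"),
) -> tuple[pd.DataFrame, list[str]]:
    """Outlier exclusion and Winsorization of outcome T scores.

    Samples whose short-to-long change score deviates from the mean change
    by more than three SDs of change are flagged ``excluded_outlier`` (the
    rule is skipped, with a log entry, when fewer than three samples have
    both timepoints or the change SD is zero). Outcome scores above T = 90
    are Winsorized to 90. Returns the cleaned copy and a log of actions.
    """
    short_col, long_col = timepoints
    out = phenos.copy()
    log: list[str] = []
    out["excluded_outlier"] = False

    both = out[short_col].notna() & out[long_col].notna()
    n_both = int(both.sum())
    if n_both < 3:
        log.append(f"change-score rule skipped: only {n_both} samples with both timepoints")
        warnings.warn("too few change scores; outlier rule skipped", stacklevel=2)
    else:
        change = (out.loc[both, long_col] - out.loc[both, short_col]).astype(float)
        sd = float(change.std(ddof=1))
        if sd == 0.0:
            log.append("change-score rule: SD of change is 0; no exclusions")
        else:
            dev = (change - change.mean()).abs()
            outliers = change.index[dev > 3.0 * sd]
            out.loc[outliers, "excluded_outlier"] = True
            for idx in outliers:
                log.append(
                    f"excluded sample {out.at[idx, 'sample_id']}: "
                    f"|change - mean| = {dev[idx]:.2f} > 3 x SD(change) = {3 * sd:.2f}"
                )
    missing_either = out.index[~both]
    for idx in missing_either:
        log.append(f"sample {out.at[idx, 'sample_id']}: change rule skipped (missing timepoint)")

    for col in timepoints:
        high = out.index[out[col] > WINSOR_CAP]
        for idx in high:
            log.append(f"Winsorized {col} for sample {out.at[idx, 'sample_id']}: {out.at[idx, col]:.1f} -> 90")
        out.loc[high, col] = WINSOR_CAP
    return out, log


def encode_additive(
    dosages: np.ndarray,
    alleles: tuple[str, str] = ("A", "G"),
) -> tuple[np.ndarray, str]:
    """Orient dosage codes so the minor allele counts up (0/1/2).

    ``dosages`` count copies of ``alleles[1]`` (the coded/alternate allele);
    missing entries are NaN or -1. If the coded allele's sample frequency
    exceeds 0.5 the coding is flipped (g -> 2 - g). At frequency exactly
    0.5 the minor allele is defined as the lexicographically smaller allele
    label. Returns the oriented codes (float, NaN for missing) and the
    counted minor allele. Monomorphic SNPs come back all zero; the model
    fit flags them invalid.
    """
    d = np.asarray(dosages, dtype=float).copy()
    d[d == -1] = np.nan
    called = ~np.isnan(d)
    if not called.any():
        raise ValueError("all genotypes missing; cannot orient coding")
    ref, alt = alleles
    f_alt = float(d[called].sum()) / (2.0 * called.sum())
    if f_alt > 0.5:
        flip = True
    elif f_alt < 0.5:
        flip = False
    else:
        flip = min(ref, alt) != alt  # tie: count the lexicographically smaller allele
    if flip:
        d = 2.0 - d
        return d, ref
    return d, alt


def _ols(X: np.ndarray, y: np.ndarray) -> dict | None:
    """OLS with t-test p-values; None when the design is rank deficient."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        return None
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        return None
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * student_t.sf(np.abs(tstat), df)
    return {"beta": beta, "se": se, "p": pvals, "df": df}


def trim_covariates(
    y: np.ndarray,
    group: np.ndarray,
    candidates: dict[str, np.ndarray],
    pc1: np.ndarray | None = None,
    trim_alpha: float = 0.05,
) -> list[str]:
    """Backward-trim non-significant covariates from the no-SNP base model.

    Fits ``y ~ group (+ PC1) + candidates`` and iteratively drops the least
    significant trimmable covariate with p >= ``trim_alpha``, refitting
    until every retained candidate is significant. Group and PC1 are never
    trimmed. Collinear candidates are dropped later-listed-first with a
    warning. Returns the retained candidate names (in input order).
    """
    names = list(candidates)
    mask = np.isfinite(y) & np.isfinite(group)
    for arr in candidates.values():
        mask &= np.isfinite(arr)
    if pc1 is not None:
        mask &= np.isfinite(pc1)

    def design(active: list[str]) -> np.ndarray:
        cols = [np.ones(mask.sum()), group[mask].astype(float)]
        if pc1 is not None:
            cols.append(pc1[mask])
        cols.extend(candidates[name][mask] for name in active)
        return np.column_stack(cols)

    active = list(names)
    # resolve collinearity first: drop later-listed offenders
    while active and np.linalg.matrix_rank(design(active)) < design(active).shape[1]:
        dropped = active.pop()
        warnings.warn(f"dropped collinear covariate {dropped!r}", stacklevel=2)

    n_fixed = 2 + (1 if pc1 is not None else 0)
    while active:
        fit = sm.OLS(y[mask], design(active)).fit()
        cand_p = fit.pvalues[n_fixed:]
        worst = int(np.argmax(cand_p))
        if cand_p[worst] >= trim_alpha:
            active.pop(worst)
        else:
            break
    return active


def fit_snp_model(
    y: np.ndarray,
    snp: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    include_interaction: bool = True,
) -> dict:
    """One per-SNP association row: main-effect and (optionally) interaction model.

    Listwise-deletes samples with missing genotype, outcome or covariates;
    requires at least (parameters + 5) complete samples. Returns a dict with
    n_used, beta/se/p for the SNP main effect and, when requested, for the
    SNP x group interaction, plus a validity flag. Invalid rows (monomorphic
    in-sample or rank-deficient design) carry no p-values.
    """
    y = np.asarray(y, dtype=float)
    snp = np.asarray(snp, dtype=float)
    group = np.asarray(group, dtype=float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != y.size:
        cov = cov.T

    mask = np.isfinite(y) & np.isfinite(snp) & np.isfinite(group)
    if cov is not None:
        mask &= np.isfinite(cov).all(axis=1)
    n = int(mask.sum())
    invalid = {
        "n_used": n, "beta_main": np.nan, "se_main": np.nan, "p_main": np.nan,
        "beta_int": np.nan, "se_int": np.nan, "p_int": np.nan, "valid": False,
    }
    base_cols = [np.ones(n), snp[mask], group[mask]]
    if cov is not None:
        base_cols.append(cov[mask])
    n_params = 3 + (cov.shape[1] if cov is not None else 0) + (1 if include_interaction else 0)
    if n < n_params + 5:
        return invalid
    if np.ptp(snp[mask]) == 0:
        return invalid

    X_main = np.column_stack(base_cols)
    fit_main = _ols(X_main, y[mask])
    if fit_main is None:
        return invalid
    row = {
        "n_used": n,
        "beta_main": float(fit_main["beta"][1]),
        "se_main": float(fit_main["se"][1]),
        "p_main": float(fit_main["p"][1]),
        "beta_int": np.nan, "se_int": np.nan, "p_int": np.nan,
        "valid": True,
    }
    if include_interaction:
        X_int = np.column_stack(base_cols + [snp[mask] * group[mask]])
        fit_int = _ols(X_int, y[mask])
        if fit_int is None:
            return invalid
        row["beta_int"] = float(fit_int["beta"][-1])
        row["se_int"] = float(fit_int["se"][-1])
        row["p_int"] = float(fit_int["p"][-1])
    return row


def _batch_scan(
    y: np.ndarray,
    S: np.ndarray,
    group: np.ndarray,
    cov: np.ndarray | None,
    include_interaction: bool,
) -> pd.DataFrame:
    """Vectorized OLS over a block of complete (no-missing) SNP columns.

    Uses Frisch-Waugh residualization: with the fixed design C = [1, group,
    covariates], the SNP (and interaction) coefficients of the full model
    equal those from regressing C-residualized y on C-residualized SNP
    columns, which vectorizes across SNPs as matrix products. Exactly
    equivalent to the per-SNP fit; cross-checked in the test suite.
    """
    n, m = S.shape
    cols = [np.ones(n), group]
    if cov is not None:
        cols.append(cov)
    C = np.column_stack(cols)
    pC = C.shape[1]
    n_params = pC + (2 if include_interaction else 1)
    if n < n_params + 5:
        return pd.DataFrame(
            {
                "n_used": n, "beta_main": np.nan, "se_main": np.nan, "p_main": np.nan,
                "beta_int": np.nan, "se_int": np.nan, "p_int": np.nan,
                "valid": np.zeros(m, dtype=bool),
            }
        )
    Q, _ = np.linalg.qr(C)

    def resid(M: np.ndarray) -> np.ndarray:
        return M - Q @ (Q.T @ M)

    y_r = resid(y[:, None])[:, 0]
    S_r = resid(S)
    ss = np.einsum("ij,ij->j", S_r, S_r)
    sy = S_r.T @ y_r
    yy = float(y_r @ y_r)
    mono = np.ptp(S, axis=0) == 0
    degenerate = mono | (ss <= 1e-9 * n)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sy / ss
        df_main = n - (pC + 1)
        rss = yy - beta * sy
        sigma2 = rss / df_main
        se = np.sqrt(sigma2 / ss)
        tstat = beta / se
        p_main = 2.0 * student_t.sf(np.abs(tstat), df_main)

    out = pd.DataFrame(
        {
            "n_used": n,
            "beta_main": beta,
            "se_main": se,
            "p_main": p_main,
            "beta_int": np.nan,
            "se_int": np.nan,
            "p_int": np.nan,
            "valid": ~degenerate,
        }
    )
    if include_interaction:
        SG_r = resid(S * group[:, None])
        a11 = ss
        a22 = np.einsum("ij,ij->j", SG_r, SG_r)
        a12 = np.einsum("ij,ij->j", S_r, SG_r)
        b1 = sy
        b2 = SG_r.T @ y_r
        det = a11 * a22 - a12**2
        bad = degenerate | (det <= 1e-9 * n)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta1 = (a22 * b1 - a12 * b2) / det
            beta2 = (a11 * b2 - a12 * b1) / det
            df_int = n - (pC + 2)
            rss_i = yy - beta1 * b1 - beta2 * b2
            sigma2_i = rss_i / df_int
            se2 = np.sqrt(sigma2_i * a11 / det)
            p_int = 2.0 * student_t.sf(np.abs(beta2 / se2), df_int)
        out["beta_int"] = beta2
        out["se_int"] = se2
        out["p_int"] = p_int
        out["valid"] = ~bad
    invalid = ~out["valid"].to_numpy()
    out.loc[invalid, ["beta_main", "se_main", "p_main", "beta_int", "se_int", "p_int"]] = np.nan
    return out


def run_scan(
    geno: GenotypeMatrix,
    phenos: pd.DataFrame,
    spec: ModelSpec,
    snp_ids: list[str] | None = None,
    pcs: pd.DataFrame | None = None,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Association scan over SNPs: preprocess once, trim once, fit every SNP.

    SNP columns with no missing calls are fitted in one vectorized pass;
    columns with missing genotypes fall back to the per-SNP fit with
    listwise deletion (identical estimates). ``pcs`` supplies ancestry
    principal components (PC1 enters the model, untrimmed, when
    ``spec.use_pc1``); ``variants`` adds gene and MAF columns to the
    output. Deterministic: no randomness anywhere.
    """
    snp_ids = list(snp_ids) if snp_ids is not None else list(geno.snp_ids)
    cleaned, _log = preprocess_outcome(phenos)
    cleaned = cleaned[~cleaned["excluded_outlier"]]
    analysis_samples = [s for s in geno.sample_ids if s in set(cleaned["sample_id"])]
    sub = geno.subset(sample_ids=analysis_samples)
    cleaned = cleaned.set_index("sample_id").loc[analysis_samples]

    y = cleaned[OUTCOME_COLUMNS[spec.outcome]].to_numpy(dtype=float)
    group = (cleaned["group"] == "TBI").to_numpy(dtype=float)
    pc1 = None
    if spec.use_pc1 and pcs is not None:
        pc1 = pcs["PC1"].reindex(analysis_samples).to_numpy(dtype=float)

    candidates = {
        name: cleaned[name].to_numpy(dtype=float)
        for name in spec.covariate_candidates
        if name in cleaned.columns
    }
    retained = trim_covariates(y, group, candidates, pc1=pc1, trim_alpha=spec.trim_alpha)
    cov_cols = [candidates[name] for name in retained]
    if pc1 is not None:
        cov_cols.append(pc1)
    cov = np.column_stack(cov_cols) if cov_cols else None

    dosage_block = sub.dosages.astype(float)
    dosage_block[dosage_block == -1] = np.nan
    index = {s: j for j, s in enumerate(sub.snp_ids)}

    # rows where phenotype/covariates are complete are shared by all SNPs
    base_mask = np.isfinite(y) & np.isfinite(group)
    if cov is not None:
        base_mask &= np.isfinite(cov).all(axis=1)
    cols = np.array([index[s] for s in snp_ids])
    block = dosage_block[np.ix_(base_mask, cols)]
    has_missing = np.isnan(block).any(axis=0)

    parts: dict[int, pd.Series | dict] = {}
    if (~has_missing).any():
        complete = _batch_scan(
            y[base_mask],
            block[:, ~has_missing],
            group[base_mask],
            cov[base_mask] if cov is not None else None,
            spec.include_interaction,
        )
        for out_row, j in zip(complete.to_dict(orient="records"), np.nonzero(~has_missing)[0]):
            parts[j] = out_row
    for j in np.nonzero(has_missing)[0]:
        parts[j] = fit_snp_model(
            y, dosage_block[:, cols[j]], group, cov, include_interaction=spec.include_interaction
        )
    rows = []
    for j, snp in enumerate(snp_ids):
        row = dict(parts[j])
        row["snp_id"] = snp
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["retained_covariates"] = retained
    table.attrs["outcome"] = spec.outcome
    if variants is not None:
        meta = variants.set_index("snp_id")
        table["gene"] = table["snp_id"].map(meta["gene"])
        if "design_maf" in meta.columns:
            table["maf"] = table["snp_id"].map(meta["design_maf"])
    cols = ["snp_id"] + [c for c in table.columns if c != "snp_id"]
    return table[cols]
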