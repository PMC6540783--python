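"""Association tests: preprocessing rules, additive coding, covariate
trimming, OLS oracle equivalence, and scan calibration."""

import numpy as np
import pandas as pd
import pytest

from oracles import ols_statsmodels_oracle
from snpenrich.association import (
    ModelSpec,
    encode_additive,
    fit_snp_model,
    preprocess_outcome,
    run_scan,
    trim_covariates,
)
from snpenrich.cohort import (
    CohortDesign,
    PlantedEffect,
    VariantSpec,
    generate_cohort,
    generate_genotypes,
    generate_phenotypes,
)


def _phenos(short, long=None, pre=None):
    n = len(short)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "group": ["TBI" if i % 2 else "OI" for i in range(n)],
            "cbcl_preinjury": pre if pre is not None else [50.0] * n,
            "cbcl_short": short,
            "cbcl_long": long if long is not None else short,
            "ses_z": [0.0] * n,
        }
    )


class TestPreprocessOutcome:
    def test_winsorizes_above_ninety(self):
        cleaned, log = preprocess_outcome(_phenos([50.0, 60.0, 91.0]))
        assert cleaned["cbcl_short"].tolist() == [50.0, 60.0, 90.0]
        assert any("Winsorized" in entry for entry in log)

    def test_exactly_ninety_untouched(self):
        cleaned, _ = preprocess_outcome(_phenos([90.0, 50.0, 60.0]))
        assert cleaned["cbcl_short"].tolist() == [90.0, 50.0, 60.0]

    def test_zero_change_sd_no_exclusions(self):
        short = [50.0] * 8
        long = [55.0] * 8  # every change identical
        cleaned, _ = preprocess_outcome(_phenos(short, long))
        assert not cleaned["excluded_outlier"].any()

    def test_five_sd_change_outlier_excluded(self):
        rng = np.random.default_rng(0)
        short = 50 + rng.normal(0, 5, 40)
        change = rng.normal(2, 1, 40)
        change[7] = 2 + 8 * change.std()  # extreme change for one sample
        cleaned, log = preprocess_outcome(_phenos(short, short + change))
        assert cleaned["excluded_outlier"].sum() == 1
        assert cleaned.loc[7, "excluded_outlier"]

    def test_too_few_change_scores_skips_rule(self):
        phenos = _phenos([50.0, 60.0], [np.nan, 65.0])
        with pytest.warns(UserWarning, match="outlier rule skipped"):
            cleaned, log = preprocess_outcome(phenos)
        assert not cleaned["excluded_outlier"].any()


class TestEncodeAdditive:
    def test_minor_allele_counts_up(self):
        # AA, AG, GG, GG with A minor (f_G = 5/8): flip so A counts up
        coded, minor = encode_additive(np.array([0, 1, 2, 2]), ("A", "G"))
        assert minor == "A"
        assert coded.tolist() == [2.0, 1.0, 0.0, 0.0]

    def test_already_minor_unchanged(self):
        coded, minor = encode_additive(np.array([0, 0, 1, 2]), ("A", "G"))
        assert minor == "G"
        assert coded.tolist() == [0.0, 0.0, 1.0, 2.0]

    def test_allele_flip_symmetry(self):
        d = np.array([0, 1, 2, 1, 0])
        coded_alt, _ = encode_additive(d, ("A", "G"))
        coded_ref, _ = encode_additive(2 - d, ("G", "A"))
        assert np.allclose(coded_alt, coded_ref)

    def test_tie_at_half_uses_allele_order(self):
        coded, minor = encode_additive(np.array([0, 2]), ("C", "T"))
        # f = 0.5: the lexicographically smaller allele (C) is counted
        assert minor == "C"
        assert coded.tolist() == [2.0, 0.0]

    def test_missing_stays_missing(self):
        coded, _ = encode_additive(np.array([0.0, np.nan, 2.0, 2.0]), ("A", "G"))
        assert np.isnan(coded[1])


class TestTrimCovariates:
    def test_null_covariate_trimmed_most_of_the_time(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            n = 500
            g = (rng.random(n) < 0.5).astype(float)
            noise_cov = rng.normal(size=n)
            y = 50 + 5 * g + rng.normal(0, 10, n)
            kept = trim_covariates(y, g, {"noise": noise_cov})
            hits += "noise" not in kept
        assert hits >= 90

    def test_strong_covariate_retained(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            n = 500
            g = (rng.random(n) < 0.5).astype(float)
            x = rng.normal(size=n)
            y = 50 + 5 * g + 10.0 * x + rng.normal(0, 10, n)  # 1-SD effect
            kept = trim_covariates(y, g, {"x": x})
            hits += "x" in kept
        assert hits >= 90

    def test_no_candidates_returns_empty(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        g = (rng.random(50) < 0.5).astype(float)
        assert trim_covariates(y, g, {}) == []

    def test_collinear_candidate_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        n = 100
        g = (rng.random(n) < 0.5).astype(float)
        x = rng.normal(size=n)
        y = 50 + 8 * x + rng.normal(0, 1, n)
        with pytest.warns(UserWarning, match="collinear"):
            kept = trim_covariates(y, g, {"x": x, "x_copy": x.copy()})
        assert kept == ["x"]


class TestFitSnpModel:
    def test_small_fixture_matches_ols_oracle(self):
        # printed n=8 fixture
        y = np.array([44.0, 61.0, 52.0, 47.0, 55.0, 49.0, 63.0, 51.0])
        snp = np.array([0.0, 2.0, 1.0, 0.0, 1.0, 0.0, 2.0, 1.0])
        group = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        row = fit_snp_model(y, snp, group, include_interaction=False)
        X = np.column_stack([np.ones(8), snp, group])
        params, bse, pvals = ols_statsmodels_oracle(X, y)
        assert row["beta_main"] == pytest.approx(params[1], abs=1e-10)
        assert row["se_main"] == pytest.approx(bse[1], abs=1e-10)
        assert row["p_main"] == pytest.approx(pvals[1], abs=1e-10)

    def test_interaction_matches_oracle(self):
        rng = np.random.default_rng(11)
        n = 60
        snp = rng.binomial(2, 0.4, n).astype(float)
        group = (rng.random(n) < 0.5).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 50 + snp + 2 * group + 1.5 * snp * group + rng.normal(0, 5, n)
        row = fit_snp_model(y, snp, group, cov, include_interaction=True)
        X = np.column_stack([np.ones(n), snp, group, cov, snp * group])
        params, bse, pvals = ols_statsmodels_oracle(X, y)
        assert row["beta_int"] == pytest.approx(params[-1], abs=1e-10)
        assert row["se_int"] == pytest.approx(bse[-1], abs=1e-10)
        assert row["p_int"] == pytest.approx(pvals[-1], abs=1e-10)

    def test_constant_snp_invalid(self):
        y = np.arange(20.0)
        g = np.tile([0.0, 1.0], 10)
        row = fit_snp_model(y, np.ones(20), g)
        assert not row["valid"]
        assert np.isnan(row["p_main"])

    def test_allele_flip_negates_beta_keeps_p(self):
        rng = np.random.default_rng(5)
        n = 80
        snp = rng.binomial(2, 0.3, n).astype(float)
        g = (rng.random(n) < 0.5).astype(float)
        y = 50 + 2 * snp + rng.normal(0, 8, n)
        a = fit_snp_model(y, snp, g, include_interaction=False)
        b = fit_snp_model(y, 2 - snp, g, include_interaction=False)
        assert a["beta_main"] == pytest.approx(-b["beta_main"])
        assert a["p_main"] == pytest.approx(b["p_main"])

    def test_listwise_deletion_on_missing_genotype(self):
        rng = np.random.default_rng(6)
        n = 50
        snp = rng.binomial(2, 0.4, n).astype(float)
        snp[:5] = np.nan
        g = (rng.random(n) < 0.5).astype(float)
        y = 50 + rng.normal(0, 5, n)
        row = fit_snp_model(y, snp, g, include_interaction=False)
        assert row["n_used"] == 45
        ref = fit_snp_model(y[5:], snp[5:], g[5:], include_interaction=False)
        assert row["beta_main"] == pytest.approx(ref["beta_main"])

    def test_random_instances_match_oracle(self):
        """100 random small designs agree with statsmodels to 1e-8."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(25, 60))
            snp = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
            if np.ptp(snp) == 0:
                continue
            g = (rng.random(n) < 0.5).astype(float)
            k = int(rng.integers(0, 3))
            cov = rng.normal(size=(n, k)) if k else None
            y = rng.normal(50, 10, n)
            row = fit_snp_model(y, snp, g, cov, include_interaction=True)
            if not row["valid"]:
                continue
            base = [np.ones(n), snp, g] + ([cov] if k else [])
            params_m, bse_m, pvals_m = ols_statsmodels_oracle(np.column_stack(base), y)
            assert row["beta_main"] == pytest.approx(params_m[1], abs=1e-8)
            assert row["se_main"] == pytest.approx(bse_m[1], abs=1e-8)
            assert row["p_main"] == pytest.approx(pvals_m[1], abs=1e-8)
            params_i, bse_i, pvals_i = ols_statsmodels_oracle(
                np.column_stack(base + [snp * g]), y
            )
            assert row["beta_int"] == pytest.approx(params_i[-1], abs=1e-8)
            assert row["se_int"] == pytest.approx(bse_i[-1], abs=1e-8)
            assert row["p_int"] == pytest.approx(pvals_i[-1], abs=1e-8)


@pytest.fixture(scope="module")
def null_scan():
    specs = [VariantSpec(f"s{i}", 0.3, f"G{i}", "1") for i in range(2000)]
    design = CohortDesign(n_samples=200, variant_specs=specs, missing_rate=0.0, seed=77)
    cohort_geno, variants = generate_genotypes(design)
    phenos = generate_phenotypes(cohort_geno, design)
    return run_scan(
        cohort_geno, phenos, ModelSpec(outcome="short_term", use_pc1=False), variants=variants
    )


class TestRunScan:
    def test_null_type_one_error_near_nominal(self, null_scan):
        rate_main = (null_scan["p_main"] < 0.05).mean()
        rate_int = (null_scan["p_int"] < 0.05).mean()
        assert 0.03 <= rate_main <= 0.07
        assert 0.03 <= rate_int <= 0.07

    def test_scan_deterministic(self, null_scan):
        specs = [VariantSpec(f"s{i}", 0.3, f"G{i}", "1") for i in range(2000)]
        design = CohortDesign(n_samples=200, variant_specs=specs, missing_rate=0.0, seed=77)
        geno, variants = generate_genotypes(design)
        phenos = generate_phenotypes(geno, design)
        again = run_scan(geno, phenos, ModelSpec(outcome="short_term", use_pc1=False),
                         variants=variants)
        pd.testing.assert_frame_equal(null_scan, again)

    def test_batch_and_listwise_paths_agree(self):
        specs = [VariantSpec(f"s{i}", 0.3, f"G{i}", "1") for i in range(50)]
        design = CohortDesign(n_samples=150, variant_specs=specs, missing_rate=0.05, seed=13)
        geno, variants = generate_genotypes(design)
        phenos = generate_phenotypes(geno, design)
        table = run_scan(geno, phenos, ModelSpec(use_pc1=False), variants=variants).set_index("snp_id")
        cleaned, _ = preprocess_outcome(phenos)
        y = cleaned["cbcl_short"].to_numpy()
        g = (cleaned["group"] == "TBI").to_numpy(float)
        cov = np.column_stack([cleaned["cbcl_preinjury"], cleaned["ses_z"]])
        kept = trim_covariates(y, g, {"pre": cov[:, 0], "ses": cov[:, 1]})
        cov = cov[:, [i for i, name in enumerate(["pre", "ses"]) if name in kept]]
        for snp in ["s0", "s7", "s33"]:
            col = geno.column(snp)
            ref = fit_snp_model(y, col, g, cov if cov.size else None, True)
            assert table.loc[snp, "p_main"] == pytest.approx(ref["p_main"], abs=1e-10)
            assert table.loc[snp, "p_int"] == pytest.approx(ref["p_int"], abs=1e-10)

    def test_group_label_swap_keeps_interaction_p(self):
        specs = [VariantSpec(f"s{i}", 0.3, f"G{i}", "1") for i in range(30)]
        design = CohortDesign(n_samples=120, variant_specs=specs, missing_rate=0.0, seed=15)
        geno, variants = generate_genotypes(design)
        phenos = generate_phenotypes(geno, design)
        spec = ModelSpec(use_pc1=False)
        a = run_scan(geno, phenos, spec, variants=variants)
        swapped = phenos.copy()
        swapped["group"] = np.where(swapped["group"] == "TBI", "OI", "TBI")
        b = run_scan(geno, swapped, spec, variants=variants)
        np.testing.assert_allclose(a["p_int"], b["p_int"], atol=1e-9)

    def test_planted_interaction_detected_above_null(self):
        detections_planted = 0
        detections_null = 0
        reps = 60
        for rep in range(reps):
            specs = [VariantSpec("hit", 0.3, "G", "1"), VariantSpec("bg", 0.3, "G2", "1")]
            design = CohortDesign(
                n_samples=140, variant_specs=specs, missing_rate=0.0, seed=3000 + rep,
                planted_effects=[PlantedEffect("hit", 0.0, 7.0)],
            )
            geno, variants = generate_genotypes(design)
            phenos = generate_phenotypes(geno, design)
            table = run_scan(geno, phenos, ModelSpec(use_pc1=False), variants=variants)
            table = table.set_index("snp_id")
            detections_planted += table.loc["hit", "p_int"] < 0.05
            detections_null += table.loc["bg", "p_int"] < 0.05
        assert detections_planted > detections_null
        assert detections_planted / reps > 0.3
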