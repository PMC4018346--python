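import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snplasso import synthetic_cohort as sc
from snplasso import single_snp_association as ssa
from snplasso.types import CohortTable, GenotypeMatrix, ValidationError


def uniform_covariate_cohort(n_cases, n_controls):
    """Cohort whose covariates carry no information (constant levels)."""
    rows = []
    for i in range(n_cases):
        rows.append(dict(sample_id=f"ca{i}", status="case", subphenotype="lowNMIT",
                         p53_class="low", age_group="<55", gender="male",
                         region="barcelona", smoking="never"))
    for i in range(n_controls):
        rows.append(dict(sample_id=f"co{i}", status="control",
                         subphenotype="control", p53_class="unknown",
                         age_group="<55", gender="male", region="barcelona",
                         smoking="never"))
    return CohortTable(pd.DataFrame(rows))


def null_cohort(seed, n=150, n_snps=1):
    cfg = sc.default_sim_config(n_cases=n, n_controls=n, n_snps=n_snps, seed=seed)
    return sc.simulate_cohort(cfg)


class TestFitSnpLogistic:
    def test_dominant_2x2_cross_product_oracle(self):
        # carrier counts: 58/968 in cases, 90/998 in controls
        g = np.concatenate([
            np.repeat([1.0, 2.0, 0.0], [56, 2, 968]),   # cases
            np.repeat([1.0, 0.0], [90, 998]),            # controls
        ])
        cohort = uniform_covariate_cohort(1026, 1088)
        r = ssa.fit_snp_logistic(g, cohort, "dominant", "snpX")
        oracle_or = (58 * 998) / (90 * 968)
        assert r.or_point == pytest.approx(oracle_or, rel=1e-6)
        assert r.ci95[0] <= r.or_point <= r.ci95[1]

    def test_constant_genotype_flagged(self, small_cohort):
        _, cohort = small_cohort
        g = np.zeros(len(cohort))
        r = ssa.fit_snp_logistic(g, cohort, "additive")
        assert "constant_genotype" in r.flags
        assert not r.ok
        assert np.isnan(r.beta)

    def test_codominant_collapse_warns(self, small_cohort):
        _, cohort = small_cohort
        g = np.r_[np.ones(30), np.zeros(len(cohort) - 30)]  # no rare homozygotes
        with pytest.warns(UserWarning, match="collapsing"):
            r = ssa.fit_snp_logistic(g, cohort, "codominant")
        assert "collapsed_codominant" in r.flags

    def test_missing_rejected(self, small_cohort):
        _, cohort = small_cohort
        g = np.zeros(len(cohort))
        g[0] = np.nan
        with pytest.raises(ValidationError, match="impute"):
            ssa.fit_snp_logistic(g, cohort, "additive")

    def test_lrt_df_by_moi(self, small_cohort):
        m, cohort = small_cohort
        res = ssa.fit_all_moi(m.dosage[:, 0], cohort)
        assert res["codominant"].lrt_df == 2
        for moi in ("additive", "dominant", "recessive"):
            assert res[moi].lrt_df == 1
            assert res[moi].lrt_stat >= 0.0

    def test_null_p_uniform_and_type1_calibrated(self):
        # simulation oracle: adjusted additive LRT p on null cohorts
        pvals = []
        for rep in range(400):
            m, c = null_cohort(seed=3000 + rep)
            pvals.append(ssa.fit_snp_logistic(m.dosage[:, 0], c, "additive").p_value)
        pvals = np.array(pvals)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        rate = (pvals <= 0.05).mean()
        band = 2.58 * np.sqrt(0.05 * 0.95 / len(pvals))
        assert abs(rate - 0.05) < band + 0.01


class TestBestMoi:
    def _mk(self, p, moi):
        return ssa.AssociationResult(
            "s", moi, 0.1, 1.1, (1.0, 1.2), 1.0, 1, p, p
        )

    def test_minimum_selected(self):
        res = {m: self._mk(p, m) for m, p in
               zip(("additive", "dominant", "recessive", "codominant"),
                   (0.04, 0.2, 0.3, 0.5))}
        assert ssa.best_moi(res) == ("additive", 0.04)

    def test_tie_order(self):
        res = {m: self._mk(0.2, m) for m in
               ("codominant", "recessive", "dominant", "additive")}
        assert ssa.best_moi(res)[0] == "additive"

    def test_flagged_excluded(self):
        res = {m: self._mk(p, m) for m, p in
               zip(("additive", "dominant", "recessive", "codominant"),
                   (0.01, 0.2, 0.3, 0.5))}
        res["additive"].flags.append("separation")
        assert ssa.best_moi(res)[0] == "dominant"

    def test_recessive_effect_recovered(self):
        # genotypes tilted on the rare-homozygote indicator only
        rng = np.random.default_rng(99)
        q, beta = 0.4, 0.8
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        tilt = hwe * np.exp(beta * np.array([0.0, 0.0, 1.0]))
        tilt /= tilt.sum()
        wins = 0
        n_rep = 60
        for rep in range(n_rep):
            _, c = null_cohort(seed=4000 + rep, n=300)
            g = np.concatenate([
                rng.choice(3, size=300, p=tilt),
                rng.choice(3, size=300, p=hwe),
            ]).astype(float)
            res = ssa.fit_all_moi(g, c)
            if ssa.best_moi(res)[0] == "recessive":
                wins += 1
        assert wins > n_rep / 2


class TestHeterogeneity:
    def test_null_het_p_uniform(self):
        pvals = []
        for rep in range(150):
            m, c = null_cohort(seed=5000 + rep)
            r = ssa.polytomous_heterogeneity(m.dosage[:, 0], c)
            assert r.het_lrt_stat >= 0.0  # nesting
            pvals.append(r.het_p)
        assert stats.kstest(np.array(pvals), "uniform").pvalue > 0.01

    def test_subtype_specific_effect_detected(self):
        # effect only in MIT cases -> heterogeneity rejects above nominal
        rng = np.random.default_rng(7)
        q, beta = 0.3, 0.7
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        tilt = hwe * np.exp(beta * np.arange(3))
        tilt /= tilt.sum()
        rejections = 0
        n_rep = 40
        for rep in range(n_rep):
            m, c = null_cohort(seed=6000 + rep, n=400)
            g = m.dosage[:, 0].copy()
            mit = (c.frame["subphenotype"] == "MIT").to_numpy()
            g[mit] = rng.choice(3, size=int(mit.sum()), p=tilt).astype(float)
            r = ssa.polytomous_heterogeneity(g, c)
            rejections += r.het_p <= 0.05
        assert rejections / n_rep > 0.15  # well above the 5% nominal rate

    def test_empty_subtype_dropped_with_warning(self):
        cfg = sc.default_sim_config(n_cases=150, n_controls=150, n_snps=1, seed=77)
        cfg.subphenotype_probs = (0.5, 0.5, 0.0)  # no MIT cases
        m, c = sc.simulate_cohort(cfg)
        with pytest.warns(UserWarning, match="MIT"):
            r = ssa.polytomous_heterogeneity(m.dosage[:, 0], c)
        assert r.subtypes == ("lowNMIT", "highNMIT")
        assert r.het_df == 1

    def test_p53_class_route(self, small_cohort):
        m, c = small_cohort
        r = ssa.polytomous_heterogeneity(m.dosage[:, 0], c, case_classes="p53_class")
        assert r.subtypes == ("low", "high")
        assert r.het_df == 1
        assert 0.0 <= r.het_p <= 1.0


class TestInteractionScan:
    def test_pair_count(self, small_cohort):
        m, c = small_cohort
        out = ssa.interaction_scan(m, c, "snp_snp")
        p = m.n_snps
        assert len(out) == p * (p - 1) // 2

    def test_full_panel_pair_count_formula(self):
        assert 184 * 183 // 2 == 16836

    def test_null_interaction_p_roughly_uniform(self):
        cfg = sc.default_sim_config(n_cases=200, n_controls=200, n_snps=15, seed=13)
        m, c = sc.simulate_cohort(cfg)
        out = ssa.interaction_scan(m, c, "snp_snp")
        pv = out.loc[out["converged"], "p_value"].to_numpy()
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(21)
        detections = 0
        n_rep = 25
        for rep in range(n_rep):
            n = 3000
            g1 = rng.choice(3, size=2 * n, p=[0.49, 0.42, 0.09]).astype(float)
            g2 = rng.choice(3, size=2 * n, p=[0.49, 0.42, 0.09]).astype(float)
            eta = -0.6 + np.log(1.5) * g1 * g2
            y = rng.random(2 * n) < 1 / (1 + np.exp(-eta))
            case_idx = np.flatnonzero(y)[:n // 2]
            ctrl_idx = np.flatnonzero(~y)[:n // 2]
            idx = np.r_[case_idx, ctrl_idx]
            cohort = uniform_covariate_cohort(len(case_idx), len(ctrl_idx))
            matrix = GenotypeMatrix(
                cohort.sample_ids, ["g1", "g2"],
                np.column_stack([g1[idx], g2[idx]]),
            )
            out = ssa.interaction_scan(matrix, cohort, "snp_snp")
            detections += float(out["p_value"].iloc[0]) <= 0.05
        assert detections / n_rep > 0.5

    def test_snp_smoking_scan(self, small_cohort):
        m, c = small_cohort
        out = ssa.interaction_scan(m, c, "snp_smoking")
        assert len(out) == m.n_snps
        assert out["p_value"].dropna().between(0, 1).all()

    def test_nesting_never_decreases_loglik(self, small_cohort):
        m, c = small_cohort
        out = ssa.interaction_scan(m, c, "snp_snp")
        assert (out["lrt_stat"] >= 0).all()


class TestMinpPermutation:
    def test_refuses_small_n_perm(self, small_cohort):
        m, c = small_cohort
        with pytest.raises(ValidationError, match="n_perm"):
            ssa.minp_permutation(m, c, n_perm=50)

    def test_single_test_family_corrected_near_raw(self):
        cfg = sc.default_sim_config(n_cases=400, n_controls=400, n_snps=1, seed=31,
                                    log_or_of={"rs11757379": 0.3})
        m, c = sc.simulate_cohort(cfg)
        corr = ssa.minp_permutation(m, c, family="trend", n_perm=500, seed=1)
        raw = corr.observed_p["rs11757379"]
        assert abs(corr.corrected_p["rs11757379"] - raw) < 0.03 + 3 * np.sqrt(
            max(raw, 0.002) * (1 - raw) / 500
        )

    def test_bound_floor_for_extreme_observed(self):
        cfg = sc.default_sim_config(n_cases=500, n_controls=500, n_snps=5, seed=32,
                                    log_or_of={"rs11757379": 1.2})
        m, c = sc.simulate_cohort(cfg)
        corr = ssa.minp_permutation(m, c, family="trend", n_perm=150, seed=2)
        assert corr.corrected_p["rs11757379"] == pytest.approx(1 / 151)

    def test_corrected_monotone_and_bounded(self, small_cohort):
        m, c = small_cohort
        corr = ssa.minp_permutation(m, c, family="lrt_additive", n_perm=150, seed=3)
        obs = np.array([corr.observed_p[s] for s in m.snp_ids])
        cor = np.array([corr.corrected_p[s] for s in m.snp_ids])
        order = np.argsort(obs)
        assert (np.diff(cor[order]) >= -1e-12).all()  # monotone in raw p
        assert (cor >= 1 / 151 - 1e-12).all() and (cor <= 1.0).all()
        assert (cor >= obs - 0.05).all()  # family min-p dominates raw

    def test_trend_agrees_with_lrt_family_ordering(self, small_cohort):
        m, c = small_cohort
        a = ssa.minp_permutation(m, c, family="trend", n_perm=150, seed=4)
        b = ssa.minp_permutation(m, c, family="lrt_additive", n_perm=150, seed=4)
        ra = pd.Series(a.observed_p).rank()
        rb = pd.Series(b.observed_p).rank()
        assert ra.corr(rb, method="spearman") > 0.7


class TestPower:
    def test_null_or_gives_alpha(self):
        assert ssa.power_per_allele(1058, 1138, 0.25, 1.0, 0.05) == pytest.approx(0.05)

    def test_reference_design_power(self):
        assert ssa.power_per_allele(1058, 1138, 0.25, 1.3, 0.05) >= 0.90

    def test_analytic_matches_simulation(self):
        analytic = ssa.power_per_allele(1058, 1138, 0.25, 1.3, 0.05)
        n_rep = 1500
        empirical = ssa.power_per_allele_sim(
            1058, 1138, 0.25, 1.3, 0.05, n_rep=n_rep, seed=8
        )
        se = np.sqrt(max(empirical * (1 - empirical), 1e-4) / n_rep)
        assert abs(analytic - empirical) < 2 * se + 0.01

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            ssa.power_per_allele(100, 100, 0.7, 1.3)
        with pytest.raises(ValidationError):
            ssa.power_per_allele(100, 100, 0.25, 1.3, alpha=1.5)


def test_association_table_layout(small_cohort):
    m, c = small_cohort
    table = ssa.association_table(m, c)
    assert len(table) == m.n_snps
    assert {"snp_id", "moi", "or", "ci_lo", "ci_hi", "p_value", "p_trend"} <= set(
        table.columns
    )
    ok = table["p_value"].notna()
    assert table.loc[ok, "p_value"].between(0, 1).all()
    assert (table.loc[ok, "ci_lo"] <= table.loc[ok, "or"]).all()
    assert (table.loc[ok, "or"] <= table.loc[ok, "ci_hi"]).all()
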