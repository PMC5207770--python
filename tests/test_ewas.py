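"""OLS engine, nested-ANOVA omnibus tests, scan power and calibration,
stability and non-linearity screens, enrichment arithmetic, admixture
mapping and the cis-SNP conditional scan."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methadmix.data import GenotypeMatrix, MethylationMatrix
from methadmix.ewas import (
    AncestryScan,
    EthnicityScan,
    RankError,
    admixture_map,
    block_f_scan,
    bonferroni,
    cis_scan,
    classify_adjustment,
    enrichment,
    fit_ols,
    m_to_fold,
    nested_anova,
    nonlinearity_test,
    stability_flag,
    stability_flags_scan,
)


def _design(**cols):
    df = pd.DataFrame(cols)
    df.insert(0, "const", 1.0)
    return df


class TestFitOLS:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2, 3, 4])
        fit = fit_ols(2 * x + 1, _design(x=x))
        assert fit.rss == pytest.approx(0, abs=1e-20)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_hand_arithmetic_slope(self):
        # five points: Sxy = 7.3, Sxx = 10 -> slope 0.73 by hand
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 2.4, 3.6, 4.1, 4.8])
        sxx = ((x - 3) ** 2).sum()
        sxy = ((x - 3) * (y - y.mean())).sum()
        assert (sxx, sxy) == (10.0, pytest.approx(7.3))
        fit = fit_ols(y, _design(x=x))
        assert fit.params["x"] == pytest.approx(sxy / sxx)
        assert fit.params["x"] == pytest.approx(0.73)

    def test_row_permutation_invariance(self, rng):
        X = _design(x=rng.normal(size=30), z=rng.normal(size=30))
        y = rng.normal(size=30)
        fit = fit_ols(y, X)
        perm = rng.permutation(30)
        fit2 = fit_ols(y[perm], X.iloc[perm].reset_index(drop=True))
        pd.testing.assert_series_equal(fit.params, fit2.params)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = _design(x=rng.normal(size=40), z=rng.normal(size=40))
        y = rng.normal(size=40)
        ours = fit_ols(y, X)
        theirs = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.params, theirs.params, rtol=1e-9)
        np.testing.assert_allclose(ours.bse, theirs.bse, rtol=1e-9)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(RankError) as err:
            fit_ols(rng.normal(size=20), _design(x=x, x_copy=x))
        assert err.value.dependent_columns


class TestNestedAnova:
    def test_identical_models_give_f_zero_p_one(self, rng):
        X = _design(x=rng.normal(size=25))
        y = rng.normal(size=25)
        res = nested_anova(fit_ols(y, X), fit_ols(y, X))
        assert res.F == 0 and res.p == 1

    def test_single_column_f_equals_t_squared(self, rng):
        X = _design(x=rng.normal(size=40), z=rng.normal(size=40))
        y = rng.normal(size=40)
        full = fit_ols(y, X)
        red = fit_ols(y, X[["const", "x"]])
        res = nested_anova(full, red)
        t = full.params["z"] / full.bse["z"]
        assert res.F == pytest.approx(t**2, rel=1e-9)
        assert res.df1 == 1

    def test_non_nested_rejected(self, rng):
        y = rng.normal(size=30)
        a = fit_ols(y, _design(x=rng.normal(size=30)))
        b = fit_ols(y, _design(w=rng.normal(size=30)))
        with pytest.raises(ValueError, match="nest"):
            nested_anova(a, b)

    def test_null_p_values_are_uniform(self, rng):
        # 2000 independent null outcomes, one shared nested comparison
        n = 50
        X_red = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        X_full = np.column_stack([X_red, rng.normal(size=(n, 3))])
        Y = rng.normal(size=(n, 2000))
        _, _, _, p = block_f_scan(Y, X_full, X_red)
        assert stats.kstest(p, "uniform").pvalue > 0.01


def _cohort_frame(rng, n=500, shift=0.0, n_cpgs=50, sd=0.45, groups=4):
    labels = ["Mexican", "PuertoRican", "Other", "Mixed"][:groups]
    eth = pd.Series(rng.choice(labels, size=n), name="ethnicity")
    Y = rng.normal(0, sd, size=(n, n_cpgs))
    Y[(eth == "PuertoRican").to_numpy()] += shift
    idx = pd.Index([f"S{i}" for i in range(n)])
    eth.index = idx
    meth = MethylationMatrix(
        pd.DataFrame(Y, index=idx, columns=[f"cg{j}" for j in range(n_cpgs)]), scale="m"
    )
    samples = pd.DataFrame({"ethnicity": eth, "age": rng.normal(12, 2, n)}, index=idx)
    return meth, samples


class TestEthnicityScan:
    def test_group_shift_detected_at_genomewide_threshold(self, rng):
        # 0.5 M shift at sd 0.45, n=500: each CpG column is an independent
        # replicate; detection rate at p<1.6e-7 far exceeds 80%
        meth, samples = _cohort_frame(rng, shift=0.5, groups=2)
        res = EthnicityScan(meth, samples, covariates=["age"]).fit()
        assert (res.table["p"] < 1.6e-7).mean() > 0.8

    def test_null_scan_bonferroni_false_positives(self, rng):
        meth, samples = _cohort_frame(rng, shift=0.0, n_cpgs=1000, groups=4)
        res = EthnicityScan(meth, samples, covariates=["age"]).fit()
        # E[# hits] = alpha under the global null; P(>3) < 1e-5
        assert res.n_hits <= 3

    def test_four_groups_use_three_df(self, rng):
        meth, samples = _cohort_frame(rng, n_cpgs=5, groups=4)
        res = EthnicityScan(meth, samples).fit()
        assert (res.table["df1"] == 3).all()


class TestAncestryScan:
    def _ancestry_study(self, rng, q, theta_afr=1.0, sd=0.45, n_cpgs=40):
        n = len(q)
        Y = rng.normal(0, sd, size=(n, n_cpgs)) + theta_afr * q[["AFR"]].to_numpy()
        meth = MethylationMatrix(
            pd.DataFrame(Y, index=q.index, columns=[f"cg{j}" for j in range(n_cpgs)]), scale="m"
        )
        samples = pd.DataFrame({"ethnicity": "Admixed", "age": rng.normal(12, 2, n)}, index=q.index)
        return meth, samples

    def test_theta_detected_and_attributed_to_afr(self, rng, diverse_cohort):
        meth, samples = self._ancestry_study(rng, diverse_cohort)
        res = AncestryScan(meth, samples, diverse_cohort, covariates=["age"]).fit()
        assert (res.table["p"] < 1.6e-7).mean() > 0.8
        assert (res.table["driven_by"] == "AFR").mean() > 0.8

    def test_permuted_ancestry_is_null(self, rng, diverse_cohort):
        meth, samples = self._ancestry_study(rng, diverse_cohort, n_cpgs=300)
        q_perm = diverse_cohort.copy()
        q_perm.iloc[:] = diverse_cohort.to_numpy()[rng.permutation(len(diverse_cohort))]
        res = AncestryScan(meth, samples, q_perm, covariates=["age"]).fit()
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.001

    def test_k_minus_one_coding(self, rng, diverse_cohort):
        meth, samples = self._ancestry_study(rng, diverse_cohort, n_cpgs=3)
        res = AncestryScan(meth, samples, diverse_cohort, covariates=["age"]).fit()
        assert (res.table["df1"] == 2).all()  # 3 components -> 2 columns


class TestStability:
    def test_orthogonal_predictors_not_flagged(self, rng):
        n = 200
        e = rng.choice([0.0, 1.0], size=n)
        a = rng.normal(size=n)
        y = rng.normal(size=n)
        un = fit_ols(y, _design(eth_b=e))
        ad = fit_ols(y, _design(eth_b=e, anc_a=a))
        assert stability_flag(ad, un) is False

    def test_near_duplicate_predictor_flagged(self, rng):
        n = 100
        e = rng.choice([0.0, 1.0], size=n)
        y = rng.normal(size=n)
        un = fit_ols(y, _design(eth_b=e))
        ad = fit_ols(y, _design(eth_b=e, anc_a=e + rng.normal(0, 1e-8, n)))
        assert stability_flag(ad, un) is True

    def test_correlation_point_nine_not_flagged_under_defaults(self, rng):
        # r = 0.9 -> VIF ~ 5.3, SE ratio ~ 2.3: well under the cutoffs
        n = 500
        e = rng.choice([0.0, 1.0], size=n)
        a = 0.9 * (e - e.mean()) / e.std() + np.sqrt(1 - 0.81) * rng.normal(size=n)
        y = rng.normal(size=n)
        un = fit_ols(y, _design(eth_b=e))
        ad = fit_ols(y, _design(eth_b=e, anc_a=a))
        assert abs(np.corrcoef(e, a)[0, 1]) > 0.85
        assert stability_flag(ad, un) is False


class TestClassification:
    def test_constructed_collinearity_marked_unstable(self, rng):
        # ethnicity an (almost) exact linear function of ancestry
        n = 300
        idx = pd.Index([f"S{i}" for i in range(n)])
        eth = pd.Series(rng.choice(["a", "b"], size=n), index=idx, name="ethnicity")
        q = pd.DataFrame(
            {
                "AFR": 0.2 + 0.3 * (eth == "b").astype(float) + rng.normal(0, 1e-9, n),
                "EUR": 0.5,
                "NAM": 0.3 - 0.3 * (eth == "b").astype(float) - rng.normal(0, 1e-9, n),
            },
            index=idx,
        )
        Y = rng.normal(0, 0.45, size=(n, 10)) + (eth == "b").to_numpy()[:, None]
        meth = MethylationMatrix(
            pd.DataFrame(Y, index=idx, columns=[f"cg{j}" for j in range(10)]), scale="m"
        )
        samples = pd.DataFrame({"ethnicity": eth}, index=idx)
        flags = stability_flags_scan(meth, samples, q, covariates=[])
        assert flags.all()
        un = EthnicityScan(meth, samples, covariates=[]).fit()
        ad = EthnicityScan(meth, samples, covariates=[], ancestry=q).fit()
        cls = classify_adjustment(un, ad, flags)
        assert (cls["classification"] == "unstable").all()


class TestNonlinearity:
    def test_null_linear_truth_calibrated(self, rng, diverse_cohort):
        ps = []
        a = diverse_cohort["NAM"]
        for _ in range(300):
            y = 0.5 * a + rng.normal(0, 0.45, len(a))
            ps.append(nonlinearity_test(pd.Series(y, index=a.index), a, method="poly").p_nonlinear)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    @pytest.mark.parametrize(("method", "min_rate"), [("poly", 0.85), ("spline", 0.8)])
    def test_quadratic_truth_detected(self, rng, method, min_rate):
        # y ~ ancestry^2, 1 M-unit effect, sd 0.45, n=500, ancestry spread
        # uniform on (0,1); the noncentral-F oracle gives ~93% power (poly)
        a = pd.Series(
            np.random.default_rng(5).uniform(0, 1, 500),
            index=[f"S{i}" for i in range(500)],
        )
        hits = 0
        for _ in range(40):
            y = pd.Series(1.0 * a**2 + rng.normal(0, 0.45, len(a)), index=a.index)
            if nonlinearity_test(y, a, method=method).p_nonlinear < 0.05:
                hits += 1
        assert hits / 40 >= min_rate

    def test_spline_block_adds_exactly_three_columns(self, rng, diverse_cohort):
        a = diverse_cohort["NAM"]
        y = pd.Series(rng.normal(size=len(a)), index=a.index)
        res = nonlinearity_test(y, a, method="spline")
        assert res.df_block == 3

    def test_ethnicity_retested_with_block(self, rng):
        n = 400
        idx = pd.Index([f"S{i}" for i in range(n)])
        eth = pd.Series(rng.choice(["a", "b"], n), index=idx)
        a = pd.Series(rng.uniform(0, 1, n), index=idx)
        y = pd.Series((eth == "b") * 0.5 + rng.normal(0, 0.45, n), index=idx)
        res = nonlinearity_test(y, a, method="poly", ethnicity=eth)
        assert res.p_ethnicity_adjusted < 1e-10


class TestBonferroni:
    def test_methylome_wide_threshold(self):
        # 0.05 / 321503 prints as 1.6e-7 at two significant figures
        thr = bonferroni(0.05, 321_503)
        assert float(f"{thr:.1e}") == 1.6e-7

    def test_candidate_set_threshold(self):
        assert float(f"{bonferroni(0.05, 4404):.1e}") == 1.1e-5

    def test_single_test(self):
        assert bonferroni(0.05, 1) == 0.05


class TestEnrichment:
    def _maps(self, n_cand, n_sig, universe_size=6000, seed=0):
        rng = np.random.default_rng(seed)
        universe = pd.Index([f"cg{j}" for j in range(universe_size)])
        cand = universe[:n_cand]
        p = pd.Series(rng.uniform(0.06, 1.0, universe_size), index=universe)
        p.iloc[:n_sig] = rng.uniform(0, 0.049, n_sig)
        return universe, cand, p

    def test_maternal_smoking_scale_enrichment(self):
        universe, cand, p = self._maps(4404, 1341)
        res = enrichment([], cand, universe, p)
        assert res.n_nominal == 1341
        assert res.nominal_rate == pytest.approx(0.304, abs=5e-4)
        assert res.binomial_p < 2e-16

    def test_zero_nominal_gives_p_near_one(self):
        universe, cand, p = self._maps(100, 0)
        res = enrichment([], cand, universe, p)
        assert res.binomial_p > 0.9

    def test_hypergeometric_matches_enumeration(self):
        # overlap 3 of 5 candidates, 10 hits, universe 50
        universe = pd.Index([f"cg{j}" for j in range(50)])
        hits = universe[:10]
        cand = universe[7:12]  # overlap = {cg7, cg8, cg9} -> 3
        p = pd.Series(1.0, index=universe)
        res = enrichment(hits, cand, universe, p)
        exact = sum(
            Fraction(math.comb(10, k) * math.comb(40, 5 - k), math.comb(50, 5))
            for k in range(3, 6)
        )
        assert res.n_overlap == 3
        assert res.hypergeom_p == pytest.approx(float(exact), rel=1e-9)

    def test_empty_candidates_rejected(self):
        universe = pd.Index(["cg0"])
        with pytest.raises(ValueError, match="empty"):
            enrichment([], [], universe, pd.Series(1.0, index=universe))


class TestFoldChange:
    @pytest.mark.parametrize("dm,fold", [(2.7, 6.50), (0.0, 1.0), (1.0, 2.0), (1.5, 2.83)])
    def test_values(self, dm, fold):
        assert m_to_fold(dm) == pytest.approx(fold, abs=5e-3)


class TestAdmixtureMap:
    def test_fixed_difference_meqtl_effect_recovered(self, small_study):
        # truth: 1.35 M per allele == per African haplotype at the locus
        m = small_study.m_values()
        y = m.values["cg_duffy_like"]
        pos_m = float(
            small_study.panel.genetic_map.bp_to_morgans(m.manifest.loc["cg_duffy_like", "pos"])
        )
        dos = small_study.local.dosage_at(pos_m)
        dos.index = m.samples
        res = admixture_map(y, dos)
        assert abs(res.effects["AFR"] - 1.35) < 2 * res.bse["AFR"]
        assert res.p_omnibus < 1e-20

    def test_constant_dosage_rejected(self, rng):
        idx = pd.Index([f"S{i}" for i in range(50)])
        dos = pd.DataFrame({"AFR": 2.0, "EUR": 0.0, "NAM": 0.0}, index=idx)
        with pytest.raises(ValueError, match="variance"):
            admixture_map(pd.Series(rng.normal(size=50), index=idx), dos)


class TestCisScan:
    def _geno(self, dosages, positions):
        dos = pd.DataFrame(np.asarray(dosages, dtype=float))
        dos.columns = [f"snp{j}" for j in dos.columns]
        dos.index = [f"S{i}" for i in range(len(dos))]
        return GenotypeMatrix(dos, pd.Series(positions, index=dos.columns))

    def test_causal_snp_ranked_first(self, rng):
        n = 500
        g = rng.binomial(2, 0.4, (n, 5)).astype(float)
        y = pd.Series(1.35 * g[:, 2] + rng.normal(0, 0.45, n))
        geno = self._geno(g, [1000, 2000, 3000, 4000, 5000])
        y.index = geno.samples
        table = cis_scan(y, geno, cpg_pos=3100, window_bp=10_000)
        assert table.iloc[0]["snp"] == "snp2"

    def test_empty_window_returns_empty_table(self, rng):
        geno = self._geno(rng.binomial(2, 0.4, (20, 2)), [1000, 2000])
        y = pd.Series(rng.normal(size=20), index=geno.samples)
        assert len(cis_scan(y, geno, cpg_pos=1_000_000, window_bp=500)) == 0

    def test_window_boundaries_inclusive(self, rng):
        geno = self._geno(rng.binomial(2, 0.4, (30, 2)), [90_000, 110_000])
        y = pd.Series(rng.normal(size=30), index=geno.samples)
        table = cis_scan(y, geno, cpg_pos=100_000, window_bp=10_000)
        assert set(table["snp"]) == {"snp0", "snp1"}

    def test_conditioning_on_duffy_snp_abolishes_ancestry_signal(self, small_study):
        m = small_study.m_values()
        y = m.values["cg_duffy_like"]
        pos_bp = float(m.manifest.loc["cg_duffy_like", "pos"])
        dos = small_study.local.dosage_at_bp(pos_bp)
        dos.index = m.samples
        table = cis_scan(y, small_study.genotypes, pos_bp, local_dosage=dos)
        assert table.attrs["best_snp"] == "rs_duffy_like"
        assert table.attrs["p_local_unconditional"] < 1e-10
        assert table.attrs["p_local_given_best"] > 0.01
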