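import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, hypergeom

from methylwindow import diff, simulate
from methylwindow.presets import null_calibration_config

from conftest import make_counts_matrix


def binomial_deviance_oracle(y, n, p):
    """Hand-rolled binomial deviance with 0*log(0) = 0."""
    dev = 0.0
    for yi, ni, pi in zip(y, n, p):
        if yi > 0:
            dev += yi * np.log(yi / (ni * pi))
        if ni - yi > 0:
            dev += (ni - yi) * np.log((ni - yi) / (ni * (1 - pi)))
    return 2.0 * dev


def lrt_oracle_no_covariate(y, n, group):
    """Covariate-free LRT statistic from closed-form group-pooled MLEs."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    g = np.asarray(group, bool)
    p_full = np.where(g, y[g].sum() / n[g].sum(), y[~g].sum() / n[~g].sum())
    p_red = np.full(len(y), y.sum() / n.sum())
    return binomial_deviance_oracle(y, n, p_red) - binomial_deviance_oracle(y, n, p_full)


class TestUniteSites:
    def test_rule_example(self):
        # only the first site reaches 10x coverage in every sample
        total = np.array([[12, 11, 10, 15], [9, 12, 10, 15], [12, 11, 10, 2]])
        meth = np.zeros_like(total)
        mat = make_counts_matrix(meth, total)
        contrast = diff.Contrast("T-C", ["s1", "s2"], ["s3", "s4"])
        mask = diff.unite_sites(mat, contrast, diff.UniteConfig(min_coverage=10))
        assert mask.tolist() == [True, False, False]

    def test_min_coverage_one_keeps_covered(self):
        total = np.array([[1, 1, 1, 1], [1, 0, 1, 1]])
        mat = make_counts_matrix(np.zeros_like(total), total)
        contrast = diff.Contrast("T-C", ["s1", "s2"], ["s3", "s4"])
        mask = diff.unite_sites(mat, contrast, diff.UniteConfig(min_coverage=1))
        assert mask.tolist() == [True, False]

    def test_min_samples_relaxation(self):
        total = np.array([[1, 0, 9, 9]])
        mat = make_counts_matrix(np.zeros_like(total), total)
        contrast = diff.Contrast("T-C", ["s1", "s2"], ["s3", "s4"])
        cfg = diff.UniteConfig(min_coverage=1, min_samples_per_group=1)
        assert diff.unite_sites(mat, contrast, cfg).tolist() == [True]

    def test_unknown_sample_raises(self):
        total = np.array([[1, 1, 1, 1]])
        mat = make_counts_matrix(np.zeros_like(total), total)
        contrast = diff.Contrast("T-C", ["s1", "nope"], ["s3", "s4"])
        with pytest.raises(ValueError, match="nope"):
            diff.unite_sites(mat, contrast, diff.UniteConfig())

    def test_retained_count_monotone_in_min_coverage(self, small_dataset):
        _, _, _, matrix, _ = small_dataset
        contrast = diff.Contrast(
            "YT-YC",
            [s for s in matrix.samples if s.startswith("YT")],
            [s for s in matrix.samples if s.startswith("YC")],
        )
        counts = [
            int(diff.unite_sites(matrix, contrast, diff.UniteConfig(min_coverage=c)).sum())
            for c in range(1, 31)
        ]
        assert counts == sorted(counts, reverse=True)


class TestTestSite:
    def test_identical_counts_null(self):
        p, d = diff.test_site([10, 10], [20, 20], [True, False])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_one_sample_per_group_matches_ml_oracle(self):
        y, n, g = [15, 5], [20, 20], [True, False]
        p, d = diff.test_site(y, n, g)
        stat_oracle = lrt_oracle_no_covariate(y, n, g)
        assert chi2.sf(stat_oracle, 1) == pytest.approx(p, abs=1e-9)
        assert chi2.isf(p, 1) == pytest.approx(stat_oracle, abs=1e-6)
        assert d == pytest.approx(15 / 20 - 5 / 20)

    def test_random_tables_match_ml_oracle(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(200):
            ns = int(rng.integers(1, 5))
            y = rng.integers(0, 21, size=2 * ns)
            n = np.full(2 * ns, 25)
            g = np.arange(2 * ns) < ns
            frac = y / n
            if np.allclose(frac, frac[0]):
                continue
            # boundary group fractions (0 or 1) take the score-test fallback
            if y[g].sum() in (0, n[g].sum()) or y[~g].sum() in (0, n[~g].sum()):
                continue
            p, _ = diff.test_site(y, n, g)
            stat = lrt_oracle_no_covariate(y, n, g)
            assert chi2.sf(stat, 1) == pytest.approx(p, abs=1e-6)
            n_checked += 1
        assert n_checked > 100

    def test_matches_statsmodels_with_covariate(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        for _ in range(25):
            ns = int(rng.integers(2, 5)) * 2
            n = rng.integers(10, 60, ns).astype(float)
            g = np.arange(ns) % 2 == 0
            kit = np.array(["kitA", "kitB"])[rng.integers(0, 2, ns)]
            y = rng.binomial(n.astype(int), 0.55 + 0.15 * g).astype(float)
            frac = y / n
            if np.allclose(frac, frac[0]):
                continue
            p, _ = diff.test_site(y, n, g, kit)
            X = np.column_stack(
                [np.ones(ns), (kit == "kitB").astype(float), g.astype(float)]
            )
            full = sm.GLM(
                np.column_stack([y, n - y]), X, family=sm.families.Binomial()
            ).fit()
            red = sm.GLM(
                np.column_stack([y, n - y]), X[:, :2], family=sm.families.Binomial()
            ).fit()
            p_sm = chi2.sf(red.deviance - full.deviance, 1)
            assert p == pytest.approx(p_sm, abs=1e-6)

    def test_separation_falls_back_to_score_test(self):
        # complete separation: all successes vs all failures
        p, d = diff.test_site([20, 20, 0, 0], [20, 20, 20, 20], [True, True, False, False])
        assert 0.0 < p < 1e-6
        assert d == pytest.approx(1.0)

    def test_zero_total_samples_excluded(self):
        p1, d1 = diff.test_site([5, 0, 2], [10, 0, 10], [True, True, False])
        p2, d2 = diff.test_site([5, 2], [10, 10], [True, False])
        assert p1 == pytest.approx(p2)
        assert d1 == pytest.approx(d2)

    def test_dispersion_correction_never_more_significant(self):
        rng = np.random.default_rng(5)
        n = np.full(8, 40)
        g = np.arange(8) < 4
        # overdispersed counts: per-sample fractions jittered around a mean
        p_sample = np.clip(rng.normal(0.6 + 0.1 * g, 0.15), 0.05, 0.95)
        y = rng.binomial(n, p_sample)
        p_plain, _ = diff.test_site(y, n, g)
        p_disp, _ = diff.test_site(y, n, g, dispersion_correction=True)
        assert p_disp >= p_plain

    def test_dispersion_correction_noop_without_overdispersion(self):
        # clean binomial data: Pearson dispersion is capped below at 1
        rng = np.random.default_rng(8)
        n = np.full(8, 200)
        g = np.arange(8) < 4
        y = rng.binomial(n, 0.6 + 0.05 * g)
        p_plain, _ = diff.test_site(y, n, g)
        p_disp, _ = diff.test_site(y, n, g, dispersion_correction=True)
        assert p_disp >= p_plain
        assert p_disp == pytest.approx(p_plain, rel=0.5)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            diff.test_site([5, 5], [10, 10], [True, True])

    def test_agrees_with_fisher_at_large_counts(self):
        # the two-sided enumeration p is discrete, so tight agreement is
        # only achievable on the significant tail; elsewhere the jump at
        # the modal table dominates (measured ~0.05 at p<0.2, cells 20-80)
        rng = np.random.default_rng(3)
        n_tail = 0
        for _ in range(150):
            a, b = rng.integers(20, 60, 2)
            c, d_ = rng.integers(20, 60, 2)
            p_lrt, _ = diff.test_site([a, c], [a + b, c + d_], [True, False])
            p_f = diff.fisher_exact_oracle(int(a), int(b), int(c), int(d_))
            assert abs(p_lrt - p_f) < 0.15
            if p_f < 0.01:
                assert abs(p_lrt - p_f) < 0.01
                n_tail += 1
        assert n_tail > 10


class TestRunContrast:
    def _planted_matrix(self, n_null=300, n_effect=100, seed=0, coverage=30):
        rng = np.random.default_rng(seed)
        n_samples = 8  # 4 vs 4
        total = rng.poisson(coverage, size=(n_null + n_effect, n_samples))
        p = np.full((n_null + n_effect, n_samples), 0.75)
        from scipy.special import expit, logit

        p[n_null:, :4] = expit(logit(0.75) - 1.5)  # hypo in the test group
        meth = rng.binomial(total, p)
        return make_counts_matrix(meth, total), n_null

    def test_conservation_identity(self):
        mat, _ = self._planted_matrix()
        contrast = diff.Contrast("T-C", ["s1", "s2", "s3", "s4"], ["s5", "s6", "s7", "s8"])
        res = diff.run_contrast(mat, contrast)
        assert res.n_hyper + res.n_hypo == res.n_significant
        summary = res.summary()
        assert summary["n_hyper"] + summary["n_hypo"] == summary["n_significant"]
        by_chrom = summary["by_chromosome"]
        assert (
            sum(v["hyper"] + v["hypo"] for v in by_chrom.values()) == res.n_significant
        )

    def test_planted_hypo_power(self):
        mat, n_null = self._planted_matrix()
        contrast = diff.Contrast("T-C", ["s1", "s2", "s3", "s4"], ["s5", "s6", "s7", "s8"])
        res = diff.run_contrast(mat, contrast)
        effect_rows = res.table.index >= n_null  # subset preserves order here
        called_hypo = (res.table.loc[effect_rows, "direction"] == "hypo").sum()
        # observed in development: 100/100 at these settings
        assert called_hypo >= 80

    def test_label_swap_antisymmetry(self):
        mat, _ = self._planted_matrix(n_null=100, n_effect=50)
        fwd = diff.Contrast("T-C", ["s1", "s2", "s3", "s4"], ["s5", "s6", "s7", "s8"])
        rev = diff.Contrast("C-T", ["s5", "s6", "s7", "s8"], ["s1", "s2", "s3", "s4"])
        r1 = diff.run_contrast(mat, fwd)
        r2 = diff.run_contrast(mat, rev)
        np.testing.assert_allclose(
            r1.table["meth_difference"], -r2.table["meth_difference"], atol=1e-12
        )
        np.testing.assert_allclose(r1.table["p_value"], r2.table["p_value"], atol=1e-8)
        assert r1.n_hyper == r2.n_hypo and r1.n_hypo == r2.n_hyper

    def test_null_calibration_small(self):
        rates = []
        for seed in range(3):
            cfg = null_calibration_config(seed)
            genome, genes, islands = simulate.generate_genome(cfg)
            mat, _ = simulate.simulate_methylomes(genome, genes, islands, cfg)
            contrast = diff.Contrast(
                "YT-YC",
                [s for s in mat.samples if s.startswith("YT")],
                [s for s in mat.samples if s.startswith("YC")],
            )
            res = diff.run_contrast(mat, contrast, contexts=["CpG"])
            rates.append((res.table["p_value"] < 0.01).mean())
        assert 0.003 <= np.mean(rates) <= 0.025

    def test_confounded_kit_inflates_when_unadjusted(self):
        # kit partially confounded with group; strong kit effect
        rng = np.random.default_rng(11)
        n_sites, coverage = 400, 30
        kits = ["kitA", "kitA", "kitA", "kitB", "kitA", "kitB", "kitB", "kitB"]
        from scipy.special import expit, logit

        p_kit = np.where(np.array(kits) == "kitB", expit(logit(0.75) + 0.8), 0.75)
        total = rng.poisson(coverage, size=(n_sites, 8))
        meth = rng.binomial(total, p_kit[None, :])
        mat = make_counts_matrix(meth, total, kits=kits)
        with_cov = diff.Contrast("T-C", ["s1", "s2", "s3", "s4"], ["s5", "s6", "s7", "s8"])
        no_cov = diff.Contrast(
            "T-C", ["s1", "s2", "s3", "s4"], ["s5", "s6", "s7", "s8"], covariates=[]
        )
        r_adj = diff.run_contrast(mat, with_cov)
        r_raw = diff.run_contrast(mat, no_cov)
        rate_adj = (r_adj.table["p_value"] < 0.01).mean()
        rate_raw = (r_raw.table["p_value"] < 0.01).mean()
        assert rate_adj < 0.04
        assert rate_raw > 3 * max(rate_adj, 0.01)

    def test_empty_after_unite_is_graceful(self):
        total = np.ones((3, 4), dtype=int)
        mat = make_counts_matrix(np.zeros_like(total), total)
        contrast = diff.Contrast("T-C", ["s1", "s2"], ["s3", "s4"])
        res = diff.run_contrast(mat, contrast, diff.UniteConfig(min_coverage=10))
        assert res.n_tested == 0 and res.n_significant == 0


class TestFisherOracle:
    def test_symmetric_table(self):
        assert diff.fisher_exact_oracle(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_table(self):
        from math import comb

        expected = 2 / comb(20, 10)
        assert diff.fisher_exact_oracle(10, 0, 0, 10) == pytest.approx(expected, rel=1e-12)

    def test_all_zero(self):
        assert diff.fisher_exact_oracle(0, 0, 0, 0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            diff.fisher_exact_oracle(-1, 0, 0, 0)

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=100, deadline=None)
    def test_matches_hypergeom_enumeration(self, a, b, c, d):
        # independent computation: sum hypergeom pmfs <= observed pmf
        n, r1, c1 = a + b + c + d, a + b, a + c
        if n == 0:
            return
        lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
        pmf = hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1)
        p_obs = hypergeom.pmf(a, n, r1, c1)
        expected = pmf[pmf <= p_obs * (1 + 1e-12)].sum()
        assert diff.fisher_exact_oracle(a, b, c, d) == pytest.approx(
            min(expected, 1.0), abs=1e-10
        )

    def test_probability_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 50, 4)
            p = diff.fisher_exact_oracle(int(a), int(b), int(c), int(d))
            assert 0.0 <= p <= 1.0


class TestStudyContrasts:
    def test_six_default_contrasts(self):
        sheet = simulate.SimulationConfig().sample_sheet()
        contrasts = diff.study_contrasts(sheet)
        assert [c.name for c in contrasts] == list(diff.STUDY_CONTRASTS)
        by_name = {c.name: c for c in contrasts}
        assert len(by_name["AT-AC"].test_group) == 7
        assert len(by_name["AT-AC"].reference_group) == 4
        assert len(by_name["YT-YC"].test_group) == 6
        for c in contrasts:
            c.validate()
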