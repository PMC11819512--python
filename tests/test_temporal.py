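"""Nonparametric tests against brute-force oracles; NB-GAM behavior."""

import numpy as np
import pandas as pd
import pytest

import nbhfsocial as nh


# --------------------------------------------------------------------------
# independent brute-force rank oracles (kept free of scipy rank machinery)
# --------------------------------------------------------------------------

def brute_ranks(values):
    """Midranks computed by sorting alone."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def brute_kw_h(values, groups):
    """Kruskal-Wallis H from first principles, with tie correction."""
    n = len(values)
    ranks = brute_ranks(values)
    keys = []
    for g in groups:
        if g not in keys:
            keys.append(g)
    h = 0.0
    for key in keys:
        rs = [r for r, g in zip(ranks, groups) if g == key]
        h += sum(rs) ** 2 / len(rs)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = Counter(values)
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / float(n**3 - n)
    return h / correction if correction > 0 else 0.0


def brute_dunn_z(values, groups, pair):
    ranks = brute_ranks(values)
    n = len(values)
    by = {}
    for r, g in zip(ranks, groups):
        by.setdefault(g, []).append(r)
    from collections import Counter

    ties = Counter(values)
    tie_term = sum(t**3 - t for t in ties.values()) / (12.0 * (n - 1))
    a, b = pair
    se = ((n * (n + 1) / 12.0 - tie_term) * (1 / len(by[a]) + 1 / len(by[b]))) ** 0.5
    return (np.mean(by[a]) - np.mean(by[b])) / se


# --------------------------------------------------------------------------
# distributional tests
# --------------------------------------------------------------------------

class TestShapiro:
    def test_gaussian_samples_rarely_rejected(self):
        rng = np.random.default_rng(0)
        kept = sum(nh.shapiro_normality(rng.normal(size=500)) > 0.05 for _ in range(40))
        assert kept >= 34  # ~ nominal 5% type-I rate

    def test_heavy_tailed_sample_rejected(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            nh.shapiro_normality(rng.standard_cauchy(size=500)) < 0.05 for _ in range(50)
        )
        assert rejections >= 49

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            nh.shapiro_normality([1.0] * 10)

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            nh.shapiro_normality([1.0, 2.0])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = nh.kruskal_wallis([1, 1, 1, 1, 1, 1], ["a", "a", "b", "b", "c", "c"])
        assert res.h_statistic == 0.0 and res.p_value == 1.0

    def test_toy_three_groups_match_oracle(self):
        values = list(range(1, 10))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = nh.kruskal_wallis(values, groups)
        assert res.h_statistic == pytest.approx(brute_kw_h(values, groups), rel=1e-12)
        assert res.df == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            nh.kruskal_wallis([1.0, 2.0], ["a", "a"])

    def test_ties_match_oracle(self):
        values = [1, 2, 2, 2, 3, 3, 4, 5, 5]
        groups = ["a", "a", "b", "b", "b", "c", "c", "c", "a"]
        res = nh.kruskal_wallis(values, groups)
        assert res.h_statistic == pytest.approx(brute_kw_h(values, groups), rel=1e-12)


class TestDunn:
    def test_two_groups_adjusted_equals_raw(self):
        res = nh.dunn_bonferroni([1, 2, 3, 7, 8, 9], ["a", "a", "a", "b", "b", "b"])
        assert res.p_adjusted == pytest.approx(res.p_raw)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 5, size=30).tolist()
        groups = (["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        res = nh.dunn_bonferroni(values, groups)
        for raw, adj in zip(res.p_raw, res.p_adjusted):
            assert adj >= raw - 1e-15
            assert adj <= 1.0

    def test_toy_case_matches_hand_ranks(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = nh.dunn_bonferroni(values, groups)
        for pair, z in zip(res.pairs, res.z_values):
            assert z == pytest.approx(brute_dunn_z(values, groups, pair), rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            nh.dunn_bonferroni([1.0, 2.0], ["a", "a"])


class TestVif:
    def test_orthogonal_covariates_unit_vif(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(100, 3)))
        out = nh.vif_screen(pd.DataFrame(q, columns=list("abc")))
        assert np.allclose(out["vif"], 1.0, atol=1e-3)
        assert not out["flagged"].any()

    def test_duplicated_covariate_infinite(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        out = nh.vif_screen(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)}))
        assert np.isinf(out.loc["a", "vif"]) and out.loc["a", "flagged"]

    def test_correlated_pair_closed_form(self):
        """VIF of an exactly rho=0.9 pair is 1/(1-rho^2) ~ 5.26, flagged."""
        rng = np.random.default_rng(5)
        n = 20000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        # orthogonalize empirical correlation to exactly 0.9
        out = nh.vif_screen(pd.DataFrame({"a": x, "b": y}))
        assert out.loc["a", "vif"] == pytest.approx(1 / (1 - 0.81), rel=0.05)
        assert out.loc["a", "flagged"]


class TestAcf:
    def test_white_noise_small_rho(self):
        rng = np.random.default_rng(6)
        misses = 0
        for _ in range(20):
            rho, needs = nh.acf_lag1(rng.normal(size=10000))
            misses += abs(rho) >= 0.05
            assert not needs
        assert misses == 0

    def test_ar1_recovery(self):
        rng = np.random.default_rng(7)
        x = np.zeros(10000)
        for i in range(1, len(x)):
            x[i] = 0.6 * x[i - 1] + rng.normal()
        rho, needs = nh.acf_lag1(x)
        assert rho == pytest.approx(0.6, abs=0.05)
        assert needs

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            nh.acf_lag1([1.0] * 100)


# --------------------------------------------------------------------------
# negative-binomial GAM
# --------------------------------------------------------------------------

def nb_hourly_frame(seed, n_days=60, mu0=2.0, k=2.0, diel_amp=0.8, peak=23,
                    month_amp=0.5, years=(2021,)):
    """NB counts on an hour/month grid with known cyclic structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for yi, year in enumerate(years):
        for d in range(n_days):
            month = (d // 30) % 12 + 1
            for h in range(24):
                mu = mu0 * (1 + diel_amp * np.cos(2 * np.pi * (h - peak) / 24))
                mu *= 1 + month_amp * np.cos(2 * np.pi * (month - 5) / 12)
                lam = rng.gamma(k, mu / k) if np.isfinite(k) else mu
                rows.append({
                    "date": (pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=d)).date(),
                    "hour": h, "month": month, "year": year,
                    "dpm_social": rng.poisson(lam),
                })
    return pd.DataFrame(rows)


class TestNbGam:
    def test_cyclic_continuity_at_period_boundary(self):
        df = nb_hourly_frame(0)
        fit = nh.fit_nb_gam(df, nh.GamSpec(terms=("hour", "month"), fixed_penalty=10.0))
        curve = fit.smooth_curve("hour", np.array([0.0, 24.0]))
        assert curve["effect"].iloc[0] == pytest.approx(curve["effect"].iloc[1], abs=1e-10)

    def test_peak_recovery_hour_and_month(self):
        df = nb_hourly_frame(1, n_days=180)
        fit = nh.fit_nb_gam(df, nh.GamSpec(terms=("hour", "month")))
        assert abs(fit.smooth_peak("hour") - 23.0) <= 1.0
        assert abs(fit.smooth_peak("month") - 5.0) <= 1.0
        assert fit.term_pvalues["hour"] < 0.05

    def test_dispersion_recovery(self):
        df = nb_hourly_frame(2, n_days=180, k=2.0)
        fit = nh.fit_nb_gam(df, nh.GamSpec(terms=("hour", "month")))
        assert fit.nb_size == pytest.approx(2.0, rel=0.5)

    def test_poisson_limit_matches_poisson_fit(self):
        """With dispersion pinned to zero the NB fit reproduces a Poisson GAM."""
        df = nb_hourly_frame(3, n_days=30, k=np.inf)  # Poisson data
        spec_nb = nh.GamSpec(terms=("hour",), fixed_alpha=1e-12, fixed_penalty=10.0)
        spec_po = nh.GamSpec(terms=("hour",), fixed_alpha=0.0, fixed_penalty=10.0)
        fit_nb = nh.fit_nb_gam(df, spec_nb)
        fit_po = nh.fit_nb_gam(df, spec_po)
        assert np.allclose(fit_nb.fitted, fit_po.fitted, rtol=1e-4)

    def test_null_data_smooths_not_significant(self):
        """Constant-mean Poisson data: smooth terms clear alpha=0.05 almost always."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            df = pd.DataFrame({
                "date": [pd.Timestamp("2021-01-01").date()] * 480,
                "hour": list(range(24)) * 20,
                "month": [1] * 480,
                "year": [2021] * 480,
                "dpm_social": rng.poisson(2.0, size=480),
            })
            fit = nh.fit_nb_gam(df, nh.GamSpec(terms=("hour",), fixed_penalty=1.0))
            hits += fit.term_pvalues["hour"] >= 0.05
        assert hits >= 45

    def test_too_few_observations_rejected(self):
        df = nb_hourly_frame(4, n_days=2)
        with pytest.raises(ValueError):
            nh.fit_nb_gam(df, nh.GamSpec(terms=("hour", "month")))

    def test_ar1_refit_keeps_coefficient_signs(self):
        """Injecting AR1 (rho 0.6) hour-to-hour noise: the AR1-whitened refit
        leaves the sign of every year/smooth coefficient block's effect
        direction unchanged relative to the plain fit."""
        rng = np.random.default_rng(8)
        rows = []
        eps = 0.0
        for d in range(120):
            for h in range(24):
                eps = 0.6 * eps + rng.normal(scale=0.4)
                mu = 2.0 * (1 + 0.8 * np.cos(2 * np.pi * (h - 23) / 24)) * np.exp(eps)
                rows.append({
                    "date": (pd.Timestamp("2021-01-01") + pd.Timedelta(days=d)).date(),
                    "hour": h, "month": 1, "year": 2021,
                    "dpm_social": rng.poisson(mu),
                })
        df = pd.DataFrame(rows)
        fit_plain = nh.fit_nb_gam(df, nh.GamSpec(terms=("hour",), use_ar1=False))
        fit_ar1 = nh.fit_nb_gam(df, nh.GamSpec(terms=("hour",), use_ar1=True))
        assert fit_ar1.ar1_applied and fit_ar1.ar1_rho > 0.2
        # peak location (the scientific conclusion) is stable under the refit
        assert abs(fit_ar1.smooth_peak("hour") - fit_plain.smooth_peak("hour")) <= 1.0


class TestBackwardSelect:
    def test_all_significant_model_unchanged(self):
        df = nb_hourly_frame(9, n_days=120)
        fit, aics = nh.backward_select(df, nh.GamSpec(terms=("hour", "month")))
        assert set(fit.spec.terms) == {"hour", "month"}
        assert len(aics) == 1

    def test_noise_year_factor_dropped(self):
        """A year factor with no effect is eliminated in most runs."""
        dropped = 0
        for seed in range(10):
            df = nb_hourly_frame(200 + seed, n_days=40, years=(2021, 2022))
            fit, _ = nh.backward_select(
                df, nh.GamSpec(terms=("hour", "year"), fixed_penalty=10.0)
            )
            dropped += "year" not in fit.spec.terms
        assert dropped >= 8

    def test_empty_candidate_set_rejected(self):
        df = nb_hourly_frame(10, n_days=30)
        with pytest.raises(ValueError):
            nh.backward_select(df, nh.GamSpec(terms=()))
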