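"""Width-feedback growth law, fixed points, lineages, MT pipeline."""
import numpy as np
import pytest

import pombetip as pt
from pombetip.stability import NoFixedPointError, division_map


def closed_form_linearized(w_init, L, w0, L0, beta, gamma, alpha_sigma0_is_w0=True):
    """Independent closed-form solution of the linearized growth law.

    For sigma = (w0/alpha)[1 + beta (w-w0)/w0 + gamma (L-L0)/L0] the
    deviation x = w - w0 obeys x' - (beta-1) x / L = gamma (w0/L0)(L-L0)/L,
    solved with an integrating factor (valid for beta not in {1, 2}).
    """
    b = beta
    g = gamma
    c = g * w0 / L0

    def antider(ell):
        return c * (ell ** (2 - b) / (2 - b) - L0 * ell ** (1 - b) / (1 - b))

    x0 = w_init - w0
    return w0 + L ** (b - 1) * (x0 * L0 ** (1 - b) + antider(L) - antider(L0))


def linearized_model(beta=0.5, gamma=0.0, w0=3.2, alpha=3.2):
    return pt.SignalWidthModel(
        form="linearized", sigma0=w0 / alpha, beta=beta, gamma=gamma,
        w0=w0, alpha=alpha,
    )


class TestGrowthLaw:
    def test_constant_sigma_exact_fixed_width(self):
        m = pt.SignalWidthModel(form="constant", sigma0=1.0, alpha=3.2, w0=3.2)
        sol = pt.integrate_mean_width(m, 3.2, 8.0, 16.0)
        assert np.allclose(sol.y[0], 3.2, rtol=1e-10)

    @pytest.mark.parametrize("beta,gamma", [(0.5, 0.1), (-0.4, -0.15), (0.9, 0.2),
                                            (1.5, 0.05)])
    def test_matches_closed_form(self, beta, gamma):
        m = linearized_model(beta, gamma)
        w_init = 1.06 * m.w0
        sol = pt.integrate_mean_width(m, w_init, m.L0, 2 * m.L0)
        L = np.linspace(m.L0, 2 * m.L0, 30)
        numeric = sol.sol(L)[0]
        exact = closed_form_linearized(w_init, L, m.w0, m.L0, beta, gamma)
        assert np.max(np.abs(numeric / exact - 1)) < 1e-6

    def test_gamma_sign_flips_interior_extremum(self):
        # starting on the division-map fixed point, the trajectory w(L)
        # returns to w* at division, passing through an interior minimum
        # for gamma > 0 and an interior maximum for gamma < 0
        for gamma, kind in [(0.15, "min"), (-0.15, "max")]:
            m = linearized_model(beta=0.5, gamma=gamma)
            w_star = pt.fixed_point(m)
            sol = pt.integrate_mean_width(m, w_star, m.L0, 2 * m.L0)
            L = np.linspace(m.L0, 2 * m.L0, 200)
            w = sol.sol(L)[0]
            i = int(np.argmax(w) if kind == "max" else np.argmin(w))
            assert 0 < i < L.size - 1, f"no interior {kind} for gamma={gamma}"


class TestFixedPoint:
    def test_constant_model_closed_form(self):
        m = pt.SignalWidthModel(form="constant", sigma0=1.1, alpha=3.0, w0=3.2)
        assert pt.fixed_point(m) == pytest.approx(3.3, rel=1e-12)

    def test_gamma_zero_linearized_fixed_point_is_w0(self):
        m = linearized_model(beta=0.6, gamma=0.0)
        assert pt.fixed_point(m) == pytest.approx(m.w0, rel=1e-9)

    def test_against_bisection_scan_of_division_map(self):
        m = linearized_model(beta=0.7, gamma=0.1)
        w_star = pt.fixed_point(m)
        # brute-force bisection on the diagonal crossing
        lo, hi = 0.5 * m.w0, 2.0 * m.w0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if division_map(m, mid) - mid > 0:
                lo = mid
            else:
                hi = mid
        assert abs(w_star - 0.5 * (lo + hi)) < 1e-6

    def test_self_consistency_one_generation(self):
        m = linearized_model(beta=0.7, gamma=0.08)
        w_star = pt.fixed_point(m)
        assert division_map(m, w_star) == pytest.approx(w_star, abs=1e-6)


class TestStabilityBeta:
    def test_geometric_mt_beta_closed_form(self):
        w0 = 3.2
        for delta in (0.2, 0.5, 1.0):
            m = pt.SignalWidthModel(
                form="geometric_mt", w0=w0, delta_mt=delta, alpha=3.2
            )
            beta_eff, stable, mult = pt.stability_beta(m)
            assert beta_eff == pytest.approx(w0 / (w0 - 2 * delta), rel=1e-9)
            assert beta_eff > 1.0 and not stable

    def test_geometric_mt_marginal_at_zero_offset(self):
        m = pt.SignalWidthModel(form="geometric_mt", w0=3.2, delta_mt=0.0, alpha=3.2)
        beta_eff, stable, mult = pt.stability_beta(m)
        assert beta_eff == pytest.approx(1.0, abs=1e-9)

    def test_finite_difference_derivative_matches_analytic(self):
        m = linearized_model(beta=0.8, gamma=0.0)
        w = 1.03 * m.w0
        fd = (m(w + 1e-6) - m(w - 1e-6)) / 2e-6
        assert abs(fd - m.dsigma_dw(w)) < 1e-8

    @pytest.mark.parametrize("beta", [0.3, 0.7, 1.3, 2.0])
    @pytest.mark.parametrize("gamma", [-0.1, 0.0, 0.1])
    def test_division_map_contraction_iff_beta_below_one(self, beta, gamma):
        m = linearized_model(beta=beta, gamma=gamma)
        beta_eff, stable, mult = pt.stability_beta(m)
        assert stable == (beta < 1.0)
        assert (abs(mult) < 1.0) == stable
        # linearized gamma-free theory predicts multiplier 2^(beta-1)
        if gamma == 0.0:
            assert mult == pytest.approx(2.0 ** (beta - 1.0), rel=1e-4)


class TestLineage:
    def test_unstable_lineage_diverges_over_11_generations(self):
        m = linearized_model(beta=1.5, gamma=0.02)
        w_star = pt.fixed_point(m)
        gens = pt.simulate_lineage(m, 1.05 * w_star, 11)
        widths = [g[0].birth_width for g in gens]
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_stable_lineage_converges_back(self):
        m = linearized_model(beta=0.5, gamma=0.0)
        w_star = pt.fixed_point(m)
        gens = pt.simulate_lineage(m, 1.3 * w_star, 11)
        errs = [abs(g[0].birth_width - w_star) for g in gens]
        assert all(b < a for a, b in zip(errs, errs[1:]))

    def test_constant_signal_uniform_width_from_second_generation(self):
        m = pt.SignalWidthModel(form="constant", sigma0=1.0, alpha=3.2, w0=3.2)
        gens = pt.simulate_lineage(m, 4.0, 3)
        # by generation 2 the tracked (new-end) daughter is all new material
        cell = gens[2][0]
        assert np.allclose(cell.seg_widths, 3.2, rtol=1e-9)

    def test_division_conserves_length(self):
        m = linearized_model(beta=0.7, gamma=0.1)
        gens = pt.simulate_lineage(m, 3.4, 4, track_both=True)
        for cells in gens[1:]:
            for c in cells:
                assert c.birth_length == pytest.approx(m.L0, rel=1e-9)

    def test_bipolar_and_monopolar_share_mean_field_division_width(self):
        # the growth law depends only on (mean width, length), so the
        # mother's mean width at division is polarity-independent
        m = linearized_model(beta=0.5, gamma=0.0)
        g_mono = pt.simulate_lineage(m, 3.4, 1, mode="monopolar", track_both=True)
        g_bi = pt.simulate_lineage(m, 3.4, 1, mode="bipolar", track_both=True)

        def division_mean(cells):
            total = sum(c.birth_length for c in cells)
            return sum(c.birth_width * c.birth_length for c in cells) / total

        assert division_mean(g_mono[1]) == pytest.approx(
            division_mean(g_bi[1]), rel=1e-9
        )


class TestMTPipeline:
    def test_sample_determinism_under_seed(self):
        fn = lambda w, L: 1.0
        s1 = pt.synth_mt_tips(fn, 3.2, 8.0, 500, seed=42)
        s2 = pt.synth_mt_tips(fn, 3.2, 8.0, 500, seed=42)
        assert np.array_equal(s1.contact_positions, s2.contact_positions)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning):
            pt.synth_mt_tips(lambda w, L: 1.0, 3.2, 8.0, 30, seed=0)

    @pytest.mark.parametrize("sigma", [0.3, 1.0, 2.0])
    def test_parameter_recovery_within_three_se(self, sigma):
        n = 10_000
        sample = pt.synth_mt_tips(lambda w, L: sigma, 3.2, 8.0, n, seed=7)
        fit, _ = pt.mt_tip_histogram_fit(sample)
        se = sigma / np.sqrt(2 * n)  # Gaussian-scale standard error
        assert abs(fit - sigma) < 3 * se * 4  # binning inflates the error

    def test_bin_width_robustness(self):
        sample = pt.synth_mt_tips(lambda w, L: 1.0, 3.2, 8.0, 20_000, seed=3)
        f1, _ = pt.mt_tip_histogram_fit(sample, bin_width=0.25)
        f2, _ = pt.mt_tip_histogram_fit(sample, bin_width=0.125)
        assert abs(f1 - f2) < 0.02 * f1

    def test_scale_family(self):
        s1 = pt.synth_mt_tips(lambda w, L: 0.7, 3.2, 8.0, 20_000, seed=11)
        s2 = pt.synth_mt_tips(lambda w, L: 1.4, 3.2, 8.0, 20_000, seed=11)
        f1, _ = pt.mt_tip_histogram_fit(s1)
        f2, _ = pt.mt_tip_histogram_fit(s2)
        assert f2 / f1 == pytest.approx(2.0, rel=0.05)


class TestWidthCurveAnalysis:
    def test_geometric_form_recovered_from_tabulated_curve(self):
        w0, alpha, delta = 3.2, 3.2, 0.5
        m = pt.SignalWidthModel(form="geometric_mt", w0=w0, delta_mt=delta, alpha=alpha)
        w_grid = np.linspace(1.5, 5.0, 30)
        sigma = np.array([m(w) for w in w_grid])
        curve = pt.mt_width_curve_analysis(w_grid, sigma, alpha)
        assert curve.intersection_diameter == pytest.approx(w0, rel=1e-6)
        assert curve.beta_at_intersection == pytest.approx(
            w0 / (w0 - 2 * delta), rel=1e-3
        )

    def test_constant_curve_beta_zero_stable(self):
        w_grid = np.linspace(2.0, 6.0, 20)
        curve = pt.mt_width_curve_analysis(w_grid, np.full(20, 1.0), alpha=3.2)
        assert curve.beta_at_intersection == pytest.approx(0.0, abs=1e-9)
        assert curve.stable

    def test_no_intersection_reported_not_fatal(self):
        w_grid = np.linspace(2.0, 6.0, 20)
        curve = pt.mt_width_curve_analysis(w_grid, np.full(20, 10.0), alpha=3.2)
        assert curve.intersection_diameter is None
        assert curve.stable is None

    def test_unfocusing_curve_unstable_at_physiological_alpha(self):
        w, s = pt.synthetic_mt_unfocusing_curve()
        for alpha in (2.89, 3.22):
            curve = pt.mt_width_curve_analysis(w, s, alpha)
            assert curve.intersection_diameter is not None
            assert curve.intersection_diameter > 7.0  # in the spike region
            assert curve.beta_at_intersection > 1.0
        # beta(alpha) eventually drops below one at much larger alpha
        betas = pt.beta_versus_alpha(w, s, np.linspace(10, 30, 9))
        stable_alphas = [
            c.alpha for c in betas if c.beta_at_intersection is not None
            and c.beta_at_intersection < 1
        ]
        assert stable_alphas and min(stable_alphas) > 5.0

    def test_fixed_point_error_when_no_root(self):
        m = pt.SignalWidthModel(
            form="linearized", sigma0=10.0, beta=0.0, gamma=0.0, w0=3.2, alpha=3.2
        )
        # sigma so large the map has no crossing inside the bracket
        with pytest.raises(NoFixedPointError):
            pt.fixed_point(m, bracket=(0.5, 3.0))
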