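import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from neqsel import (
    GAS_CONSTANT,
    WorkSet,
    bar,
    bootstrap_se,
    cgi,
    estimate_all,
    jarzynski,
    sample_crooks_gaussian,
)
from neqsel.exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
)

RT298 = GAS_CONSTANT * 298.15


def bennett_residual_oracle(dg, wf, wr, beta):
    """Independent Bennett residual, written from the Fermi-function form."""
    nf, nr = len(wf), len(wr)
    term_f = np.sum(1.0 / (1.0 + (nf / nr) * np.exp(beta * (np.asarray(wf) - dg))))
    term_r = np.sum(1.0 / (1.0 + (nr / nf) * np.exp(beta * (np.asarray(wr) + dg))))
    return term_f - term_r


def bar_grid_oracle(ws, resolution=2001):
    """Dense grid-search minimizer of the squared Bennett residual."""
    lo = min(ws.forward.min(), (-ws.reverse).min()) - 30.0
    hi = max(ws.forward.max(), (-ws.reverse).max()) + 30.0
    grid = np.linspace(lo, hi, resolution)
    res = [bennett_residual_oracle(g, ws.forward, ws.reverse, ws.beta) ** 2 for g in grid]
    # refine around the coarse minimum
    i = int(np.argmin(res))
    fine = np.linspace(grid[max(i - 1, 0)], grid[min(i + 1, resolution - 1)], 20001)
    fres = [bennett_residual_oracle(g, ws.forward, ws.reverse, ws.beta) ** 2 for g in fine]
    return fine[int(np.argmin(fres))]


def bar_self_consistent_oracle(ws, iters=200):
    """Independent BAR via damped fixed-point iteration of the Bennett ratio.

    dG update: dG' = dG + (1/beta) * ln(sum_F f / sum_R f) with Fermi
    weights evaluated at the current dG; converges to the same root the
    production solver brackets.
    """
    beta = ws.beta
    wf, wr = ws.forward, ws.reverse
    nf, nr = wf.size, wr.size
    m = np.log(nf / nr)
    dg = float(np.mean(wf) - np.mean(wr)) / 2.0
    for _ in range(iters):
        num = np.sum(expit(-(m + beta * (wf - dg))))
        den = np.sum(expit(-(-m + beta * (wr + dg))))
        dg = dg + np.log(den / num) / beta
    return dg


class TestJarzynski:
    def test_single_sample_identity(self):
        ws = WorkSet(forward=[5.0], reverse=[])
        assert jarzynski(ws, "forward").dG == pytest.approx(5.0, abs=1e-12)

    def test_degenerate_distribution(self):
        ws = WorkSet(forward=[3.3] * 7, reverse=[])
        assert jarzynski(ws, "forward").dG == pytest.approx(3.3, abs=1e-12)

    def test_gaussian_analytic_limit(self):
        """<exp(-bW)> over N(mu, s^2) gives dG = mu - b*s^2/2 = 10 exactly."""
        rng = np.random.default_rng(21)
        mu = 10.0 + 4.0 / (2.0 * RT298)
        ws = WorkSet(forward=rng.normal(mu, 2.0, 10**5), reverse=[])
        assert jarzynski(ws, "forward").dG == pytest.approx(10.0, abs=0.2)

    def test_reverse_negates_reverse_process(self):
        ws = WorkSet(forward=[], reverse=[4.0])
        # one reverse work of +4 means the reverse process costs 4, so the
        # forward free energy difference is -4
        assert jarzynski(ws, "reverse").dG == pytest.approx(-4.0, abs=1e-12)

    def test_combined_is_mean_of_sides(self):
        ws = WorkSet(forward=[6.0], reverse=[-4.0])
        est = jarzynski(ws, "combined")
        assert est.dG == pytest.approx(5.0, abs=1e-12)
        assert est.method == "JAR"

    def test_missing_direction_raises(self):
        ws = WorkSet(forward=[1.0], reverse=[])
        with pytest.raises(InsufficientDataError):
            jarzynski(ws, "reverse")
        with pytest.raises(InsufficientDataError):
            jarzynski(ws, "combined")

    def test_overflow_free_at_large_beta_w(self):
        ws = WorkSet(forward=[4000.0, 4010.0], reverse=[])
        est = jarzynski(ws, "forward")
        # naive exp(-beta*4000) underflows to 0; log-sum-exp keeps the
        # exact value, which lies just above the smaller work
        assert np.isfinite(est.dG)
        assert 4000.0 < est.dG < 4010.0
        assert est.dG == pytest.approx(4001.675, abs=0.01)


class TestCGI:
    def test_equal_variance_midpoint(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0.0, 1.0, 400)
        # identical shapes shifted to means 12 (forward) and -8 (reverse,
        # own sign): equal variances => midpoint of 12 and 8 exactly
        ws = WorkSet(forward=12.0 + 2 * base, reverse=-(8.0 + 2 * base))
        m_f, m_r = ws.forward.mean(), (-ws.reverse).mean()
        assert cgi(ws).dG == pytest.approx(0.5 * (m_f + m_r), abs=1e-12)

    def test_unequal_variance_matches_density_scan(self):
        """CGI root equals a dense numeric intersection of the two fitted pdfs."""
        rng = np.random.default_rng(4)
        ws = WorkSet(
            forward=rng.normal(12.0, 2.0, 3000),
            reverse=-rng.normal(8.0, 1.0, 3000),
        )
        m_f, v_f = ws.forward.mean(), ws.forward.var(ddof=1)
        neg = -ws.reverse
        m_r, v_r = neg.mean(), neg.var(ddof=1)
        grid = np.linspace(m_r, m_f, 2_000_001)
        lp_f = -0.5 * np.log(2 * np.pi * v_f) - (grid - m_f) ** 2 / (2 * v_f)
        lp_r = -0.5 * np.log(2 * np.pi * v_r) - (grid - m_r) ** 2 / (2 * v_r)
        crossing = grid[np.argmin(np.abs(lp_f - lp_r))]
        assert cgi(ws).dG == pytest.approx(crossing, abs=(m_f - m_r) / 2_000_000 * 2)

    def test_antisymmetric_under_direction_swap(self):
        rng = np.random.default_rng(5)
        ws = WorkSet(forward=rng.normal(11, 2, 100), reverse=rng.normal(-9, 3, 100))
        assert cgi(ws.swapped()).dG == pytest.approx(-cgi(ws).dG, abs=1e-10)

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientDataError):
            cgi(WorkSet(forward=[1.0], reverse=[1.0, 2.0]))

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.raises(DegenerateFitError):
            cgi(WorkSet(forward=[5.0, 5.0], reverse=[-1.0, -1.0]))

    def test_zero_variance_equal_means_returns_mean(self):
        ws = WorkSet(forward=[5.0, 5.0], reverse=[-5.0, -5.0])
        assert cgi(ws).dG == pytest.approx(5.0, abs=1e-12)


class TestBAR:
    def test_degenerate_crooks_consistent_case(self):
        ws = WorkSet(forward=[7.5] * 4, reverse=[-7.5] * 4)
        assert bar(ws).dG == pytest.approx(7.5, abs=1e-7)

    def test_recovers_truth_on_gaussian_samples(self):
        ws = sample_crooks_gaussian(10.0, 2.0, 2000, 2000, seed=6)
        est = bar(ws)
        se = bootstrap_se(ws, "BAR", n_boot=100, seed=0)
        assert est.dG == pytest.approx(10.0, abs=3 * se)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_grid_search_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        nf, nr = rng.integers(2, 11, size=2)
        ws = WorkSet(
            forward=rng.normal(8, 3, nf),
            reverse=rng.normal(-6, 2, nr),
            temperature=298.15,
        )
        assert bar(ws, tol=1e-10).dG == pytest.approx(bar_grid_oracle(ws), abs=1e-4)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_independent_self_consistent_iteration(self, seed):
        ws = sample_crooks_gaussian(5.0, 2.5, 150, 120, seed=seed)
        assert bar(ws, tol=1e-12).dG == pytest.approx(
            bar_self_consistent_oracle(ws), abs=1e-6
        )

    def test_residual_strictly_monotone(self, rng):
        ws = WorkSet(forward=rng.normal(5, 4, 30), reverse=rng.normal(-3, 4, 25))
        grid = np.linspace(-40, 50, 400)
        res = [bennett_residual_oracle(g, ws.forward, ws.reverse, ws.beta) for g in grid]
        assert np.all(np.diff(res) > 0)

    def test_requires_both_directions(self):
        with pytest.raises(InsufficientDataError):
            bar(WorkSet(forward=[1.0], reverse=[]))


class TestBootstrap:
    def test_degenerate_works_have_zero_se(self):
        ws = WorkSet(forward=[2.0] * 10, reverse=[-2.0] * 10)
        assert bootstrap_se(ws, "BAR", n_boot=50, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_same_se(self, gaussian_workset):
        a = bootstrap_se(gaussian_workset, "CGI", n_boot=60, seed=5)
        b = bootstrap_se(gaussian_workset, "CGI", n_boot=60, seed=5)
        assert a == b

    def test_se_shrinks_with_sample_size(self):
        """Bootstrap SE scales roughly 1/sqrt(n): ratio near 2 for n=50 vs 200."""
        ses = {n: [] for n in (50, 200)}
        for seed in range(20):
            for n in (50, 200):
                ws = sample_crooks_gaussian(10.0, 2.0, n, n, seed=1000 + seed)
                ses[n].append(bootstrap_se(ws, "BAR", n_boot=60, seed=seed))
        ratio = np.mean(ses[50]) / np.mean(ses[200])
        assert 1.5 < ratio < 2.7

    def test_invalid_n_boot(self, gaussian_workset):
        with pytest.raises(InvalidParameterError):
            bootstrap_se(gaussian_workset, "BAR", n_boot=1, seed=0)


class TestEstimateAll:
    def test_both_directions_give_three_estimates(self, gaussian_workset):
        estimates, skipped = estimate_all(gaussian_workset)
        assert [e.method for e in estimates] == ["JAR", "CGI", "BAR"]
        assert skipped == {}

    def test_forward_only_gates_two_sided_methods(self):
        ws = WorkSet(forward=[1.0, 2.0, 3.0], reverse=[])
        estimates, skipped = estimate_all(ws)
        assert [e.method for e in estimates] == ["JAR_forward"]
        assert set(skipped) == {"CGI", "BAR"}

    def test_degenerate_set_all_methods_agree(self):
        ws = WorkSet(forward=[4.0] * 5, reverse=[-4.0] * 5)
        estimates, _ = estimate_all(ws)
        assert len(estimates) == 3
        for est in estimates:
            assert est.dG == pytest.approx(4.0, abs=1e-7)

    def test_bootstrap_attaches_ses(self, gaussian_workset):
        estimates, _ = estimate_all(gaussian_workset, n_boot=30, seed=2)
        assert all(e.se is not None and e.se >= 0 for e in estimates)


class TestEstimatorProperties:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(-20, 20), st.floats(0.5, 4.0))
    def test_antisymmetry(self, seed, dg, sigma):
        """Swapping direction roles negates JAR-combined, CGI and BAR."""
        ws = sample_crooks_gaussian(dg, sigma, 25, 25, seed=seed)
        sw = ws.swapped()
        assert jarzynski(sw).dG == pytest.approx(-jarzynski(ws).dG, abs=1e-10)
        assert cgi(sw).dG == pytest.approx(-cgi(ws).dG, abs=1e-10)
        assert bar(sw, tol=1e-12).dG == pytest.approx(-bar(ws, tol=1e-12).dG, abs=1e-8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(-30, 30))
    def test_shift_equivariance(self, seed, shift):
        """W_F + c, W_R - c shifts every estimate by exactly +c."""
        ws = sample_crooks_gaussian(4.0, 2.0, 20, 20, seed=seed)
        shifted = WorkSet(
            forward=ws.forward + shift,
            reverse=ws.reverse - shift,
            temperature=ws.temperature,
        )
        for f in (jarzynski, cgi, bar):
            assert f(shifted).dG == pytest.approx(f(ws).dG + shift, abs=1e-8)

    def test_gaussian_consistency(self):
        """CGI/BAR deviate from truth by <= 0.5 kJ/mol on average at n=200."""
        devs = {"CGI": [], "BAR": []}
        for seed in range(50):
            ws = sample_crooks_gaussian(10.0, 2.0, 200, 200, seed=seed)
            devs["CGI"].append(cgi(ws).dG - 10.0)
            devs["BAR"].append(bar(ws).dG - 10.0)
        assert abs(np.mean(devs["CGI"])) <= 0.5
        assert abs(np.mean(devs["BAR"])) <= 0.5

    def test_one_sided_jar_bias_signs_and_decay(self):
        """Wide work distributions make the one-sided Jarzynski bias visible:
        positive for forward, negative for reverse, shrinking with n."""
        bias = {}
        for n in (20, 200):
            jf, jr = [], []
            for seed in range(50):
                ws = sample_crooks_gaussian(10.0, 5.0, n, n, seed=3000 + seed)
                jf.append(jarzynski(ws, "forward").dG - 10.0)
                jr.append(jarzynski(ws, "reverse").dG - 10.0)
            bias[n] = (np.mean(jf), np.mean(jr))
        assert bias[20][0] > 0 and bias[200][0] > 0
        assert bias[20][1] < 0 and bias[200][1] < 0
        assert bias[200][0] < bias[20][0]
        assert bias[200][1] > bias[20][1]
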