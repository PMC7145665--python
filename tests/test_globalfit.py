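"""Constrained global fitting and confidence-contour identifiability."""

import numpy as np
import lmfit
import pytest

from polbkin import (
    AmplitudeModel,
    NoiseModel,
    RateParameters,
    SchemeGlobalFit,
    standard_policy,
    generate_stopped_flow_dataset,
    fitspace_threshold,
)
from polbkin.globalfit import Constraint, ParameterConstraints, profile_objective, profile_interval


CONCS = [2.0, 10.0, 50.0]


def small_dataset(params, sigma=0.0, seed=0, concs=CONCS, **kw):
    traces, _ = generate_stopped_flow_dataset(
        params, AmplitudeModel(), concs, noise=NoiseModel(sigma=sigma), seed=seed,
        n_points=60, **kw,
    )
    return traces


@pytest.fixture(scope="module")
def fast_params():
    return RateParameters(
        KD_dNTP=10.0, kon_dNTP=100.0, k2f=120.0, k2r=3.0,
        k3f=30.0, k3r=10.0, k4f=8.0, k5f=15.0,
    )


class TestConstraints:
    def test_fixed_needs_value(self):
        with pytest.raises(ValueError, match="needs a value"):
            Constraint("fixed")

    def test_bounds_ordering(self):
        with pytest.raises(ValueError, match="lo < hi"):
            Constraint("bounded", lo=2.0, hi=1.0)

    def test_at_least_one_free(self):
        with pytest.raises(ValueError, match="at least one"):
            ParameterConstraints({"k2f": Constraint("fixed", value=1.0)})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameters"):
            ParameterConstraints({"k9f": Constraint("free")})


class TestGlobalFit:
    def test_noiseless_data_from_truth_converges_immediately(self, fast_params):
        traces = small_dataset(fast_params)
        policy = standard_policy(
            fast_params.KD_dNTP, fast_params.k2r, fast_params.k3r
        )
        res = SchemeGlobalFit(traces, policy, fast_params).fit(multistart=1)
        assert res.success
        assert res.chisqr <= res.objective_at_init + 1e-9
        for name in ("k2f", "k3f", "k4f", "k5f"):
            assert getattr(res.estimates, name) == pytest.approx(
                getattr(fast_params, name), rel=1e-4
            )

    def test_fixed_parameters_returned_exactly(self, fast_params):
        traces = small_dataset(fast_params, sigma=0.02, seed=2)
        policy = standard_policy(fast_params.KD_dNTP, fast_params.k2r, fast_params.k3r)
        res = SchemeGlobalFit(traces, policy, fast_params).fit(multistart=1)
        assert res.estimates.KD_dNTP == fast_params.KD_dNTP
        assert res.estimates.k2r == fast_params.k2r
        assert res.estimates.k3r == fast_params.k3r
        assert res.estimates.k4r == 0.0

    def test_descent_and_fixed_point_contracts(self, fast_params):
        traces = small_dataset(fast_params, sigma=0.02, seed=5)
        policy = standard_policy(fast_params.KD_dNTP, fast_params.k2r, fast_params.k3r)
        init = fast_params.replace(k2f=300.0, k3f=10.0)
        res = SchemeGlobalFit(traces, policy, init).fit(multistart=1)
        assert res.chisqr <= res.objective_at_init
        # refit from the solution reproduces it
        res2 = SchemeGlobalFit(traces, policy, res.estimates).fit(multistart=1)
        for name in ("k2f", "k3f", "k4f", "k5f"):
            assert getattr(res2.estimates, name) == pytest.approx(
                getattr(res.estimates, name), rel=1e-4
            )

    def test_noisy_recovery_within_3se(self, fast_params):
        traces = small_dataset(fast_params, sigma=0.02, seed=8)
        policy = standard_policy(fast_params.KD_dNTP, fast_params.k2r, fast_params.k3r)
        init = fast_params.replace(k2f=2 * fast_params.k2f, k3f=fast_params.k3f / 2)
        res = SchemeGlobalFit(traces, policy, init).fit(multistart=3, seed=0)
        assert abs(res.estimates.k2f - fast_params.k2f) <= 3 * max(
            res.bse["k2f"], 1e-12
        )

    def test_single_concentration_warns(self, fast_params):
        traces = small_dataset(fast_params, concs=[10.0])
        policy = standard_policy(fast_params.KD_dNTP, fast_params.k2r, fast_params.k3r)
        with pytest.warns(UserWarning, match="fewer than 2"):
            SchemeGlobalFit(traces, policy, fast_params)

    def test_missing_conc_metadata_rejected(self, fast_params):
        traces = small_dataset(fast_params)
        del traces[0].meta["dntp_conc"]
        policy = standard_policy(fast_params.KD_dNTP, fast_params.k2r, fast_params.k3r)
        with pytest.raises(ValueError, match="dntp_conc"):
            SchemeGlobalFit(traces, policy, fast_params)

    def test_summary_lists_constraint_provenance(self, fast_params):
        traces = small_dataset(fast_params)
        policy = standard_policy(fast_params.KD_dNTP, fast_params.k2r, fast_params.k3r)
        res = SchemeGlobalFit(traces, policy, fast_params).fit(multistart=1)
        text = res.summary()
        assert "K_D from biochemical fit" in text
        assert "competition assay" in text
        assert "pyrophosphorolysis" in text


class TestProfiling:
    def quad_setup(self):
        """Linear-Gaussian toy: residuals linear in two parameters, so the
        profiled objective is an exact quadratic with a known covariance."""
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)])
        beta = np.array([0.5, 1.2, -0.7])
        y = X @ beta  # noiseless: minimum exactly at beta, chisqr_min = 0

        def residual(p):
            b = np.array([p["b0"].value, p["b1"].value, p["b2"].value])
            return X @ b - y

        params = lmfit.Parameters()
        for i, b in enumerate(beta):
            params.add(f"b{i}", value=float(b), vary=True)
        return X, beta, residual, params

    def test_quadratic_toy_contours_match_analytic_ellipse(self):
        X, beta, residual, params = self.quad_setup()
        H = X.T @ X  # Hessian/2 of the SSE
        grid1 = beta[1] + np.linspace(-0.3, 0.3, 7)
        grid2 = beta[2] + np.linspace(-0.3, 0.3, 7)
        obj = profile_objective(residual, params, ("b1", "b2"), grid1, grid2)
        # analytic profile: SSE(theta) = d' S d with S the Schur complement
        # of the profiled-out parameter block
        sub = np.ix_([1, 2], [1, 2])
        S = H[sub] - np.outer(H[1:3, 0], H[0, 1:3]) / H[0, 0]
        for iy, g2 in enumerate(grid2):
            for ix, g1 in enumerate(grid1):
                d = np.array([g1 - beta[1], g2 - beta[2]])
                assert obj[iy, ix] == pytest.approx(d @ S @ d, abs=1e-9)

    def test_profile_interval_matches_analytic_se(self):
        X, beta, residual, params = self.quad_setup()
        # add gaussian-ish residual floor so chisqr_min > 0 is not needed:
        # with delta_chisqr=1 the interval half-width is the usual
        # sqrt([ (X'X)^-1 ]_jj )
        lo, hi = profile_interval(residual, params, "b1", 0.0, delta_chisqr=1.0)
        cov = np.linalg.inv(X.T @ X)
        half = np.sqrt(cov[1, 1])
        assert hi - beta[1] == pytest.approx(half, rel=0.05)
        assert beta[1] - lo == pytest.approx(half, rel=0.05)

    def test_fitspace_threshold_monotone_in_alpha(self):
        t05 = fitspace_threshold(100.0, 500, 4, alpha=0.05)
        t01 = fitspace_threshold(100.0, 500, 4, alpha=0.01)
        assert t01 > t05 > 100.0

    def test_contour_map_on_mechanism_fit(self, fast_params):
        traces = small_dataset(fast_params, sigma=0.02, seed=4)
        policy = standard_policy(
            fast_params.KD_dNTP, fast_params.k2r, fast_params.k3r,
            free=("k2f", "k4f"),
        )
        res = SchemeGlobalFit(traces, policy, fast_params).fit(multistart=1)
        cmap = res.profile_pair("k2f", "k4f", grid_size=5, span_factor=3.0)
        assert cmap.objective.min() >= res.chisqr * (1 - 1e-6)
        assert cmap.threshold > res.chisqr
        # well-designed dataset: both parameters constrained
        assert cmap.constrained
        # the generating values lie inside the confidence region
        ix = np.argmin(np.abs(cmap.grid_x - fast_params.k2f))
        iy = np.argmin(np.abs(cmap.grid_y - fast_params.k4f))
        assert cmap.objective[iy, ix] <= cmap.threshold

    def test_insensitive_parameter_flagged_unconstrained(self):
        """A dataset whose window is far shorter than 1/k5f carries no
        information on k5f; the contour must say so."""
        p = RateParameters(
            KD_dNTP=10.0, kon_dNTP=100.0, k2f=120.0, k2r=3.0,
            k3f=30.0, k3r=10.0, k4f=8.0, k5f=0.01,
        )
        traces, _ = generate_stopped_flow_dataset(
            p, AmplitudeModel(), CONCS, noise=NoiseModel(sigma=0.02), seed=3,
            t_max=0.5, n_points=60,
        )
        policy = standard_policy(p.KD_dNTP, p.k2r, p.k3r, free=("k2f", "k5f"))
        res = SchemeGlobalFit(traces, policy, p).fit(multistart=1)
        with pytest.warns(UserWarning, match="not constrained"):
            cmap = res.profile_pair("k2f", "k5f", grid_size=5, span_factor=10.0)
        assert not cmap.bounded_y or not cmap.bounded_x
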