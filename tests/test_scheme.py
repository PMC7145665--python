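"""Mechanism ODE model: rate law, integration, first-passage and kobs oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

from polbkin import (
    RateParameters,
    AssayConditions,
    derivative_field,
    simulate_timecourse,
    default_time_grid,
    mean_first_passage_rate,
    predicted_kobs,
)
from polbkin.parameters import SPECIES, SPECIES_INDEX
from polbkin.scheme import rate_matrix

from conftest import random_rate_parameters


# ---------------------------------------------------------------------------
# independent mass-action oracle: explicit reaction list, assembled term by
# term, sharing no code with the implementation
# ---------------------------------------------------------------------------

def oracle_derivative(state, p: RateParameters):
    c = dict(zip(SPECIES, state))
    reactions = [
        # (rate expression, consumed species, produced species)
        (p.kon_dNTP * c["E_DNA"] * c["dNTP"], ["E_DNA", "dNTP"], ["EO"]),
        (p.kon_dNTP * p.KD_dNTP * c["EO"], ["EO"], ["E_DNA", "dNTP"]),
        (p.k2f * c["EO"], ["EO"], ["EC"]),
        (p.k2r * c["EC"], ["EC"], ["EO"]),
        (p.k3f * c["EC"], ["EC"], ["ECS"]),
        (p.k3r * c["ECS"], ["ECS"], ["EC"]),
        (p.k4f * c["ECS"], ["ECS"], ["ECP"]),
        (p.k4r * c["ECP"], ["ECP"], ["ECS"]),
        (p.k5f * c["ECP"], ["ECP"], ["EOP"]),
    ]
    d = dict.fromkeys(SPECIES, 0.0)
    for rate, consumed, produced in reactions:
        for s in consumed:
            d[s] -= rate
        for s in produced:
            d[s] += rate
    return np.array([d[s] for s in SPECIES])


class TestDerivativeField:
    def test_all_rates_zero_gives_zero_vector(self):
        p = RateParameters(KD_dNTP=1.0, kon_dNTP=1e-12)
        state = np.array([0.1, 0.02, 0.03, 0.01, 0.0, 0.0, 50.0])
        # kon cannot be exactly 0 by the invariant; with empty E_DNA/EO the
        # binding fluxes vanish exactly
        state[SPECIES_INDEX["E_DNA"]] = 0.0
        state[SPECIES_INDEX["EO"]] = 0.0
        assert np.allclose(derivative_field(state, p), 0.0)

    def test_enzyme_conservation_exact(self, rng):
        for _ in range(50):
            p = random_rate_parameters(rng)
            state = rng.uniform(0, 1, size=7)
            d = derivative_field(state, p)
            assert abs(d[:6].sum()) < 1e-12 * max(1.0, np.abs(d).max())

    def test_binary_complex_binding_term(self, wt_control):
        state = np.zeros(7)
        state[SPECIES_INDEX["E_DNA"]] = 0.2
        state[SPECIES_INDEX["dNTP"]] = 100.0
        d = derivative_field(state, wt_control)
        assert d[SPECIES_INDEX["E_DNA"]] == pytest.approx(-wt_control.kon_dNTP * 0.2 * 100.0)

    def test_matches_independent_oracle_term_by_term(self, rng):
        for _ in range(20):
            p = random_rate_parameters(rng)
            state = rng.uniform(0, 2, size=7)
            np.testing.assert_allclose(
                derivative_field(state, p), oracle_derivative(state, p), rtol=1e-12
            )

    def test_rejects_negative_concentration(self, wt_control):
        state = np.zeros(7)
        state[0] = -0.1
        with pytest.raises(ValueError, match="negative"):
            derivative_field(state, wt_control)

    def test_rejects_wrong_species_count(self, wt_control):
        with pytest.raises(ValueError, match="entries"):
            derivative_field(np.zeros(5), wt_control)


class TestSimulateTimecourse:
    def test_initial_condition_exact(self, wt_control, saturating_conditions):
        traj = simulate_timecourse(wt_control, saturating_conditions)
        y0 = traj.occupancy[0]
        assert y0[SPECIES_INDEX["E_DNA"]] == saturating_conditions.complex_total
        assert y0[SPECIES_INDEX["dNTP"]] == saturating_conditions.dntp_0
        assert np.all(y0[1:6] == 0.0)

    def test_rejects_non_monotone_grid(self, wt_control, saturating_conditions):
        with pytest.raises(ValueError, match="increasing"):
            simulate_timecourse(wt_control, saturating_conditions, [0.0, 0.2, 0.1])
        with pytest.raises(ValueError, match="start at 0"):
            simulate_timecourse(wt_control, saturating_conditions, [0.1, 0.2])

    def test_matrix_exponential_oracle_pseudo_first_order(self, rng):
        """With trace complex (no dNTP depletion) the system is linear and
        the trajectory must match expm of the rate matrix."""
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 25)])
        cond = AssayConditions(enzyme_total=1e-4, dna_total=1e-4, dntp_0=100.0)
        for _ in range(20):
            p = random_rate_parameters(rng)
            traj = simulate_timecourse(p, cond, grid, rtol=1e-10, atol=1e-14)
            A = rate_matrix(p, cond.dntp_0)
            c0 = np.zeros(6)
            c0[0] = cond.complex_total
            for i, t in enumerate(grid[1:], 1):
                ref = expm(A * t) @ c0
                np.testing.assert_allclose(
                    traj.occupancy[i, :6], ref, atol=1e-6 * cond.complex_total
                )

    def test_irreversible_chain_matches_bateman_convolution(self, wt_control):
        """Reverse rates zeroed, start in the open ternary complex: the
        cumulative product is the analytic three-step sequential solution."""
        p = wt_control.replace(k2r=0.0, k3r=0.0, KD_dNTP=1e-6)  # koff ~ 0
        ks = np.array([p.k2f, p.k3f, p.k4f])
        cond = AssayConditions(enzyme_total=0.2, dna_total=0.2, dntp_0=1e4)
        y0 = np.zeros(7)
        y0[SPECIES_INDEX["EO"]] = 0.2
        y0[SPECIES_INDEX["dNTP"]] = 1e4
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 2.0, 40)])
        traj = simulate_timecourse(p, cond, grid, y0=y0, rtol=1e-10, atol=1e-14)
        product = (traj.species("ECP") + traj.species("EOP")) / 0.2
        for i, t in enumerate(grid):
            surv = 0.0
            for j, kj in enumerate(ks):  # Bateman terms, distinct rates
                cj = np.prod([ks[m] / (ks[m] - kj) for m in range(3) if m != j])
                surv += cj * np.exp(-kj * t)
            assert product[i] == pytest.approx(1.0 - surv, abs=5e-6)

    def test_conservation_over_random_parameters(self, rng):
        cond = AssayConditions(enzyme_total=0.4, dna_total=0.2, dntp_0=20.0)
        grid = default_time_grid(t_max=10.0, n=40)
        for _ in range(10):
            p = random_rate_parameters(rng)
            traj = simulate_timecourse(p, cond, grid)
            assert traj.conservation_error() < 1e-6
            # nucleotide conservation: free + bound + consumed
            ntp_total = (
                traj.species("dNTP")
                + traj.species("EO") + traj.species("EC") + traj.species("ECS")
                + traj.species("ECP") + traj.species("EOP")
            )
            np.testing.assert_allclose(ntp_total, ntp_total[0], rtol=1e-6)

    def test_chemistry_blocked_forms_no_product(self, wt_control):
        cond = AssayConditions(dntp_0=50.0, chemistry_blocked=True)
        traj = simulate_timecourse(wt_control, cond)
        assert np.all(traj.species("ECP") == 0.0)
        assert np.all(traj.species("EOP") == 0.0)

    def test_grid_refinement_invariance(self, wt_control, saturating_conditions):
        coarse = np.linspace(0.0, 2.0, 41)
        fine = np.linspace(0.0, 2.0, 81)
        t1 = simulate_timecourse(wt_control, saturating_conditions, coarse)
        t2 = simulate_timecourse(wt_control, saturating_conditions, fine)
        scale = saturating_conditions.complex_total
        np.testing.assert_allclose(
            t1.occupancy[:, :6], t2.occupancy[::2, :6], atol=1e-5 * scale
        )


# ---------------------------------------------------------------------------
# first passage
# ---------------------------------------------------------------------------

def monte_carlo_first_passage(p: RateParameters, n_runs: int, rng) -> float:
    """Stochastic first-passage oracle: jump process EO -> ... -> ECP."""
    # states: 0=EO, 1=EC, 2=ECS, 3=ECP (absorbing)
    rates = {
        0: [(p.k2f, 1)],
        1: [(p.k2r, 0), (p.k3f, 2)],
        2: [(p.k3r, 1), (p.k4f, 3)],
    }
    state = np.zeros(n_runs, dtype=int)
    t = np.zeros(n_runs)
    alive = np.ones(n_runs, dtype=bool)
    while alive.any():
        for s, outs in rates.items():
            sel = alive & (state == s)
            if not sel.any():
                continue
            total = sum(r for r, _ in outs)
            t[sel] += rng.exponential(1.0 / total, size=sel.sum())
            u = rng.uniform(0, total, size=sel.sum())
            dest = np.full(sel.sum(), outs[-1][1])
            acc = 0.0
            for r, d in outs[:-1]:
                acc += r
                dest[u < acc] = d
                u[u < acc] = np.inf
            state[sel] = dest
        alive = state != 3
    return float(t.mean())


class TestMeanFirstPassage:
    def test_single_slow_step(self):
        p = RateParameters(k2f=1e9, k3f=1e9, k4f=5.0)
        assert mean_first_passage_rate(p) == pytest.approx(5.0, rel=1e-6)

    def test_harmonic_sum_irreversible(self):
        p = RateParameters(k2f=10.0, k3f=10.0, k4f=10.0)
        assert mean_first_passage_rate(p) == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_against_monte_carlo(self, wt_control, rng):
        mc_rate = 1.0 / monte_carlo_first_passage(wt_control, 20000, rng)
        assert mean_first_passage_rate(wt_control) == pytest.approx(mc_rate, rel=0.05)

    def test_zero_forward_rate_reported(self):
        with pytest.raises(ValueError, match="no passage"):
            mean_first_passage_rate(RateParameters(k2f=5.0, k3f=0.0, k4f=5.0))


class TestPredictedKobs:
    def test_single_step_limit(self):
        p = RateParameters(k2f=5e3, k3f=5e3, k4f=2.0, k5f=100.0, KD_dNTP=1.0)
        cond = AssayConditions(dntp_0=1000.0)
        assert predicted_kobs(p, cond) == pytest.approx(2.0, rel=0.02)

    def test_matches_slowest_eigenvalue_when_phases_separated(self):
        p = RateParameters(
            KD_dNTP=1.0, kon_dNTP=100.0, k2f=200.0, k2r=2.0,
            k3f=100.0, k3r=5.0, k4f=1.0, k5f=50.0,
        )
        cond = AssayConditions(dntp_0=500.0)
        A = rate_matrix(p, cond.dntp_0)
        eigs = np.sort(np.abs(np.linalg.eigvals(A).real))
        slowest = eigs[1]  # eigs[0] ~ 0 (absorbing product)
        assert predicted_kobs(p, cond) == pytest.approx(slowest, rel=0.05)

    def test_consistent_with_first_passage_rate(self, wt_control):
        cond = AssayConditions(dntp_0=500.0)
        kobs = predicted_kobs(wt_control, cond)
        mfpr = mean_first_passage_rate(wt_control)
        assert 0.5 < kobs / mfpr < 2.0

    def test_chemistry_blocked_rejected(self, wt_control):
        with pytest.raises(ValueError, match="blocked"):
            predicted_kobs(wt_control, AssayConditions(chemistry_blocked=True))


# hypothesis property: the rate law conserves enzyme and matches the
# independent oracle for arbitrary admissible states and rate sets
from hypothesis import given, settings, strategies as st

rate_value = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)
positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)
conc = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    kd=positive,
    kon=positive,
    rates=st.tuples(*[rate_value] * 6),
    state=st.tuples(*[conc] * 7),
)
def test_rate_law_conservation_property(kd, kon, rates, state):
    p = RateParameters(
        KD_dNTP=kd, kon_dNTP=kon,
        k2f=rates[0], k2r=rates[1], k3f=rates[2], k3r=rates[3],
        k4f=rates[4], k5f=rates[5],
    )
    y = np.asarray(state)
    d = derivative_field(y, p)
    assert abs(d[:6].sum()) <= 1e-9 * max(1.0, np.abs(d).max())
    np.testing.assert_allclose(d, oracle_derivative(y, p), rtol=1e-10, atol=1e-12)
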