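"""Unit tests for the 6-state GLT-1 kinetic scheme."""

import math

import numpy as np
import pytest

from astroglt.glt1 import (GLT1Params, IonState, NoReversalError, Occupancy,
                           RateGenerator, build_generator, find_reversal_glu,
                           integrate_occupancy, reversal_dialect_params,
                           steady_state, transporter_current_density, u_factor)

RING = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]


class TestUFactor:
    @pytest.mark.parametrize("V,P,expected", [
        (0.0, 0.5, 1.0),
        (-40.0, 0.0, 1.0),
        (53.4, 1.0, math.e),
    ])
    def test_examples(self, V, P, expected):
        assert u_factor(V, P) == pytest.approx(expected, rel=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            u_factor(float("nan"), 0.5)
        with pytest.raises(ValueError):
            u_factor(0.0, float("inf"))


class TestGenerator:
    def test_unit_concentrations_give_bare_rate(self, default_params):
        ions = IonState(na_in=1, na_out=1, k_in=1, k_out=1, glu_in=1, glu_out=1)
        gen = build_generator(0.0, ions, default_params)
        assert gen.rates[0, 1] == pytest.approx(20.0)

    def test_na_binding_rate_hand_evaluated(self, default_params, default_ions):
        # 150 mM * 0.015 /mM/ms * exp(0.5 * (-85) / 53.4), evaluated by hand
        gen = build_generator(-85.0, default_ions, default_params)
        assert gen.rates[1, 2] == pytest.approx(1.0151639, rel=1e-6)

    def test_zero_substrate_zero_rate(self, default_params):
        gen = build_generator(-60.0, IonState(glu_out=0.0), default_params)
        assert gen.rates[0, 1] == 0.0

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            IonState(glu_out=-0.1)

    @pytest.mark.parametrize("V", [-120.0, -85.0, -40.0, 0.0, 40.0])
    def test_generator_invariants(self, V, default_params):
        ions = IonState(glu_out=0.1)
        gen = build_generator(V, ions, default_params)
        Q = gen.Q
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-12 * max(1.0, np.abs(Q).max())
        allowed = set(RING) | {(j, i) for i, j in RING}
        for i in range(6):
            for j in range(6):
                if i != j and (i, j) not in allowed:
                    assert Q[i, j] == 0.0


def _generator_from_matrix(R, params, ions):
    Q = R.copy()
    np.fill_diagonal(Q, -R.sum(axis=1))
    return RateGenerator(Q=Q, V=0.0, ions=ions, params=params)


class TestSteadyState:
    def test_symmetric_ring_is_uniform(self, default_params, default_ions):
        R = np.zeros((6, 6))
        for i, j in RING:
            R[i, j] = R[j, i] = 0.7
        occ = steady_state(_generator_from_matrix(R, default_params, default_ions))
        assert np.allclose(occ.p, 1 / 6, atol=1e-12)

    def test_two_state_detailed_balance(self, default_params, default_ions):
        R = np.zeros((6, 6))
        k12, k21 = 3.0, 0.5
        R[0, 1], R[1, 0] = k12, k21
        for j in range(2, 6):  # transient states drain into the pair
            R[j, 0] = 1.0
        occ = steady_state(_generator_from_matrix(R, default_params, default_ions))
        assert occ.p[2:].max() < 1e-12
        assert occ.p[0] / occ.p[1] == pytest.approx(k21 / k12, rel=1e-9)

    def test_matches_long_time_integration(self, default_params):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ions = IonState(glu_out=float(rng.uniform(0.001, 0.5)),
                            k_out=float(rng.uniform(1, 10)))
            V = float(rng.uniform(-100, 0))
            gen = build_generator(V, ions, default_params)
            ss = steady_state(gen)
            sched = lambda t: (V, ions)
            _, traj = integrate_occupancy(ss.p * 0 + 1 / 6, sched, dt=10.0,
                                          T=1e4, params=default_params)
            assert np.max(np.abs(traj[-1] - ss.p)) < 1e-6


class TestIntegrateOccupancy:
    def test_steady_state_is_fixed_point(self, default_params):
        ions = IonState(glu_out=0.05)
        gen = build_generator(-85.0, ions, default_params)
        p0 = steady_state(gen)
        _, traj = integrate_occupancy(p0, lambda t: (-85.0, ions), dt=0.1,
                                      T=50.0, params=default_params)
        assert np.max(np.abs(traj - p0.p)) < 1e-8

    def test_pulse_returns_to_steady_state(self, default_params):
        rest_ions = IonState(glu_out=0.0)
        pulse_ions = IonState(glu_out=0.1)
        gen = build_generator(-85.0, rest_ions, default_params)
        p0 = steady_state(gen)
        sched = lambda t: (-85.0, pulse_ions if t <= 5.0 else rest_ions)
        _, traj = integrate_occupancy(p0, sched, dt=0.5, T=3000.0,
                                      params=default_params)
        assert np.max(np.abs(traj[-1] - p0.p)) < 1e-6

    def test_dt_convergence(self, default_params):
        ions = IonState(glu_out=0.1)
        sched = lambda t: (-85.0, ions)
        p0 = np.full(6, 1 / 6)
        _, a = integrate_occupancy(p0, sched, dt=0.2, T=2000.0, params=default_params)
        _, b = integrate_occupancy(p0, sched, dt=0.1, T=2000.0, params=default_params)
        assert np.max(np.abs(a[-1] - b[-1])) < 1e-6

    def test_conservation_along_trajectory(self, default_params):
        ions = IonState(glu_out=0.1)
        _, traj = integrate_occupancy(np.full(6, 1 / 6),
                                      lambda t: (-60.0, ions), dt=0.05, T=20.0,
                                      params=default_params)
        assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-8


class TestTransporterCurrent:
    def test_zero_density_zero_current(self, default_ions):
        p = GLT1Params(density=0.0)
        occ = steady_state(build_generator(-85.0, default_ions, p))
        assert transporter_current_density(occ, -85.0, default_ions, p) == 0.0

    def test_linear_in_density(self, default_ions):
        base = GLT1Params()
        double = GLT1Params(density=2e4)
        ions = default_ions.replace(glu_out=0.1)
        occ = steady_state(build_generator(-85.0, ions, base))
        i1 = transporter_current_density(occ, -85.0, ions, base)
        i2 = transporter_current_density(occ, -85.0, ions, double)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)

    def test_uptake_current_is_inward(self, default_params):
        ions = IonState(glu_out=0.1)
        occ = steady_state(build_generator(-85.0, ions, default_params))
        assert transporter_current_density(occ, -85.0, ions, default_params) < 0

    def test_steady_current_equals_cycle_flux_oracle(self):
        """Independent oracle: I = -e * den * (net cycle flux) * (total charge).

        Holds for the thermodynamically consistent current dialect at steady
        state (single-cycle scheme: every edge carries the same net flux).
        """
        rng = np.random.default_rng(42)
        for _ in range(20):
            kw = {k: float(rng.uniform(0.01, 5.0)) for k in
                  ("k12", "k21", "k23", "k32", "k34", "k43",
                   "k45", "k54", "k56", "k65", "k16", "k61")}
            ch = {k: float(rng.uniform(-0.5, 0.7)) for k in
                  ("p12", "p23", "p34", "p45", "p56", "p16")}
            params = GLT1Params(**kw, **ch, current_dialect="consistent")
            ions = IonState(na_in=10, na_out=140, k_in=100, k_out=4,
                            glu_in=0.2, glu_out=0.05)
            V = float(rng.uniform(-100, 20))
            gen = build_generator(V, ions, params)
            occ = steady_state(gen)
            R = gen.rates
            flux = occ.p[0] * R[0, 1] - occ.p[1] * R[1, 0]
            total_charge = (ch["p12"] + ch["p23"] + ch["p34"] + ch["p45"]
                            + ch["p56"] - ch["p16"])
            oracle = -params.e_charge * params.density * flux * total_charge * 1e11
            impl = transporter_current_density(occ, V, ions, params)
            assert impl == pytest.approx(oracle, rel=1e-9, abs=1e-25)


class TestReversal:
    def test_reversal_point_current_negligible(self):
        params = reversal_dialect_params()
        glu, V = find_reversal_glu(5.0, params=params)
        ions = IonState(glu_out=glu, k_out=5.0)
        occ = steady_state(build_generator(V, ions, params))
        i_rev = abs(transporter_current_density(occ, V, ions, params))
        ions_t = IonState(glu_out=0.1, k_out=5.0)
        occ_t = steady_state(build_generator(V, ions_t, params))
        i_transport = abs(transporter_current_density(occ_t, V, ions_t, params))
        assert i_rev < 1e-3 * i_transport

    def test_monotone_in_k_out(self):
        """Brute-force scan: reversal [Glu]o strictly increases with [K]o."""
        kos = np.arange(1.0, 10.01, 0.5)
        revs = [find_reversal_glu(float(ko))[0] for ko in kos]
        assert np.all(np.diff(revs) > 0)

    def test_no_reversal_reports_error(self):
        with pytest.raises(NoReversalError):
            find_reversal_glu(5.0, bracket=(0.3, 1.0))
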