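"""Tests of the coupled K+-hotspot / glutamate-uptake simulation.

These use a compressed protocol (same amplitudes and sphere geometry, shorter
K+ transient) so each coupled run takes ~1 s; the full published timing is
exercised by the acceptance suite.
"""

import numpy as np
import pytest

from astroglt.glt1 import GLT1Params
from astroglt.hotspot import (FARADAY, GeometryError, StimulusField,
                              centered_field, distance_profile,
                              hotspot_current, sample_extracellular,
                              simulate_coupled, suppression_experiment)


class TestSampleExtracellular:
    def test_plateau_amplitudes_at_centre(self):
        f = StimulusField()
        ko, glu = sample_extracellular(f, np.array(f.k_center), 500.0)
        assert ko == 5.0
        ko, glu = sample_extracellular(f, np.array(f.glu_center), 900.5)
        assert glu == 0.1

    def test_baseline_after_dissipation(self):
        f = StimulusField()
        ko, glu = sample_extracellular(f, np.array(f.k_center), 1500.0)
        assert (ko, glu) == (2.5, 0.0)

    def test_far_outside_is_exact_baseline_without_skirt(self):
        f = StimulusField()
        far = np.asarray(f.k_center) + np.array([2.5 * f.k_diameter, 0, 0])
        ko, glu = sample_extracellular(f, far, 500.0)
        assert (ko, glu) == (2.5, 0.0)

    def test_skirt_decays_with_distance(self):
        f = StimulusField(skirt_lambda_um=5.0)
        r = f.k_diameter / 2.0
        near = np.asarray(f.k_center) + np.array([r + 2.0, 0, 0])
        far = np.asarray(f.k_center) + np.array([r + 10.0, 0, 0])
        ko_near, _ = sample_extracellular(f, near, 500.0)
        ko_far, _ = sample_extracellular(f, far, 500.0)
        assert 2.5 < ko_far < ko_near < 5.0


class TestCoupledSimulation:
    def test_unperturbed_steady_state(self, small_graph, short_field):
        f = short_field.replace(k_amplitude=short_field.k_baseline, glu_peak=0.0)
        res = simulate_coupled(small_graph, f, T=100.0)
        v_rest = res.config["v_rest"]
        assert np.max(np.abs(res.v - v_rest)) < 0.5
        assert np.max(np.abs(res.k_in - res.k_in[0])) < 1e-3
        assert np.max(np.abs(res.hotspot_i_glut - res.hotspot_i_glut[0])) \
            < 1e-3 * abs(res.hotspot_i_glut[0]) + 1e-12

    def test_k_bolus_depolarises_and_k_in_rises_then_decays(self, small_graph,
                                                            short_field):
        f = short_field.replace(glu_peak=0.0, k_duration=150.0)
        res = simulate_coupled(small_graph, f, T=400.0)
        ctrl = simulate_coupled(
            small_graph, f.replace(k_amplitude=f.k_baseline), T=400.0)
        v_rest = res.config["v_rest"]
        inside = np.linalg.norm(
            small_graph.position - np.asarray(f.k_center), axis=1
        ) <= f.k_diameter / 2.0
        i_end_bolus = np.searchsorted(res.snap_times, 150.0)
        assert np.all(res.v[i_end_bolus - 1][inside] > v_rest + 1e-3)
        # bolus-attributable intracellular K+ (relative to the no-bolus
        # control): rises well under 1 mM during the bolus, decays after
        w = small_graph.volume / small_graph.volume.sum()
        kbar = (res.k_in - ctrl.k_in) @ w
        rise = kbar[i_end_bolus - 1]
        assert 0 < rise < 1.0
        assert kbar[-1] < rise

    def test_kir_charge_matches_k_gain(self, small_graph, short_field):
        f = short_field.replace(glu_peak=0.0)
        # no axial diffusion: charge/mass balance must hold per compartment
        res = simulate_coupled(small_graph, f, T=150.0, d_k_um2_ms=0.0)
        dk_mol = (res.k_in[-1] - res.k_in[0]) * small_graph.volume * 1e-18
        kir_mol = -res.kir_charge_per_comp / FARADAY
        big = np.abs(kir_mol) > 1e-30
        assert np.allclose(dk_mol[big], kir_mol[big], rtol=0.01)
        # with diffusion the balance holds cell-wide
        res2 = simulate_coupled(small_graph, f, T=150.0)
        assert np.sum((res2.k_in[-1] - res2.k_in[0]) * small_graph.volume * 1e-18) \
            == pytest.approx(np.sum(-res2.kir_charge_per_comp / FARADAY), rel=1e-6)

    def test_density_scaling_doubles_peak(self, small_graph, short_field):
        r1 = simulate_coupled(small_graph, short_field, T=150.0)
        r2 = simulate_coupled(small_graph, short_field, T=150.0,
                              glt1=GLT1Params(density=2e4))
        p1 = hotspot_current(r1, short_field)["peak_ma_cm2"]
        p2 = hotspot_current(r2, short_field)["peak_ma_cm2"]
        assert p2 == pytest.approx(2 * p1, rel=0.02)

    def test_identical_runs_identical_outputs(self, small_graph, short_field):
        a = simulate_coupled(small_graph, short_field, T=150.0)
        b = simulate_coupled(small_graph, short_field, T=150.0)
        assert np.array_equal(a.hotspot_i_glut, b.hotspot_i_glut)
        assert np.array_equal(a.v, b.v)

    def test_clamped_voltage_stays_clamped(self, small_graph, short_field):
        res = simulate_coupled(small_graph, short_field, T=150.0, clamp_mv=-85.0)
        assert np.all(res.v == -85.0)

    def test_missing_hotspot_raises(self, small_graph, short_field):
        f = short_field.replace(glu_center=(500.0, 500.0, 500.0),
                                k_center=(500.0, 500.0, 500.0))
        with pytest.raises(GeometryError):
            simulate_coupled(small_graph, f, T=150.0)

    def test_depolarisation_graded_with_distance(self, small_graph, short_field):
        """Compartments inside the K+ sphere depolarise at least as much as
        compartments outside it (the near-isopotential cell attenuates, but
        never inverts, the spatial gradient)."""
        f = short_field.replace(glu_peak=0.0)
        res = simulate_coupled(small_graph, f, T=150.0)
        r = np.linalg.norm(small_graph.position - np.asarray(f.k_center), axis=1)
        inside = r <= f.k_diameter / 2.0
        outside = r > f.k_diameter / 2.0
        dv = res.v[-1] - res.config["v_rest"]
        if np.any(outside):
            assert dv[inside].mean() >= dv[outside].mean() - 1e-9


class TestSuppression:
    def test_suppression_positive_and_dt_robust(self, small_graph, short_field):
        base = suppression_experiment(small_graph, short_field)
        assert base["suppression_pct"] > 0
        halved = suppression_experiment(small_graph, short_field,
                                        dt_coarse=0.05, dt_fine=0.005)
        assert abs(halved["suppression_pct"] - base["suppression_pct"]) < 1.0

    def test_site_outside_k_sphere_unsuppressed(self, small_graph, short_field):
        far_branch = np.flatnonzero(small_graph.cls == 1)[-1]
        f = short_field.replace(
            glu_center=tuple(small_graph.position[far_branch]),
            k_center=(-200.0, 0.0, 0.0))
        pair = suppression_experiment(small_graph, f)
        assert abs(pair["suppression_pct"]) < 2.0

    def test_distance_profile_minimal(self, small_graph, short_field):
        prof = distance_profile(small_graph, short_field, n_sites=2)
        assert len(prof) == 2
        for row in prof:
            assert set(row) >= {"distance_um", "peak_baseline",
                                "peak_elevated", "suppression_ratio"}
        assert prof[0]["distance_um"] < prof[1]["distance_um"]
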