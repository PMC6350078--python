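"""Rigor engine: rates, conservation, equilibria, protocols, series element."""

import numpy as np
import pytest

from crossbridge import rigor
from crossbridge.elasticity import make_profile
from crossbridge.rigor import (LengthProtocol, RigorParameters, attach_rate,
                               detach_rate, ensemble_force, ensemble_stiffness,
                               equilibrate, partition_length_change,
                               probe_sarcomere_stiffness, run_protocol, step,
                               to_tension)


@pytest.fixture(scope="module")
def nl_params():
    return RigorParameters()


@pytest.fixture(scope="module")
def lin_params():
    return RigorParameters(profile=make_profile("rigor_AM", "linear"), k_se=250.0)


class TestRates:
    def test_detach_rate_zero_strain(self, nl_params):
        assert detach_rate(nl_params, 0, 0.0) == pytest.approx(0.0014)

    def test_detach_rate_site_shifted(self, nl_params):
        assert detach_rate(nl_params, 1, 5.5) == pytest.approx(0.0014)

    def test_detach_rate_strained(self, lin_params):
        # |F| = 2.5 pN at 1 nm -> kd = 0.0014 exp(2.5 * 1.4 / 4)
        expect = 0.0014 * np.exp(2.5 * 1.4 / 4.0)
        assert detach_rate(lin_params, 0, 1.0) == pytest.approx(expect)

    def test_detailed_balance(self, nl_params):
        for x in np.linspace(-2.75, 2.75, 17):
            for i in (-2, -1, 0, 1, 2):
                ka = attach_rate(nl_params, i, x)
                kd = detach_rate(nl_params, i, x)
                e = x - 5.5 * i
                dG = nl_params.dG_min + nl_params.profile.strain_energy(e)
                if ka < nl_params.ka_cap:  # cap intentionally breaks the identity
                    assert ka / kd == pytest.approx(np.exp(-dG), rel=1e-9)

    def test_attach_rate_capped(self, nl_params):
        assert attach_rate(nl_params, 0, 0.0) <= nl_params.ka_cap

    def test_bad_site_raises(self, nl_params):
        with pytest.raises(ValueError):
            detach_rate(nl_params, 7, 0.0)


class TestKinetics:
    def test_zero_dt_is_identity(self, nl_params):
        st = equilibrate(nl_params)
        st2 = step(st, nl_params, 0.0)
        assert np.allclose(st2.m, st.m) and np.allclose(st2.a, st.a)

    def test_probability_conservation(self, nl_params):
        st = equilibrate(nl_params)
        for _ in range(50):
            st = step(st, nl_params, 0.05)
        assert np.max(np.abs(1.0 - st.total())) < 1e-8

    def test_boltzmann_state_is_fixed_point(self, nl_params):
        st = equilibrate(nl_params, kind="boltzmann")
        st2 = step(st, nl_params, 0.5)
        assert np.allclose(st2.m, st.m, atol=1e-10)
        assert np.allclose(st2.a, st.a, atol=1e-10)

    def test_long_relaxation_approaches_boltzmann(self):
        # coarse grid keeps the many-step relaxation cheap
        p = RigorParameters(grid_points=60)
        st = rigor.RigorState(m=np.ones(60), a=np.zeros((5, 60)))
        for _ in range(400):
            st = step(st, p, 10.0)  # far beyond the detachment time scale
        ref = equilibrate(p, kind="boltzmann")
        assert np.allclose(st.a, ref.a, atol=5e-3)


class TestEquilibria:
    def test_linear_isometric_tension_zero(self, lin_params):
        st = equilibrate(lin_params)
        assert abs(to_tension(ensemble_force(st, lin_params), lin_params)) < 0.5

    def test_nonlinear_isometric_tension_positive(self, nl_params):
        st = equilibrate(nl_params)
        assert to_tension(ensemble_force(st, nl_params), nl_params) > 10.0

    def test_site_occupancy_peaks_at_own_site(self, nl_params):
        st = equilibrate(nl_params, kind="boltzmann")
        x = nl_params.grid
        # site 0 is the most occupied state near x = 0
        i0 = np.argmin(np.abs(x))
        assert np.argmax(st.a[:, i0]) == 2  # row 2 <-> site index 0

    def test_series_element_balances_force(self, nl_params):
        st = equilibrate(nl_params)
        F = ensemble_force(st, nl_params)
        assert F == pytest.approx(nl_params.k_se * st.x_se, rel=1e-6)


class TestEnsembleAverages:
    def test_tension_conversion(self):
        # 200 pN per half filament over 2e-15 m^2 is 100 kPa
        assert to_tension(200.0) == pytest.approx(100.0)

    def test_all_detached_zero_force(self, nl_params):
        n = nl_params.grid_points
        st = rigor.RigorState(m=np.ones(n), a=np.zeros((5, n)))
        assert ensemble_force(st, nl_params) == 0.0

    def test_full_occupancy_linear_stiffness(self, lin_params):
        # every head attached at its own site: 294 heads x 2.5 pN/nm
        n = lin_params.grid_points
        a = np.zeros((5, n))
        a[2] = 1.0
        st = rigor.RigorState(m=np.zeros(n), a=a)
        assert ensemble_stiffness(st, lin_params) == pytest.approx(294 * 2.5)

    def test_stiffness_nonnegative(self, nl_params):
        st = equilibrate(nl_params)
        assert ensemble_stiffness(st, nl_params) >= 0.0


class TestSeriesPartition:
    def test_force_balance_gives_zero(self):
        assert partition_length_change(250.0, 300.0, 250.0, 1.0) == 0.0

    def test_stiff_crossbridge_limit(self):
        assert abs(partition_length_change(0.0, 1e12, 250.0, 1.0)) < 1e-9

    def test_plugin_value(self):
        assert partition_length_change(0.0, 250.0, 250.0, 1.0) == pytest.approx(0.5)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(ValueError):
            partition_length_change(1.0, -250.0, 250.0, 0.0)


class TestProtocols:
    def test_flat_force_without_length_change_linear(self, lin_params):
        ts = run_protocol(lin_params, LengthProtocol(((0.5, 0.0),)))
        assert np.max(np.abs(ts["tension_kPa"])) < 0.5

    def test_stretch_shortening_hysteresis_nonlinear(self, nl_params):
        """Cross-bridge stiffness is higher in the stretched state and lower
        in the shortened state than initially (heads cross into the stiff /
        compliant segments of the nonlinear law)."""
        st = equilibrate(nl_params)
        s0 = ensemble_stiffness(st, nl_params)
        up = run_protocol(nl_params, LengthProtocol(((4.0, 10.0),)), state=st)
        s_up = up["stiffness_kPa_per_nm"].iloc[-1] * 2.0  # back to pN/nm
        down = run_protocol(
            nl_params, LengthProtocol(((4.0, 10.0), (-8.0, -10.0))), state=st)
        s_down = down["stiffness_kPa_per_nm"].iloc[-1] * 2.0
        assert s_up > s0 > s_down

    def test_velocity_independence_of_stiffness_change(self, nl_params):
        """A 100x faster ramp leaves the stiffness-vs-stretch outcome unchanged."""
        out = {}
        for v in (10.0, 1000.0):
            ts = run_protocol(nl_params, LengthProtocol(((3.0, v),)))
            out[v] = ts["stiffness_kPa_per_nm"].iloc[-1]
        assert out[10.0] == pytest.approx(out[1000.0], rel=0.02)

    def test_bad_protocols_rejected(self):
        with pytest.raises(ValueError):
            LengthProtocol(())
        with pytest.raises(ValueError):
            LengthProtocol(((1.0, 5000.0),))

    def test_probe_series_combination_limits(self, nl_params, lin_params):
        # detached ensemble: the cross-bridge element bears no force, so the
        # sarcomere (cross-bridges in series with myofilaments) has no stiffness
        n = nl_params.grid_points
        st = rigor.RigorState(m=np.ones(n), a=np.zeros((5, n)))
        assert probe_sarcomere_stiffness(nl_params, st) == pytest.approx(0.0, abs=1e-9)
        # fully attached linear ensemble: probe equals the series combination
        a = np.zeros((5, lin_params.grid_points))
        a[2] = 1.0
        st = rigor.RigorState(m=np.zeros(lin_params.grid_points), a=a)
        S = ensemble_stiffness(st, lin_params)
        expect = to_tension(lin_params.k_se * S / (lin_params.k_se + S), lin_params)
        assert probe_sarcomere_stiffness(lin_params, st) == pytest.approx(expect, rel=1e-3)

    def test_probe_linear_about_twice_nonlinear(self, nl_params, lin_params):
        s_nl = probe_sarcomere_stiffness(nl_params, equilibrate(nl_params))
        s_lin = probe_sarcomere_stiffness(lin_params, equilibrate(lin_params))
        assert 1.5 < s_lin / s_nl < 2.5
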