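"""The discrete two-cell map: subthreshold potential, calcium iteration,
the explicit burst-length formula, fixed points and their stability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caburst import (
    MapState,
    NoSwitchError,
    ca_active,
    ca_silent,
    derive_constants,
    find_gAHP_for_k,
    fixed_point,
    iterate_map,
    map_step,
    nspb,
    nspb_real,
    vsub,
)
from caburst import paced_params
from caburst.camap import BracketError, _strict_ceil
from helpers import ca_loop, near_integer, nspb_brute

_DC = derive_constants(paced_params())


class TestVsub:
    def test_calcium_free_uninhibited_cell_rests_at_leak_balance(self, defaults):
        # with no AHP activation and no inhibition the balance is
        # -gl (v - EL) + Iapp = 0, i.e. v = EL + Iapp/gl
        expected = defaults.EL + defaults.Iapp / defaults.gl
        assert vsub(0.0, 0.0, defaults) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-58.889, abs=1e-3)

    def test_large_adaptation_conductance_pins_potential_at_EK(self, defaults):
        v = vsub(5.0, 0.0, defaults.replace(gAHP=1e9))
        assert v == pytest.approx(defaults.EK, abs=1e-5)

    def test_strictly_decreasing_in_calcium(self, defaults):
        grid = np.linspace(0.0, 50.0, 200)
        for si in (0.0, 0.2, 1.0):
            v = vsub(grid, si, defaults)
            assert np.all(np.diff(v) < 0)


class TestCalciumIteration:
    def test_zero_cycles_is_identity(self, dc_paced):
        assert ca_active(1.7, 0, dc_paced) == 1.7
        assert ca_silent(1.7, 0, dc_paced) == 1.7

    def test_asymptotic_level_is_a_fixed_point(self, dc_paced):
        for n in (1, 5, 50):
            assert ca_active(dc_paced.Abar, n, dc_paced) == pytest.approx(
                dc_paced.Abar, rel=1e-14)

    def test_silent_cell_never_gains_calcium(self, dc_paced):
        assert ca_silent(0.0, 7, dc_paced) == 0.0
        assert ca_silent(3.0, 10, dc_paced) == pytest.approx(
            3.0 * dc_paced.r ** 10, rel=1e-14)

    def test_closed_form_equals_explicit_loop(self, defaults):
        dc = derive_constants(defaults)
        assert ca_active(0.0, 25, dc) == pytest.approx(ca_loop(0.0, 25, dc), rel=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a0=st.floats(0.0, 60.0), n=st.integers(0, 200))
    def test_closed_form_equals_loop_property(self, a0, n):
        assert ca_active(a0, n, _DC) == pytest.approx(ca_loop(a0, n, _DC),
                                                      rel=1e-10, abs=1e-10)


class TestNspbFormula:
    def test_strict_ceiling(self):
        assert _strict_ceil(2.3) == 3
        assert _strict_ceil(2.0) == 3  # min{z in Z : z > x} is strict
        assert _strict_ceil(-0.4) == 0

    def test_matches_brute_force_oracle_on_grid(self, paced, dc_paced):
        grid = np.linspace(0.0, 0.95 * dc_paced.Abar, 25)
        checked = 0
        for x0 in grid:
            for y0 in grid:
                try:
                    ncap = nspb_real(x0, y0, paced, dc_paced)
                except NoSwitchError:
                    assert nspb_brute(x0, y0, paced, dc_paced) == 0
                    continue
                if near_integer(ncap):
                    continue  # measure-zero integer boundary
                assert nspb(x0, y0, paced, dc_paced) == max(
                    nspb_brute(x0, y0, paced, dc_paced), 1), (x0, y0)
                checked += 1
        assert checked > 500

    def test_root_satisfies_potential_equality(self, paced, dc_paced):
        # substituting the real-valued solution back: the two cells'
        # subthreshold potentials coincide at that cycle count
        for x0, y0 in [(0.0, 3.0), (1.0, 5.0), (2.5, 2.6), (0.5, 7.0)]:
            n = nspb_real(x0, y0, paced, dc_paced)
            va = vsub(ca_active(x0, n, dc_paced), 0.0, paced)
            vs = vsub(ca_silent(y0, n, dc_paced), dc_paced.siEnd, paced)
            assert va == pytest.approx(vs, abs=1e-9)

    def test_huge_adaptation_conductance_interchanges_within_first_cycle(self, paced):
        # at the low-count fixed points D_k an overwhelming adaptation
        # current forces the interchange inside the first cycle (the
        # gAHP -> inf limit of n_Ca(D_k) is ln((1+r^k)/2)/ln(r), below 1
        # for k = 1, 2 at the paced retention factor)
        q = paced.replace(gAHP=1e6)
        for k in (1, 2):
            fp = fixed_point(k, q)
            assert nspb_real(fp.point.Cx, fp.point.Cy, q) < 1.0
            assert nspb(fp.point.Cx, fp.point.Cy, q) == 1

    def test_vanishing_adaptation_never_interchanges(self, paced):
        q = paced.replace(gAHP=1e-9)
        with pytest.raises(NoSwitchError):
            nspb_real(0.0, 3.0, q)

    def test_degenerate_quadratic_silent_cell_empty(self, paced, dc_paced):
        # y0 = 0 makes the quadratic linear; result must still agree with
        # the brute-force comparison
        n = nspb(1.0, 0.0, paced, dc_paced)
        assert n == max(nspb_brute(1.0, 0.0, paced, dc_paced), 1)

    def test_monotone_in_conductances(self, paced):
        x0, y0 = 1.0, 4.0
        n_gahp = [nspb_real(x0, y0, paced.replace(gAHP=g)) for g in
                  np.linspace(35.0, 60.0, 15)]
        assert np.all(np.diff(n_gahp) < 0)
        n_gi = [nspb_real(x0, y0, paced.replace(gi=g)) for g in
                np.linspace(15.0, 28.0, 15)]
        assert np.all(np.diff(n_gi) > 0)

    def test_rejects_negative_calcium(self, paced):
        with pytest.raises(ValueError):
            nspb_real(-0.1, 1.0, paced)


class TestMapStep:
    def test_roles_swap(self, paced, dc_paced):
        s1, n = map_step(MapState(0.0, 3.0), paced, dc_paced)
        assert s1.Cx == pytest.approx(dc_paced.r ** n * 3.0)
        assert s1.Cy == pytest.approx(dc_paced.r ** n * 0.0
                                      + dc_paced.Abar * (1 - dc_paced.r ** n))

    def test_empty_silent_cell_stays_empty_through_swap(self, paced, dc_paced):
        s1, _ = map_step(MapState(2.0, 0.0), paced, dc_paced)
        assert s1.Cx == 0.0

    def test_former_active_carries_more_calcium(self, paced, dc_paced):
        s1, _ = map_step(MapState(1.0, 4.0), paced, dc_paced)
        assert s1.Cy > s1.Cx

    def test_contraction_for_states_sharing_burst_count(self, paced, dc_paced):
        u, v = MapState(1.0, 4.0), MapState(1.05, 4.05)
        nu = nspb(u.Cx, u.Cy, paced, dc_paced)
        assert nu == nspb(v.Cx, v.Cy, paced, dc_paced)
        fu, _ = map_step(u, paced, dc_paced)
        fv, _ = map_step(v, paced, dc_paced)
        dist0 = np.linalg.norm(u.as_array() - v.as_array())
        dist1 = np.linalg.norm(fu.as_array() - fv.as_array())
        assert dist1 <= dc_paced.r ** nu * dist0 + 1e-12

    def test_orbits_converge_to_constant_burst_count(self, paced, dc_paced, rng):
        for _ in range(100):
            s = MapState(*rng.uniform(0.0, dc_paced.Abar, 2))
            _, ns = iterate_map(s, 200, paced, dc_paced)
            assert len(ns) == 200
            tail = ns[-10:]
            assert len(set(tail)) == 1  # unique stable fixed point here

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            MapState(-1.0, 0.0)


class TestFixedPoints:
    def test_closed_form(self, paced, dc_paced):
        for k in (1, 3, 7):
            res = fixed_point(k, paced, dc_paced)
            rk = dc_paced.r ** k
            assert res.point.Cx == pytest.approx(dc_paced.Abar * rk / (1 + rk), rel=1e-12)
            assert res.point.Cy == pytest.approx(dc_paced.Abar / (1 + rk), rel=1e-12)

    def test_large_burst_count_limit(self, paced, dc_paced):
        res = fixed_point(500, paced, dc_paced)
        assert res.point.Cx == pytest.approx(0.0, abs=1e-12)
        assert res.point.Cy == pytest.approx(dc_paced.Abar, rel=1e-9)

    def test_stability_window_at_paced_defaults(self, paced, dc_paced):
        stable = [k for k in range(1, 10) if fixed_point(k, paced, dc_paced).stable]
        assert stable == [4]
        res = fixed_point(4, paced, dc_paced)
        assert 3 < res.nCa_at_point < 4

    def test_stable_point_is_invariant_and_attracting(self, paced, dc_paced, rng):
        res = fixed_point(4, paced, dc_paced)
        s1, n = map_step(res.point, paced, dc_paced)
        assert n == 4
        assert np.allclose(s1.as_array(), res.point.as_array(), atol=1e-10)
        for _ in range(10):
            pert = res.point.as_array() + rng.uniform(-0.05, 0.05, 2)
            s = MapState(*np.clip(pert, 0.0, None))
            for _ in range(60):
                s, _ = map_step(s, paced, dc_paced)
            assert np.allclose(s.as_array(), res.point.as_array(), atol=1e-8)

    def test_invalid_burst_count(self, paced):
        with pytest.raises(ValueError):
            fixed_point(0, paced)


class TestFindGahp:
    def test_self_consistency(self, paced):
        for k in (1, 2, 5):
            g = find_gAHP_for_k(k, paced)
            res = fixed_point(k, paced.replace(gAHP=g))
            assert res.stable
            assert res.nCa_at_point == pytest.approx(k - 0.5, abs=1e-3)

    def test_burst_length_decreases_with_gahp_at_fixed_point(self, paced):
        k = 3
        vals = []
        for g in np.linspace(20.0, 120.0, 12):
            q = paced.replace(gAHP=g)
            vals.append(fixed_point(k, q).nCa_at_point)
        assert np.all(np.diff(vals) < 0)

    def test_bracket_failure_reports_endpoints(self, paced):
        with pytest.raises(BracketError, match="n_Ca"):
            find_gAHP_for_k(3, paced, bracket=(100.0, 200.0))
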