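"""Unit and property tests for spring equilibration and buckling mechanics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from myofil.kinetics import HeadState, InvalidParameterError
from myofil.mechanics import (
    LEADING,
    TRAILING,
    ActinMechanics,
    FreeFilamentError,
    Head,
    MyofilamentParams,
    apply_powerstroke,
    attach_head,
    bare_zone_tension,
    bending_rigidity,
    critical_curvature,
    curvature_to_shortening,
    equilibrate_buckling,
    equilibrium_position,
    euler_buckling_force,
    shortening_to_curvature,
)


def _attached(end, rest):
    return Head(end=end, state=HeadState.RIGOR, rest_pos=rest)


def _brute_force_minimum(rests, kappa=1.0):
    res = minimize_scalar(
        lambda X: sum(0.5 * kappa * (r - X) ** 2 for r in rests),
        bounds=(min(rests) - 1, max(rests) + 1),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return res.x


class TestEquilibriumPosition:
    def test_single_spring_relaxes_fully(self):
        assert equilibrium_position([_attached(LEADING, 7.0)]) == pytest.approx(7.0)

    def test_symmetric_pair_balances_at_origin(self):
        heads = [_attached(LEADING, 3.0), _attached(TRAILING, -3.0)]
        assert equilibrium_position(heads) == pytest.approx(0.0)

    def test_three_springs_mean_and_zero_net_force(self):
        heads = [_attached(LEADING, 0.0), _attached(TRAILING, 0.0), _attached(LEADING, 5.0)]
        X = equilibrium_position(heads)
        assert X == pytest.approx(5 / 3)
        assert X == pytest.approx(_brute_force_minimum([0, 0, 5]), abs=1e-9)
        net = sum(1.0 * (h.rest_pos - X) for h in heads)
        assert abs(net) < 1e-9

    def test_detached_heads_ignored(self):
        heads = [_attached(LEADING, 4.0), Head(end=TRAILING, state=HeadState.DETACHED_ATP)]
        assert equilibrium_position(heads) == pytest.approx(4.0)

    def test_no_attached_heads_signals_free_filament(self):
        with pytest.raises(FreeFilamentError):
            equilibrium_position([Head(end=LEADING)])

    def test_matches_brute_force_on_random_configurations(self):
        """Equilibrium == energy minimum for 1000 random spring sets."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            rests = rng.normal(0, 20, n)
            heads = [
                _attached(LEADING if rng.random() < 0.5 else TRAILING, r) for r in rests
            ]
            X = equilibrium_position(heads)
            assert X == pytest.approx(_brute_force_minimum(list(rests)), abs=1e-6)
            assert abs(sum(h.rest_pos - X for h in heads)) < 1e-9


class TestPowerstroke:
    def test_leading_head_always_steps(self):
        h = _attached(LEADING, 0.0)
        moved = apply_powerstroke(h, MyofilamentParams(), np.random.default_rng(0))
        assert moved and h.rest_pos == pytest.approx(5.0)

    def test_trailing_head_never_steps_at_p_st_zero(self):
        h = _attached(TRAILING, 1.0)
        moved = apply_powerstroke(h, MyofilamentParams(p_st=0.0), np.random.default_rng(0))
        assert not moved and h.rest_pos == pytest.approx(1.0)

    def test_trailing_step_fraction_matches_p_st(self):
        rng = np.random.default_rng(7)
        p = MyofilamentParams(p_st=0.1)
        n = 100_000
        stepped = sum(apply_powerstroke(_attached(TRAILING, 0.0), p, rng) for _ in range(n))
        se = math.sqrt(0.1 * 0.9 / n)
        assert abs(stepped / n - 0.1) < 3 * se

    def test_powerstroke_on_detached_head_is_an_error(self):
        with pytest.raises(InvalidParameterError):
            apply_powerstroke(Head(end=LEADING), MyofilamentParams(), np.random.default_rng(0))


class TestAttachment:
    def test_attach_has_zero_spring_force(self):
        h = Head(end=LEADING, state=HeadState.BOUND_ADP_PI)
        attach_head(h, X=12.0)
        assert h.effective_rest() == pytest.approx(12.0)

    def test_attach_then_equilibrate_leaves_position_unchanged(self):
        heads = [_attached(LEADING, 2.0), _attached(TRAILING, -2.0)]
        X = equilibrium_position(heads)
        new = Head(end=TRAILING, state=HeadState.BOUND_ADP_PI)
        attach_head(new, X=X)
        assert equilibrium_position(heads + [new]) == pytest.approx(X)

    def test_trailing_anchor_absorbs_buckling_offset(self):
        h = Head(end=TRAILING, state=HeadState.BOUND_ADP_PI)
        attach_head(h, X=10.0, delta=2.0)
        assert h.rest_pos == pytest.approx(8.0)
        assert h.effective_rest(delta=2.0) == pytest.approx(10.0)

    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    def test_single_stroke_shifts_filament_by_d_over_n(self, n):
        heads = [_attached(LEADING, 0.0) for _ in range(n)]
        X0 = equilibrium_position(heads)
        heads[0].rest_pos += 5.0
        X1 = equilibrium_position(heads)
        assert X1 - X0 == pytest.approx(5.0 / n)
        assert X1 == pytest.approx(_brute_force_minimum([h.rest_pos for h in heads]), abs=1e-6)


class TestBareZoneTension:
    def test_symmetric_configuration_carries_no_load(self):
        heads = [_attached(LEADING, 0.0), _attached(TRAILING, 0.0)]
        assert bare_zone_tension(heads, X=0.0) == pytest.approx(0.0)

    def test_no_trailing_head_means_no_brake(self):
        heads = [_attached(LEADING, 5.0)]
        assert bare_zone_tension(heads, X=5.0) == 0.0

    def test_two_spring_hand_example(self):
        heads = [_attached(LEADING, 5.0), _attached(TRAILING, 0.0)]
        X = equilibrium_position(heads)
        assert X == pytest.approx(2.5)
        assert bare_zone_tension(heads, X) == pytest.approx(2.5)

    def test_action_reaction_on_random_configurations(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            heads = [
                _attached(LEADING if rng.random() < 0.5 else TRAILING, r)
                for r in rng.normal(0, 10, int(rng.integers(2, 10)))
            ]
            if len({h.end for h in heads}) < 2:
                continue
            X = equilibrium_position(heads)
            lead = sum(h.rest_pos - X for h in heads if h.end == LEADING)
            trail = sum(h.rest_pos - X for h in heads if h.end == TRAILING)
            assert abs(lead + trail) < 1e-9
            assert bare_zone_tension(heads, X) == pytest.approx(abs(trail), abs=1e-9)


class TestActinMechanics:
    def test_bending_rigidity_from_persistence_length(self):
        assert bending_rigidity(15.0, 4.0) == pytest.approx(6.0e4)
        assert bending_rigidity(30.0, 4.0) == pytest.approx(2 * bending_rigidity(15.0, 4.0))
        with pytest.raises(InvalidParameterError):
            bending_rigidity(0.0, 4.0)

    def test_euler_buckling_force_of_bare_zone_is_23_pN(self):
        assert round(euler_buckling_force(6.0e4, 160.0)) == 23

    def test_euler_inverse_square_and_identity(self):
        assert euler_buckling_force(6.0e4, 320.0) == pytest.approx(
            euler_buckling_force(6.0e4, 160.0) / 4
        )
        assert euler_buckling_force(1.0, math.pi) == pytest.approx(1.0)
        with pytest.raises(InvalidParameterError):
            euler_buckling_force(-1.0, 160.0)

    @pytest.mark.parametrize("r, expected", [(0.18, 5.6), (1.0, 1.0), (0.5, 2.0)])
    def test_critical_curvature(self, r, expected):
        assert round(critical_curvature(r), 1) == pytest.approx(expected)

    def test_derived_quantities_consistent(self):
        a = ActinMechanics()
        assert a.EI == pytest.approx(6.0e4)
        assert a.F_c == pytest.approx(math.pi**2 * a.EI / a.l_bz**2)
        assert a.kappa_crit == pytest.approx(1 / 0.18)


class TestShorteningToCurvature:
    def test_straight_filament_has_zero_curvature(self):
        assert shortening_to_curvature(0.0, 160.0) == 0.0

    def test_critical_curvature_reached_near_3nm_shortening(self):
        delta = curvature_to_shortening(5.6, 160.0)
        assert delta == pytest.approx(3.2, abs=0.1)
        assert shortening_to_curvature(delta, 160.0) == pytest.approx(5.6)

    def test_sqrt_scaling(self):
        k1 = shortening_to_curvature(1.0, 160.0)
        k2 = shortening_to_curvature(2.0, 160.0)
        assert k2 / k1 == pytest.approx(math.sqrt(2))

    def test_monotone_and_invertible(self):
        deltas = np.linspace(0.01, 20, 50)
        curvs = [shortening_to_curvature(d, 160.0) for d in deltas]
        assert np.all(np.diff(curvs) > 0)
        for d, c in zip(deltas, curvs):
            assert curvature_to_shortening(c, 160.0) == pytest.approx(d, abs=1e-9)

    def test_amplitude_matches_numerical_arc_length(self):
        """The closed form A = (2/pi)sqrt(l*delta) is the leading-order
        inversion of the sine-mode arc-length constraint: a buckle of that
        amplitude over the shortened chord has arc length ~l."""
        l, delta = 160.0, 3.2
        A = (2 / math.pi) * math.sqrt(l * delta)
        chord = l - delta
        arc = quad(
            lambda x: math.sqrt(1 + (A * math.pi / chord * math.cos(math.pi * x / chord)) ** 2),
            0,
            chord,
        )[0]
        assert (arc - chord) == pytest.approx(delta, rel=0.02)

    def test_domain_errors(self):
        with pytest.raises(InvalidParameterError):
            shortening_to_curvature(-0.1, 160.0)
        with pytest.raises(InvalidParameterError):
            shortening_to_curvature(160.0, 160.0)


class TestEquilibrateBuckling:
    F_C = euler_buckling_force(6.0e4, 160.0)

    def test_below_threshold_stays_straight(self):
        heads = [_attached(LEADING, 20.0), _attached(TRAILING, 0.0)]  # T0 = 10 pN
        st = equilibrate_buckling(heads, F_c=self.F_C)
        assert st.delta == 0.0
        assert st.tension == pytest.approx(10.0)

    def test_above_threshold_pins_tension_at_F_c(self):
        heads = [_attached(LEADING, 60.0), _attached(TRAILING, 0.0)]  # T0 = 30 pN
        st = equilibrate_buckling(heads, F_c=self.F_C)
        assert st.delta > 0
        assert st.tension == pytest.approx(self.F_C, abs=1e-6)
        # two-spring algebra: tension drops kappa/2 per nm of delta
        assert st.delta == pytest.approx(2 * (30.0 - self.F_C) / 1.0, abs=1e-6)

    def test_root_agrees_with_brute_force_scan(self):
        heads = [
            _attached(LEADING, 45.0),
            _attached(LEADING, 55.0),
            _attached(TRAILING, 0.0),
            _attached(TRAILING, 4.0),
            _attached(TRAILING, -3.0),
        ]
        st = equilibrate_buckling(heads, F_c=self.F_C)

        def tension_at(delta):
            X = equilibrium_position(heads, delta)
            return bare_zone_tension(heads, X, 1.0, delta)

        grid = np.linspace(0, 100, 200_001)
        vals = np.array([tension_at(d) for d in grid])
        best = grid[np.argmin(np.abs(vals - self.F_C))]
        assert st.delta == pytest.approx(best, abs=1e-3)
        assert st.tension <= self.F_C + 1e-9

    def test_missing_end_relaxes_to_straight(self):
        heads = [_attached(LEADING, 10.0), _attached(LEADING, 30.0)]
        st = equilibrate_buckling(heads, F_c=self.F_C)
        assert st.delta == 0.0 and st.tension == 0.0


def test_params_invariants():
    with pytest.raises(InvalidParameterError):
        MyofilamentParams(n_m=30, n_leading=10, n_trailing=15)
    with pytest.raises(InvalidParameterError):
        MyofilamentParams(p_st=1.5)
    with pytest.raises(InvalidParameterError):
        MyofilamentParams(d=-1.0)
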