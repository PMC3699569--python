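import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inflammode.exceptions import InvalidInputError
from inflammode.model import (
    STATE_ORDER,
    DoseProtocol,
    classify_outcome,
    resting_state,
    rhs,
    simulate,
)
from inflammode.params import HILL_PARAMS, PARAM_ORDER, young_default

S = {name: i for i, name in enumerate(STATE_ORDER)}


def zero_sources(params):
    return params.replace(s6=1e-300, s10=1e-300)  # effectively sourceless


def test_zero_state_without_sources_is_static(young):
    p = zero_sources(young)
    d = rhs(np.zeros(9), p)
    assert np.allclose(d, 0.0, atol=1e-250)


def test_lps_only_state_drives_leukocyte_activation(young):
    """With P=1 and everything else 0, only P decays and leukocytes activate."""
    p = zero_sources(young)
    state = np.zeros(9)
    state[S["P"]] = 1.0
    d = rhs(state, p)
    assert d[S["P"]] == pytest.approx(-p["kpe"])
    assert d[S["MA"]] == pytest.approx(p["kmpe"] * 1.0 / (p["xmpe"] + 1.0))
    assert d[S["NA"]] == pytest.approx(p["knpe"] * 1.0 / (p["xnpe"] + 1.0))
    for name in ("INOS", "NO", "TNF", "IL6", "IL10", "D"):
        assert d[S[name]] == pytest.approx(0.0, abs=1e-250)


def test_nonfinite_inputs_are_rejected_by_name(young):
    state = np.zeros(9)
    state[S["TNF"]] = float("nan")
    with pytest.raises(InvalidInputError, match="TNF"):
        rhs(state, young)


def _sympy_rhs_and_jacobian():
    """Independent symbolic statement of the model equations."""
    import sympy as sp

    y = sp.symbols("P MA NA INOS NO TNF IL6 IL10 D", positive=True)
    P, MA, NA, INOS, NO, TNF, IL6, IL10, D = y
    p = {name: sp.Symbol(name, positive=True) for name in PARAM_ORDER}

    def up(x, X, h):
        return x ** h / (X ** h + x ** h)

    def down(x, X, h):
        return X ** h / (X ** h + x ** h)

    brake = down(IL10, p["x10l"], p["hn10"])
    eqs = [
        -p["kpe"] * P,
        (p["kmpe"] * up(P, p["xmpe"], 1) + p["kmd"] * up(D, p["xmd"], 2)
         + p["km6"] * up(IL6, p["xm6"], 2)) * brake * (1 - MA / p["Mmax"])
        - p["kma"] * MA,
        p["knpe"] * up(P, p["xnpe"], 1) * brake * (1 - NA / p["Nmax"])
        - p["kn"] * NA,
        p["kinosm"] * MA + p["kinosn"] * NA - p["kdinos"] * INOS,
        p["knono"] * INOS - p["kno"] * NO,
        p["kcpm"] * MA * down(IL6, p["xcp6"], p["hcp6"])
        * down(IL10, p["xcp10"], p["hcp10"]) - p["kcp"] * TNF,
        p["s6"] + (p["k6m"] * MA + p["k6n"] * NA)
        * (1 + p["k6cp"] * up(TNF, p["x6cp"], p["h6cp"])
           + p["k6no"] * up(NO, p["x6no"], 2)) - p["kd6"] * IL6,
        p["s10"] + p["k10m0"] * MA
        * (1 + p["k10cp"] * up(TNF, p["x10cp"], p["h10cp"])) - p["k10"] * IL10,
        p["kdn"] * up(NA, p["xdn"], 2) - p["kdd"] * D,
    ]
    f = sp.Matrix(eqs)
    jac = f.jacobian(sp.Matrix(y))
    syms = list(y) + [p[name] for name in PARAM_ORDER]
    return (sp.lambdify(syms, f, "numpy"), sp.lambdify(syms, jac, "numpy"))


def test_rhs_matches_symbolic_equations_and_jacobian(young):
    """rhs and its FD Jacobian agree with an independent symbolic model."""
    f_sym, jac_sym = _sympy_rhs_and_jacobian()
    rng = np.random.default_rng(7)
    pvec = [young[k] for k in PARAM_ORDER]
    for _ in range(5):
        state = rng.uniform(0.05, 1.0, size=9)
        state[S["IL6"]] *= 1000
        state[S["IL10"]] *= 100
        state[S["TNF"]] *= 100
        state[S["NO"]] *= 10
        args = list(state) + pvec
        expected = np.asarray(f_sym(*args), dtype=float).ravel()
        got = rhs(state, young)
        assert np.allclose(got, expected, rtol=1e-9, atol=1e-12)

        jac_expected = np.asarray(jac_sym(*args), dtype=float)
        h = 1e-6
        jac_fd = np.empty((9, 9))
        for j in range(9):
            dx = h * max(abs(state[j]), 1.0)
            sp_, sm_ = state.copy(), state.copy()
            sp_[j] += dx
            sm_[j] -= dx
            jac_fd[:, j] = (rhs(sp_, young) - rhs(sm_, young)) / (2 * dx)
        assert np.allclose(jac_fd, jac_expected, rtol=1e-6,
                           atol=1e-9 * np.abs(jac_expected).max())


def test_resting_state_residual_is_tiny(young, young_rest):
    assert np.max(np.abs(rhs(young_rest, young))) < 1e-9
    assert (young_rest >= 0).all()


def test_resting_state_closed_forms(young):
    # no sources -> origin
    p0 = zero_sources(young)
    rest0 = resting_state(p0)
    assert np.max(np.abs(rest0)) < 1e-9
    # IL-6 balance: s6/kd6 when macrophage/neutrophil production is off
    p6 = young.replace(k6m=1e-300, k6n=1e-300, km6=1e-300)
    rest6 = resting_state(p6)
    assert rest6[S["IL6"]] == pytest.approx(p6["s6"] / p6["kd6"], rel=1e-9)


def test_dose_zero_from_rest_is_constant(young, young_rest):
    res = simulate(young, DoseProtocol(dose=0.0), init=young_rest,
                   obs_times=np.arange(0.0, 1441.0, 60.0))
    drift = np.abs(res.states - young_rest[None, :])
    tol = 1e-6 * np.maximum(np.abs(young_rest), 1e-2)
    assert (drift <= tol[None, :]).all()


def test_decoupled_lps_elimination_is_exponential(young, young_rest):
    """With leukocyte activation off, P decays as a pure exponential."""
    p = young.replace(kmpe=1e-300, knpe=1e-300, km6=1e-300, kmd=1e-300)
    times = np.array([0.0, 30.0, 120.0, 600.0, 1440.0])
    res = simulate(p, DoseProtocol(dose=1.0), init=resting_state(p),
                   obs_times=times, rtol=1e-10, atol=1e-12)
    expected = np.exp(-p["kpe"] * times)
    assert np.allclose(res.get("P"), expected, rtol=1e-8)


def test_peak_ordering_tnf_il6_no(young_dense_sim):
    """The canonical mediator cascade: TNF peaks first, then IL-6, then NO."""
    res = young_dense_sim
    t_tnf = res.times[np.argmax(res.get("TNF"))]
    t_il6 = res.times[np.argmax(res.get("IL6"))]
    t_no = res.times[np.argmax(res.get("NO"))]
    assert 60.0 <= t_tnf <= 120.0
    assert 120.0 <= t_il6 <= 360.0
    assert t_no > 360.0
    assert t_tnf < t_il6 < t_no


def test_monotone_dose_response_in_peak_tnf(young):
    peaks = []
    for dose in (0.1, 0.5, 1.0, 2.0):
        res = simulate(young, DoseProtocol(dose=dose),
                       obs_times=np.arange(0.0, 1441.0, 2.0))
        peaks.append(res.get("TNF").max())
    assert all(a <= b for a, b in zip(peaks, peaks[1:]))


def test_directional_parameter_effects(young):
    """Fold changes move the trajectories the way their meanings imply."""
    def dense(params):
        return simulate(params, DoseProtocol(dose=1.0),
                        obs_times=np.arange(0.0, 1441.0, 2.0))

    base = dense(young)
    stronger_lps = dense(young.replace(kmpe=young["kmpe"] * 9))
    assert stronger_lps.get("TNF").max() > base.get("TNF").max()
    assert stronger_lps.get("IL6").max() > base.get("IL6").max()

    faster_death = dense(young.replace(kn=young["kn"] * 16))
    assert (np.trapezoid(faster_death.get("NA"), faster_death.times)
            < np.trapezoid(base.get("NA"), base.times))

    weaker_brake = dense(young.replace(xcp6=young["xcp6"] * 11))
    assert weaker_brake.get("TNF").max() > base.get("TNF").max()


def test_obs_times_outside_horizon_rejected(young):
    with pytest.raises(InvalidInputError):
        simulate(young, DoseProtocol(dose=1.0, horizon=100.0),
                 obs_times=[0.0, 200.0])


def test_negative_init_rejected(young):
    bad = np.zeros(9)
    bad[S["IL6"]] = -1.0
    with pytest.raises(InvalidInputError):
        simulate(young, DoseProtocol(dose=1.0), init=bad, obs_times=[0.0, 10.0])


def test_outcome_classification(young, young_rest, young_dense_sim):
    base_d = float(young_rest[S["D"]])
    # LPS challenge at baseline parameters resolves within 24 h
    assert classify_outcome(young_dense_sim, base_d, tol=0.1) == "resolved"
    # without repair, damage accumulates and stays up
    broken = young.replace(kdd=1e-12)
    res = simulate(broken, DoseProtocol(dose=1.0),
                   obs_times=np.arange(0.0, 1441.0, 10.0))
    assert classify_outcome(res, base_d, tol=0.1) == "unresolved"
    # under-observed trajectories are refused
    short = simulate(young, DoseProtocol(dose=1.0, horizon=720.0),
                     obs_times=np.arange(0.0, 721.0, 10.0))
    with pytest.raises(InvalidInputError):
        classify_outcome(short, base_d)


@settings(max_examples=20, deadline=None)
@given(data=st.data())
def test_states_stay_nonnegative_under_random_params(data):
    """Trajectories never go (meaningfully) negative for valid parameters."""
    young = young_default()
    factors = {
        name: data.draw(st.floats(min_value=0.25, max_value=4.0), label=name)
        for name in ("kmpe", "knpe", "kcpm", "k6m", "k10m0", "kn", "kma",
                     "kd6", "k10", "kcp", "kdinos", "kno")
    }
    params = young.replace(**{k: young[k] * f for k, f in factors.items()})
    res = simulate(params, DoseProtocol(dose=1.0),
                   obs_times=np.arange(0.0, 1441.0, 30.0))
    assert res.states.min() >= 0.0  # clipped output
    assert res.solver_report["min_state_preclip"] >= -1e-6
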