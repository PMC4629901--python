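"""Measurement machinery: activation detection, APD90, classification,
pacing schedules, the T(AR) curve and its fit.

Everything here runs on synthetic traces, the toy excitable kernel, or the
single-cell integrator; the expensive tissue searches live in the
acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anisoblock.fixtures import TOY_THRESHOLD, run_toy_cable, toy_tissue_case
from anisoblock.protocols import (
    CriticalCurve,
    FitParameters,
    PacingProtocol,
    RAMP_THRESHOLD_PERIOD,
    activation_times,
    apd90,
    classify_conduction,
    critical_ar_single_pulse,
    evaluate_T,
    fit_T_curve,
    restitution_curve,
)
from anisoblock.solver import SpaceTimeRecord
from anisoblock.cell import CellConditions


# ---------------------------------------------------------------------------
# activation detection
# ---------------------------------------------------------------------------

def test_resting_trace_has_no_activations():
    assert activation_times(np.full(1000, -85.0), 0.1).size == 0


def test_square_pulse_detected_at_crossing_sample():
    v = np.full(200, -85.0)
    v[50:80] = 10.0
    t = activation_times(v, 0.5)
    assert t.tolist() == [25.0]


@given(
    starts=st.lists(st.integers(min_value=0, max_value=1800), min_size=0,
                    max_size=6, unique=True),
    width=st.integers(min_value=1, max_value=120),
)
@settings(deadline=None, max_examples=60)
def test_activation_detection_invariants(starts, width):
    """Detected crossings are sorted, >= one refractory apart, and never
    exceed the number of injected pulses."""
    v = np.full(2000, -85.0)
    for s in starts:
        v[s:s + width] = 10.0
    t = activation_times(v, 0.5)
    assert np.all(np.diff(t) >= 50.0)
    assert t.size <= len(starts)
    if starts and min(starts) > 0:
        assert t.size >= 1


def test_refractory_debounce_suppresses_chatter():
    v = np.full(400, -85.0)
    v[100:104] = 0.0
    v[110:114] = 0.0   # 1 ms later at dt=0.1: inside the 50 ms window
    v[300:304] = 0.0   # 20 ms later: outside
    t = activation_times(v, 0.1)
    assert t.size == 1
    t = activation_times(v, 1.0)   # now the third pulse is 200 ms later
    assert t.size == 2


# ---------------------------------------------------------------------------
# APD90
# ---------------------------------------------------------------------------

def test_apd90_of_ideal_trapezoid():
    """Trapezoid AP with known geometry: closed-form APD90."""
    dt = 0.1
    t = np.arange(0, 500, dt)
    v = np.full_like(t, -80.0)
    # instant upstroke at 50 ms to +20, plateau 200 ms, linear 100 ms ramp down
    up, plateau, ramp = 50.0, 200.0, 100.0
    in_plateau = (t >= up) & (t < up + plateau)
    in_ramp = (t >= up + plateau) & (t < up + plateau + ramp)
    v[in_plateau] = 20.0
    v[in_ramp] = 20.0 - (t[in_ramp] - up - plateau) / ramp * 100.0
    # V90 = -80 + 0.1*100 = -70; crossing at plateau + 0.9*ramp
    act = activation_times(v, dt)[0]
    expected = (up + plateau + 0.9 * ramp) - act
    assert apd90(t, v, act, stim_time=up) == pytest.approx(expected, abs=2 * dt)


def test_apd90_flags_incomplete_repolarization():
    t = np.arange(0, 100, 0.1)
    v = np.where(t > 10, 10.0, -80.0)   # never repolarizes
    act = activation_times(v, 0.1)[0]
    assert np.isnan(apd90(t, v, act, stim_time=10.0))


# ---------------------------------------------------------------------------
# pacing schedules
# ---------------------------------------------------------------------------

def test_constant_train_above_ramp_threshold():
    p = PacingProtocol(period=400.0, n_stim=7, n_ignore=3)
    times = p.stimulus_times()
    assert times.size == 7
    assert np.allclose(np.diff(times), 400.0)
    assert p.analyzed_times().size == 4


def test_ramp_engages_below_2p7_hz_period():
    p = PacingProtocol(period=320.0, n_stim=7, n_ignore=3)
    times = p.stimulus_times()
    gaps = np.diff(times)
    # ramp decrements by 5 ms per cycle from 370 down to the target
    assert gaps[0] == 370.0
    assert np.all(np.diff(gaps[gaps > 320.0]) == -5.0)
    assert np.allclose(gaps[-(p.n_stim - 1):], 320.0)
    assert p.period < RAMP_THRESHOLD_PERIOD


def test_invalid_protocols_rejected():
    with pytest.raises(ValueError):
        PacingProtocol(period=-5.0)
    with pytest.raises(ValueError):
        PacingProtocol(period=500.0, n_stim=3, n_ignore=3)


# ---------------------------------------------------------------------------
# conduction classification (toy kernel + synthetic records)
# ---------------------------------------------------------------------------

def _toy_record(case, stim_times=(0.0,)):
    return run_toy_cable(case["sigma_profile"], case["params"],
                         stim_times=stim_times, probe_ix=case["probe_ix"],
                         duration=60.0 + 70.0 * len(stim_times))


@pytest.mark.parametrize("kind", ["toy_pulse", "toy_two_region"])
def test_toy_conduction_patterns(kind):
    case = toy_tissue_case(kind)
    rec = _toy_record(case, stim_times=(0.0, 70.0))
    rep = classify_conduction(rec, period=70.0, n_ignore=0, threshold=TOY_THRESHOLD)
    assert rep.pattern == case["expected_pattern"]


def test_alternating_conduction_labeled_one_to_two():
    """Synthetic probe traces with every second beat blocked distally."""
    dt_s, period, n = 1.0, 300.0, 6
    t = np.arange(0, period * n + 200, dt_s)
    prox = np.full_like(t, -85.0)
    dist = np.full_like(t, -85.0)
    stims = [k * period for k in range(n)]
    for k, ts in enumerate(stims):
        i = int(ts + 20)
        prox[i:i + 50] = 10.0
        if k % 2 == 0:
            dist[i + 40:i + 90] = 10.0
    rec = SpaceTimeRecord(
        frame_times=np.zeros(0), frames=np.zeros((0, 1, 1), dtype=np.float32),
        dvdt_frames=None, probe_times=t,
        probe_traces=np.stack([prox, dist], axis=1).astype(np.float32),
        probe_nodes=np.zeros((2, 2), dtype=int), dt=dt_s, h_mm=0.125,
        stim_times=np.asarray(stims), duration=float(t[-1]),
        stopped_early=False, meta={"period": period},
    )
    rep = classify_conduction(rec, n_ignore=2)
    assert rep.pattern == "1:2"
    assert rep.conducted.tolist() == [True, False, True, False]


def test_no_sign_change_in_bracket_is_an_error(normal_cond):
    with pytest.raises(RuntimeError, match="conducts"):
        critical_ar_single_pulse(normal_cond, tol=0.05, bracket=(1.5, 1.6))


def test_bisection_tolerance_floor(normal_cond):
    with pytest.raises(ValueError):
        critical_ar_single_pulse(normal_cond, tol=0.001)


# ---------------------------------------------------------------------------
# restitution (single cell; fast)
# ---------------------------------------------------------------------------

def test_restitution_shape_and_saturation(normal_cond):
    pairs = dict(restitution_curve(normal_cond, [350.0, 500.0, 1000.0, 2000.0, 3000.0]))
    assert pairs[350.0] < pairs[500.0] < pairs[1000.0]
    assert abs(pairs[3000.0] - pairs[2000.0]) < 2.0


def test_ikr_block_prolongs_apd(normal_cond):
    apd_n = dict(restitution_curve(normal_cond, [1000.0]))[1000.0]
    apd_kr = dict(restitution_curve(CellConditions(g_kr=0.25), [1000.0]))[1000.0]
    assert apd_kr > apd_n


def test_ical_block_shortens_apd(normal_cond):
    apd_n = dict(restitution_curve(normal_cond, [1000.0]))[1000.0]
    apd_ca = dict(restitution_curve(CellConditions(g_cal=0.25), [1000.0]))[1000.0]
    assert apd_ca < apd_n


def test_single_cell_apd_matches_reference_oracle(normal_state, normal_cond):
    """APD90 at 1 Hz pacing within 5 ms of the independent integrator."""
    import reference_tp06 as ref
    from anisoblock import constants as c

    # package value (4th beat of a 1 Hz train)
    apd_pkg = dict(restitution_curve(normal_cond, [1000.0]))[1000.0]

    # reference: sequential stimulated beats, V reset to 50 between
    y = normal_state.values.copy()
    traces_t, traces_v = [], []
    for beat in range(4):
        y[c.IV] = 50.0
        t_eval = np.arange(0.0, 1000.0, 0.25)
        sol = ref.integrate(y, (0.0, 1000.0), t_eval)
        traces_t.append(t_eval + beat * 1000.0)
        traces_v.append(sol.y[0])
        y = sol.y[:, -1].copy()
    t = np.concatenate(traces_t)
    v = np.concatenate(traces_v)
    act = activation_times(v, 0.25)
    apd_ref = apd90(t, v, act[-1], stim_time=3000.0)
    assert apd_pkg == pytest.approx(apd_ref, abs=5.0)


# ---------------------------------------------------------------------------
# T(AR) closed form and fit
# ---------------------------------------------------------------------------

TABLE_NORMAL = FitParameters(ar1=3.72, a=307.0, b=0.0014, c=9.09, d=0.333)


def test_critical_period_curve_limits():
    # AR -> 0: the power term vanishes, T -> a
    assert evaluate_T(TABLE_NORMAL, 1e-9) == pytest.approx(307.0, abs=1e-6)
    # vertical asymptote at AR1
    assert evaluate_T(TABLE_NORMAL, 3.7199) > 1e4 * 0  # finite but large
    assert evaluate_T(TABLE_NORMAL, 3.71) > evaluate_T(TABLE_NORMAL, 3.5)
    with pytest.raises(ValueError):
        evaluate_T(TABLE_NORMAL, 3.72)


def test_critical_period_curve_regression_value():
    # frozen direct evaluation of the closed form at AR = 3.0
    assert evaluate_T(TABLE_NORMAL, 3.0) == pytest.approx(340.9366, abs=0.01)


def test_fit_recovers_generating_parameters():
    """Points generated by the closed form are refit to the same (b, c, d)."""
    true = FitParameters(ar1=3.72, a=307.0, b=0.01, c=7.0, d=0.4)
    ars = np.linspace(2.0, 3.6, 9)
    pts = []
    for ar in ars:
        t_mid = evaluate_T(true, ar)
        pts.append((float(ar), t_mid + 2.5, t_mid - 2.5))
    fit = fit_T_curve(CriticalCurve("synthetic", pts), ar1=3.72, a=307.0)
    assert fit.c == pytest.approx(true.c, rel=0.05)
    assert fit.d == pytest.approx(true.d, rel=0.05)
    assert np.log(fit.b) == pytest.approx(np.log(true.b), abs=0.3)


def test_critical_curve_validates_ordering():
    with pytest.raises(ValueError):
        CriticalCurve("bad", [(3.0, 300.0, 400.0)])


def test_fit_parameters_invariants():
    with pytest.raises(ValueError):
        FitParameters(ar1=0.9, a=300.0, b=1.0, c=1.0, d=0.3)
    with pytest.raises(ValueError):
        FitParameters(ar1=3.7, a=-1.0, b=1.0, c=1.0, d=0.3)
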