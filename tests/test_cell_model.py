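"""Single-cell TP06 behaviour: currents, stepping, equilibration."""

import numpy as np
import pytest

import reference_tp06 as ref
from anisoblock import constants as c
from anisoblock.cell import (
    CellConditions,
    CellState,
    compute_currents,
    equilibrate,
    step_cell,
    tp06_derivatives,
)
from anisoblock import kernels


def test_zero_driving_force_kills_potassium_currents(normal_state):
    """With V at E_K the K+ currents carried by (V - E_K) vanish."""
    ki = normal_state["Ki"]
    ek = c.RTF * np.log(5.4 / ki)
    st = normal_state.copy()
    st.values[c.IV] = ek
    cur = compute_currents(st, CellConditions())
    assert cur.i_k1 == pytest.approx(0.0, abs=1e-12)
    assert cur.i_kr == pytest.approx(0.0, abs=1e-12)
    assert cur.i_pk == pytest.approx(0.0, abs=1e-12)


def test_equilibrated_state_is_charge_balanced(normal_state, normal_cond):
    cur = compute_currents(normal_state, normal_cond)
    assert abs(cur.i_ion) < 0.01


def test_resting_potential_in_physiological_range(normal_state):
    assert -88.0 <= normal_state.V <= -84.0


def test_compute_currents_rejects_nonfinite_state(normal_state, normal_cond):
    st = normal_state.copy()
    st.values[c.STATE_NAMES.index("Cai")] = np.nan
    with pytest.raises(ValueError, match="Cai"):
        compute_currents(st, normal_cond)


def test_conductance_scale_factors_validated():
    with pytest.raises(ValueError, match="g_na"):
        CellConditions(g_na=0.0)
    with pytest.raises(ValueError, match="g_k1"):
        CellConditions(g_k1=1.5)
    with pytest.raises(ValueError, match="ik1_rule"):
        CellConditions(ik1_rule="sometimes")


def test_ik1_phase_rule_semantics():
    cond = CellConditions(g_k1=0.25, ik1_rule="front_only")
    assert cond.ik1_multiplier(+1, -80.0) == 0.25
    assert cond.ik1_multiplier(-1, -80.0) == 1.0
    assert cond.ik1_multiplier(0, -80.0) == 1.0      # ties count as tail
    tail = CellConditions(g_k1=0.25, ik1_rule="tail_only")
    assert tail.ik1_multiplier(0, -80.0) == 0.25
    sub = CellConditions(g_k1=0.25, ik1_rule="subthreshold_front")
    assert sub.ik1_multiplier(+1, -60.0) == 0.25
    assert sub.ik1_multiplier(+1, -40.0) == 1.0


def test_step_cell_fixed_point_at_equilibrium(normal_state, normal_cond):
    out = step_cell(normal_state, normal_cond, 0.02)
    assert np.allclose(out.values, normal_state.values, rtol=1e-6, atol=1e-7)


def test_step_cell_rejects_oversized_dt(normal_state, normal_cond):
    with pytest.raises(ValueError):
        step_cell(normal_state, normal_cond, 0.05)


def test_first_order_consistency_of_euler_step(normal_state, normal_cond):
    """|step(dt) - 2 x step(dt/2)| shrinks at least linearly with dt.

    (The one-step comparison is dominated by the local truncation error,
    which halves at least quadratically; consistency requires >= linear.)
    """
    st = normal_state.copy()
    st.values[c.IV] = -30.0   # off equilibrium so derivatives are large

    def err(dt):
        a = step_cell(st, normal_cond, dt, gate_mode="euler")
        b = step_cell(
            step_cell(st, normal_cond, dt / 2, gate_mode="euler"),
            normal_cond, dt / 2, gate_mode="euler",
        )
        return np.max(np.abs(a.values - b.values))

    r = err(0.02) / err(0.01)
    assert r > 1.8


def test_gates_bounded_after_integration(normal_state, normal_cond):
    st = normal_state.copy()
    st.values[c.IV] = 50.0    # stimulated
    y, _ = kernels.integrate_single_cell(st.values, normal_cond, 0.005, 40_000, 0)
    gates = y[c.IM:c.IXS + 1]
    assert np.all(gates >= 0.0) and np.all(gates <= 1.0)


def test_stimulated_ap_matches_independent_reference(normal_state, normal_cond):
    """Production kernel vs a separate scipy transcription: <1 mV RMS."""
    y0 = normal_state.values.copy()
    y0[c.IV] = 50.0
    t_eval = np.arange(0.0, 500.0, 1.0)
    sol = ref.integrate(y0, (0.0, 500.0), t_eval)

    tb = kernels.build_tables(normal_cond, 0.005)
    fields = kernels.state_to_fields(y0)
    v_kernel = np.empty_like(t_eval)
    for i in range(t_eval.size):
        v_kernel[i] = fields[0][0, 0]
        kernels._run_cell(fields, tb, 200, step0=i * 200)
    rms = np.sqrt(np.mean((v_kernel - sol.y[0]) ** 2))
    assert rms < 1.0


def test_sodium_block_never_speeds_the_upstroke(normal_state):
    """Max dV/dt during a threshold-triggered upstroke is monotone in g_Na."""
    def max_dvdt(g_na):
        cond = CellConditions(g_na=g_na)
        st = normal_state.copy()
        st.values[c.IV] = -30.0   # suprathreshold launch
        peak = 0.0
        for _ in range(400):      # 2 ms at dt 0.005
            nxt = step_cell(st, cond, 0.005)
            peak = max(peak, (nxt.V - st.V) / 0.005)
            st = nxt
        return peak

    rates = [max_dvdt(g) for g in (1.0, 0.5, 0.25)]
    assert rates[0] > rates[1] > rates[2]


def test_hyperkalemia_depolarizes_rest(normal_state):
    st12 = equilibrate(CellConditions(ko=12.0)).state
    assert st12.V > normal_state.V


def test_strong_ik1_suppression_flagged_as_oscillatory():
    res = equilibrate(CellConditions(g_k1=0.05), duration=20_000.0)
    assert not res.converged


def test_state_dict_roundtrip(normal_state):
    again = CellState.from_dict(normal_state.as_dict())
    assert np.array_equal(again.values, normal_state.values)


def test_derivatives_balance_matches_reference(normal_state, normal_cond):
    """Both transcriptions give the same time derivative at a test state."""
    st = normal_state.copy()
    st.values[c.IV] = -30.0
    dy, _ = tp06_derivatives(st, normal_cond)
    dy_ref = np.asarray(ref.rhs(0.0, st.values))
    assert np.allclose(dy, dy_ref, rtol=1e-9, atol=1e-12)
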