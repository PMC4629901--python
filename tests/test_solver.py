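"""Monodomain solver: diffusion stencil, stimuli, full runs."""

import numpy as np
import pytest

import reference_tp06 as ref
from anisoblock import constants as c
from anisoblock.cell import CellConditions
from anisoblock.geometry import ConductivityMap, build_conductivity, two_region_cable
from anisoblock.solver import (
    SimulationConfig,
    SimulationUnstableError,
    apply_stimulus,
    diffusion_term,
    run_tissue,
    stimulus_bar_mask,
    stimulus_disc_mask,
)
from anisoblock.protocols import activation_times


def _uniform_cmap(ny, nx, sigma=0.154):
    return ConductivityMap(
        sigx=np.full((ny, nx - 1), sigma),
        sigy=np.full((max(ny - 1, 0), nx), sigma),
        sigma_par=sigma, sigma_perp=sigma, ar=1.0,
    )


def test_diffusion_of_uniform_field_vanishes():
    cmap = _uniform_cmap(4, 8)
    out = diffusion_term(np.full((4, 8), -85.0), cmap, 0.125)
    assert np.allclose(out, 0.0)


def test_diffusion_conserves_total_charge_under_neumann():
    rng = np.random.default_rng(42)
    v = rng.normal(-60, 20, size=(6, 11))
    cmap = _uniform_cmap(6, 11)
    out = diffusion_term(v, cmap, 0.125)
    assert abs(out.sum()) < 1e-9 * np.abs(out).sum()


def test_diffusion_shape_mismatch_rejected():
    cmap = _uniform_cmap(4, 8)
    with pytest.raises(ValueError, match="shape"):
        diffusion_term(np.zeros((4, 9)), cmap, 0.125)


def test_stimulus_sets_region_to_fifty_and_is_idempotent():
    v = np.full((3, 10), -85.0)
    mask = np.zeros_like(v, dtype=bool)
    mask[:, :2] = True
    apply_stimulus(v, mask)
    assert np.all(v[:, :2] == 50.0) and np.all(v[:, 2:] == -85.0)
    apply_stimulus(v, mask)
    assert np.all(v[:, :2] == 50.0)


def test_empty_stimulus_region_rejected():
    with pytest.raises(ValueError, match="empty"):
        apply_stimulus(np.zeros((2, 2)), np.zeros((2, 2), dtype=bool))


def test_bar_and_disc_masks():
    geom = two_region_cable(length_mm=8.0)
    assert stimulus_bar_mask(geom, 6).sum() == 6
    disc = stimulus_disc_mask(geom, 4.0, 0.0, radius_mm=0.3)
    assert disc.sum() >= 1


def test_stability_guard_rejects_coarse_timestep():
    cfg = SimulationConfig(dt=0.05, h_um=125.0, duration=10.0)
    with pytest.raises(ValueError, match="stability"):
        cfg.validate_stability(0.154)


def test_quiescent_tissue_stays_at_rest(normal_state, normal_cond):
    """No stimulus for 1 s: V drifts by less than 0.1 mV everywhere."""
    geom = two_region_cable(length_mm=4.0)   # 32 nodes
    cmap = build_conductivity(geom, 2.0)
    cfg = SimulationConfig(duration=1000.0, frame_stride_ms=0.0, probe_stride_ms=1.0)
    rec = run_tissue(geom, cmap, normal_cond, [], cfg, initial=normal_state,
                     probes=[(0, 0), (0, 16), (0, 31)])
    v = rec.probe_traces
    assert np.nanmax(np.abs(v - normal_state.V)) < 0.1


def test_nonfinite_state_aborts_with_location(normal_state, normal_cond):
    geom = two_region_cable(length_mm=4.0)
    cmap = build_conductivity(geom, 2.0)
    bad = normal_state.copy()
    bad.values[c.IV] = np.nan
    cfg = SimulationConfig(duration=10.0, frame_stride_ms=0.0)
    with pytest.raises(SimulationUnstableError):
        run_tissue(geom, cmap, normal_cond, [], cfg, initial=bad)


def test_plane_wave_speed_matches_method_of_lines_reference(normal_state, normal_cond):
    """Same discrete cable integrated by scipy (method of lines) and by the
    production kernel: conduction velocities agree within 5%."""
    sigma, h, length = 0.154, 0.125, 12.0
    nx = int(length / h)
    geom = two_region_cable(length_mm=length)
    cmap = _uniform_cmap(1, nx, sigma)
    cfg = SimulationConfig(duration=22.0, frame_stride_ms=0.0)
    p1, p2 = int(4.0 / h), int(9.0 / h)
    mask = stimulus_bar_mask(geom, 6)
    rec = run_tissue(geom, cmap, normal_cond, [(0.0, mask)], cfg,
                     initial=normal_state, probes=[(0, p1), (0, p2)])
    dt_s = cfg.probe_stride_ms
    t1 = activation_times(rec.probe_traces[:, 0], dt_s)[0]
    t2 = activation_times(rec.probe_traces[:, 1], dt_s)[0]
    v_kernel = (p2 - p1) * h / (t2 - t1)

    # method-of-lines reference on the identical grid
    y0 = np.tile(normal_state.values, (nx, 1))
    y0[:6, 0] = 50.0

    def mol_rhs(t, yflat):
        y = yflat.reshape(nx, 19)
        dy = ref.rhs_vec(t, y)
        v = y[:, 0]
        lap = np.zeros(nx)
        flux = sigma * (v[1:] - v[:-1])
        lap[:-1] += flux
        lap[1:] -= flux
        dy[:, 0] += lap / h ** 2
        return dy.ravel()

    from scipy.integrate import solve_ivp
    t_eval = np.arange(0.0, 22.0, 0.1)
    # node-major layout couples neighbouring V at offset 19: banded Jacobian
    sol = solve_ivp(mol_rhs, (0, 22.0), y0.ravel(), method="LSODA",
                    rtol=1e-6, atol=1e-8, t_eval=t_eval, lband=19, uband=19)
    vs = sol.y.reshape(nx, 19, -1)[:, 0, :]
    r1 = activation_times(vs[p1], 0.1)[0]
    r2 = activation_times(vs[p2], 0.1)[0]
    v_ref = (p2 - p1) * h / (r2 - r1)
    assert v_kernel == pytest.approx(v_ref, rel=0.05)


def test_record_frames_and_metadata(normal_state, normal_cond):
    geom = two_region_cable(length_mm=4.0)
    cmap = build_conductivity(geom, 2.0)
    cfg = SimulationConfig(duration=20.0, frame_stride_ms=5.0)
    mask = stimulus_bar_mask(geom, 6)
    rec = run_tissue(geom, cmap, normal_cond, [(0.0, mask)], cfg,
                     initial=normal_state, probes=[(0, 16)],
                     meta={"ar": 2.0})
    assert rec.frames.shape[0] == len(rec.frame_times)
    assert np.all(np.diff(rec.frame_times) > 0)
    assert rec.meta["ar"] == 2.0
    assert rec.meta["condition"] == "normal"
    m = rec.spacetime_matrix()
    assert m.shape == (rec.frames.shape[0], geom.nx)


def test_record_hdf5_roundtrip(tmp_path, normal_state, normal_cond):
    geom = two_region_cable(length_mm=4.0)
    cmap = build_conductivity(geom, 2.0)
    cfg = SimulationConfig(duration=10.0, frame_stride_ms=5.0)
    mask = stimulus_bar_mask(geom, 6)
    rec = run_tissue(geom, cmap, normal_cond, [(0.0, mask)], cfg,
                     initial=normal_state, probes=[(0, 8)])
    path = tmp_path / "rec.h5"
    rec.save(path)
    from anisoblock.solver import SpaceTimeRecord
    again = SpaceTimeRecord.load(path)
    assert np.array_equal(again.probe_traces, rec.probe_traces)
    assert again.meta["condition"] == rec.meta["condition"]
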