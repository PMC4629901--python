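"""Explicit monodomain integration on 1D/2D grids.

One unsplit forward-Euler step advances diffusion (half-node flux
differences, Neumann boundaries) and the TP06 reaction term together, via
the compiled kernel in :mod:`.kernels`.  Stimulation is a one-step voltage
reset to +50 mV in a region; there is no injected current.

The public entry point is :func:`run_tissue`, which runs a full protocol
(initial broadcast state, stimulus schedule, recording, optional early-stop
monitor) and returns a :class:`SpaceTimeRecord`.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from . import constants as c
from .cell import CellConditions, CellState, equilibrate
from .geometry import ConductivityMap, TissueGeometry
from . import kernels

__all__ = [
    "SimulationConfig",
    "SpaceTimeRecord",
    "SimulationUnstableError",
    "diffusion_term",
    "apply_stimulus",
    "run_tissue",
    "stimulus_bar_mask",
    "stimulus_disc_mask",
    "PRESET_1D",
    "PRESET_2D",
    "PRESET_FINE",
]

# (dt ms, h um) pairs used throughout
PRESET_1D = (0.005, 125.0)
PRESET_2D = (0.02, 250.0)
PRESET_FINE = (0.0008, 50.0)
_SUPPORTED_PRESETS = (PRESET_1D, PRESET_2D, PRESET_FINE)


class SimulationUnstableError(RuntimeError):
    def __init__(self, step: int, node: tuple, value: float):
        self.step = step
        self.node = node
        super().__init__(
            f"non-finite V at step {step}, node {node} (V={value}); "
            "explicit scheme unstable for this (dt, h, sigma)"
        )


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Numerical configuration of one tissue run."""

    dt: float = 0.005           # ms
    h_um: float = 125.0         # um
    duration: float = 500.0     # ms
    frame_stride_ms: float = 1.0    # 0 disables full-grid frames
    probe_stride_ms: float = 0.1    # sampling period of dense site traces
    record_dvdt: bool = False       # store dV/dt frames (wave-tip tracking)
    chunk_ms: float = 50.0          # monitor/stability-check granularity
    rev_refresh_ms: float = 0.1     # reversal-potential refresh period

    @property
    def h_mm(self) -> float:
        return self.h_um / 1000.0

    def validate_stability(self, sigma_max: float) -> None:
        """Reject (dt, h) violating the explicit bound dt <= 0.9 h^2/(4 sigma)."""
        dt_max = 0.9 * self.h_mm ** 2 / (4.0 * sigma_max)
        if self.dt > dt_max:
            raise ValueError(
                f"dt={self.dt} ms exceeds stability bound {dt_max:.5f} ms "
                f"for h={self.h_um} um, sigma_max={sigma_max} mm^2/ms"
            )


@dataclasses.dataclass
class SpaceTimeRecord:
    """Voltage sampled on the grid over time, plus dense probe traces.

    ``frames`` is (n_frames, ny, nx) float32 (empty when frame recording is
    off); ``probe_traces`` is (n_samples, n_probes).  ``meta`` carries the
    generating condition/geometry/protocol information needed to re-run the
    simulation.
    """

    frame_times: np.ndarray
    frames: np.ndarray
    dvdt_frames: Optional[np.ndarray]
    probe_times: np.ndarray
    probe_traces: np.ndarray
    probe_nodes: np.ndarray       # (n_probes, 2) (iy, ix)
    dt: float
    h_mm: float
    stim_times: np.ndarray
    duration: float               # actually simulated model time, ms
    stopped_early: bool
    meta: dict

    def probe_trace(self, i: int) -> tuple:
        tr = self.probe_traces[:, i]
        ok = ~np.isnan(tr)
        return self.probe_times[ok], tr[ok]

    def spacetime_matrix(self) -> np.ndarray:
        """(n_frames, nx) matrix of mid-row V, the space-time plot."""
        if self.frames.size == 0:
            raise ValueError("frame recording was disabled for this run")
        return self.frames[:, self.frames.shape[1] // 2, :]

    def export_spacetime_txt(self, path) -> None:
        np.savetxt(path, self.spacetime_matrix(), fmt="%.3f")

    def save(self, path) -> None:
        """Persist to an HDF5 container with the metadata embedded."""
        import json
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("frame_times", "frames", "probe_times", "probe_traces",
                         "probe_nodes", "stim_times"):
                f.create_dataset(name, data=getattr(self, name))
            if self.dvdt_frames is not None:
                f.create_dataset("dvdt_frames", data=self.dvdt_frames)
            f.attrs["dt"] = self.dt
            f.attrs["h_mm"] = self.h_mm
            f.attrs["duration"] = self.duration
            f.attrs["stopped_early"] = self.stopped_early
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "SpaceTimeRecord":
        import json
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                frame_times=f["frame_times"][...],
                frames=f["frames"][...],
                dvdt_frames=f["dvdt_frames"][...] if "dvdt_frames" in f else None,
                probe_times=f["probe_times"][...],
                probe_traces=f["probe_traces"][...],
                probe_nodes=f["probe_nodes"][...],
                dt=float(f.attrs["dt"]),
                h_mm=float(f.attrs["h_mm"]),
                stim_times=f["stim_times"][...],
                duration=float(f.attrs["duration"]),
                stopped_early=bool(f.attrs["stopped_early"]),
                meta=json.loads(f.attrs["meta"]),
            )


def diffusion_term(v_field: np.ndarray, cmap: ConductivityMap, h_mm: float) -> np.ndarray:
    """Half-node flux-difference divergence, Neumann (J=0) boundaries.

    Reference numpy implementation used by the passive cases and tests; the
    production loop applies the identical stencil inside the compiled kernel.
    """
    v = np.atleast_2d(np.asarray(v_field, dtype=float))
    if not np.all(np.isfinite(v)):
        raise ValueError("V field contains non-finite values")
    ny, nx = v.shape
    if cmap.sigx.shape != (ny, nx - 1) or (ny > 1 and cmap.sigy.shape != (ny - 1, nx)):
        raise ValueError(
            f"conductivity map shape {cmap.sigx.shape}/{cmap.sigy.shape} "
            f"does not match field {v.shape}"
        )
    out = np.zeros_like(v)
    jx = cmap.sigx * (v[:, 1:] - v[:, :-1])
    out[:, :-1] += jx
    out[:, 1:] -= jx
    if ny > 1:
        jy = cmap.sigy * (v[1:, :] - v[:-1, :])
        out[:-1, :] += jy
        out[1:, :] -= jy
    out /= h_mm ** 2
    return out.reshape(np.shape(v_field))


def stimulus_bar_mask(geom: TissueGeometry, width_px: int = 6) -> np.ndarray:
    """Rectangle ``width_px`` wide along the left edge of the sample."""
    mask = np.zeros(geom.shape, dtype=bool)
    mask[:, :width_px] = True
    return mask


def stimulus_disc_mask(geom: TissueGeometry, x_mm: float, y_mm: float, radius_mm: float = 1.0) -> np.ndarray:
    h = geom.h_mm
    ys, xs = np.mgrid[0:geom.ny, 0:geom.nx]
    mask = ((xs * h - x_mm) ** 2 + (ys * h - y_mm) ** 2) <= radius_mm ** 2
    return mask


def apply_stimulus(v_field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Set V to exactly +50 mV inside ``mask``; all other variables untouched."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(v_field):
        raise ValueError("stimulus mask shape does not match the field")
    if not mask.any():
        raise ValueError("empty stimulus region")
    v_field[mask] = 50.0
    return v_field


def run_tissue(
    geom: TissueGeometry,
    cmap: ConductivityMap,
    cond: CellConditions,
    stimuli: Sequence[tuple],
    config: SimulationConfig,
    initial: Optional[CellState] = None,
    probes: Optional[Sequence[tuple]] = None,
    monitor: Optional[Callable[[np.ndarray, np.ndarray, float], bool]] = None,
    meta: Optional[dict] = None,
) -> SpaceTimeRecord:
    """Run the full monodomain protocol and record it.

    Parameters
    ----------
    stimuli
        Sequence of ``(time_ms, mask)``; each is a one-step voltage reset.
        Masks must match the grid shape.
    initial
        Spatially uniform starting state.  Defaults to the 50 s equilibrated
        state for ``cond``.
    probes
        ``(iy, ix)`` node pairs traced at ``probe_stride_ms`` resolution.
    monitor
        Called after each chunk as ``monitor(probe_times, probe_traces,
        t_now)`` with the filled samples so far; returning True stops the
        run early (the record is truncated and flagged).
    """
    ny, nx = geom.shape
    if cmap.sigx.shape != (ny, max(nx - 1, 0)):
        raise ValueError("conductivity map does not match geometry")
    config.validate_stability(cmap.sigma_max)

    if initial is None:
        initial = equilibrate(cond).state
    tb = kernels.build_tables(cond, config.dt)
    V, Vp, Vn, G, C, REV = kernels.state_to_fields(initial.values, ny, nx)

    dt = config.dt
    n_total = int(round(config.duration / dt))
    probe_stride = max(1, int(round(config.probe_stride_ms / dt)))
    frame_stride = int(round(config.frame_stride_ms / dt)) if config.frame_stride_ms > 0 else 0
    rev_refresh = max(1, int(round(config.rev_refresh_ms / dt)))

    probes = list(probes or [])
    probe_iy = np.array([p[0] for p in probes], dtype=np.int64)
    probe_ix = np.array([p[1] for p in probes], dtype=np.int64)
    n_samples = n_total // probe_stride + 1 if probes else 0
    probe_out = np.full((n_samples, len(probes)), np.nan, dtype=np.float32)

    if frame_stride:
        n_frames = n_total // frame_stride + 1
        frames_v = np.full((n_frames, ny, nx), np.nan, dtype=np.float32)
        frames_d = (
            np.full((n_frames, ny, nx), np.nan, dtype=np.float32)
            if config.record_dvdt
            else np.zeros((0, ny, nx), dtype=np.float32)
        )
    else:
        frames_v = np.zeros((0, ny, nx), dtype=np.float32)
        frames_d = np.zeros((0, ny, nx), dtype=np.float32)

    # event schedule: stimulus applications at step boundaries
    stim_steps = []
    for t_stim, mask in stimuli:
        step = int(round(t_stim / dt))
        if not (0 <= step <= n_total):
            raise ValueError(f"stimulus at {t_stim} ms outside the run duration")
        stim_steps.append((step, mask))
    stim_steps.sort(key=lambda sm: sm[0])

    chunk_steps = max(1, int(round(config.chunk_ms / dt)))
    step = 0
    stopped = False
    i_stim = 0
    while step < n_total and not stopped:
        while i_stim < len(stim_steps) and stim_steps[i_stim][0] == step:
            apply_stimulus(V, stim_steps[i_stim][1])
            i_stim += 1
        next_event = stim_steps[i_stim][0] if i_stim < len(stim_steps) else n_total
        n_seg = min(next_event, step + chunk_steps) - step
        if n_seg <= 0:  # stimulus exactly at current step already applied
            n_seg = min(chunk_steps, n_total - step)
        try:
            kernels.advance_grid(
                V, Vp, Vn, G, C, REV,
                cmap.sigx, cmap.sigy, 1.0 / config.h_mm ** 2, dt,
                tb.tab_v, tb.tab_d,
                tb.gna, tb.gto, tb.gkr, tb.gks, tb.gk1_scale, tb.rule, tb.cm_inv, tb.ko,
                n_seg, step, rev_refresh,
                probe_iy, probe_ix, probe_stride if probes else 0, probe_out,
                frame_stride, frames_v, frames_d,
            )
        except (ZeroDivisionError, FloatingPointError):
            # the fastmath kernel can trip on a non-finite field before the
            # per-chunk check below gets to see it
            for arr in (V, Vp, Vn):
                if not np.all(np.isfinite(arr)):
                    bad = np.argwhere(~np.isfinite(arr))[0]
                    raise SimulationUnstableError(
                        step, tuple(bad), float(arr[tuple(bad)])) from None
            raise
        step += n_seg
        if not np.all(np.isfinite(V)):
            bad = np.argwhere(~np.isfinite(V))[0]
            raise SimulationUnstableError(step, tuple(bad), float(V[tuple(bad)]))
        if monitor is not None:
            nrow = min(step // probe_stride + 1, n_samples) if probes else 0
            t_now = step * dt
            if monitor(
                np.arange(nrow) * probe_stride * dt,
                probe_out[:nrow],
                t_now,
            ):
                stopped = True

    # final sample/frame at the end state
    t_end = step * dt
    if probes and step % probe_stride == 0 and step // probe_stride < n_samples:
        probe_out[step // probe_stride] = V[probe_iy, probe_ix]
    if frame_stride and step % frame_stride == 0 and step // frame_stride < frames_v.shape[0]:
        frames_v[step // frame_stride] = V
        if config.record_dvdt:
            frames_d[step // frame_stride] = (V - Vp) / dt

    n_rows = min(step // probe_stride + 1, n_samples) if probes else 0
    n_fr = min(step // frame_stride + 1, frames_v.shape[0]) if frame_stride else 0

    rec = SpaceTimeRecord(
        frame_times=np.arange(n_fr) * (frame_stride * dt) if frame_stride else np.zeros(0),
        frames=frames_v[:n_fr],
        dvdt_frames=frames_d[:n_fr] if config.record_dvdt else None,
        probe_times=np.arange(n_rows) * (probe_stride * dt),
        probe_traces=probe_out[:n_rows],
        probe_nodes=np.stack([probe_iy, probe_ix], axis=1) if probes else np.zeros((0, 2), dtype=int),
        dt=dt,
        h_mm=config.h_mm,
        stim_times=np.array([t for t, _ in stimuli], dtype=float),
        duration=t_end,
        stopped_early=stopped,
        meta=dict(
            meta or {},
            condition=cond.label(),
            condition_params={
                "g_na": cond.g_na, "g_cal": cond.g_cal, "g_kr": cond.g_kr,
                "g_ks": cond.g_ks, "g_k1": cond.g_k1, "ko": cond.ko,
                "ik1_rule": cond.ik1_rule, "cm": cond.cm,
            },
            geometry=geom.as_dict(),
            dt=config.dt,
        ),
    )
    rec._final_fields = (V, G, C)  # for chained runs / state extraction
    return rec
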