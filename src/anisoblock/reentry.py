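"""2D reentry induction at the fiber-orientation border and wave-tip tracking.

The induction protocol mirrors the tissue-scale experiments: a point
stimulus 6 mm to the transverse side of the border produces an elliptical
wave that is blocked frontally at the border but penetrates obliquely about
1 cm away; a second stimulus 500 ms later interacts with the refractory
tail of the first and sets up a rotating wave whose core sits near the
border.  In the fully anisotropic domain the core drifts along the border
(upward for the chirality induced by a stimulus below mid-height); an
isotropic strip or patch around the border can be added to probe whether
the drift can be arrested.

Wave tips are located per recorded frame as the crossing of the V = -40 mV
isoline with the wavefront/waveback watershed (dV/dt = 0 isoline,
implemented with a small positive margin to reject quiescent-tissue
noise) -- a standard phase-singularity proxy sufficient for drift-sign and
confinement measurements.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .cell import CellConditions
from .geometry import TissueGeometry, build_conductivity, two_region_sheet, SIGMA_PAR_DEFAULT
from .solver import (
    PRESET_2D,
    SimulationConfig,
    SpaceTimeRecord,
    run_tissue,
    stimulus_disc_mask,
)
from .protocols import activation_times

__all__ = ["ReentryProtocol", "ReentryReport", "run_reentry", "detect_and_track",
           "first_crossing_offset", "drift_profile"]

TIP_V_ISO = -40.0       # mV
TIP_DVDT_MARGIN = 0.1   # mV/ms; separates front (dV/dt >> 0) from tail


@dataclasses.dataclass(frozen=True)
class ReentryProtocol:
    """Two point stimuli near the border of an anisotropic sheet.

    Defaults reproduce the transient-reentry experiment: AR 2.0, severe
    hyperkalemia ([K+]o = 10 mM), both stimuli at the same site 6 mm into
    the transverse side of the border, 500 ms apart.  The sheet is quoted
    as (along-border) x (across-border): the border runs along the long
    axis ("vertical"), so the 6.4 x 3.2 cm sheet maps to width 3.2 cm
    across the border and height 6.4 cm along it, and the drift experiment
    extends the along-border length fourfold.  The stimulus sits below
    mid-height (``stim_y_frac`` of the height) so the oblique penetration
    above it sets a defined chirality.
    """

    width_cm: float = 3.2
    height_cm: float = 6.4
    ar: float = 2.0
    conditions: CellConditions = CellConditions(ko=10.0)
    stim_offset_mm: float = 6.0
    stim_y_frac: float = 0.25
    delay_ms: float = 500.0
    radius_mm: float = 3.0
    strip_halfwidth_mm: float = 0.0
    strip_sigma: str = "par"         # coupling inside the strip (see geometry)
    strip_patch_y_frac: float = None     # None: strip spans the full height
    strip_patch_halfheight_mm: float = None
    post_window_ms: float = 3000.0   # recorded time after the second stimulus

    def __post_init__(self) -> None:
        if self.delay_ms <= 0:
            raise ValueError("inter-stimulus delay must be positive")
        if self.stim_offset_mm <= self.radius_mm:
            raise ValueError("stimulus must lie inside the transverse region")

    def geometry(self, h_um: float = PRESET_2D[1]) -> TissueGeometry:
        y_center = (None if self.strip_patch_y_frac is None
                    else self.strip_patch_y_frac * self.height_cm * 10.0)
        return two_region_sheet(self.width_cm, self.height_cm, h_um,
                                self.strip_halfwidth_mm,
                                strip_y_center_mm=y_center,
                                strip_halfheight_mm=self.strip_patch_halfheight_mm)


@dataclasses.dataclass
class ReentryReport:
    """Outcome of a reentry-induction run."""

    sustained: bool               # >= 2 re-activations after the last stimulus
    period_ms: Optional[float]    # median cycle length of the reentrant source
    trajectory: np.ndarray        # (n, 3) columns t, x, y (ms, mm, mm); smoothed
    outcome: str                  # sustained | annihilated-at-boundary | stabilized | none


def run_reentry(
    protocol: ReentryProtocol,
    config: Optional[SimulationConfig] = None,
    monitor=None,
    initial=None,
) -> SpaceTimeRecord:
    """Run the two-stimulus induction protocol and record frames + dV/dt.

    ``initial`` defaults to the 50 s steady state equilibrated under the
    protocol's conditions (fully accommodated hyperkalemic tissue).
    """
    geom = protocol.geometry(config.h_um if config else PRESET_2D[1])
    duration = protocol.delay_ms + protocol.post_window_ms
    if config is None:
        config = SimulationConfig(
            dt=PRESET_2D[0], h_um=PRESET_2D[1], duration=duration,
            frame_stride_ms=5.0, record_dvdt=True, chunk_ms=100.0,
        )
    cmap = build_conductivity(geom, protocol.ar, SIGMA_PAR_DEFAULT,
                              strip_sigma=protocol.strip_sigma)
    x_stim = geom.border_x_mm - protocol.stim_offset_mm
    y_stim = protocol.stim_y_frac * geom.height_mm
    mask = stimulus_disc_mask(geom, x_stim, y_stim, protocol.radius_mm)
    probes = [
        (geom.node_at_y(y_stim), geom.node_at_x(x_stim)),
        (geom.node_at_y(geom.height_mm / 2), geom.node_at_x(geom.border_x_mm + 10.0)),
    ]
    rec = run_tissue(
        geom, cmap, protocol.conditions,
        [(0.0, mask), (protocol.delay_ms, mask)],
        config, probes=probes, monitor=monitor, initial=initial,
        meta={"protocol": "reentry", "ar": protocol.ar,
              "stim_xy_mm": (x_stim, y_stim),
              "strip_halfwidth_mm": protocol.strip_halfwidth_mm,
              "border_x_mm": geom.border_x_mm,
              "last_stim_ms": protocol.delay_ms},
    )
    return rec


def _tip_candidates(v_frame: np.ndarray, dvdt_frame: np.ndarray, h_mm: float,
                    margin_px: int = 2) -> np.ndarray:
    """(x, y) mm of 2x2 cells crossed by both the V and dV/dt isolines."""
    a = v_frame > TIP_V_ISO
    b = dvdt_frame > TIP_DVDT_MARGIN
    a00, a01, a10, a11 = a[:-1, :-1], a[:-1, 1:], a[1:, :-1], a[1:, 1:]
    b00, b01, b10, b11 = b[:-1, :-1], b[:-1, 1:], b[1:, :-1], b[1:, 1:]
    a_any = a00 | a01 | a10 | a11
    a_all = a00 & a01 & a10 & a11
    b_any = b00 | b01 | b10 | b11
    b_all = b00 & b01 & b10 & b11
    cand = a_any & ~a_all & b_any & ~b_all
    if margin_px:
        cand[:margin_px, :] = False
        cand[-margin_px:, :] = False
        cand[:, :margin_px] = False
        cand[:, -margin_px:] = False
    iy, ix = np.nonzero(cand)
    return np.stack([(ix + 0.5) * h_mm, (iy + 0.5) * h_mm], axis=1)


def detect_and_track(record: SpaceTimeRecord) -> ReentryReport:
    """Detect sustained reentry and track the wave-tip trajectory.

    Sustained means the reference node (the stimulus site) re-activates at
    least twice after the last stimulus with no further stimulation.  The
    tip is tracked frame by frame (nearest candidate to the previous tip;
    initialized nearest to the border) and the trajectory smoothed with a
    10 ms moving window.
    """
    if record.dvdt_frames is None or record.frames.size == 0:
        raise ValueError("reentry tracking needs frames recorded with dV/dt")
    last_stim = float(record.stim_times.max())

    # sustained iff any node re-activates >= 2 times after the last stimulus
    # (counted on the recorded frames; the stimulus-evoked upstroke itself
    # is excluded by starting just after the stimulus)
    post = record.frame_times > last_stim + 30.0
    fr = record.frames[post]
    t_post = record.frame_times[post][:-1]
    up = (fr[:-1] < TIP_V_ISO) & (fr[1:] >= TIP_V_ISO)
    # debounce: crossings closer than 80 ms at a node are border flicker,
    # not a new wave
    min_sep = 80.0

    def _debounced(mask_1d):
        tt = t_post[mask_1d]
        keep = []
        last = -np.inf
        for t in tt:
            if t - last >= min_sep:
                keep.append(t)
                last = t
        return np.asarray(keep)

    n_acts = up.sum(axis=0)
    sustained = False
    period = None
    if n_acts.size and n_acts.max() >= 2:
        order = np.argsort(n_acts.ravel())[::-1][:50]
        best = np.zeros(0)
        for flat in order:
            iy, ix = np.unravel_index(int(flat), n_acts.shape)
            tt = _debounced(up[:, iy, ix])
            if tt.size > best.size:
                best = tt
            if best.size >= 3:
                break
        sustained = best.size >= 2
        if best.size >= 2:
            period = float(np.median(np.diff(best)))

    h = record.h_mm
    border_x = record.meta.get("border_x_mm", 0.5 * record.frames.shape[2] * h)
    track = []
    prev = None
    for i, t in enumerate(record.frame_times):
        if t <= last_stim:
            continue
        pts = _tip_candidates(record.frames[i], record.dvdt_frames[i], h)
        if pts.shape[0] == 0:
            continue
        if prev is None:
            j = int(np.argmin(np.abs(pts[:, 0] - border_x)))
        else:
            d2 = (pts[:, 0] - prev[0]) ** 2 + (pts[:, 1] - prev[1]) ** 2
            j = int(np.argmin(d2))
            if d2[j] > 20.0 ** 2:   # lost the tip; re-seed near the border
                j = int(np.argmin(np.abs(pts[:, 0] - border_x)))
        near = pts[((pts[:, 0] - pts[j, 0]) ** 2 + (pts[:, 1] - pts[j, 1]) ** 2) < 4.0 ** 2]
        xy = near.mean(axis=0)
        prev = xy
        track.append((float(t), float(xy[0]), float(xy[1])))

    traj = np.asarray(track) if track else np.zeros((0, 3))
    if traj.shape[0] >= 3:
        frame_dt = float(record.frame_times[1] - record.frame_times[0])
        win = max(1, int(round(10.0 / frame_dt)))
        kern = np.ones(win) / win
        sm = traj.copy()
        for col in (1, 2):
            sm[:, col] = np.convolve(traj[:, col], kern, mode="same")
        sm[:win, 1:] = traj[:win, 1:]
        sm[-win:, 1:] = traj[-win:, 1:]
        traj = sm

    # terminal outcome
    ny = record.frames.shape[1]
    height_mm = ny * h
    end_active = bool((record.frames[-1] > TIP_V_ISO).any())
    tail = traj[traj[:, 0] > record.frame_times[-1] - 300.0] if traj.size else traj
    strip_hw = record.meta.get("strip_halfwidth_mm", 0.0)
    if not sustained:
        outcome = "none"
    elif end_active:
        if (strip_hw > 0 and tail.shape[0] > 0
                and np.all(np.abs(tail[:, 1] - border_x) <= strip_hw + 5.0)):
            outcome = "stabilized"
        else:
            outcome = "sustained"
    else:
        # locate the last activity from the frames themselves (the tip
        # detector can lose the core in the final fragmenting cycles)
        y_last = None
        for i in range(record.frames.shape[0] - 1, -1, -1):
            iy, _ = np.nonzero(record.frames[i] > TIP_V_ISO)
            if iy.size:
                y_last = iy.mean() * h
                break
        if y_last is not None and (y_last > height_mm - 10.0 or y_last < 10.0):
            outcome = "annihilated-at-boundary"
        else:
            outcome = "extinguished"

    return ReentryReport(sustained=sustained, period_ms=period,
                         trajectory=traj, outcome=outcome)


def drift_profile(record: SpaceTimeRecord, period_ms: float,
                  t_start: Optional[float] = None) -> np.ndarray:
    """Rotation-averaged y position of the excited region over time.

    Averaging the excited-area centroid over one rotation removes the
    within-cycle oscillation of the tip, leaving the slow drift of the core
    along the border.  Returns (window_center_ms, y_mm) rows for windows
    that contained activity.
    """
    if t_start is None:
        t_start = float(record.stim_times.max()) + 30.0
    h = record.h_mm
    rows = []
    for a in np.arange(t_start, record.frame_times[-1], period_ms):
        sel = (record.frame_times >= a) & (record.frame_times < a + period_ms)
        ys = []
        for i in np.nonzero(sel)[0]:
            iy, _ = np.nonzero(record.frames[i] > TIP_V_ISO)
            if iy.size:
                ys.append(iy.mean() * h)
        if ys:
            rows.append((a + period_ms / 2, float(np.mean(ys))))
    return np.asarray(rows)


def first_crossing_offset(record: SpaceTimeRecord) -> Optional[float]:
    """|y| distance (mm) between the stimulus site and the point where the
    wave first penetrates the border, from the recorded frames."""
    border_x = record.meta["border_x_mm"]
    x_stim, y_stim = record.meta["stim_xy_mm"]
    last_stim = float(record.stim_times.max())
    h = record.h_mm
    ix0 = int(border_x / h) + 3   # a few columns past the border
    for i, t in enumerate(record.frame_times):
        if t <= last_stim:
            continue
        sub = record.frames[i][:, ix0:ix0 + 4]
        if (sub > -20.0).any():
            iy = np.nonzero((sub > -20.0).any(axis=1))[0]
            y = iy.mean() * h
            return abs(float(y) - y_stim)
    return None
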