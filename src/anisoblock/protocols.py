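"""Measurement and search procedures on the two-region cable.

Everything the study quantifies lives here: activation detection, APD90,
restitution under decremental pacing, conduction classification at the
fiber-orientation border, the bisection searches for the critical
anisotropy ratio (single pulse and at fixed pacing frequency), the scan for
the critical block frequency, and the closed-form critical-period curve
T(AR) with its fit.

Default measurement conventions (all configurable):

* activation = upward crossing of -20 mV, debounced by a 50 ms refractory
  window;
* probes sit 10 mm on either side of the border, far enough that the
  electrotonic foot of the border delay does not reach them;
* paced trains deliver 7 stimuli of which the first 3 are ignored, so a 1:2
  pattern is observable twice among the 4 analyzed beats;
* a single pulse conducts iff the distal probe activates within 500 ms of
  the stimulus; a paced beat conducts iff the distal probe activates within
  one pacing period of the proximal activation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .cell import CellConditions, equilibrate
from .geometry import (
    SIGMA_PAR_DEFAULT,
    TissueGeometry,
    ConductivityMap,
    build_conductivity,
    two_region_cable,
)
from .solver import (
    PRESET_1D,
    SimulationConfig,
    SpaceTimeRecord,
    run_tissue,
    stimulus_bar_mask,
)

__all__ = [
    "PacingProtocol",
    "ConductionReport",
    "CriticalCurve",
    "FitParameters",
    "activation_times",
    "apd90",
    "restitution_curve",
    "classify_conduction",
    "single_pulse_conducts",
    "paced_conduction",
    "critical_ar_single_pulse",
    "critical_ar_at_frequency",
    "critical_block_frequency",
    "critical_period_at_ar",
    "evaluate_T",
    "fit_T_curve",
    "measure_plane_speed",
]

ACTIVATION_THRESHOLD = -20.0   # mV
REFRACTORY_MS = 50.0
PROBE_OFFSET_MM = 10.0
SINGLE_PULSE_WINDOW_MS = 500.0
RAMP_THRESHOLD_PERIOD = 1000.0 / 2.7   # ~370.4 ms; faster pacing is ramped
RAMP_START_PERIOD = 370.0
RAMP_DECREMENT = 5.0


# ---------------------------------------------------------------------------
# protocol / report containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PacingProtocol:
    """Periodic stimulation at the left edge of the sample.

    For target periods below the 2.7 Hz period the train is preceded by a
    decremental ramp: pacing starts at 370 ms and shortens by 5 ms per cycle
    until the target period is reached; ramp beats are never analyzed.
    """

    period: float
    n_stim: int = 7
    n_ignore: int = 3
    stim_width_px: int = 6

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.n_ignore < 0:
            raise ValueError("n_ignore must be >= 0")
        if self.n_stim <= self.n_ignore:
            raise ValueError("need more stimuli than ignored beats")

    def stimulus_times(self) -> np.ndarray:
        """Absolute stimulus times (ms), ramp beats first when engaged.

        The last ramp beat doubles as the first beat of the constant-period
        train (it falls among the ignored beats in any analysis).
        """
        times = [0.0]
        if self.period < RAMP_THRESHOLD_PERIOD:
            p = RAMP_START_PERIOD
            while p > self.period:
                times.append(times[-1] + p)
                p -= RAMP_DECREMENT
        for _ in range(self.n_stim - 1):
            times.append(times[-1] + self.period)
        return np.asarray(times)

    def analyzed_times(self) -> np.ndarray:
        """Stimulus times of the analyzed (post-ignore, post-ramp) beats."""
        t = self.stimulus_times()
        return t[-(self.n_stim - self.n_ignore):]


@dataclasses.dataclass
class ConductionReport:
    """Per-stimulus conduction outcome at the distal probe."""

    stim_times: np.ndarray
    analyzed: np.ndarray          # bool mask over stimuli
    conducted: np.ndarray         # bool per analyzed stimulus
    pattern: Optional[str]        # "1:1", "m:n", "full_block", or None
    delays_ms: Optional[np.ndarray] = None   # per conducted analyzed beat

    @property
    def n_analyzed(self) -> int:
        return int(self.analyzed.sum())

    @property
    def all_conducted(self) -> bool:
        return bool(self.conducted.all()) if self.conducted.size else False

    @property
    def any_blocked(self) -> bool:
        return bool((~self.conducted).any()) if self.conducted.size else True


@dataclasses.dataclass
class CriticalCurve:
    """(AR, T_pass, T_block) triples bracketing the critical period."""

    condition: str
    points: list  # of (ar, t_pass, t_block); t_block None if never blocked

    def __post_init__(self) -> None:
        for ar, t_pass, t_block in self.points:
            if t_pass is not None and t_block is not None and not t_pass > t_block:
                raise ValueError(f"T_pass must exceed T_block at AR={ar}")
        self.points = sorted(self.points, key=lambda p: p[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.points, columns=["AR", "T_pass", "T_block"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class FitParameters:
    """Parameters of the critical-period curve T(AR) = a + b AR^c/(AR1-AR)^d."""

    ar1: float    # single-pulse critical anisotropy (vertical asymptote)
    a: float      # short-period refractory asymptote, ms
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.ar1 <= 1.0:
            raise ValueError("AR1 must exceed 1")
        if self.a <= 0 or self.d <= 0:
            raise ValueError("a and d must be positive")


# ---------------------------------------------------------------------------
# trace analysis
# ---------------------------------------------------------------------------

def activation_times(
    trace: np.ndarray,
    dt_sample: float,
    threshold: float = ACTIVATION_THRESHOLD,
    refractory_ms: float = REFRACTORY_MS,
    t0: float = 0.0,
) -> np.ndarray:
    """Upward threshold crossings of a uniformly sampled voltage trace.

    Returns crossing times (the first sample at/above threshold), debounced
    so crossings closer than ``refractory_ms`` to the previous one are
    ignored.  Empty array if the trace never crosses.
    """
    v = np.asarray(trace, dtype=float)
    if v.size < 2:
        return np.zeros(0)
    ok = np.isfinite(v)
    idx = np.where(ok[:-1] & ok[1:] & (v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
    times = []
    last = -np.inf
    for i in idx:
        t = t0 + i * dt_sample
        if t - last >= refractory_ms:
            times.append(t)
            last = t
    return np.asarray(times)


def apd90(
    times: np.ndarray,
    trace: np.ndarray,
    activation_time: float,
    stim_time: Optional[float] = None,
    end_time: Optional[float] = None,
) -> float:
    """Action-potential duration to 90% repolarization, ms.

    Measured from ``activation_time`` to recovery of V below
    V_rest + 0.1 (V_peak - V_rest), where V_rest is the pre-stimulus
    voltage (the sample just before ``stim_time``, defaulting to just
    before the activation) and V_peak the maximum of the AP.  Returns NaN
    if repolarization does not complete inside the window (flagged missing
    value).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(trace, dtype=float)
    ref = activation_time if stim_time is None else stim_time
    pre = np.where(t < ref)[0]
    if pre.size == 0:
        return float("nan")
    v_rest = v[pre[-1]]
    sel = t >= activation_time
    if end_time is not None:
        sel &= t <= end_time
    tw, vw = t[sel], v[sel]
    if tw.size < 3:
        return float("nan")
    ipk = int(np.argmax(vw))
    v_peak = vw[ipk]
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    below = np.where(vw[ipk:] <= v90)[0]
    if below.size == 0:
        return float("nan")
    i = ipk + below[0]
    if i == 0:
        return float("nan")
    # linear interpolation between the bracketing samples
    t_cross = tw[i - 1] + (tw[i] - tw[i - 1]) * (vw[i - 1] - v90) / (vw[i - 1] - vw[i])
    return float(t_cross - activation_time)


# ---------------------------------------------------------------------------
# cable construction and runs
# ---------------------------------------------------------------------------

def _default_config(dt_h=PRESET_1D, duration=SINGLE_PULSE_WINDOW_MS, **kw) -> SimulationConfig:
    dt, h = dt_h
    return SimulationConfig(dt=dt, h_um=h, duration=duration, frame_stride_ms=0.0, **kw)


def _cable_assets(geom: TissueGeometry, launch_side: str = "left"):
    """Stimulus mask and (proximal, distal) probe nodes for a cable run."""
    h = geom.h_mm
    xb = geom.border_x_mm
    off = PROBE_OFFSET_MM
    if launch_side == "left":
        mask = stimulus_bar_mask(geom, 6)
        prox = (0, geom.node_at_x(xb - off))
        dist = (0, geom.node_at_x(xb + off))
    elif launch_side == "right":
        mask = np.zeros(geom.shape, dtype=bool)
        mask[:, -6:] = True
        prox = (0, geom.node_at_x(xb + off))
        dist = (0, geom.node_at_x(xb - off))
    else:
        raise ValueError(f"unknown launch side {launch_side!r}")
    return mask, [prox, dist]


class _ConductionMonitor:
    """Incremental per-stimulus conduction verdicts for early exit.

    Probe 0 is proximal (stimulated side of the border), probe 1 distal.
    A beat conducts iff the distal probe activates within ``dist_window``
    of the beat's proximal activation; the proximal activation itself must
    occur within ``prox_window`` of the stimulus (otherwise the beat never
    launched and counts as blocked).
    """

    def __init__(self, stim_times, analyzed_mask, prox_window, dist_window,
                 dt_sample, threshold=ACTIVATION_THRESHOLD):
        self.stim_times = np.asarray(stim_times, dtype=float)
        self.analyzed_mask = np.asarray(analyzed_mask, dtype=bool)
        self.prox_window = prox_window
        self.dist_window = dist_window
        self.dt_sample = dt_sample
        self.threshold = threshold
        self.verdicts = {}   # stim index -> bool conducted

    def _acts(self, traces, col):
        return activation_times(traces[:, col], self.dt_sample, self.threshold)

    def evaluate(self, times, traces, t_now) -> None:
        if traces.shape[0] < 2:
            return
        prox_acts = self._acts(traces, 0)
        dist_acts = self._acts(traces, 1)
        for k, ts in enumerate(self.stim_times):
            if not self.analyzed_mask[k] or k in self.verdicts:
                continue
            pa = prox_acts[(prox_acts >= ts) & (prox_acts < ts + self.prox_window)]
            if pa.size == 0:
                if t_now > ts + self.prox_window:
                    self.verdicts[k] = False
                continue
            p0 = pa[0]
            da = dist_acts[(dist_acts >= p0) & (dist_acts < p0 + self.dist_window)]
            if da.size:
                self.verdicts[k] = True
            elif t_now > p0 + self.dist_window:
                self.verdicts[k] = False

    def decided(self) -> bool:
        n_analyzed = int(self.analyzed_mask.sum())
        if any(not v for v in self.verdicts.values()):
            return True
        return len(self.verdicts) == n_analyzed

    def __call__(self, times, traces, t_now) -> bool:
        self.evaluate(times, traces, t_now)
        return self.decided()

    def report(self) -> ConductionReport:
        idx = [k for k in range(len(self.stim_times)) if self.analyzed_mask[k]]
        conducted = np.array([self.verdicts.get(k, False) for k in idx], dtype=bool)
        return ConductionReport(
            stim_times=self.stim_times,
            analyzed=self.analyzed_mask,
            conducted=conducted,
            pattern=_pattern_label(conducted),
        )


def _pattern_label(conducted: np.ndarray) -> Optional[str]:
    n = conducted.size
    if n < 2:
        return None
    if conducted.all():
        return "1:1"
    if not conducted.any():
        return "full_block"
    # periodic m-of-n conduction: find the smallest period consistent with
    # the outcome sequence
    for p in range(2, n + 1):
        if all(conducted[i] == conducted[i % p] for i in range(n)):
            m = int(conducted[:p].sum())
            g = math.gcd(m, p)
            return f"{m // g}:{p // g}"
    return "irregular"


def single_pulse_conducts(
    cond: CellConditions,
    ar: float,
    sigma_par: float = SIGMA_PAR_DEFAULT,
    geom: Optional[TissueGeometry] = None,
    config: Optional[SimulationConfig] = None,
    launch_side: str = "left",
    window_ms: float = SINGLE_PULSE_WINDOW_MS,
    return_record: bool = False,
):
    """Does one plane wave cross the fiber-orientation border?

    Launches a single stimulus from the chosen side of the two-region cable
    and reports whether the probe 10 mm beyond the border activates within
    ``window_ms`` of the stimulus.
    """
    geom = geom or two_region_cable()
    config = config or _default_config(duration=window_ms)
    cmap = build_conductivity(geom, ar, sigma_par)
    mask, probes = _cable_assets(geom, launch_side)
    mon = _ConductionMonitor([0.0], [True], window_ms, window_ms, config.probe_stride_ms)
    rec = run_tissue(
        geom, cmap, cond, [(0.0, mask)], config,
        probes=probes, monitor=mon,
        meta={"ar": ar, "protocol": "single_pulse", "launch_side": launch_side},
    )
    mon.evaluate(rec.probe_times, rec.probe_traces, rec.duration + config.probe_stride_ms)
    conducted = bool(mon.verdicts.get(0, False))
    return (conducted, rec) if return_record else conducted


def paced_conduction(
    cond: CellConditions,
    ar: float,
    protocol: PacingProtocol,
    sigma_par: float = SIGMA_PAR_DEFAULT,
    geom: Optional[TissueGeometry] = None,
    config: Optional[SimulationConfig] = None,
    return_record: bool = False,
):
    """Run a full pacing train at the border and classify each analyzed beat."""
    geom = geom or two_region_cable()
    stim_times = protocol.stimulus_times()
    duration = stim_times[-1] + protocol.period + SINGLE_PULSE_WINDOW_MS
    config = config or _default_config(duration=duration)
    cmap = build_conductivity(geom, ar, sigma_par)
    mask, probes = _cable_assets(geom)
    analyzed_mask = np.zeros(len(stim_times), dtype=bool)
    analyzed_mask[-(protocol.n_stim - protocol.n_ignore):] = True
    prox_window = max(protocol.period, 350.0)
    mon = _ConductionMonitor(
        stim_times, analyzed_mask, prox_window, protocol.period, config.probe_stride_ms
    )
    rec = run_tissue(
        geom, cmap, cond, [(t, mask) for t in stim_times], config,
        probes=probes, monitor=mon,
        meta={"ar": ar, "protocol": "paced", "period": protocol.period,
              "n_ignore": protocol.n_ignore},
    )
    mon.evaluate(rec.probe_times, rec.probe_traces, rec.duration + config.probe_stride_ms)
    report = mon.report()
    return (report, rec) if return_record else report


def classify_conduction(
    record: SpaceTimeRecord,
    period: Optional[float] = None,
    n_ignore: int = 3,
    compute_delays: bool = False,
    cond: Optional[CellConditions] = None,
    threshold: float = ACTIVATION_THRESHOLD,
) -> ConductionReport:
    """Post-hoc conduction classification of a recorded cable run.

    The record must carry proximal/distal probe traces (probes 0 and 1).
    ``period`` defaults to the record's pacing period (or the single-pulse
    window for one stimulus).  With ``compute_delays`` the border-crossing
    delay of each conducted beat is reported relative to the transit time
    expected from uniform-medium speeds at the same AR, isolating the
    boundary effect.
    """
    stim_times = record.stim_times
    dt_sample = float(record.probe_times[1] - record.probe_times[0])
    if period is None:
        period = record.meta.get("period")
    single = len(stim_times) == 1
    prox_window = SINGLE_PULSE_WINDOW_MS if single else max(period, 350.0)
    dist_window = SINGLE_PULSE_WINDOW_MS if single else period
    analyzed_mask = np.zeros(len(stim_times), dtype=bool)
    analyzed_mask[0 if single else min(n_ignore, len(stim_times) - 1):] = True
    mon = _ConductionMonitor(stim_times, analyzed_mask, prox_window, dist_window,
                             dt_sample, threshold)
    mon.evaluate(record.probe_times, record.probe_traces, record.duration + dt_sample)
    report = mon.report()

    if compute_delays:
        ar = record.meta.get("ar")
        if ar is None or cond is None:
            raise ValueError("delay computation needs the record AR and the condition")
        v_par = measure_plane_speed(cond, SIGMA_PAR_DEFAULT)
        v_perp = measure_plane_speed(cond, SIGMA_PAR_DEFAULT / ar ** 2)
        t_ref = PROBE_OFFSET_MM / v_perp + PROBE_OFFSET_MM / v_par
        prox_acts = activation_times(record.probe_traces[:, 0], dt_sample, threshold)
        dist_acts = activation_times(record.probe_traces[:, 1], dt_sample, threshold)
        delays = []
        idx = [k for k in range(len(stim_times)) if analyzed_mask[k]]
        for j, k in enumerate(idx):
            if not report.conducted[j]:
                continue
            ts = stim_times[k]
            p0 = prox_acts[(prox_acts >= ts) & (prox_acts < ts + prox_window)][0]
            d0 = dist_acts[(dist_acts >= p0) & (dist_acts < p0 + dist_window)][0]
            delays.append((d0 - p0) - t_ref)
        report.delays_ms = np.asarray(delays)
    return report


_SPEED_CACHE: dict = {}


def measure_plane_speed(
    cond: CellConditions,
    sigma: float,
    dt_h=PRESET_1D,
    length_mm: float = 40.0,
) -> float:
    """Plane-wave speed (mm/ms) in a uniform cable of coupling ``sigma``."""
    key = (cond, float(sigma), dt_h)
    if key in _SPEED_CACHE:
        return _SPEED_CACHE[key]
    dt, h_um = dt_h
    h = h_um / 1000.0
    nx = int(round(length_mm / h))
    geom = TissueGeometry(width_mm=length_mm, height_mm=h, h_um=h_um,
                          border_x_mm=length_mm / 2)
    cmap = ConductivityMap(
        sigx=np.full((1, nx - 1), sigma), sigy=np.zeros((0, nx)),
        sigma_par=sigma, sigma_perp=sigma, ar=1.0,
    )
    x1, x2 = 0.25 * length_mm, 0.75 * length_mm
    probes = [(0, geom.node_at_x(x1)), (0, geom.node_at_x(x2))]
    mask = stimulus_bar_mask(geom, 6)
    config = SimulationConfig(dt=dt, h_um=h_um, duration=1500.0, frame_stride_ms=0.0)
    rec = run_tissue(geom, cmap, cond, [(0.0, mask)], config, probes=probes,
                     monitor=lambda t, tr, now: bool(
                         activation_times(tr[:, 1], config.probe_stride_ms).size))
    dt_s = config.probe_stride_ms
    a1 = activation_times(rec.probe_traces[:, 0], dt_s)
    a2 = activation_times(rec.probe_traces[:, 1], dt_s)
    if a1.size == 0 or a2.size == 0:
        raise RuntimeError("plane wave failed to traverse the uniform cable")
    v = (x2 - x1) / (a2[0] - a1[0])
    _SPEED_CACHE[key] = v
    return v


# ---------------------------------------------------------------------------
# critical-parameter searches
# ---------------------------------------------------------------------------

def critical_ar_single_pulse(
    cond: CellConditions,
    tol: float = 0.01,
    bracket: tuple = (1.5, 8.0),
    **run_kw,
) -> float:
    """Critical anisotropy ratio for a single travelling pulse, by bisection.

    Conduction at the lower bracket and block at the upper are verified
    first; the bracket is then halved until narrower than ``tol`` and the
    midpoint returned.
    """
    if tol < 0.005:
        raise ValueError("tol below the supported resolution (0.005)")
    lo, hi = bracket
    ok_lo = single_pulse_conducts(cond, lo, **run_kw)
    ok_hi = single_pulse_conducts(cond, hi, **run_kw)
    if not ok_lo or ok_hi:
        raise RuntimeError(
            f"no conduction/block sign change in AR bracket {bracket}: "
            f"AR={lo} {'conducts' if ok_lo else 'blocks'}, "
            f"AR={hi} {'conducts' if ok_hi else 'blocks'}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if single_pulse_conducts(cond, mid, **run_kw):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def critical_ar_at_frequency(
    cond: CellConditions,
    f_hz: float,
    tol: float = 0.01,
    bracket: tuple = (1.5, 8.0),
    n_stim: int = 7,
    n_ignore: int = 3,
    **run_kw,
) -> float:
    """Critical AR under periodic pacing at ``f_hz`` (block = any analyzed
    beat failing to conduct)."""
    if not (0.3 <= f_hz <= 3.4):
        raise ValueError(f"pacing frequency {f_hz} Hz outside the supported range")
    protocol = PacingProtocol(period=1000.0 / f_hz, n_stim=n_stim, n_ignore=n_ignore)

    def blocks(ar):
        return paced_conduction(cond, ar, protocol, **run_kw).any_blocked

    lo, hi = bracket
    if blocks(lo) or not blocks(hi):
        raise RuntimeError(f"no conduction/block sign change in AR bracket {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if blocks(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def critical_block_frequency(
    cond: CellConditions,
    ar: float,
    f_min: float = 0.5,
    f_max: float = 3.3,
    df: float = 0.1,
    n_stim: int = 7,
    n_ignore: int = 3,
    **run_kw,
) -> Optional[float]:
    """Lowest pacing frequency (on a ``df`` grid) that produces block at
    fixed AR.

    Returns None if even the fastest rate conducts 1:1.  Uses bisection on
    the frequency grid; block is monotone in rate over the studied regime
    (shorter diastolic interval only hinders recovery at the border).
    """
    freqs = np.round(np.arange(f_min, f_max + df / 2, df), 10)

    def blocks(f):
        protocol = PacingProtocol(period=1000.0 / f, n_stim=n_stim, n_ignore=n_ignore)
        return paced_conduction(cond, ar, protocol, **run_kw).any_blocked

    if blocks(freqs[0]):
        return float(freqs[0])
    if not blocks(freqs[-1]):
        return None
    lo, hi = 0, len(freqs) - 1   # lo conducts, hi blocks
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if blocks(freqs[mid]):
            hi = mid
        else:
            lo = mid
    return float(freqs[hi])


def critical_period_at_ar(
    cond: CellConditions,
    ar: float,
    t_hi: float = 1500.0,
    t_lo: float = 305.0,
    resolution: float = 5.0,
    n_stim: int = 7,
    n_ignore: int = 3,
    **run_kw,
) -> tuple:
    """Bracket the critical pacing period at fixed AR to ``resolution`` ms.

    Returns (T_pass, T_block): the shortest tested period that conducts 1:1
    and the longest that blocks.  If every tested period conducts, T_block
    is None (far sub-critical AR).
    """
    def conducts(period):
        protocol = PacingProtocol(period=period, n_stim=n_stim, n_ignore=n_ignore)
        return not paced_conduction(cond, ar, protocol, **run_kw).any_blocked

    if not conducts(t_hi):
        raise RuntimeError(f"block even at T={t_hi} ms; AR={ar} exceeds the "
                           "single-pulse critical AR for this condition")
    if conducts(t_lo):
        return (t_lo, None)
    # grid bisection on multiples of `resolution`
    lo = int(t_lo // resolution)          # blocks
    hi = int(math.ceil(t_hi / resolution))  # passes
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if conducts(mid * resolution):
            hi = mid
        else:
            lo = mid
    return (hi * resolution, lo * resolution)


# ---------------------------------------------------------------------------
# single-cell pacing and restitution
# ---------------------------------------------------------------------------

def _single_cell_geometry() -> TissueGeometry:
    return TissueGeometry(width_mm=0.125, height_mm=0.125, h_um=125.0,
                          border_x_mm=0.0625)


def paced_single_cell(
    cond: CellConditions,
    protocol: PacingProtocol,
    dt: float = 0.02,
    tail_ms: float = 600.0,
) -> SpaceTimeRecord:
    """Pace an isolated cell by voltage reset and record its dense trace."""
    geom = _single_cell_geometry()
    cmap = ConductivityMap(sigx=np.zeros((1, 0)), sigy=np.zeros((0, 1)),
                           sigma_par=SIGMA_PAR_DEFAULT, sigma_perp=SIGMA_PAR_DEFAULT,
                           ar=1.0)
    stim_times = protocol.stimulus_times()
    config = SimulationConfig(dt=dt, h_um=125.0, duration=stim_times[-1] + tail_ms,
                              frame_stride_ms=0.0, chunk_ms=200.0)
    mask = np.ones((1, 1), dtype=bool)
    return run_tissue(geom, cmap, cond, [(t, mask) for t in stim_times], config,
                      probes=[(0, 0)],
                      meta={"protocol": "single_cell_pacing", "period": protocol.period,
                            "n_ignore": protocol.n_ignore})


def restitution_curve(
    cond: CellConditions,
    periods: Sequence[float],
    n_stim: int = 6,
    n_ignore: int = 3,
    dt: float = 0.02,
) -> list:
    """APD90 restitution under the decremental pacing rule.

    For each period the cell is paced with the ramp rule engaged below the
    2.7 Hz period; the mean APD90 of the analyzed beats is reported.  A
    period at which the cell itself drops beats (2:1 at the cell level) or
    fails to repolarize yields NaN, the flagged missing value.
    """
    out = []
    for period in periods:
        protocol = PacingProtocol(period=period, n_stim=n_stim, n_ignore=n_ignore)
        rec = paced_single_cell(cond, protocol, dt=dt)
        t, v = rec.probe_times, rec.probe_traces[:, 0]
        analyzed = protocol.analyzed_times()
        apds = []
        for k, ts in enumerate(analyzed):
            acts = activation_times(v, float(t[1] - t[0]))
            acts = acts[(acts >= ts) & (acts < ts + period)]
            if acts.size == 0:
                apds.append(float("nan"))
                continue
            end = analyzed[k + 1] if k + 1 < len(analyzed) else None
            apds.append(apd90(t, v, acts[0], stim_time=ts, end_time=end))
        out.append((float(period), float(np.mean(apds)) if apds else float("nan")))
    return out


# ---------------------------------------------------------------------------
# the critical-period curve and its fit
# ---------------------------------------------------------------------------

def evaluate_T(fit: FitParameters, ar) -> float:
    """The critical-period curve T(AR) = a + b AR^c / (AR1 - AR)^d (ms)."""
    ar = np.asarray(ar, dtype=float)
    if np.any(ar >= fit.ar1):
        raise ValueError(f"T(AR) is defined only below AR1={fit.ar1}")
    val = fit.a + fit.b * ar ** fit.c / (fit.ar1 - ar) ** fit.d
    return float(val) if val.ndim == 0 else val


def fit_T_curve(curve: CriticalCurve, ar1: float, a: float) -> FitParameters:
    """Least-squares fit of (b, c, d) on the log-period scale.

    AR1 and the short-period asymptote ``a`` are held fixed; the fit targets
    the midpoints (T_pass + T_block)/2 of the bracketing pairs.  Positivity
    of b and d is enforced by fitting their logarithms.
    """
    from scipy.optimize import least_squares

    pts = [(ar, 0.5 * (tp + tb)) for ar, tp, tb in curve.points if tb is not None]
    if len(pts) < 3:
        raise ValueError("need at least 3 bracketed points to fit b, c, d")
    ars = np.array([p[0] for p in pts])
    tmid = np.array([p[1] for p in pts])
    if np.any(ars >= ar1):
        raise ValueError("all fitted points must lie below AR1")

    def resid(p):
        log_b, cc, log_d = p
        model = a + np.exp(log_b) * ars ** cc / (ar1 - ars) ** np.exp(log_d)
        return np.log(model) - np.log(tmid)

    sol = least_squares(resid, x0=[np.log(0.01), 6.0, np.log(0.4)], method="lm")
    log_b, cc, log_d = sol.x
    return FitParameters(ar1=ar1, a=a, b=float(np.exp(log_b)), c=float(cc),
                         d=float(np.exp(log_d)))
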