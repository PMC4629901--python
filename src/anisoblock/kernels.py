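"""Compiled monodomain integration kernels.

The production integrator advances the TP06 reaction term together with the
half-node flux diffusion term in a single unsplit explicit step, exactly as
the discretized monodomain scheme prescribes: V and concentrations by
forward Euler, gates by Rush-Larsen exponential relaxation.

For speed, every purely voltage-dependent factor of the model (gate steady
states, Rush-Larsen multipliers for the chosen dt, and the voltage parts of
I_CaL, I_NaCa, I_NaK, I_pK) is pre-tabulated on a 0.01 mV grid and linearly
interpolated inside the numba kernel; the I_K1 rectification factor is
tabulated against V - E_K.  Reversal potentials are recomputed from the
dynamic intracellular concentrations every ``rev_refresh`` steps (default
0.1 ms); the concentrations drift by far less than table resolution on that
horizon.  Table interpolation error is ~1e-6 relative, orders of magnitude
below the discretization error of the scheme itself.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from . import constants as c
from .cell import (
    CellConditions,
    VOLTAGE_GATES,
    ical_factors,
    inaca_factors,
    inak_voltage_factor,
    ipk_voltage_factor,
    xk1_inf,
)

__all__ = ["Tables", "build_tables", "advance_grid", "integrate_single_cell"]

# voltage table grid
VMIN, VMAX, VSTEP = -120.0, 80.0, 0.01
# V - E_K grid for the I_K1 rectification factor
DMIN, DMAX, DSTEP = -100.0, 200.0, 0.01

_GATE_ORDER = ("m", "h", "j", "d", "f", "f2", "r", "s", "xr1", "xr2", "xs")
# table column layout: (inf, rl) pairs for the 11 voltage gates, then the
# current factors
_CA1, _CA2, _CB1, _CB2, _CNAK, _CPK = 22, 23, 24, 25, 26, 27
_NCOL = 28

# constants captured by the jitted kernel

# local bindings of model constants for the jitted kernels
_RTF = c.RTF
_NAO = c.NAO
_CAO = c.CAO
_P_KNA = c.P_KNA
_K_MNA = c.K_MNA
_G_PCA = c.G_PCA
_K_PCA = c.K_PCA
_G_BNA = c.G_BNA
_G_BCA = c.G_BCA
_MAX_SR = c.MAX_SR
_MIN_SR = c.MIN_SR
_EC_SR = c.EC_SR
_K1_PRIME = c.K1_PRIME
_K2_PRIME = c.K2_PRIME
_K3_RYR = c.K3_RYR
_K4_RYR = c.K4_RYR
_V_REL = c.V_REL
_V_LEAK = c.V_LEAK
_VMAX_UP = c.VMAX_UP
_K_UP = c.K_UP
_V_XFER = c.V_XFER
_BUF_C = c.BUF_C
_K_BUF_C = c.K_BUF_C
_BUF_SR = c.BUF_SR
_K_BUF_SR = c.K_BUF_SR
_BUF_SS = c.BUF_SS
_K_BUF_SS = c.K_BUF_SS

_CMVF = c.CM / (c.V_C * c.F)
_CM2SSF = c.CM / (2.0 * c.V_SS * c.F)
_VSR_VC = c.V_SR / c.V_C
_VSR_VSS = c.V_SR / c.V_SS
_VC_VSS = c.V_C / c.V_SS


@dataclasses.dataclass(frozen=True)
class Tables:
    """Pre-tabulated voltage factors plus baked conductance scalars."""

    tab_v: np.ndarray      # (npts, 28)
    tab_d: np.ndarray      # (npts_d,) I_K1 factor incl. G_K1*sqrt(Ko/5.4)
    dt: float
    ko: float
    gna: float             # G_Na * g_na
    gto: float
    gkr: float             # G_Kr * sqrt(Ko/5.4) * g_kr
    gks: float
    gk1_scale: float       # the conditional multiplier of the phase rule
    rule: int
    cm_inv: float


_TABLES_CACHE: dict = {}


def build_tables(cond: CellConditions, dt: float) -> Tables:
    key = (cond, float(dt))
    if key in _TABLES_CACHE:
        return _TABLES_CACHE[key]

    V = np.arange(VMIN, VMAX + VSTEP / 2, VSTEP)
    tab = np.empty((V.size, _NCOL))
    for k, name in enumerate(_GATE_ORDER):
        inf, tau = VOLTAGE_GATES[name](V)
        tab[:, 2 * k] = inf
        tab[:, 2 * k + 1] = np.exp(-dt / tau)
    a1, a2 = ical_factors(V)
    tab[:, _CA1] = cond.g_cal * a1
    tab[:, _CA2] = cond.g_cal * a2
    b1, b2 = inaca_factors(V)
    tab[:, _CB1] = b1
    tab[:, _CB2] = b2
    tab[:, _CNAK] = (
        c.P_NAK * cond.ko / (cond.ko + c.K_MK) * inak_voltage_factor(V)
    )
    tab[:, _CPK] = ipk_voltage_factor(V)

    dgrid = np.arange(DMIN, DMAX + DSTEP / 2, DSTEP)
    sqrt_ko = np.sqrt(cond.ko / 5.4)
    tab_d = c.G_K1 * sqrt_ko * xk1_inf(dgrid)

    res = Tables(
        tab_v=np.ascontiguousarray(tab),
        tab_d=np.ascontiguousarray(tab_d),
        dt=float(dt),
        ko=float(cond.ko),
        gna=c.G_NA * cond.g_na,
        gto=c.G_TO,
        gkr=c.G_KR * sqrt_ko * cond.g_kr,
        gks=c.G_KS * cond.g_ks,
        gk1_scale=cond.g_k1,
        rule=cond.rule_code,
        cm_inv=1.0 / cond.cm,
    )
    _TABLES_CACHE[key] = res
    return res


@njit(cache=True, fastmath=True)
def _refresh_rev(REV, C, ko):
    ny, nx = C.shape[0], C.shape[1]
    for iy in range(ny):
        for ix in range(nx):
            nai = C[iy, ix, 0]
            ki = C[iy, ix, 1]
            cai = C[iy, ix, 2]
            REV[iy, ix, 0] = _RTF * np.log(_NAO / nai)
            REV[iy, ix, 1] = _RTF * np.log(ko / ki)
            REV[iy, ix, 2] = _RTF * np.log((ko + _P_KNA * _NAO) / (ki + _P_KNA * nai))
            REV[iy, ix, 3] = 0.5 * _RTF * np.log(_CAO / cai)


@njit(cache=True, fastmath=True)
def advance_grid(
    V, Vprev, Vnew, G, C, REV,
    sigx, sigy, h2inv, dt,
    tab_v, tab_d,
    gna, gto, gkr, gks, gk1_scale, rule, cm_inv, ko,
    n_steps, step0, rev_refresh,
    probe_iy, probe_ix, probe_stride, probe_out,
    frame_stride, frames_v, frames_dvdt,
):
    """Advance the full monodomain state by ``n_steps`` unsplit Euler steps.

    Stimuli are applied by the caller between kernel calls (a stimulus is a
    plain voltage reset, so in-place modification of V at a step boundary is
    exactly the discrete scheme).  Probe rows / frame slabs are written at
    global-step indices so chunked calls fill one shared output array.
    On return V holds the final potential field and Vprev the previous step.
    """
    ny, nx = V.shape
    nprobe = probe_iy.shape[0]
    vinv = 1.0 / VSTEP
    dinv = 1.0 / DSTEP
    nv = tab_v.shape[0]
    nd = tab_d.shape[0]
    record_dvdt = frames_dvdt.shape[0] > 0

    A = Vprev
    B = V
    N = Vnew
    for istep in range(n_steps):
        gstep = step0 + istep
        if istep == 0 or gstep % rev_refresh == 0:
            _refresh_rev(REV, C, ko)
        # --- recording at step start (state at time gstep*dt) ---
        if probe_stride > 0:
            if gstep % probe_stride == 0:
                row = gstep // probe_stride
                if row < probe_out.shape[0]:
                    for p in range(nprobe):
                        probe_out[row, p] = B[probe_iy[p], probe_ix[p]]
        if frame_stride > 0:
            if gstep % frame_stride == 0:
                fr = gstep // frame_stride
                if fr < frames_v.shape[0]:
                    for iy in range(ny):
                        for ix in range(nx):
                            frames_v[fr, iy, ix] = B[iy, ix]
                            if record_dvdt:
                                frames_dvdt[fr, iy, ix] = (B[iy, ix] - A[iy, ix]) / dt

        for iy in range(ny):
            for ix in range(nx):
                v = B[iy, ix]
                # half-node flux differences; missing links = Neumann J=0
                lap = 0.0
                if ix + 1 < nx:
                    lap += sigx[iy, ix] * (B[iy, ix + 1] - v)
                if ix > 0:
                    lap -= sigx[iy, ix - 1] * (v - B[iy, ix - 1])
                if iy + 1 < ny:
                    lap += sigy[iy, ix] * (B[iy + 1, ix] - v)
                if iy > 0:
                    lap -= sigy[iy - 1, ix] * (v - B[iy - 1, ix])
                lap *= h2inv

                # table row for this voltage; NaN (instability) clamps to
                # the table edge and is caught by the caller's finite check
                t = (v - VMIN) * vinv
                if not (t >= 0.0):
                    t = 0.0
                elif t > nv - 2:
                    t = float(nv - 2)
                i0 = int(t)
                w = t - i0
                r0 = tab_v[i0]
                r1 = tab_v[i0 + 1]

                m = G[iy, ix, 0]
                hh = G[iy, ix, 1]
                jj = G[iy, ix, 2]
                d = G[iy, ix, 3]
                f = G[iy, ix, 4]
                f2 = G[iy, ix, 5]
                fcass = G[iy, ix, 6]
                r = G[iy, ix, 7]
                s = G[iy, ix, 8]
                xr1 = G[iy, ix, 9]
                xr2 = G[iy, ix, 10]
                xs = G[iy, ix, 11]
                nai = C[iy, ix, 0]
                ki = C[iy, ix, 1]
                cai = C[iy, ix, 2]
                casr = C[iy, ix, 3]
                cass = C[iy, ix, 4]
                rq = C[iy, ix, 5]
                ena = REV[iy, ix, 0]
                ek = REV[iy, ix, 1]
                eks = REV[iy, ix, 2]
                eca = REV[iy, ix, 3]

                # --- currents at the old state ---
                i_na = gna * m * m * m * hh * jj * (v - ena)

                dvs = v - A[iy, ix]
                if rule == 0:
                    mult = gk1_scale
                elif rule == 1:
                    mult = gk1_scale if dvs > 0.0 else 1.0
                elif rule == 2:
                    mult = gk1_scale if dvs <= 0.0 else 1.0
                elif rule == 3:
                    mult = gk1_scale if (dvs > 0.0 and v < -50.0) else 1.0
                else:
                    mult = gk1_scale if (dvs > 0.0 and v > -50.0) else 1.0
                dk = v - ek
                td = (dk - DMIN) * dinv
                if not (td >= 0.0):
                    td = 0.0
                elif td > nd - 2:
                    td = float(nd - 2)
                j0 = int(td)
                wd = td - j0
                xk1f = tab_d[j0] + (tab_d[j0 + 1] - tab_d[j0]) * wd
                i_k1 = mult * xk1f * dk

                i_to = gto * r * s * dk
                i_kr = gkr * xr1 * xr2 * dk
                i_ks = gks * xs * xs * (v - eks)

                a1 = r0[22] + (r1[22] - r0[22]) * w
                a2 = r0[23] + (r1[23] - r0[23]) * w
                i_cal = d * f * f2 * fcass * (a1 * cass - a2)

                b1 = r0[24] + (r1[24] - r0[24]) * w
                b2 = r0[25] + (r1[25] - r0[25]) * w
                i_naca = b1 * nai * nai * nai - b2 * cai

                nakf = r0[26] + (r1[26] - r0[26]) * w
                i_nak = nakf * nai / (nai + _K_MNA)

                i_pca = _G_PCA * cai / (cai + _K_PCA)
                pkf = r0[27] + (r1[27] - r0[27]) * w
                i_pk = pkf * dk
                i_bna = _G_BNA * (v - ena)
                i_bca = _G_BCA * (v - eca)

                i_ion = (
                    i_na + i_k1 + i_to + i_kr + i_ks + i_cal
                    + i_naca + i_nak + i_pca + i_pk + i_bca + i_bna
                )

                N[iy, ix] = v + dt * (lap - i_ion * cm_inv)

                # --- calcium subsystem (old state) ---
                kcasr = _MAX_SR - (_MAX_SR - _MIN_SR) / (1.0 + (_EC_SR / casr) ** 2)
                k1 = _K1_PRIME / kcasr
                k2 = _K2_PRIME * kcasr
                drq = -k2 * cass * rq + _K4_RYR * (1.0 - rq)
                oo = k1 * cass * cass * rq / (_K3_RYR + k1 * cass * cass)
                i_rel = _V_REL * oo * (casr - cass)
                i_leak = _V_LEAK * (casr - cai)
                i_up = _VMAX_UP / (1.0 + (_K_UP / cai) ** 2)
                i_xfer = _V_XFER * (cass - cai)

                buf_c = 1.0 / (1.0 + _BUF_C * _K_BUF_C / ((cai + _K_BUF_C) ** 2))
                buf_sr = 1.0 / (1.0 + _BUF_SR * _K_BUF_SR / ((casr + _K_BUF_SR) ** 2))
                buf_ss = 1.0 / (1.0 + _BUF_SS * _K_BUF_SS / ((cass + _K_BUF_SS) ** 2))

                C[iy, ix, 2] = cai + dt * buf_c * (
                    (i_leak - i_up) * _VSR_VC
                    + i_xfer
                    - (i_bca + i_pca - 2.0 * i_naca) * _CMVF * 0.5
                )
                C[iy, ix, 3] = casr + dt * buf_sr * (i_up - i_rel - i_leak)
                C[iy, ix, 4] = cass + dt * buf_ss * (
                    -i_cal * _CM2SSF + i_rel * _VSR_VSS - i_xfer * _VC_VSS
                )
                C[iy, ix, 0] = nai - dt * (i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * _CMVF
                C[iy, ix, 1] = ki - dt * (
                    i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk
                ) * _CMVF
                C[iy, ix, 5] = rq + dt * drq

                # --- Rush-Larsen gate relaxation toward V-dependent targets ---
                G[iy, ix, 0] = r0[0] + (r1[0] - r0[0]) * w + (m - (r0[0] + (r1[0] - r0[0]) * w)) * (r0[1] + (r1[1] - r0[1]) * w)
                G[iy, ix, 1] = r0[2] + (r1[2] - r0[2]) * w + (hh - (r0[2] + (r1[2] - r0[2]) * w)) * (r0[3] + (r1[3] - r0[3]) * w)
                G[iy, ix, 2] = r0[4] + (r1[4] - r0[4]) * w + (jj - (r0[4] + (r1[4] - r0[4]) * w)) * (r0[5] + (r1[5] - r0[5]) * w)
                G[iy, ix, 3] = r0[6] + (r1[6] - r0[6]) * w + (d - (r0[6] + (r1[6] - r0[6]) * w)) * (r0[7] + (r1[7] - r0[7]) * w)
                G[iy, ix, 4] = r0[8] + (r1[8] - r0[8]) * w + (f - (r0[8] + (r1[8] - r0[8]) * w)) * (r0[9] + (r1[9] - r0[9]) * w)
                G[iy, ix, 5] = r0[10] + (r1[10] - r0[10]) * w + (f2 - (r0[10] + (r1[10] - r0[10]) * w)) * (r0[11] + (r1[11] - r0[11]) * w)
                G[iy, ix, 7] = r0[12] + (r1[12] - r0[12]) * w + (r - (r0[12] + (r1[12] - r0[12]) * w)) * (r0[13] + (r1[13] - r0[13]) * w)
                G[iy, ix, 8] = r0[14] + (r1[14] - r0[14]) * w + (s - (r0[14] + (r1[14] - r0[14]) * w)) * (r0[15] + (r1[15] - r0[15]) * w)
                G[iy, ix, 9] = r0[16] + (r1[16] - r0[16]) * w + (xr1 - (r0[16] + (r1[16] - r0[16]) * w)) * (r0[17] + (r1[17] - r0[17]) * w)
                G[iy, ix, 10] = r0[18] + (r1[18] - r0[18]) * w + (xr2 - (r0[18] + (r1[18] - r0[18]) * w)) * (r0[19] + (r1[19] - r0[19]) * w)
                G[iy, ix, 11] = r0[20] + (r1[20] - r0[20]) * w + (xs - (r0[20] + (r1[20] - r0[20]) * w)) * (r0[21] + (r1[21] - r0[21]) * w)

                # fCaSS depends on subspace calcium, handled analytically
                xfc = (cass / 0.05) ** 2
                fcinf = 0.6 / (1.0 + xfc) + 0.4
                fctau = 80.0 / (1.0 + xfc) + 2.0
                G[iy, ix, 6] = fcinf + (fcass - fcinf) * np.exp(-dt / fctau)

        # rotate buffers: prev <- cur, cur <- new, new <- old prev storage
        tmp = A
        A = B
        B = N
        N = tmp

    # leave caller-visible arrays holding the final fields
    Bc = B.copy()
    Ac = A.copy()
    for iy in range(ny):
        for ix in range(nx):
            V[iy, ix] = Bc[iy, ix]
            Vprev[iy, ix] = Ac[iy, ix]


_EMPTY_PROBES = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))


def state_to_fields(y, ny=1, nx=1):
    """Broadcast a flat state vector to (V, Vprev, Vnew, G, C, REV) fields."""
    y = np.asarray(y, dtype=float)
    V = np.full((ny, nx), y[c.IV])
    G = np.empty((ny, nx, 12))
    for k in range(12):
        G[:, :, k] = y[1 + k]
    C = np.empty((ny, nx, 6))
    for k in range(6):
        C[:, :, k] = y[13 + k]
    REV = np.zeros((ny, nx, 4))
    return V, V.copy(), np.empty_like(V), G, C, REV


def fields_to_state(V, G, C, iy=0, ix=0):
    y = np.empty(c.N_STATE)
    y[c.IV] = V[iy, ix]
    y[1:13] = G[iy, ix, :]
    y[13:19] = C[iy, ix, :]
    return y


def _run_cell(fields, tb: Tables, n_steps: int, step0: int = 0):
    V, Vp, Vn, G, C, REV = fields
    sigx = np.zeros((V.shape[0], 0))
    sigy = np.zeros((0, V.shape[1]))
    empty_f = np.zeros((0, 1, 1), dtype=np.float32)
    empty_p = np.zeros((0, 0), dtype=np.float32)
    advance_grid(
        V, Vp, Vn, G, C, REV, sigx, sigy, 0.0, tb.dt,
        tb.tab_v, tb.tab_d,
        tb.gna, tb.gto, tb.gkr, tb.gks, tb.gk1_scale, tb.rule, tb.cm_inv, tb.ko,
        n_steps, step0, max(1, int(round(0.1 / tb.dt))),
        _EMPTY_PROBES[0], _EMPTY_PROBES[1], 0, empty_p,
        0, empty_f, empty_f,
    )


def integrate_single_cell(y0, cond: CellConditions, dt: float, n_steps: int, n_tail: int):
    """Integrate one unstimulated cell; returns final state and the
    per-variable absolute change over the final ``n_tail`` steps."""
    tb = build_tables(cond, dt)
    fields = state_to_fields(y0)
    head = max(0, n_steps - n_tail)
    if head:
        _run_cell(fields, tb, head)
    y_mid = fields_to_state(fields[0], fields[3], fields[4])
    if n_tail:
        _run_cell(fields, tb, n_tail, step0=head)
    y_end = fields_to_state(fields[0], fields[3], fields[4])
    return y_end, np.abs(y_end - y_mid)
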