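"""Independent reference integration of the TP06 epicardial cell model.

This is a second, deliberately separate transcription of the published
model equations, integrated with scipy's stiff ODE machinery rather than
the package's tabulated Rush-Larsen kernel.  It shares no code with
``anisoblock`` beyond the state-variable ordering, and exists purely as a
test oracle: agreement between the two routes checks the production kernel
(tables, interpolation, exponential gate updates, concentration balances)
against a plain transcription of the equations.
"""

import numpy as np
from scipy.integrate import solve_ivp

R, T, F = 8314.472, 310.0, 96485.3415
RTF = R * T / F

CM, VC, VSR, VSS = 0.185, 0.016404, 0.001094, 0.00005468
NAO, CAO = 140.0, 2.0

STATE = ("V", "m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
         "xr1", "xr2", "xs", "Nai", "Ki", "Cai", "CaSR", "CaSS", "Rq")


def rhs(t, y, ko=5.4, g_na=1.0, g_cal=1.0, g_kr=1.0, g_ks=1.0, g_k1=1.0):
    (V, m, h, j, d, f, f2, fcass, r, s, xr1, xr2, xs,
     Nai, Ki, Cai, CaSR, CaSS, Rq) = y

    ENa = RTF * np.log(NAO / Nai)
    EK = RTF * np.log(ko / Ki)
    EKs = RTF * np.log((ko + 0.03 * NAO) / (Ki + 0.03 * Nai))
    ECa = 0.5 * RTF * np.log(CAO / Cai)
    sq = np.sqrt(ko / 5.4)

    INa = g_na * 14.838 * m**3 * h * j * (V - ENa)

    ak1 = 0.1 / (1 + np.exp(0.06 * (V - EK - 200)))
    bk1 = (3 * np.exp(0.0002 * (V - EK + 100)) + np.exp(0.1 * (V - EK - 10))) / (
        1 + np.exp(-0.5 * (V - EK)))
    IK1 = g_k1 * 5.405 * sq * ak1 / (ak1 + bk1) * (V - EK)

    Ito = 0.294 * r * s * (V - EK)
    IKr = g_kr * 0.153 * sq * xr1 * xr2 * (V - EK)
    IKs = g_ks * 0.392 * xs**2 * (V - EKs)

    z = 2 * (V - 15) / RTF
    if abs(z) < 1e-7:
        ghk = 2 * F * (0.25 * CaSS - CAO)
    else:
        ghk = 2 * F * z * (0.25 * CaSS * np.exp(z) - CAO) / (np.exp(z) - 1)
    ICaL = g_cal * 3.98e-5 * d * f * f2 * fcass * ghk

    e1 = np.exp(0.35 * V / RTF)
    e2 = np.exp(-0.65 * V / RTF)
    INaCa = 1000.0 * (e1 * Nai**3 * CAO - e2 * NAO**3 * Cai * 2.5) / (
        (87.5**3 + NAO**3) * (1.38 + CAO) * (1 + 0.1 * e2))

    INaK = 2.724 * ko / (ko + 1.0) * Nai / (Nai + 40.0) / (
        1 + 0.1245 * np.exp(-0.1 * V / RTF) + 0.0353 * np.exp(-V / RTF))

    IpCa = 0.1238 * Cai / (Cai + 0.0005)
    IpK = 0.0146 * (V - EK) / (1 + np.exp((25 - V) / 5.98))
    IbNa = 0.00029 * (V - ENa)
    IbCa = 0.000592 * (V - ECa)

    Iion = INa + IK1 + Ito + IKr + IKs + ICaL + INaCa + INaK + IpCa + IpK + IbCa + IbNa

    # gate kinetics
    minf = 1 / (1 + np.exp((-56.86 - V) / 9.03))**2
    taum = (1 / (1 + np.exp((-60 - V) / 5))) * (
        0.1 / (1 + np.exp((V + 35) / 5)) + 0.1 / (1 + np.exp((V - 50) / 200)))
    hinf = 1 / (1 + np.exp((V + 71.55) / 7.43))**2
    if V < -40:
        ah, bh = 0.057 * np.exp(-(V + 80) / 6.8), 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1 + np.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1 + np.exp(-0.1378 * (V + 40.14)))
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1 + np.exp(-0.1 * (V + 32)))
    tauh, tauj = 1 / (ah + bh), 1 / (aj + bj)
    jinf = hinf

    dinf = 1 / (1 + np.exp((-8 - V) / 7.5))
    taud = ((1.4 / (1 + np.exp((-35 - V) / 13)) + 0.25) * (1.4 / (1 + np.exp((V + 5) / 5)))
            + 1 / (1 + np.exp((50 - V) / 20)))
    finf = 1 / (1 + np.exp((V + 20) / 7))
    tauf = (1102.5 * np.exp(-(V + 27)**2 / 225) + 200 / (1 + np.exp((13 - V) / 10))
            + 180 / (1 + np.exp((V + 30) / 10)) + 20)
    f2inf = 0.67 / (1 + np.exp((V + 35) / 7)) + 0.33
    tauf2 = (562 * np.exp(-(V + 27)**2 / 240) + 31 / (1 + np.exp((25 - V) / 10))
             + 80 / (1 + np.exp((V + 30) / 10)))
    fcinf = 0.6 / (1 + (CaSS / 0.05)**2) + 0.4
    taufc = 80 / (1 + (CaSS / 0.05)**2) + 2
    rinf = 1 / (1 + np.exp((20 - V) / 6))
    taur = 9.5 * np.exp(-(V + 40)**2 / 1800) + 0.8
    sinf = 1 / (1 + np.exp((V + 20) / 5))
    taus = 85 * np.exp(-(V + 45)**2 / 320) + 5 / (1 + np.exp((V - 20) / 5)) + 3
    xr1inf = 1 / (1 + np.exp((-26 - V) / 7))
    tauxr1 = (450 / (1 + np.exp((-45 - V) / 10))) * (6 / (1 + np.exp((V + 30) / 11.5)))
    xr2inf = 1 / (1 + np.exp((V + 88) / 24))
    tauxr2 = (3 / (1 + np.exp((-60 - V) / 20))) * (1.12 / (1 + np.exp((V - 60) / 20)))
    xsinf = 1 / (1 + np.exp((-5 - V) / 14))
    tauxs = (1400 / np.sqrt(1 + np.exp((5 - V) / 6))) * (1 / (1 + np.exp((V - 35) / 15))) + 80

    # calcium handling
    kcasr = 2.5 - 1.5 / (1 + (1.5 / CaSR)**2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    dRq = -k2 * CaSS * Rq + 0.005 * (1 - Rq)
    O = k1 * CaSS**2 * Rq / (0.06 + k1 * CaSS**2)
    Irel = 0.102 * O * (CaSR - CaSS)
    Ileak = 0.00036 * (CaSR - Cai)
    Iup = 0.006375 / (1 + (0.00025 / Cai)**2)
    Ixfer = 0.0038 * (CaSS - Cai)

    bc = 1 / (1 + 0.2 * 0.001 / (Cai + 0.001)**2)
    bsr = 1 / (1 + 10 * 0.3 / (CaSR + 0.3)**2)
    bss = 1 / (1 + 0.4 * 0.00025 / (CaSS + 0.00025)**2)

    dCai = bc * ((Ileak - Iup) * VSR / VC + Ixfer
                 - (IbCa + IpCa - 2 * INaCa) * CM / (2 * VC * F))
    dCaSR = bsr * (Iup - Irel - Ileak)
    dCaSS = bss * (-ICaL * CM / (2 * VSS * F) + Irel * VSR / VSS - Ixfer * VC / VSS)
    dNai = -(INa + IbNa + 3 * INaK + 3 * INaCa) * CM / (VC * F)
    dKi = -(IK1 + Ito + IKr + IKs - 2 * INaK + IpK) * CM / (VC * F)

    return [
        -Iion,
        (minf - m) / taum, (hinf - h) / tauh, (jinf - j) / tauj,
        (dinf - d) / taud, (finf - f) / tauf, (f2inf - f2) / tauf2,
        (fcinf - fcass) / taufc, (rinf - r) / taur, (sinf - s) / taus,
        (xr1inf - xr1) / tauxr1, (xr2inf - xr2) / tauxr2, (xsinf - xs) / tauxs,
        dNai, dKi, dCai, dCaSR, dCaSS, dRq,
    ]


def rhs_vec(t, Y):
    """Vectorized variant of :func:`rhs` over an array of cells (n, 19).

    Identical equations; the only change is np.where in place of the
    V < -40 branches so scipy can integrate a whole cable efficiently.
    """
    (V, m, h, j, d, f, f2, fcass, r, s, xr1, xr2, xs,
     Nai, Ki, Cai, CaSR, CaSS, Rq) = [Y[:, k] for k in range(19)]
    ko = 5.4

    ENa = RTF * np.log(NAO / Nai)
    EK = RTF * np.log(ko / Ki)
    EKs = RTF * np.log((ko + 0.03 * NAO) / (Ki + 0.03 * Nai))
    ECa = 0.5 * RTF * np.log(CAO / Cai)

    INa = 14.838 * m**3 * h * j * (V - ENa)
    ak1 = 0.1 / (1 + np.exp(0.06 * (V - EK - 200)))
    bk1 = (3 * np.exp(0.0002 * (V - EK + 100)) + np.exp(0.1 * (V - EK - 10))) / (
        1 + np.exp(-0.5 * (V - EK)))
    IK1 = 5.405 * ak1 / (ak1 + bk1) * (V - EK)
    Ito = 0.294 * r * s * (V - EK)
    IKr = 0.153 * xr1 * xr2 * (V - EK)
    IKs = 0.392 * xs**2 * (V - EKs)
    z = 2 * (V - 15) / RTF
    ez = np.exp(z)
    small = np.abs(z) < 1e-7
    ghk = np.where(
        small, 2 * F * (0.25 * CaSS - CAO),
        2 * F * z * (0.25 * CaSS * ez - CAO) / np.where(small, 1.0, ez - 1))
    ICaL = 3.98e-5 * d * f * f2 * fcass * ghk
    e1, e2 = np.exp(0.35 * V / RTF), np.exp(-0.65 * V / RTF)
    INaCa = 1000.0 * (e1 * Nai**3 * CAO - e2 * NAO**3 * Cai * 2.5) / (
        (87.5**3 + NAO**3) * (1.38 + CAO) * (1 + 0.1 * e2))
    INaK = 2.724 * ko / (ko + 1.0) * Nai / (Nai + 40.0) / (
        1 + 0.1245 * np.exp(-0.1 * V / RTF) + 0.0353 * np.exp(-V / RTF))
    IpCa = 0.1238 * Cai / (Cai + 0.0005)
    IpK = 0.0146 * (V - EK) / (1 + np.exp((25 - V) / 5.98))
    IbNa = 0.00029 * (V - ENa)
    IbCa = 0.000592 * (V - ECa)
    Iion = INa + IK1 + Ito + IKr + IKs + ICaL + INaCa + INaK + IpCa + IpK + IbCa + IbNa

    low = V < -40
    minf = 1 / (1 + np.exp((-56.86 - V) / 9.03))**2
    taum = (1 / (1 + np.exp((-60 - V) / 5))) * (
        0.1 / (1 + np.exp((V + 35) / 5)) + 0.1 / (1 + np.exp((V - 50) / 200)))
    hinf = 1 / (1 + np.exp((V + 71.55) / 7.43))**2
    ah = np.where(low, 0.057 * np.exp(-(V + 80) / 6.8), 0.0)
    bh = np.where(low, 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
                  0.77 / (0.13 * (1 + np.exp(-(V + 10.66) / 11.1))))
    aj = np.where(low,
                  (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
                  * (V + 37.78) / (1 + np.exp(0.311 * (V + 79.23))), 0.0)
    bj = np.where(low,
                  0.02424 * np.exp(-0.01052 * V) / (1 + np.exp(-0.1378 * (V + 40.14))),
                  0.6 * np.exp(0.057 * V) / (1 + np.exp(-0.1 * (V + 32))))
    dinf = 1 / (1 + np.exp((-8 - V) / 7.5))
    taud = ((1.4 / (1 + np.exp((-35 - V) / 13)) + 0.25) * (1.4 / (1 + np.exp((V + 5) / 5)))
            + 1 / (1 + np.exp((50 - V) / 20)))
    finf = 1 / (1 + np.exp((V + 20) / 7))
    tauf = (1102.5 * np.exp(-(V + 27)**2 / 225) + 200 / (1 + np.exp((13 - V) / 10))
            + 180 / (1 + np.exp((V + 30) / 10)) + 20)
    f2inf = 0.67 / (1 + np.exp((V + 35) / 7)) + 0.33
    tauf2 = (562 * np.exp(-(V + 27)**2 / 240) + 31 / (1 + np.exp((25 - V) / 10))
             + 80 / (1 + np.exp((V + 30) / 10)))
    fcinf = 0.6 / (1 + (CaSS / 0.05)**2) + 0.4
    taufc = 80 / (1 + (CaSS / 0.05)**2) + 2
    rinf = 1 / (1 + np.exp((20 - V) / 6))
    taur = 9.5 * np.exp(-(V + 40)**2 / 1800) + 0.8
    sinf = 1 / (1 + np.exp((V + 20) / 5))
    taus = 85 * np.exp(-(V + 45)**2 / 320) + 5 / (1 + np.exp((V - 20) / 5)) + 3
    xr1inf = 1 / (1 + np.exp((-26 - V) / 7))
    tauxr1 = (450 / (1 + np.exp((-45 - V) / 10))) * (6 / (1 + np.exp((V + 30) / 11.5)))
    xr2inf = 1 / (1 + np.exp((V + 88) / 24))
    tauxr2 = (3 / (1 + np.exp((-60 - V) / 20))) * (1.12 / (1 + np.exp((V - 60) / 20)))
    xsinf = 1 / (1 + np.exp((-5 - V) / 14))
    tauxs = (1400 / np.sqrt(1 + np.exp((5 - V) / 6))) * (1 / (1 + np.exp((V - 35) / 15))) + 80

    kcasr = 2.5 - 1.5 / (1 + (1.5 / CaSR)**2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    dRq = -k2 * CaSS * Rq + 0.005 * (1 - Rq)
    O = k1 * CaSS**2 * Rq / (0.06 + k1 * CaSS**2)
    Irel = 0.102 * O * (CaSR - CaSS)
    Ileak = 0.00036 * (CaSR - Cai)
    Iup = 0.006375 / (1 + (0.00025 / Cai)**2)
    Ixfer = 0.0038 * (CaSS - Cai)
    bc = 1 / (1 + 0.2 * 0.001 / (Cai + 0.001)**2)
    bsr = 1 / (1 + 10 * 0.3 / (CaSR + 0.3)**2)
    bss = 1 / (1 + 0.4 * 0.00025 / (CaSS + 0.00025)**2)

    out = np.empty_like(Y)
    out[:, 0] = -Iion
    out[:, 1] = (minf - m) / taum
    out[:, 2] = (hinf - h) * (ah + bh)
    out[:, 3] = (hinf - j) * (aj + bj)
    out[:, 4] = (dinf - d) / taud
    out[:, 5] = (finf - f) / tauf
    out[:, 6] = (f2inf - f2) / tauf2
    out[:, 7] = (fcinf - fcass) / taufc
    out[:, 8] = (rinf - r) / taur
    out[:, 9] = (sinf - s) / taus
    out[:, 10] = (xr1inf - xr1) / tauxr1
    out[:, 11] = (xr2inf - xr2) / tauxr2
    out[:, 12] = (xsinf - xs) / tauxs
    out[:, 13] = -(INa + IbNa + 3 * INaK + 3 * INaCa) * CM / (VC * F)
    out[:, 14] = -(IK1 + Ito + IKr + IKs - 2 * INaK + IpK) * CM / (VC * F)
    out[:, 15] = bc * ((Ileak - Iup) * VSR / VC + Ixfer
                       - (IbCa + IpCa - 2 * INaCa) * CM / (2 * VC * F))
    out[:, 16] = bsr * (Iup - Irel - Ileak)
    out[:, 17] = bss * (-ICaL * CM / (2 * VSS * F) + Irel * VSR / VSS - Ixfer * VC / VSS)
    out[:, 18] = dRq
    return out


def integrate(y0, t_span, t_eval=None, **cond):
    sol = solve_ivp(
        rhs, t_span, y0, args=tuple(cond.get(k, v) for k, v in
                                    (("ko", 5.4), ("g_na", 1.0), ("g_cal", 1.0),
                                     ("g_kr", 1.0), ("g_ks", 1.0), ("g_k1", 1.0))),
        method="LSODA", rtol=1e-8, atol=1e-10, t_eval=t_eval, max_step=1.0,
    )
    if not sol.success:
        raise RuntimeError(sol.message)
    return sol
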