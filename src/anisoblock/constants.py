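"""TP06 human ventricular epicardial parameter set.

All values are the epicardial-cell constants of the ten Tusscher & Panfilov
(2006) human ventricular ionic model ("TP06"), as distributed in the authors'
reference source and the curated CellML encoding of the model.  Units follow
the model's conventions: time in ms, voltage in mV, concentrations in mM,
currents in pA/pF, maximal conductances in nS/pF.

Do not edit individual numbers in place; this file is the single versioned
source of the model constants for every integration path in the package.
"""

# physical constants
R = 8314.472        # J/(kmol*K)
T = 310.0           # K
F = 96485.3415      # C/mol
RTF = R * T / F     # mV
FRT = 1.0 / RTF

# cell geometry / capacitance (enters only the concentration balances)
CM = 0.185          # membrane capacitance used in flux scaling, uF
V_C = 0.016404      # cytoplasmic volume, um^3 (model units)
V_SR = 0.001094     # sarcoplasmic reticulum volume
V_SS = 0.00005468   # dyadic subspace volume

# external ionic concentrations (mM); Ko is the *default*, overridden by
# CellConditions for hyperkalemia scans
KO_DEFAULT = 5.4
NAO = 140.0
CAO = 2.0

# maximal conductances (nS/pF), epicardial variant
G_NA = 14.838
G_K1 = 5.405
G_TO = 0.294        # epicardial transient outward
G_KR = 0.153
G_KS = 0.392        # epicardial
G_CAL = 3.98e-5     # L-type Ca, cm^3/(uF*s) in the model's formulation
G_BNA = 0.00029
G_BCA = 0.000592
G_PCA = 0.1238
G_PK = 0.0146
K_PCA = 0.0005

# Na/K pump and Na/Ca exchanger
P_NAK = 2.724
K_MK = 1.0
K_MNA = 40.0
K_NACA = 1000.0
K_SAT = 0.1
ALPHA_NACA = 2.5
GAMMA_NACA = 0.35
KM_CA = 1.38
KM_NAI = 87.5

# IKs K/Na permeability ratio
P_KNA = 0.03

# calcium handling (RyR release, SERCA uptake, leak, subspace transfer)
K1_PRIME = 0.15
K2_PRIME = 0.045
K3_RYR = 0.06
K4_RYR = 0.005
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0
V_REL = 0.102       # mM/ms
V_XFER = 0.0038
K_UP = 0.00025
V_LEAK = 0.00036
VMAX_UP = 0.006375

# cytosolic / SR / subspace buffering
BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

# published TP06 epicardial initial conditions (steady state under 1 Hz
# pacing in the reference implementation); used only as an integration
# starting point -- production runs re-equilibrate per condition.
INITIAL_STATE = {
    "V": -85.23,
    "m": 0.00172,
    "h": 0.7444,
    "j": 0.7045,
    "d": 3.373e-5,
    "f": 0.7888,
    "f2": 0.9755,
    "fcass": 0.9953,
    "r": 2.42e-8,
    "s": 0.999998,
    "xr1": 0.00621,
    "xr2": 0.4712,
    "xs": 0.0095,
    "Nai": 8.604,
    "Ki": 136.89,
    "Cai": 0.000126,
    "CaSR": 3.64,
    "CaSS": 0.00036,
    "Rq": 0.9073,
}

# canonical state-vector layout shared by every integrator in the package
STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
    "xr1", "xr2", "xs", "Nai", "Ki", "Cai", "CaSR", "CaSS", "Rq",
)
N_STATE = len(STATE_NAMES)
GATE_NAMES = ("m", "h", "j", "d", "f", "f2", "fcass", "r", "s", "xr1", "xr2", "xs")

# index constants (kept explicit so numba kernels can use them as globals)
IV, IM, IH, IJ, ID, IF, IF2, IFCASS, IR, IS, IXR1, IXR2, IXS, \
    INAI, IKI, ICAI, ICASR, ICASS, IRQ = range(N_STATE)
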