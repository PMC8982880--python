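"""Gate-based human cardiac cell models: TP (ventricular) and ST (Purkinje).

Full ODE implementations of the ten Tusscher–Panfilov 2006 epicardial
ventricular model (TP) and the Stewart et al. 2009 Purkinje model (ST),
transcribed from the original publications / their standard CellML
encodings.  Both models drive the L-type calcium current through the gate
product O = d·f·f2·fcass and the shared driving-force expression
I_CaL = O × Imax, which is the decomposition the Markov-chain replacement
in :mod:`icalmc.markov_ical` plugs into.

State layout (gates deliberately last, so the hybrid models can keep the
base block untouched and swap the gate block for Markov occupancies):

* TP:  V, Ki, Nai, Cai, CaSR, CaSS, Rbar, m, h, j, r, s, Xr1, Xr2, Xs,
       d, f, f2, fCass                                    (19 states)
* ST:  same plus the funny-current gate y before the I_CaL gates
                                                          (20 states)

Units: time ms, voltage mV, concentrations mM, currents A/F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numba import njit

__all__ = [
    "MODEL_IDS",
    "ICAL_GATES",
    "CellModelSpec",
    "gate_rates",
    "opening_fraction_gates",
    "ical_driving_force",
    "gate_model_rhs",
    "build_gate_model",
    "R_GAS",
    "TEMPERATURE",
    "FARADAY",
    "G_CAL",
    "CA_O",
]

MODEL_IDS = ("TP", "ST")
ICAL_GATES = ("d", "f", "f2", "fcass")


class ConfigurationError(ValueError):
    """Unknown model, gate or variant identifier."""


class NumericalStateError(ValueError):
    """A state variable left its physical range beyond tolerance."""


class SimulationFailure(RuntimeError):
    """The right-hand side produced a non-finite derivative."""


# ----------------------------------------------------------------------
# Physical constants and parameters shared by both models
# ----------------------------------------------------------------------

R_GAS = 8314.472        # J/(kmol*K)
TEMPERATURE = 310.0     # K
FARADAY = 96485.3415    # C/mmol

K_O = 5.4               # mM
NA_O = 140.0            # mM
CA_O = 2.0              # mM

CM = 0.185              # uF
V_C = 0.016404          # um^3 (bulk cytoplasm)
V_SR = 0.001094
V_SS = 0.00005468

G_CAL = 3.98e-5         # maximum I_CaL conductance (both models)
P_KNA = 0.03

# Calcium subsystem (identical in TP and ST)
BUF_C, K_BUF_C = 0.2, 0.001
BUF_SR, K_BUF_SR = 10.0, 0.3
BUF_SS, K_BUF_SS = 0.4, 0.00025
VMAX_UP, K_UP = 0.006375, 0.00025
V_REL, V_LEAK, V_XFER = 0.102, 0.00036, 0.0038
K1_PRIME, K2_PRIME, K3, K4 = 0.15, 0.045, 0.06, 0.005
EC_SR, MAX_SR, MIN_SR = 1.5, 2.5, 1.0

# Na/K pump, Na/Ca exchanger, background and plateau currents (shared)
P_NAK, K_MK, K_MNA = 2.724, 1.0, 40.0
K_NACA, K_SAT, GAMMA_NACA = 1000.0, 0.1, 0.35
KM_NAI, KM_CA, ALPHA_NACA = 87.5, 1.38, 2.5
G_BNA, G_BCA = 0.00029, 0.000592
G_PCA, K_PCA, G_PK = 0.1238, 0.0005, 0.0146

# TP (epicardial) conductances
TP_G_NA, TP_G_K1, TP_G_KR = 14.838, 5.405, 0.153
TP_G_KS, TP_G_TO = 0.392, 0.294

# ST (Purkinje) conductances
ST_G_NA, ST_G_K1, ST_G_KR = 130.5744, 0.065, 0.0918
ST_G_KS, ST_G_TO = 0.2352, 0.08184
ST_G_SUS, ST_G_F_NA, ST_G_F_K = 0.0227, 0.0145654, 0.0234346

_RTF = R_GAS * TEMPERATURE / FARADAY


# ----------------------------------------------------------------------
# I_CaL gate kinetics (scalar, numba-compiled; shared by gate and MC code)
# ----------------------------------------------------------------------

@njit(cache=True)
def _d_gate(v):
    d_inf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    a = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    b = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    g = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    return d_inf, a * b + g


@njit(cache=True)
def _f_gate(v):
    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tau = (1102.5 * math.exp(-((v + 27.0) ** 2) / 225.0)
           + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
           + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0)
    return f_inf, tau


@njit(cache=True)
def _f2_gate(v):
    # the revised (author-code) time constant, shared by both models
    f2_inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    tau = (562.0 * math.exp(-((v + 27.0) ** 2) / 240.0)
           + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
           + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0)))
    return f2_inf, tau


@njit(cache=True)
def _fcass_gate(css):
    s = 1.0 / (1.0 + (css / 0.05) ** 2)
    return 0.6 * s + 0.4, 80.0 * s + 2.0


@njit(cache=True)
def _driving_force(v, css):
    """Imax of I_CaL = O × Imax (A/F); removable singularity at v = 15 mV."""
    z = 2.0 * (v - 15.0) * FARADAY / (R_GAS * TEMPERATURE)
    num = 0.25 * css * math.exp(z) - CA_O
    if abs(z) < 1e-7:
        # z/(e^z - 1) ~ 1 - z/2 + z^2/12
        frac = (1.0 - z / 2.0 + z * z / 12.0) * _RTF / 2.0
    else:
        frac = (v - 15.0) / math.expm1(z)
    return G_CAL * 4.0 * FARADAY * FARADAY / (R_GAS * TEMPERATURE) * frac * num


# ----------------------------------------------------------------------
# Shared base dynamics (everything except I_CaL and its gates)
# ----------------------------------------------------------------------
# y[0..14] = V, Ki, Nai, Cai, CaSR, CaSS, Rbar, m, h, j, r, s, Xr1, Xr2, Xs

@njit(cache=True)
def _base_rhs(y, dy, i_cal, i_stim, st_model, y_gate):
    v, ki, nai, cai, casr, cass = y[0], y[1], y[2], y[3], y[4], y[5]
    rbar = y[6]
    m, h, j = y[7], y[8], y[9]
    r, s = y[10], y[11]
    xr1, xr2, xs = y[12], y[13], y[14]

    e_k = _RTF * math.log(K_O / ki)
    e_na = _RTF * math.log(NA_O / nai)
    e_ks = _RTF * math.log((K_O + P_KNA * NA_O) / (ki + P_KNA * nai))
    e_ca = 0.5 * _RTF * math.log(CA_O / cai)

    # Fast sodium
    g_na = ST_G_NA if st_model else TP_G_NA
    i_na = g_na * m ** 3 * h * j * (v - e_na)

    # Inward rectifier
    if st_model:
        xk1_inf = 1.0 / (1.0 + math.exp(0.1 * (v + 75.44)))
        i_k1 = ST_G_K1 * xk1_inf * (v - 8.0 - e_k)
    else:
        a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
        b_k1 = ((3.0 * math.exp(0.0002 * (v - e_k + 100.0))
                 + math.exp(0.1 * (v - e_k - 10.0)))
                / (1.0 + math.exp(-0.5 * (v - e_k))))
        i_k1 = TP_G_K1 * a_k1 / (a_k1 + b_k1) * math.sqrt(K_O / 5.4) * (v - e_k)

    g_kr = ST_G_KR if st_model else TP_G_KR
    i_kr = g_kr * math.sqrt(K_O / 5.4) * xr1 * xr2 * (v - e_k)

    g_ks = ST_G_KS if st_model else TP_G_KS
    i_ks = g_ks * xs * xs * (v - e_ks)

    g_to = ST_G_TO if st_model else TP_G_TO
    i_to = g_to * r * s * (v - e_k)

    i_nak = (P_NAK * K_O * nai
             / ((K_O + K_MK) * (nai + K_MNA)
                * (1.0 + 0.1245 * math.exp(-0.1 * v / _RTF)
                   + 0.0353 * math.exp(-v / _RTF))))
    i_naca = (K_NACA
              * (math.exp(GAMMA_NACA * v / _RTF) * nai ** 3 * CA_O
                 - math.exp((GAMMA_NACA - 1.0) * v / _RTF)
                 * NA_O ** 3 * cai * ALPHA_NACA)
              / ((KM_NAI ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                 * (1.0 + K_SAT * math.exp((GAMMA_NACA - 1.0) * v / _RTF))))
    i_pca = G_PCA * cai / (cai + K_PCA)
    i_pk = G_PK * (v - e_k) / (1.0 + math.exp((25.0 - v) / 5.98))
    i_bna = G_BNA * (v - e_na)
    i_bca = G_BCA * (v - e_ca)

    # ST extras: funny current and sustained outward current
    i_f_na = 0.0
    i_f_k = 0.0
    i_sus = 0.0
    if st_model:
        i_f_na = ST_G_F_NA * y_gate * (v - e_na)
        i_f_k = ST_G_F_K * y_gate * (v - e_k)
        a_sus = 1.0 / (1.0 + math.exp((5.0 - v) / 17.0))
        i_sus = ST_G_SUS * a_sus * (v - e_k)

    # SR calcium handling
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    o_rel = k1 * cass * cass * rbar / (K3 + k1 * cass * cass)
    i_rel = V_REL * o_rel * (casr - cass)
    i_up = VMAX_UP / (1.0 + (K_UP / cai) ** 2)
    i_leak = V_LEAK * (casr - cai)
    i_xfer = V_XFER * (cass - cai)

    buf_i = 1.0 / (1.0 + BUF_C * K_BUF_C / (cai + K_BUF_C) ** 2)
    buf_sr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (casr + K_BUF_SR) ** 2)
    buf_ss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / (cass + K_BUF_SS) ** 2)

    dy[3] = buf_i * ((i_leak - i_up) * V_SR / V_C + i_xfer
                     - (i_bca + i_pca - 2.0 * i_naca) * CM / (2.0 * V_C * FARADAY))
    dy[4] = buf_sr * (i_up - i_rel - i_leak)
    dy[5] = buf_ss * (-i_cal * CM / (2.0 * V_SS * FARADAY)
                      + i_rel * V_SR / V_SS - i_xfer * V_C / V_SS)
    dy[6] = -k2 * cass * rbar + K4 * (1.0 - rbar)

    dy[2] = -(i_na + i_bna + i_f_na + 3.0 * i_nak + 3.0 * i_naca) * CM / (V_C * FARADAY)
    dy[1] = -(i_k1 + i_to + i_sus + i_f_k + i_kr + i_ks + i_pk + i_stim
              - 2.0 * i_nak) * CM / (V_C * FARADAY)

    dy[0] = -(i_k1 + i_to + i_sus + i_kr + i_ks + i_cal + i_nak + i_na
              + i_bna + i_naca + i_bca + i_pk + i_pca + i_f_na + i_f_k + i_stim)

    # Sodium gates (shared kinetics)
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    b_m = (0.1 / (1.0 + math.exp((v + 35.0) / 5.0))
           + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0)))
    tau_m = a_m * b_m

    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        a_h = 0.057 * math.exp(-(v + 80.0) / 6.8)
        b_h = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    tau_h = 1.0 / (a_h + b_h)

    j_inf = h_inf
    if v >= -40.0:
        a_j = 0.0
        b_j = (0.6 * math.exp(0.057 * v)
               / (1.0 + math.exp(-0.1 * (v + 32.0))))
    else:
        a_j = ((-2.5428e4 * math.exp(0.2444 * v)
                - 6.948e-6 * math.exp(-0.04391 * v)) * (v + 37.78)
               / (1.0 + math.exp(0.311 * (v + 79.23))))
        b_j = (0.02424 * math.exp(-0.01052 * v)
               / (1.0 + math.exp(-0.1378 * (v + 40.14))))
    tau_j = 1.0 / (a_j + b_j)

    dy[7] = (m_inf - m) / tau_m
    dy[8] = (h_inf - h) / tau_h
    dy[9] = (j_inf - j) / tau_j

    # Transient outward gates (model-specific)
    if st_model:
        r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 13.0))
        tau_r = 10.45 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 7.3
        s_inf = 1.0 / (1.0 + math.exp((v + 27.0) / 13.0))
        tau_s = (85.0 * math.exp(-((v + 25.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + math.exp((v - 40.0) / 5.0)) + 42.0)
    else:
        r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
        tau_r = 9.5 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
        s_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
        tau_s = (85.0 * math.exp(-((v + 45.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0)
    dy[10] = (r_inf - r) / tau_r
    dy[11] = (s_inf - s) / tau_s

    # Delayed rectifier gates
    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    a_xr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    dy[12] = (xr1_inf - xr1) / (a_xr1 * b_xr1)

    xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    dy[13] = (xr2_inf - xr2) / (a_xr2 * b_xr2)

    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    a_xs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    dy[14] = (xs_inf - xs) / (a_xs * b_xs + 80.0)


@njit(cache=True)
def _y_gate_rhs(v, yg):
    y_inf = 1.0 / (1.0 + math.exp((v + 80.6) / 6.8))
    a_y = math.exp(-2.9 - 0.04 * v)
    b_y = math.exp(3.6 + 0.11 * v)
    tau_y = 4000.0 / (a_y + b_y)
    return (y_inf - yg) / tau_y


@njit(cache=True)
def tp_gate_rhs(y, t, i_stim, sci):
    """Full TP gate-model RHS (19 states); sci clamps fcass to 1."""
    dy = np.zeros(19)
    v, css = y[0], y[5]
    d, f, f2, fc = y[15], y[16], y[17], y[18]
    fc_eff = 1.0 if sci else fc
    i_cal = d * f * f2 * fc_eff * _driving_force(v, css)
    _base_rhs(y, dy, i_cal, i_stim, False, 0.0)
    d_inf, tau_d = _d_gate(v)
    f_inf, tau_f = _f_gate(v)
    f2_inf, tau_f2 = _f2_gate(v)
    fc_inf, tau_fc = _fcass_gate(css)
    dy[15] = (d_inf - d) / tau_d
    dy[16] = (f_inf - f) / tau_f
    dy[17] = (f2_inf - f2) / tau_f2
    dy[18] = (fc_inf - fc) / tau_fc
    return dy


@njit(cache=True)
def st_gate_rhs(y, t, i_stim, sci):
    """Full ST gate-model RHS (20 states); sci clamps fcass to 1."""
    dy = np.zeros(20)
    v, css = y[0], y[5]
    yg = y[15]
    d, f, f2, fc = y[16], y[17], y[18], y[19]
    fc_eff = 1.0 if sci else fc
    i_cal = d * f * f2 * fc_eff * _driving_force(v, css)
    _base_rhs(y, dy, i_cal, i_stim, True, yg)
    dy[15] = _y_gate_rhs(v, yg)
    d_inf, tau_d = _d_gate(v)
    f_inf, tau_f = _f_gate(v)
    f2_inf, tau_f2 = _f2_gate(v)
    fc_inf, tau_fc = _fcass_gate(css)
    dy[16] = (d_inf - d) / tau_d
    dy[17] = (f_inf - f) / tau_f
    dy[18] = (f2_inf - f2) / tau_f2
    dy[19] = (fc_inf - fc) / tau_fc
    return dy


# ----------------------------------------------------------------------
# Initial conditions (original publications / standard CellML encodings)
# ----------------------------------------------------------------------

TP_STATE_NAMES = (
    "V", "Ki", "Nai", "Cai", "CaSR", "CaSS", "Rbar",
    "m", "h", "j", "r", "s", "Xr1", "Xr2", "Xs",
    "d", "f", "f2", "fCass",
)

# Resting (unpaced) initial conditions of the original TP source code.
TP_RESTING_STATE = np.array([
    -86.2, 138.3, 7.67, 0.00007, 1.3, 0.00007, 1.0,
    0.0, 0.75, 0.75, 0.0, 1.0, 0.0, 1.0, 0.0,
    0.0, 1.0, 1.0, 1.0,
])

# Default TP start: the state after 100 conditioning beats at 1 Hz from the
# resting state (full precision).  The published rounded "steady-state"
# vector is not an exact fixed point of the paced equations, and the
# conditioned state is what reproduces the reference 11th-beat biomarkers.
TP_INITIAL_STATE = np.array([
    -8.5534431006461361e+01, 1.3687923444052177e+02, 8.6666904287421485e+00,
    1.0089451523312364e-04, 3.3443177125963861e+00, 2.0984854943831234e-04,
    9.8916203010285053e-01,
    1.6079784375742903e-03, 7.5315885253062498e-01, 7.5278737961448650e-01,
    2.2971526269093394e-08, 9.9999796846877209e-01, 2.0299342768161370e-04,
    4.7433882262513583e-01, 3.1978761750321742e-03,
    3.2380585852748175e-05, 9.7653330090465251e-01, 9.9950954840741424e-01,
    9.9997283242620671e-01,
])

ST_STATE_NAMES = (
    "V", "Ki", "Nai", "Cai", "CaSR", "CaSS", "Rbar",
    "m", "h", "j", "r", "s", "Xr1", "Xr2", "Xs", "y",
    "d", "f", "f2", "fCass",
)

ST_INITIAL_STATE = np.array([
    -69.1370441635924, 136.781894160227, 8.80420286531673,
    0.000101878186157052, 3.10836886659417, 0.000446818714055411,
    0.991580051907845,
    0.0417391656294997, 0.190678733735145, 0.238219836154029,
    0.00103618091196912, 0.963861017995785,
    0.00550281999719088, 0.313213286437995, 0.00953708522974789,
    0.0457562667986602,
    0.000287906256206415, 0.989328560287987, 0.995474890442185,
    0.999955429598213,
])


# ----------------------------------------------------------------------
# Public gate functions (vectorized)
# ----------------------------------------------------------------------

_GATE_FUNCS = {
    ("TP", "d"): _d_gate, ("ST", "d"): _d_gate,
    ("TP", "f"): _f_gate, ("ST", "f"): _f_gate,
    ("TP", "f2"): _f2_gate, ("ST", "f2"): _f2_gate,
    ("TP", "fcass"): _fcass_gate, ("ST", "fcass"): _fcass_gate,
}


def gate_rates(model_id: str, gate_id: str, driver_value):
    """Steady state and time constant of one I_CaL gate.

    Parameters
    ----------
    model_id : {"TP", "ST"}
    gate_id : {"d", "f", "f2", "fcass"}
    driver_value : float or array
        Membrane voltage (mV) for d, f, f2; subspace calcium (mM) for fcass.

    Returns
    -------
    (g_inf, tau) : steady-state fraction (dimensionless) and time constant (ms).
    """
    key = (str(model_id).upper(), str(gate_id).lower())
    if key not in _GATE_FUNCS:
        raise ConfigurationError(
            f"unknown model/gate combination {model_id!r}/{gate_id!r}")
    fn = _GATE_FUNCS[key]
    arr = np.asarray(driver_value, dtype=float)
    if arr.ndim == 0:
        return fn(float(arr))
    flat = arr.ravel()
    ginf = np.empty_like(flat)
    tau = np.empty_like(flat)
    for i, u in enumerate(flat):
        ginf[i], tau[i] = fn(u)
    return ginf.reshape(arr.shape), tau.reshape(arr.shape)


def opening_fraction_gates(d, f, f2, fcass, tol: float = 1e-6):
    """Gate-product opening fraction O = d·f·f2·fcass ∈ [0, 1]."""
    vals = [np.asarray(g, dtype=float) for g in (d, f, f2, fcass)]
    for name, g in zip(("d", "f", "f2", "fcass"), vals):
        if np.any(g < -tol) or np.any(g > 1.0 + tol):
            raise NumericalStateError(f"gate {name} outside [0, 1]")
    out = vals[0] * vals[1] * vals[2] * vals[3]
    return np.clip(out, 0.0, 1.0)


def ical_driving_force(v, css, cao: float = CA_O, gcal: float = G_CAL,
                       rgas: float = R_GAS, temp: float = TEMPERATURE,
                       faraday: float = FARADAY):
    """Imax of I_CaL = O × Imax (A/F), vectorized.

    The (V − 15)/(e^z − 1) factor has a removable singularity at V = 15 mV,
    handled with its series expansion.
    """
    v = np.asarray(v, dtype=float)
    css = np.asarray(css, dtype=float)
    if np.any(css <= 0) or cao <= 0:
        raise ValueError("calcium concentrations must be positive")
    rtf = rgas * temp / faraday
    z = 2.0 * (v - 15.0) / rtf
    num = 0.25 * css * np.exp(z) - cao
    small = np.abs(z) < 1e-7
    zs = np.where(small, 1.0, z)
    frac = np.where(
        small,
        (1.0 - z / 2.0 + z * z / 12.0) * rtf / 2.0,
        (v - 15.0) / np.expm1(zs),
    )
    out = gcal * 4.0 * faraday / rtf * frac * num
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# Model specs
# ----------------------------------------------------------------------

@dataclass
class CellModelSpec:
    """A runnable cell model: state layout, initial state and RHS kernel.

    ``rhs_kernel(y, t, i_stim, sci_arg, params)`` must be a numba-compiled
    function; ``sci_arg`` is model-kind specific (flag for gate models,
    frozen css for hybrids) and ``params`` an optional float64 array.
    """

    model_id: str
    variant: str                       # "gate" or "mc"
    state_names: tuple
    initial_state: np.ndarray
    rhs_kernel: Callable
    params: np.ndarray = field(default_factory=lambda: np.zeros(0))
    open_index: int | None = None      # MC open-state index (hybrids)

    def __post_init__(self):
        if len(set(self.state_names)) != len(self.state_names):
            raise ConfigurationError("state names must be unique")
        for required in ("V", "Cai", "CaSS"):
            if required not in self.state_names:
                raise ConfigurationError(f"state {required} missing")
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.initial_state.shape != (len(self.state_names),):
            raise ConfigurationError("initial state length mismatch")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def rhs(self, state, t: float = 0.0, stimulus: float = 0.0,
            sci_arg: float = 0.0) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        dy = self.rhs_kernel(state, t, stimulus, sci_arg, self.params)
        if not np.all(np.isfinite(dy)):
            bad = [self.state_names[i] for i in np.nonzero(~np.isfinite(dy))[0]]
            raise SimulationFailure(
                f"non-finite derivative for state(s) {bad} of {self.model_id}")
        return dy

    def opening_fraction(self, states: np.ndarray, sci: bool = False):
        """O per sample from a (n_samples, n_states) state array."""
        states = np.atleast_2d(states)
        if self.variant == "gate":
            gates = [states[:, self.index(g)] for g in ("d", "f", "f2")]
            fc = np.ones(states.shape[0]) if sci else states[:, self.index("fCass")]
            return np.clip(gates[0] * gates[1] * gates[2] * fc, 0.0, 1.0)
        return np.clip(states[:, self.open_index], 0.0, 1.0)

    def ical(self, states: np.ndarray, sci: bool = False):
        """I_CaL (A/F) per sample from a state array."""
        states = np.atleast_2d(states)
        v = states[:, self.index("V")]
        css = states[:, self.index("CaSS")]
        return self.opening_fraction(states, sci=sci) * ical_driving_force(v, css)


@njit(cache=True)
def _tp_gate_kernel(y, t, i_stim, sci_arg, params):
    return tp_gate_rhs(y, t, i_stim, sci_arg != 0.0)


@njit(cache=True)
def _st_gate_kernel(y, t, i_stim, sci_arg, params):
    return st_gate_rhs(y, t, i_stim, sci_arg != 0.0)


def build_gate_model(model_id: str, variant: str = "epi") -> CellModelSpec:
    """Assemble the gate-based TP or ST model spec.

    Only the epicardial TP variant is shipped; the argument exists so the
    choice is explicit in configs.
    """
    model_id = str(model_id).upper()
    if model_id == "TP":
        if variant != "epi":
            raise ConfigurationError(
                f"only the epicardial TP variant is available, not {variant!r}")
        return CellModelSpec("TP", "gate", TP_STATE_NAMES,
                             TP_INITIAL_STATE.copy(), _tp_gate_kernel)
    if model_id == "ST":
        return CellModelSpec("ST", "gate", ST_STATE_NAMES,
                             ST_INITIAL_STATE.copy(), _st_gate_kernel)
    raise ConfigurationError(f"unknown model id {model_id!r}")


def gate_model_rhs(model_id: str, state, t: float = 0.0,
                   stimulus: float = 0.0, sci: bool = False) -> np.ndarray:
    """Time derivative of the gate-based model state (convenience wrapper)."""
    return build_gate_model(model_id).rhs(state, t, stimulus,
                                          1.0 if sci else 0.0)
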