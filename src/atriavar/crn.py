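"""Courtemanche–Ramirez–Nattel (CRN) human atrial ionic model.

The 1998 CRN model describes the human atrial action potential with 21 state
variables: membrane potential, 15 Hodgkin–Huxley-type gates, and 5
intracellular/SR ionic concentrations.  Nine maximal conductances (channel
conductances plus the Na/K pump and Na/Ca exchanger maxima) are exposed as
dimensionless multipliers so that parameter-varied model populations can be
generated.

Integration uses Rush–Larsen updates for the gating variables (exact for
frozen rates, unconditionally stable) and forward Euler for the membrane
potential and concentrations.  A two-level time step is used during pacing:
a fine step around the stimulus/upstroke and a coarser step during plateau,
repolarisation and diastole; the recorded final beat is integrated entirely
at the fine step so that biomarkers are extracted from a densely sampled
trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
from numba import njit

from .biomarkers import APTrace

__all__ = [
    "ConductanceScaling",
    "CellState",
    "PacingProtocol",
    "REST_STATE",
    "STATE_NAMES",
    "ionic_rhs",
    "pace_cell",
    "apd90_restitution",
]

# ---------------------------------------------------------------------------
# Model constants (published 1998 parameter set, Cm = 100 pF)
# ---------------------------------------------------------------------------

R = 8.3143        # J/(mol K)
T = 310.0         # K
F = 96.4867       # C/mmol
CM = 100.0        # pF

V_I = 13668.0     # um^3, myoplasmic volume
V_UP = 1109.52    # um^3, SR uptake compartment
V_REL = 96.48     # um^3, SR release compartment

K_O = 5.4         # mM
NA_O = 140.0
CA_O = 1.8

G_NA = 7.8            # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
I_NAK_MAX = 0.59933874   # pA/pF
I_NACA_MAX = 1600.0      # pA/pF
I_PCA_MAX = 0.275        # pA/pF
G_B_NA = 0.0006744375
G_B_CA = 0.001131

KM_NA_I = 10.0
KM_K_O = 1.5
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35

CA_UP_MAX = 15.0
K_REL = 30.0
K_UP = 0.00092
I_UP_MAX = 0.005

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

TAU_TR = 180.0
TAU_F_CA = 2.0
TAU_U = 8.0
K_Q10 = 3.0

_SIGMA_NAK = (np.exp(NA_O / 67.3) - 1.0) / 7.0
_RT_F = R * T / F

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel",
)

#: Published resting state of the unscaled model (quasi-equilibrium).
REST_STATE = np.array([
    -81.18,        # V (mV)
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # fca
    0.0,           # u
    1.0,           # v
    9.992e-1,      # w
    11.17,         # Nai (mM)
    139.0,         # Ki
    1.013e-4,      # Cai
    1.488,         # Caup
    1.488,         # Carel
])

N_STATES = 21
GATE_IDX_LO = 1
GATE_IDX_HI = 16  # states 1..15 are gates


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductanceScaling:
    """Dimensionless multipliers of the nine sampled maxima.

    Each multiplier scales the corresponding baseline maximal conductance
    (or pump/exchanger maximal current) and must lie in [0, 3], i.e. from
    -100% to +200% of the standard value.
    """

    s_gNa: float = 1.0
    s_gTo: float = 1.0
    s_gKur: float = 1.0
    s_gKr: float = 1.0
    s_gKs: float = 1.0
    s_gK1: float = 1.0
    s_gCaL: float = 1.0
    s_gNaK: float = 1.0
    s_gNaCa: float = 1.0

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not (0.0 <= v <= 3.0):
                raise ValueError(
                    f"{f_.name}={v!r} outside the sampled range [0, 3]")

    def as_array(self) -> np.ndarray:
        return np.array([self.s_gNa, self.s_gTo, self.s_gKur, self.s_gKr,
                         self.s_gKs, self.s_gK1, self.s_gCaL, self.s_gNaK,
                         self.s_gNaCa])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "ConductanceScaling":
        a = np.asarray(a, dtype=float)
        if a.shape != (9,):
            raise ValueError("expected 9 multipliers")
        return cls(*a.tolist())


BASELINE_SCALING = ConductanceScaling()


@dataclass
class CellState:
    """Full model state: V (mV), 15 gates in [0,1], concentrations (mM)."""

    y: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (N_STATES,):
            raise ValueError(f"state vector must have {N_STATES} entries")

    def validate(self) -> None:
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite state")
        g = self.y[GATE_IDX_LO:GATE_IDX_HI]
        if np.any(g < -1e-9) or np.any(g > 1.0 + 1e-9):
            raise ValueError("gate variable outside [0, 1]")
        if np.any(self.y[16:] <= 0.0):
            raise ValueError("non-positive ionic concentration")

    @classmethod
    def rest(cls) -> "CellState":
        return cls(REST_STATE.copy())

    def as_dict(self) -> dict:
        return dict(zip(STATE_NAMES, self.y.tolist()))


@dataclass(frozen=True)
class PacingProtocol:
    """Single-cell pacing protocol (current-clamp stimulus train)."""

    n_beats: int = 101
    bcl: float = 1000.0            # ms
    stim_amplitude: float = -45.0  # pA/pF
    stim_duration: float = 1.0     # ms
    quiescence: float = 10_000.0   # ms recorded after the final beat
    dt_fine: float = 0.02          # ms, stimulus/upstroke window + last beat
    dt_coarse: float = 0.1         # ms, plateau/repolarisation/diastole
    fine_window: float = 30.0      # ms of fine stepping after each stimulus


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _eval(y, mult, istim, dy, ginf, gtau):
    """Fill dy with state derivatives and (ginf, gtau) with gate targets.

    y: length-21 state; mult: length-9 multipliers; istim in pA/pF.
    Gate derivatives are also written to dy as (inf - y)/tau so that the
    same routine serves a plain ODE right-hand side.
    """
    V = y[0]
    m = y[1]; h = y[2]; j = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]
    d = y[10]; f = y[11]; fca = y[12]
    u = y[13]; v = y[14]; w = y[15]
    Nai = y[16]; Ki = y[17]; Cai = y[18]; Caup = y[19]; Carel = y[20]

    # reversal potentials
    E_Na = _RT_F * np.log(NA_O / Nai)
    E_K = _RT_F * np.log(K_O / Ki)
    E_Ca = 0.5 * _RT_F * np.log(CA_O / Cai)

    # membrane currents (pA/pF)
    i_Na = mult[0] * G_NA * m * m * m * h * j * (V - E_Na)
    i_K1 = mult[5] * G_K1 * (V - E_K) / (1.0 + np.exp(0.07 * (V + 80.0)))
    i_to = mult[1] * G_TO * oa * oa * oa * oi * (V - E_K)
    g_Kur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    i_Kur = mult[2] * g_Kur * ua * ua * ua * ui * (V - E_K)
    i_Kr = mult[3] * G_KR * xr * (V - E_K) / (1.0 + np.exp((V + 15.0) / 22.4))
    i_Ks = mult[4] * G_KS * xs * xs * (V - E_K)
    i_CaL = mult[6] * G_CAL * d * f * fca * (V - 65.0)

    f_NaK = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / _RT_F)
                   + 0.0365 * _SIGMA_NAK * np.exp(-V / _RT_F))
    i_NaK = (mult[7] * I_NAK_MAX * f_NaK
             / (1.0 + (KM_NA_I / Nai) ** 1.5)
             * K_O / (K_O + KM_K_O))

    expg = np.exp(GAMMA * V / _RT_F)
    expg1 = np.exp((GAMMA - 1.0) * V / _RT_F)
    i_NaCa = (mult[8] * I_NACA_MAX
              * (expg * Nai ** 3 * CA_O - expg1 * NA_O ** 3 * Cai)
              / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                 * (1.0 + K_SAT * expg1)))

    i_b_Na = G_B_NA * (V - E_Na)
    i_b_Ca = G_B_CA * (V - E_Ca)
    i_p_Ca = I_PCA_MAX * Cai / (0.0005 + Cai)

    # SR fluxes (mM/ms)
    i_rel = K_REL * u * u * v * w * (Carel - Cai)
    i_up = I_UP_MAX / (1.0 + K_UP / Cai)
    i_up_leak = I_UP_MAX * Caup / CA_UP_MAX
    i_tr = (Caup - Carel) / TAU_TR

    # --- gating rates ---------------------------------------------------
    # m
    dv = V + 47.13
    if abs(dv) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * dv / (1.0 - np.exp(-0.1 * dv))
    b_m = 0.08 * np.exp(-V / 11.0)
    ginf[0] = a_m / (a_m + b_m)
    gtau[0] = 1.0 / (a_m + b_m)
    # h, j
    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = (0.3 * np.exp(-2.535e-7 * V)
               / (1.0 + np.exp(-0.1 * (V + 32.0))))
    else:
        a_h = 0.135 * np.exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        a_j = ((-1.2714e5 * np.exp(0.2444 * V)
                - 3.474e-5 * np.exp(-0.04391 * V)) * (V + 37.78)
               / (1.0 + np.exp(0.311 * (V + 79.23))))
        b_j = (0.1212 * np.exp(-0.01052 * V)
               / (1.0 + np.exp(-0.1378 * (V + 40.14))))
    ginf[1] = a_h / (a_h + b_h)
    gtau[1] = 1.0 / (a_h + b_h)
    ginf[2] = a_j / (a_j + b_j)
    gtau[2] = 1.0 / (a_j + b_j)
    # oa / ua share alpha-beta forms
    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    ginf[3] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    gtau[3] = 1.0 / ((a_oa + b_oa) * K_Q10)
    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    ginf[4] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    gtau[4] = 1.0 / ((a_oi + b_oi) * K_Q10)
    ginf[5] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    gtau[5] = gtau[3]  # ua alpha/beta identical to oa
    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    ginf[6] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    gtau[6] = 1.0 / ((a_ui + b_ui) * K_Q10)
    # xr
    dv = V + 14.1
    if abs(dv) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dv / (1.0 - np.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-10:
        b_xr = 3.7862e-4
    else:
        b_xr = 7.3898e-5 * dv / (np.exp(dv / 5.1237) - 1.0)
    ginf[7] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    gtau[7] = 1.0 / (a_xr + b_xr)
    # xs
    dv = V - 19.9
    if abs(dv) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * dv / (1.0 - np.exp(-dv / 17.0))
        b_xs = 3.5e-5 * dv / (np.exp(dv / 9.0) - 1.0)
    ginf[8] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    gtau[8] = 0.5 / (a_xs + b_xs)
    # d
    dv = V + 10.0
    if abs(dv) < 1e-10:
        tau_d = (1.0 / 6.24) / (0.035 * 2.0)
    else:
        e = np.exp(-dv / 6.24)
        tau_d = (1.0 - e) / (0.035 * dv * (1.0 + e))
    ginf[9] = 1.0 / (1.0 + np.exp(-dv / 8.0))
    gtau[9] = tau_d
    # f
    ginf[10] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    gtau[10] = 9.0 / (0.0197 * np.exp(-0.0337 * 0.0337 * (V + 10.0) ** 2)
                      + 0.02)
    # fca
    ginf[11] = 1.0 / (1.0 + Cai / 0.00035)
    gtau[11] = TAU_F_CA
    # SR release gates u, v (driven by Fn), w (voltage)
    Fn = 1e3 * (1e-15 * V_REL * i_rel
                - 1e-15 / (2.0 * F) * (0.5 * i_CaL * CM - 0.2 * i_NaCa * CM))
    e_fn = np.exp(-(Fn - 3.4175e-13) / 1.367e-15)
    ginf[12] = 1.0 / (1.0 + e_fn)
    gtau[12] = TAU_U
    ginf[13] = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 1.367e-15))
    gtau[13] = 1.91 + 2.09 / (1.0 + e_fn)
    ginf[14] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    dv = V - 7.9
    if abs(dv) < 1e-10:
        gtau[14] = 6.0 * 0.2 / 1.3
    else:
        e = np.exp(-dv / 5.0)
        gtau[14] = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dv)

    # --- derivatives ----------------------------------------------------
    dy[0] = -(i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_b_Na + i_b_Ca
              + i_NaK + i_p_Ca + i_NaCa + i_CaL + istim)
    for k in range(15):
        dy[1 + k] = (ginf[k] - y[1 + k]) / gtau[k]
    dy[16] = (-3.0 * i_NaK - 3.0 * i_NaCa - i_b_Na - i_Na) * CM / (F * V_I)
    dy[17] = (2.0 * i_NaK - i_K1 - i_to - i_Kur - i_Kr - i_Ks) * CM / (F * V_I)
    B1 = ((2.0 * i_NaCa - i_p_Ca - i_CaL - i_b_Ca) * CM / (2.0 * F * V_I)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    B2 = (1.0 + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (Cai + KM_CMDN) ** 2)
    dy[18] = B1 / B2
    dy[19] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dy[20] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN
                               / (Carel + KM_CSQN) ** 2)
    return dy[0]


#: Maximum membrane-potential change per sub-step (mV); steps during the
#: fast upstroke are subdivided so the explicit V update stays accurate.
DV_MAX = 0.2


@njit(cache=True)
def _step(y, mult, istim, dt, dy, ginf, gtau):
    """One Rush–Larsen / forward-Euler step in place; returns dV/dt.

    The step is internally subdivided whenever the voltage would move more
    than ``DV_MAX`` in one update, which confines the extra cost to the
    ~2 ms of the AP upstroke.
    """
    dvdt0 = _eval(y, mult, istim, dy, ginf, gtau)
    n = int(abs(dvdt0) * dt / DV_MAX) + 1
    if n > 200:
        n = 200
    sub = dt / n
    for _ in range(n):
        if _ > 0:
            _eval(y, mult, istim, dy, ginf, gtau)
        y[0] += sub * dy[0]
        for k in range(15):
            y[1 + k] = ginf[k] + (y[1 + k] - ginf[k]) * np.exp(-sub / gtau[k])
        for k in range(16, 21):
            y[k] += sub * dy[k]
    return dvdt0


@njit(cache=True)
def _pace(y, mult, n_beats, bcl, stim_amp, stim_dur,
          dt_fine, dt_coarse, fine_window,
          quiesc, q_rec_dt,
          last_t, last_v, q_t, q_v):
    """Pace one cell; record the final beat (fine dt) and quiescent tail.

    Returns (n_last, n_q, ok).  ok=False signals numerical blow-up.
    """
    dy = np.empty(N_STATES)
    ginf = np.empty(15)
    gtau = np.empty(15)

    n_stim_f = int(round(stim_dur / dt_fine))
    n_fine = int(round(fine_window / dt_fine))
    n_coarse = int(round((bcl - fine_window) / dt_coarse))
    n_last = int(round(bcl / dt_fine))

    # pre-beats: fine window then coarse remainder
    for beat in range(n_beats - 1):
        for i in range(n_fine):
            istim = stim_amp if i < n_stim_f else 0.0
            _step(y, mult, istim, dt_fine, dy, ginf, gtau)
        for i in range(n_coarse):
            _step(y, mult, 0.0, dt_coarse, dy, ginf, gtau)
        if not np.isfinite(y[0]) or abs(y[0]) > 500.0:
            return 0, 0, False

    # final beat, fully fine, recorded every step
    for i in range(n_last):
        last_t[i] = i * dt_fine
        last_v[i] = y[0]
        istim = stim_amp if i < n_stim_f else 0.0
        _step(y, mult, istim, dt_fine, dy, ginf, gtau)
        if not np.isfinite(y[0]) or abs(y[0]) > 500.0:
            return 0, 0, False
    last_t[n_last] = n_last * dt_fine
    last_v[n_last] = y[0]

    # quiescent tail, coarse dt, subsampled recording
    n_q_steps = int(round(quiesc / dt_coarse))
    stride = max(1, int(round(q_rec_dt / dt_coarse)))
    nq = 0
    for i in range(n_q_steps):
        if i % stride == 0:
            q_t[nq] = bcl + i * dt_coarse
            q_v[nq] = y[0]
            nq += 1
        _step(y, mult, 0.0, dt_coarse, dy, ginf, gtau)
        if not np.isfinite(y[0]) or abs(y[0]) > 500.0:
            return n_last + 1, nq, False
    if quiesc > 0.0:
        q_t[nq] = bcl + n_q_steps * dt_coarse
        q_v[nq] = y[0]
        nq += 1
    return n_last + 1, nq, False if not np.isfinite(y[0]) else True


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def ionic_rhs(state: CellState, scaling: ConductanceScaling,
              istim: float = 0.0):
    """Time derivatives of all state variables plus total ionic current.

    Returns ``(dy, J_ion)`` with dy in model units per ms and J_ion in
    pA/pF (depolarising currents negative).  Raises on a non-finite state,
    which signals numerical blow-up upstream.
    """
    y = np.asarray(state.y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite cell state")
    dy = np.empty(N_STATES)
    ginf = np.empty(15)
    gtau = np.empty(15)
    dvdt = _eval(y, scaling.as_array(), istim, dy, ginf, gtau)
    j_ion = -dvdt - istim
    return dy, j_ion


def pace_cell(scaling: ConductanceScaling,
              protocol: PacingProtocol = PacingProtocol(),
              initial: CellState | None = None):
    """Pace a cell and return (last-beat trace, quiescent trace, end state).

    The last-beat trace starts at the final stimulus onset (its first sample
    is the diastolic potential recorded before the stimulus current is
    applied) and is sampled at the fine time step.  The end state is the
    checkpoint used to initialise tissue nodes.  Solver blow-up is reported
    by ``APTrace.ok = False`` rather than raised, so batch screens can mark
    the member unstable and continue.
    """
    p = protocol
    if p.n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if p.bcl <= p.stim_duration:
        raise ValueError("bcl must exceed the stimulus duration")
    y = (initial.y.copy() if initial is not None else REST_STATE.copy())
    mult = scaling.as_array()

    n_last = int(round(p.bcl / p.dt_fine)) + 1
    q_rec_dt = 0.5
    n_q = int(round(p.quiescence / p.dt_coarse)) // max(
        1, int(round(q_rec_dt / p.dt_coarse))) + 2
    last_t = np.empty(n_last)
    last_v = np.empty(n_last)
    q_t = np.empty(max(n_q, 1))
    q_v = np.empty(max(n_q, 1))

    nl, nq, ok = _pace(y, mult, p.n_beats, p.bcl, p.stim_amplitude,
                       p.stim_duration, p.dt_fine, p.dt_coarse,
                       p.fine_window, p.quiescence, q_rec_dt,
                       last_t, last_v, q_t, q_v)
    last = APTrace(times=last_t[:nl].copy(), voltages=last_v[:nl].copy(),
                   stimulus_onset=0.0, ok=bool(ok))
    quiet = APTrace(times=q_t[:nq].copy(), voltages=q_v[:nq].copy(),
                    stimulus_onset=np.nan, ok=bool(ok))
    end = CellState(y, t=p.n_beats * p.bcl + p.quiescence)
    return last, quiet, end


def apd90_restitution(scaling: ConductanceScaling,
                      bcls: Sequence[float],
                      n_beats: int = 101) -> list[tuple[float, float]]:
    """Steady-state APD90 restitution: pace to steady state at each BCL.

    Each cycle length is paced from the model resting state for ``n_beats``
    beats; APD90 is measured on the final beat.  Returns (bcl, APD90) pairs.
    """
    from .biomarkers import compute_biomarkers

    out = []
    for bcl in bcls:
        if bcl < 300.0:
            raise ValueError("bcl below 300 ms is outside the supported range")
        proto = PacingProtocol(n_beats=n_beats, bcl=float(bcl), quiescence=0.0)
        last, _, _ = pace_cell(scaling, proto)
        bm = compute_biomarkers(last)
        out.append((float(bcl), bm.APD90))
    return out
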