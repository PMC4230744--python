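"""Dopamine release, re-uptake and its modulation of LMC excitability.

Dopamine concentration in the left/right laryngeal motor cortex (LMC) obeys
two mass-balance equations driven by ipsilateral substantia nigra (SNc)
firing:

    dc/dt = beta(t) * Q_snc  -  V_max * c / (K_m + c)

with a step-function production rate beta(t) (beta_max during speech windows,
beta_min otherwise) and Michaelis-Menten re-uptake.  Concentration feeds back
on LMC excitability through a saturating gain

    G(c) = G_min + (G_max - G_min) * k c / (1 + k c),      k = antagonism,

which multiplies the LMC's excitatory-to-excitatory coupling and scales the
opening odds of its potassium channels (keeping the open fraction a
probability).  G(0) = 1 exactly and G < G_max for all c >= 0.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from numba import njit

from .params import ModelParameters, ParameterError, TaskSchedule

__all__ = [
    "production_rate",
    "uptake_flux",
    "dopamine_drift",
    "dopamine_steady_state",
    "gain",
    "modulated_aee",
    "modulated_opening",
    "modulated_potassium_activation",
]


@njit(cache=True)
def _beta_core(t_ms: float, task: bool, cycle_ms: float, speech_ms: float,
               beta_min: float, beta_max: float) -> float:
    if not task:
        return beta_min
    if t_ms % cycle_ms < speech_ms:
        return beta_max
    return beta_min


@njit(cache=True)
def _uptake_core(c: float, v_max: float, K_m: float) -> float:
    return v_max * c / (K_m + c)


@njit(cache=True)
def _gain_core(c: float, k: float, g_min: float, g_max: float) -> float:
    x = k * c
    return g_min + (g_max - g_min) * x / (1.0 + x)


def production_rate(t: float, sched: TaskSchedule, p: ModelParameters) -> float:
    """Dopamine production rate beta(t) in mM per unit firing.

    Piecewise constant: ``beta_max`` inside speech windows of a task
    schedule, ``beta_min`` otherwise (including all of rest mode).  Time in
    ms.  The convention beta * Q (Q in kHz = spikes/ms) has units mM/ms.
    """
    if t < 0:
        raise ParameterError("time must be nonnegative")
    return _beta_core(t, sched.mode == "task", sched.cycle_s * 1000.0,
                      sched.speech_s * 1000.0, p.beta_min, p.beta_max)


def uptake_flux(c, p: ModelParameters):
    """Michaelis-Menten re-uptake flux V_max * c / (K_m + c) in mM/ms."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ParameterError("dopamine concentration must be nonnegative")
    out = p.v_max_uptake * c / (p.K_m + c)
    return float(out) if out.ndim == 0 else out

def dopamine_drift(c: np.ndarray, q_snc: np.ndarray, t: float,
                   sched: TaskSchedule, p: ModelParameters) -> np.ndarray:
    """Drift of the (left, right) LMC dopamine concentrations in mM/ms.

    Strictly ipsilateral: the left LMC pool is driven by left SNc firing and
    vice versa; there is no crosstalk term and no noise on these components.
    """
    c = np.asarray(c, dtype=float)
    q_snc = np.asarray(q_snc, dtype=float)
    if c.shape != (2,) or q_snc.shape != (2,):
        raise ParameterError("c and q_snc must both be 2-vectors (left, right)")
    beta = production_rate(t, sched, p)
    return beta * q_snc - uptake_flux(c, p)


def dopamine_steady_state(q_bar: float, beta: float, p: ModelParameters) -> float:
    """Closed-form fixed point c* = K_m * beta*Q / (V_max - beta*Q).

    Exists only while production beta*Q stays below the saturable uptake
    capacity V_max; beyond that the concentration grows without settling and
    a warning is emitted (the caller receives ``inf``).
    """
    inflow = beta * q_bar
    if inflow >= p.v_max_uptake:
        warnings.warn(
            "dopamine production rate exceeds maximal re-uptake capacity; "
            "concentration has no finite steady state", stacklevel=2)
        return math.inf
    return p.K_m * inflow / (p.v_max_uptake - inflow)


def gain(c, p: ModelParameters):
    """Dopamine-dependent gain G(c): 1 at c = 0, saturating at G_max."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ParameterError("dopamine concentration must be nonnegative")
    x = p.antagonism * c
    out = p.G_min + (p.G_max - p.G_min) * x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def modulated_aee(a_ee: float, g, p: ModelParameters):
    """Effective excitatory-to-excitatory coupling G * a_ee in the LMC.

    Equals a_ee at unity gain and is bounded by G_max * a_ee.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 1):
        raise ParameterError("gain must be >= 1")
    out = g * a_ee
    return float(out) if out.ndim == 0 else out


def modulated_opening(m, g):
    """Dopamine-scaled channel opening probability, still a fraction in [0,1].

    Dopamine multiplies the opening *odds* by the gain G:
    m' = G m / (1 + (G - 1) m).  Identity at G = 1, strictly increasing in
    both arguments, and bounded by 1 for every admissible gain, so the
    modulated open fraction remains a probability.
    """
    m = np.asarray(m, dtype=float)
    g = np.asarray(g, dtype=float)
    out = g * m / (1.0 + (g - 1.0) * m)
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _modulated_opening_core(m: float, g: float) -> float:
    return g * m / (1.0 + (g - 1.0) * m)


def modulated_potassium_activation(W, V, g, p: ModelParameters):
    """Gain-modulated relaxation term of the open-K-channel fraction (1/ms).

    phi * (m'(V, G) - W) / tau_K with the odds-scaled target fraction
    m' = G m_K / (1 + (G - 1) m_K).  At G = 1 this is exactly the
    unmodulated (non-LMC) term; since m' <= 1 for every gain, the magnitude
    is bounded by phi * (1 + |W|) / tau_K <= G * phi * (1 + |W|) / tau_K.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 1):
        raise ParameterError("gain must be >= 1")
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    m_K = 0.5 * (1.0 + np.tanh((V - p.T_K) / p.delta_K))
    out = p.phi * (modulated_opening(m_K, g) - W) / p.tau_K
    return float(out) if out.ndim == 0 else out
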