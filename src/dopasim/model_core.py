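"""Drift and diffusion of the coupled neural mass model.

Each of N brain regions carries a mean excitatory membrane potential V, a
mean inhibitory potential Z and a fraction W of open potassium channels;
voltage-gated Ca/Na/K channels plus a passive leak drive V, sigmoidal firing
rates close excitatory/inhibitory feedback loops, and excitatory firing is
shared between regions through a nonnegative coupling matrix C acting on the
vector of regional firing rates.  Two extra components hold the dopamine
concentration in the left/right laryngeal motor cortex (LMC), which
modulates those two regions' excitatory coupling and potassium activation
through a saturating gain.  Non-specific input enters as constant additive
noise from a single scalar Wiener process, so the full system is a
(3N+2)-dimensional SDE with state layout [V(N), Z(N), W(N), c(2)].

All sigmoids arise from normally distributed thresholds across the neural
population and take the hyperbolic-tangent form

    m_j(V)  = 0.5 * (1 + tanh((V - T_j) / delta_j))          (channels)
    Q(V)    = 0.5 * Q_max * (1 + tanh((V - V_T) / delta_V))  (firing)
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .dopamine import _beta_core, _gain_core, _modulated_opening_core, \
    _uptake_core
from .params import (
    CouplingMatrix,
    ModelParameters,
    NeuralState,
    ParameterError,
    RegionSet,
    RegionalHeterogeneity,
    TaskSchedule,
)

__all__ = [
    "channel_open_fraction",
    "firing_rate",
    "coupled_excitatory_input",
    "drift",
    "diffusion",
    "initial_state",
    "NeuralModel",
]


def channel_open_fraction(V, T_j: float, delta_j: float):
    """Fraction of open ion channels at potential V.

    Sigmoid in [0, 1] from normally distributed opening thresholds with mean
    ``T_j`` and dispersion ``delta_j``; equals 1/2 at V = T_j.
    """
    if not delta_j > 0:
        raise ParameterError("threshold dispersion must be strictly positive")
    V = np.asarray(V, dtype=float)
    out = 0.5 * (1.0 + np.tanh((V - T_j) / delta_j))
    return float(out) if out.ndim == 0 else out


def firing_rate(V, mean: float, dispersion: float, Q_max: float):
    """Mean population firing rate in [0, Q_max] (kHz) at potential V."""
    if not dispersion > 0:
        raise ParameterError("firing dispersion must be strictly positive")
    if not Q_max > 0:
        raise ParameterError("maximum firing rate must be strictly positive")
    V = np.asarray(V, dtype=float)
    out = 0.5 * Q_max * (1.0 + np.tanh((V - mean) / dispersion))
    return float(out) if out.ndim == 0 else out


def coupled_excitatory_input(Q_V: np.ndarray, C: CouplingMatrix, i: int) -> float:
    """Weighted excitatory input sum_j c_ij * Q_V[j] arriving at region i."""
    Q_V = np.asarray(Q_V, dtype=float)
    if Q_V.shape != (C.n_regions,):
        raise ParameterError(
            f"firing-rate vector of length {Q_V.shape} does not match "
            f"{C.n_regions} regions")
    return float(C.weights[i] @ Q_V)


# ---------------------------------------------------------------------------
# Packed-parameter drift kernel (shared by the public drift() and the fast
# integration loop).  Parameter vector layout:
_P = {name: k for k, name in enumerate([
    "T_Ca", "delta_Ca", "g_Ca", "V_Ca",
    "T_K", "delta_K", "g_K", "V_K",
    "T_Na", "delta_Na", "g_Na", "V_Na",
    "V_L", "g_L",
    "V_T", "Z_T", "delta_V", "delta_Z", "Q_V_max", "Q_Z_max",
    "a_ee", "a_ei", "a_ni",
    "phi", "tau_K", "r_nmda",
    "noise_amplitude", "inhibitory_noise_scale",
    "v_max_uptake", "K_m", "beta_min", "beta_max",
    "antagonism", "G_min", "G_max",
])}


def _pack_parameters(p: ModelParameters) -> np.ndarray:
    par = np.empty(len(_P), dtype=np.float64)
    for name, k in _P.items():
        par[k] = getattr(p, name)
    return par


@njit(cache=True)
def _drift_kernel(t, y, out, C, a_ie, par, idx, sched):
    """Evaluate the full drift into ``out`` (length 3N+2)."""
    n = C.shape[0]
    qv = np.empty(n)
    for i in range(n):
        qv[i] = 0.5 * par[18] * (1.0 + np.tanh((y[i] - par[14]) / par[16]))
    u = C @ qv
    c_l = y[3 * n]
    c_r = y[3 * n + 1]
    beta = _beta_core(t, sched[0] > 0.5, sched[1], sched[2], par[30], par[31])
    for i in range(n):
        V = y[i]
        Z = y[n + i]
        W = y[2 * n + i]
        m_ca = 0.5 * (1.0 + np.tanh((V - par[0]) / par[1]))
        m_na = 0.5 * (1.0 + np.tanh((V - par[8]) / par[9]))
        m_k = 0.5 * (1.0 + np.tanh((V - par[4]) / par[5]))
        q_z = 0.5 * par[19] * (1.0 + np.tanh((Z - par[15]) / par[17]))
        if i == idx[0]:
            g = _gain_core(c_l, par[32], par[33], par[34])
        elif i == idx[1]:
            g = _gain_core(c_r, par[32], par[33], par[34])
        else:
            g = 1.0
        aee = g * par[20]
        out[i] = (
            -(par[2] + par[25] * aee * u[i]) * m_ca * (V - par[3])
            - (par[10] * m_na + aee * u[i]) * (V - par[11])
            - par[6] * W * (V - par[7])
            - par[13] * (V - par[12])
            - a_ie[i] * Z * q_z
        )
        out[n + i] = par[21] * V * qv[i]
        out[2 * n + i] = par[23] * (_modulated_opening_core(m_k, g) - W) / par[24]
    out[3 * n] = beta * qv[idx[2]] - _uptake_core(max(c_l, 0.0), par[28], par[29])
    out[3 * n + 1] = beta * qv[idx[3]] - _uptake_core(max(c_r, 0.0), par[28], par[29])
    return out


def _pack_schedule(sched: TaskSchedule) -> np.ndarray:
    return np.array([1.0 if sched.mode == "task" else 0.0,
                     sched.cycle_s * 1000.0, sched.speech_s * 1000.0])


def drift(t: float, state, p: ModelParameters, C: CouplingMatrix,
          het: RegionalHeterogeneity, sched: TaskSchedule,
          regions: RegionSet) -> np.ndarray:
    """Deterministic force of the full model at time t (ms).

    ``state`` may be a :class:`NeuralState` or a flat [V, Z, W, c] vector.
    Non-LMC regions follow the unmodulated regional dynamics; the two LMC
    regions apply the dopamine gain to their excitatory coupling and
    potassium activation; the two dopamine components follow the
    production/re-uptake mass balance.  Side-effect free.
    """
    y = state.flatten() if isinstance(state, NeuralState) else \
        np.asarray(state, dtype=float)
    n = C.n_regions
    if y.shape != (3 * n + 2,):
        raise ParameterError(
            f"state length {y.shape} does not match 3N+2 = {3 * n + 2}")
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise ParameterError(f"non-finite state at flat component {bad}")
    if het.n_regions != n:
        raise ParameterError("heterogeneity length does not match region count")
    out = np.empty_like(y)
    idx = np.array([regions.lmc_left, regions.lmc_right,
                    regions.snc_left, regions.snc_right], dtype=np.int64)
    _drift_kernel(float(t), y, out, C.weights, het.a_ie,
                  _pack_parameters(p), idx, _pack_schedule(sched))
    return out


def diffusion(p: ModelParameters, het) -> np.ndarray:
    """Constant additive noise vector b of the SDE dY = a dt + b dW.

    One scalar Wiener increment multiplies the whole vector: excitatory
    components carry delta * a_ne_i, inhibitory components
    delta * kappa * a_ni, and the W and dopamine components are
    noise-free.  ``het`` may be a :class:`RegionalHeterogeneity` or a region
    count (homogeneous a_ne at its mean).
    """
    if isinstance(het, (int, np.integer)):
        het = RegionalHeterogeneity.homogeneous(p, int(het))
    n = het.n_regions
    b = np.zeros(3 * n + 2)
    b[:n] = p.noise_amplitude * het.a_ne
    b[n:2 * n] = p.noise_amplitude * p.inhibitory_noise_scale * p.a_ni
    return b


def initial_state(p: ModelParameters, n: int, seed: int) -> NeuralState:
    """Initial condition shared by rest and task runs of one experiment.

    V and Z start uniformly in [-0.1, 0.1] mV around rest, W at the
    potassium open-channel fraction consistent with V, and dopamine at the
    tonic level c_0.
    """
    rng = np.random.default_rng(seed)
    V = rng.uniform(-0.1, 0.1, size=n)
    Z = rng.uniform(-0.1, 0.1, size=n)
    W = channel_open_fraction(V, p.T_K, p.delta_K)
    return NeuralState(V=V, Z=Z, W=W, c=np.full(2, p.c_0))


class NeuralModel:
    """Bundle of drift + diffusion ready for the SDE integrator.

    Packs parameters, coupling, heterogeneity, schedule and region roles
    into the flat arrays the jitted kernel consumes, and exposes
    ``drift_fn(t, y) -> array`` / ``diffusion_vector`` for generic solvers.
    The last two state components (dopamine) are clamped at zero after each
    integration step (``clamp_low`` contract used by the integrator).
    """

    def __init__(self, p: ModelParameters, C: CouplingMatrix,
                 regions: RegionSet, het: RegionalHeterogeneity,
                 sched: TaskSchedule):
        if C.n_regions != regions.n_regions:
            raise ParameterError("coupling matrix does not match region set")
        if het.n_regions != regions.n_regions:
            raise ParameterError("heterogeneity does not match region set")
        self.p = p
        self.C = C
        self.regions = regions
        self.het = het
        self.sched = sched
        self._par = _pack_parameters(p)
        self._idx = np.array([regions.lmc_left, regions.lmc_right,
                              regions.snc_left, regions.snc_right],
                             dtype=np.int64)
        self._sched = _pack_schedule(sched)

    @property
    def dim(self) -> int:
        return 3 * self.regions.n_regions + 2

    # indices clamped at zero after each step (dopamine nonnegativity)
    @property
    def clamp_low(self) -> slice:
        return slice(self.dim - 2, self.dim)

    @property
    def diffusion_vector(self) -> np.ndarray:
        return diffusion(self.p, self.het)

    def drift_fn(self, t: float, y: np.ndarray) -> np.ndarray:
        out = np.empty_like(y)
        _drift_kernel(float(t), y, out, self.C.weights, self.het.a_ie,
                      self._par, self._idx, self._sched)
        return out

    def kernel_args(self):
        """Arrays consumed by the jitted integration loop."""
        return self.C.weights, self.het.a_ie, self._par, self._idx, self._sched
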