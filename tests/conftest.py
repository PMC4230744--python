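"""Shared fixtures and independent scalar oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

import dopasim as ds


@pytest.fixture(scope="session")
def params() -> ds.ModelParameters:
    return ds.ModelParameters()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def small_setup(n: int, seed: int, mode: str = "rest"):
    """A consistent n-region model bundle for drift/integration tests."""
    p = ds.ModelParameters()
    regions = ds.make_region_manifest(n)
    C = ds.generate_coupling_matrix(
        ds.SyntheticConnectomeSpec(n=n, density=0.5, seed=seed))
    het = ds.sample_heterogeneity(p, n, seed=seed + 1)
    sched = ds.TaskSchedule(mode=mode, n_cycles=1)
    model = ds.NeuralModel(p, C, regions, het, sched)
    return p, regions, C, het, sched, model


# ---------------------------------------------------------------------------
# scalar, loop-based transcription of the model equations (oracle).
# Written with plain math.* calls, one region at a time, independent of the
# vectorized/jitted implementation.

def _sig(v: float, mean: float, disp: float) -> float:
    return 0.5 * (1.0 + math.tanh((v - mean) / disp))


def oracle_beta(t_ms: float, sched: ds.TaskSchedule, p: ds.ModelParameters) -> float:
    if sched.mode != "task":
        return p.beta_min
    within = math.fmod(t_ms, sched.cycle_s * 1000.0)
    return p.beta_max if within < sched.speech_s * 1000.0 else p.beta_min


def oracle_gain(c: float, p: ds.ModelParameters) -> float:
    return p.G_min + (p.G_max - p.G_min) * (p.antagonism * c) / (
        1.0 + p.antagonism * c)


def oracle_drift(t, y, p, C, het, sched, regions):
    """Component-by-component transcription of the full drift."""
    n = C.n_regions
    w = C.weights
    V = y[:n]
    Z = y[n:2 * n]
    W = y[2 * n:3 * n]
    c = y[3 * n:]
    out = [0.0] * (3 * n + 2)
    beta = oracle_beta(t, sched, p)
    for i in range(n):
        q_v_i = 0.0  # coupled input: explicit summation over all regions
        for j in range(n):
            q_j = 0.5 * p.Q_V_max * (1.0 + math.tanh((V[j] - p.V_T) / p.delta_V))
            q_v_i += w[i, j] * q_j
        if i == regions.lmc_left:
            g = oracle_gain(c[0], p)
        elif i == regions.lmc_right:
            g = oracle_gain(c[1], p)
        else:
            g = 1.0
        aee = g * p.a_ee
        m_ca = _sig(V[i], p.T_Ca, p.delta_Ca)
        m_na = _sig(V[i], p.T_Na, p.delta_Na)
        m_k = _sig(V[i], p.T_K, p.delta_K)
        q_z = 0.5 * p.Q_Z_max * (1.0 + math.tanh((Z[i] - p.Z_T) / p.delta_Z))
        q_v_own = 0.5 * p.Q_V_max * (1.0 + math.tanh((V[i] - p.V_T) / p.delta_V))
        dv = (-(p.g_Ca + p.r_nmda * aee * q_v_i) * m_ca * (V[i] - p.V_Ca)
              - (p.g_Na * m_na + aee * q_v_i) * (V[i] - p.V_Na)
              - p.g_K * W[i] * (V[i] - p.V_K)
              - p.g_L * (V[i] - p.V_L)
              - het.a_ie[i] * Z[i] * q_z)
        dz = p.a_ei * V[i] * q_v_own
        m_mod = g * m_k / (1.0 + (g - 1.0) * m_k)
        dw = p.phi * (m_mod - W[i]) / p.tau_K
        out[i] = dv
        out[n + i] = dz
        out[2 * n + i] = dw
    for side, snc in ((0, regions.snc_left), (1, regions.snc_right)):
        q_snc = 0.5 * p.Q_V_max * (1.0 + math.tanh((V[snc] - p.V_T) / p.delta_V))
        cc = max(c[side], 0.0)
        out[3 * n + side] = beta * q_snc - p.v_max_uptake * cc / (p.K_m + cc)
    return np.array(out)
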