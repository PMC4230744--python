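"""Strong order-1.5 Runge-Kutta and Milstein integration of the model SDE.

The model is a non-autonomous SDE with *constant additive scalar* noise,

    dY = a(t, Y) dt + b dW,        b constant, W a scalar Wiener process,

which admits an explicit strong order-1.5 scheme needing no diffusion
derivatives and exactly three drift evaluations per step.  With supporting
points  Y± = Y + a0 h ± b sqrt(h)  and  a0 = a(t, Y),  a± = a(t + h, Y±):

    Y' = Y + b dW + (h/2) a0 + (h/4)(a+ + a-) + (dZ / (2 sqrt(h)))(a+ - a-)

where the pair (dW, dZ) — the Wiener increment and the double stochastic
integral of W over the step — is jointly Gaussian with

    Var dW = h,   Var dZ = h^3 / 3,   Cov(dW, dZ) = h^2 / 2,

generated from two independent standard normals u1, u2 as
dW = u1 sqrt(h),  dZ = (h^{3/2} / 2)(u1 + u2 / sqrt(3)).  For additive noise
the Milstein scheme reduces to Euler-Maruyama (one drift evaluation) and is
kept as a reference integrator.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_core import NeuralModel, _drift_kernel
from .params import NeuralState, ParameterError, SolverConfig

__all__ = [
    "correlated_increments",
    "rk15_step",
    "milstein_step",
    "integrate",
    "SamplePath",
    "DivergenceError",
    "ou_convergence_study",
]

_SQRT3 = np.sqrt(3.0)


class DivergenceError(RuntimeError):
    """Integration produced a non-finite state.

    Carries the failing step and flat state component, plus the partial
    sample path accumulated so far (``partial_path``) for diagnosis.
    """

    def __init__(self, step: int, component: int, partial_path=None):
        super().__init__(
            f"non-finite state at step {step}, flat component {component}")
        self.step = step
        self.component = component
        self.partial_path = partial_path


def correlated_increments(h: float, rng: np.random.Generator, size=None):
    """Draw the correlated pair (dW, dZ) for one or ``size`` steps."""
    if h <= 0:
        raise ParameterError("step size must be positive")
    u1 = rng.standard_normal(size)
    u2 = rng.standard_normal(size)
    sqh = np.sqrt(h)
    dw = u1 * sqh
    dz = 0.5 * h * sqh * (u1 + u2 / _SQRT3)
    return dw, dz


def rk15_step(y, t, h, drift, b, dw, dz):
    """One explicit strong order-1.5 step (three drift evaluations)."""
    y = np.asarray(y, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), y.shape)
    sqh = np.sqrt(h)
    a0 = np.asarray(drift(t, y), dtype=float)
    yp = y + a0 * h + b * sqh
    ym = y + a0 * h - b * sqh
    ap = np.asarray(drift(t + h, yp), dtype=float)
    am = np.asarray(drift(t + h, ym), dtype=float)
    return (y + b * dw + 0.5 * h * a0 + 0.25 * h * (ap + am)
            + (dz / (2.0 * sqh)) * (ap - am))


def milstein_step(y, t, h, drift, b, dw):
    """One Milstein step; for additive noise this is Euler-Maruyama."""
    y = np.asarray(y, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), y.shape)
    return y + np.asarray(drift(t, y), dtype=float) * h + b * dw


@dataclass
class SamplePath:
    """Stored trajectory: strictly increasing times (ms) x state rows."""

    times: np.ndarray
    states: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ParameterError("times and state rows must align")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")

    @property
    def n_regions(self) -> int:
        return (self.states.shape[1] - 2) // 3

    def component(self, block: str) -> np.ndarray:
        """Time series of one state block: 'V', 'Z', 'W' or 'c'."""
        n = self.n_regions
        off = {"V": (0, n), "Z": (n, 2 * n), "W": (2 * n, 3 * n),
               "c": (3 * n, 3 * n + 2)}[block]
        return self.states[:, off[0]:off[1]]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.times)
            f.create_dataset("state", data=self.states)
            meta = f.create_group("meta")
            for k, v in self.meta.items():
                meta.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "SamplePath":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(times=f["time"][...], states=f["state"][...],
                       meta=dict(f["meta"].attrs))

    def to_text(self, path) -> None:
        """Delimited-text export: first column time (ms), then state columns."""
        np.savetxt(path, np.column_stack([self.times, self.states]),
                   delimiter="\t", header="time_ms\tstate[3N+2]")


@njit(cache=True)
def _integrate_kernel(y0, h, n_steps, stride, use_rk15, U, b,
                      C, a_ie, par, idx, sched, times, states):
    dim = y0.size
    y = y0.copy()
    a0 = np.empty(dim)
    ap = np.empty(dim)
    am = np.empty(dim)
    yp = np.empty(dim)
    ym = np.empty(dim)
    sqh = np.sqrt(h)
    times[0] = 0.0
    states[0] = y
    row = 0
    t = 0.0
    for k in range(n_steps):
        u1 = U[k, 0]
        u2 = U[k, 1]
        dw = u1 * sqh
        dz = 0.5 * h * sqh * (u1 + u2 / _SQRT3)
        _drift_kernel(t, y, a0, C, a_ie, par, idx, sched)
        if use_rk15:
            for j in range(dim):
                yp[j] = y[j] + a0[j] * h + b[j] * sqh
                ym[j] = y[j] + a0[j] * h - b[j] * sqh
            _drift_kernel(t + h, yp, ap, C, a_ie, par, idx, sched)
            _drift_kernel(t + h, ym, am, C, a_ie, par, idx, sched)
            for j in range(dim):
                y[j] += (b[j] * dw + 0.5 * h * a0[j]
                         + 0.25 * h * (ap[j] + am[j])
                         + (dz / (2.0 * sqh)) * (ap[j] - am[j]))
        else:
            for j in range(dim):
                y[j] += a0[j] * h + b[j] * dw
        if y[dim - 2] < 0.0:
            y[dim - 2] = 0.0
        if y[dim - 1] < 0.0:
            y[dim - 1] = 0.0
        t = (k + 1) * h
        for j in range(dim):
            if not np.isfinite(y[j]):
                return k, j, row
        if (k + 1) % stride == 0:
            row += 1
            times[row] = t
            states[row] = y
    return -1, -1, row


def integrate(initial, cfg: SolverConfig, model) -> SamplePath:
    """Integrate the SDE over cfg.duration_ms, storing every cfg.stride-th step.

    ``model`` is a :class:`~dopasim.model_core.NeuralModel` (fast jitted
    loop) or any object with ``drift_fn(t, y)`` and ``diffusion_vector``
    attributes (generic loop; an optional ``clamp_low`` slice is floored at
    zero after each step).  The path is reproducible bit-for-bit given
    identical (seed, config, inputs); the RNG is numpy's PCG64 seeded with
    ``cfg.seed``, drawing two standard normals per step.
    """
    y0 = initial.flatten() if isinstance(initial, NeuralState) else \
        np.asarray(initial, dtype=float).copy()
    n_steps = cfg.n_steps
    n_rows = n_steps // cfg.stride + 1
    rng = np.random.default_rng(cfg.seed)
    U = rng.standard_normal((n_steps, 2))
    times = np.empty(n_rows)
    states = np.empty((n_rows, y0.size))
    meta = {"seed": cfg.seed, "scheme": cfg.scheme, "h": cfg.h,
            "stride": cfg.stride, "duration_ms": cfg.duration_ms}

    if isinstance(model, NeuralModel):
        if y0.size != model.dim:
            raise ParameterError(
                f"initial state length {y0.size} != model dim {model.dim}")
        meta["params_hash"] = hashlib.sha256(
            model._par.tobytes() + model.C.weights.tobytes()).hexdigest()[:16]
        C, a_ie, par, idx, sched = model.kernel_args()
        bad_step, bad_comp, row = _integrate_kernel(
            y0, cfg.h, n_steps, cfg.stride, cfg.scheme == "rk15",
            U, model.diffusion_vector, C, a_ie, par, idx, sched,
            times, states)
        if bad_step >= 0:
            raise DivergenceError(bad_step, bad_comp, SamplePath(
                times=times[:row + 1], states=states[:row + 1], meta=meta))
        return SamplePath(times=times[:row + 1], states=states[:row + 1],
                          meta=meta)

    # generic (pure-python) loop for arbitrary drift/diffusion bundles
    b = np.broadcast_to(np.asarray(model.diffusion_vector, dtype=float),
                        y0.shape)
    clamp = getattr(model, "clamp_low", None)
    y = y0.copy()
    times[0] = 0.0
    states[0] = y
    row = 0
    t = 0.0
    for k in range(n_steps):
        u1, u2 = U[k]
        sqh = np.sqrt(cfg.h)
        dw = u1 * sqh
        dz = 0.5 * cfg.h * sqh * (u1 + u2 / _SQRT3)
        if cfg.scheme == "rk15":
            y = rk15_step(y, t, cfg.h, model.drift_fn, b, dw, dz)
        else:
            y = milstein_step(y, t, cfg.h, model.drift_fn, b, dw)
        if clamp is not None:
            np.maximum(y[clamp], 0.0, out=y[clamp])
        t = (k + 1) * cfg.h
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise DivergenceError(k, bad, SamplePath(
                times=times[:row + 1], states=states[:row + 1], meta=meta))
        if (k + 1) % cfg.stride == 0:
            row += 1
            times[row] = t
            states[row] = y
    return SamplePath(times=times[:row + 1], states=states[:row + 1],
                      meta=meta)


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck strong-convergence benchmark

def ou_convergence_study(n_paths: int = 200, exponents=range(3, 8),
                         T: float = 1.0, a: float = 1.0, sigma: float = 1.0,
                         x0: float = 1.0, seed: int = 0) -> dict:
    """Empirical strong order of both schemes on the OU process dX = -aX dt + sigma dW.

    For each path, correlated increment pairs are drawn on the finest grid
    h = 2^-max(exponents) and coarsened pairwise (dW' = dW1 + dW2,
    dZ' = dZ1 + dZ2 + h dW1), so every step size sees the same Wiener path.
    The reference solution uses the exact OU propagator per finest step,
    X' = e^{-ah} X + sigma (dW - a dZ), whose truncation error is O(h^2) —
    below both schemes' strong errors on the tested range.  Returns the
    step sizes, mean absolute endpoint errors and fitted log2-log2 slopes.
    """
    exponents = sorted(exponents)
    h_min = 2.0 ** (-exponents[-1])
    n_min = int(round(T / h_min))
    rng = np.random.default_rng(seed)
    errors = {"rk15": np.zeros(len(exponents)),
              "milstein": np.zeros(len(exponents))}
    for _ in range(n_paths):
        dw, dz = correlated_increments(h_min, rng, size=n_min)
        # exact endpoint on the finest grid
        x_ref = x0
        decay = np.exp(-a * h_min)
        for k in range(n_min):
            x_ref = decay * x_ref + sigma * (dw[k] - a * dz[k])
        # coarsen and integrate at every level
        levels = {exponents[-1]: (dw, dz)}
        for m in reversed(exponents[:-1]):
            dw2, dz2 = levels[m + 1]
            h2 = 2.0 ** (-(m + 1))
            dw = dw2[0::2] + dw2[1::2]
            dz = dz2[0::2] + dz2[1::2] + h2 * dw2[0::2]
            levels[m] = (dw, dz)
        drift = lambda t, x: -a * x
        for li, m in enumerate(exponents):
            h = 2.0 ** (-m)
            dw_l, dz_l = levels[m]
            y_rk = np.array([x0])
            y_mi = np.array([x0])
            for k in range(dw_l.size):
                t = k * h
                y_rk = rk15_step(y_rk, t, h, drift, sigma, dw_l[k], dz_l[k])
                y_mi = milstein_step(y_mi, t, h, drift, sigma, dw_l[k])
            errors["rk15"][li] += abs(float(y_rk[0]) - x_ref)
            errors["milstein"][li] += abs(float(y_mi[0]) - x_ref)
    hs = 2.0 ** (-np.array(exponents, dtype=float))
    out = {"h": hs}
    for scheme in ("rk15", "milstein"):
        err = errors[scheme] / n_paths
        slope = -np.polyfit(np.array(exponents, dtype=float),
                            np.log2(err), 1)[0]
        out[scheme] = {"errors": err, "slope": float(slope)}
    return out
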