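"""Balloon-Windkessel conversion of neural activity to simulated BOLD.

The neural drive z(t) of each region (by default its excitatory firing
rate, kHz) perturbs a vasodilatory signal s, which drives blood inflow f;
venous volume v and deoxyhemoglobin content q follow through the balloon
model with outflow v^(1/alpha) (Grubb exponent) and flow-dependent oxygen
extraction E(f) = 1 - (1 - rho)^(1/f):

    ds/dt = eps z - kappa s - gamma (f - 1)
    df/dt = s
    tau0 dv/dt = f - v^(1/alpha)
    tau0 dq/dt = f E(f)/rho - v^(1/alpha) q / v

    BOLD % = 100 V0 [k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)],
    k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2.

At zero drive the system rests at s = 0, f = v = q = 1 and the output is a
constant 0% baseline.  Constants are the canonical hemodynamic values and
live in :class:`HemodynamicParameters`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError

__all__ = ["HemodynamicParameters", "BoldSignal", "balloon_windkessel",
           "sample_at_tr", "sample_sparse"]


@dataclass(frozen=True)
class HemodynamicParameters:
    kappa: float = 0.65   # signal decay rate (1/s)
    gamma: float = 0.41   # flow autoregulation rate (1/s)
    tau0: float = 0.98    # mean transit time (s)
    alpha: float = 0.32   # Grubb vessel stiffness exponent
    rho: float = 0.34     # resting oxygen extraction fraction
    V0: float = 0.02      # resting venous blood volume fraction
    epsilon: float = 0.5  # neural efficacy (per unit drive)

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau0", "alpha", "rho", "V0",
                     "epsilon"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"hemodynamic constant {name} must be "
                                     "strictly positive")


@dataclass
class BoldSignal:
    """Per-region BOLD time series in % signal change, sampled every tr_s."""

    values: np.ndarray          # (time, regions)
    tr_s: float
    drive: str = "firing_rate"  # which neural variable generated the signal

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("BOLD series contains non-finite values")
        if self.tr_s <= 0:
            raise ParameterError("sampling interval must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def balloon_windkessel(neural: np.ndarray, dt_s: float,
                       params: HemodynamicParameters | None = None,
                       drive_name: str = "firing_rate") -> BoldSignal:
    """Integrate the balloon model over a dense per-region drive series.

    ``neural`` has shape (time, regions); the drive is held constant over
    each dt_s step and the hemodynamic ODEs are advanced with classical RK4
    (their time constants of ~1 s are far slower than any sensible dt).
    Returns the dense BOLD series at the same sampling as the input.
    """
    p = params or HemodynamicParameters()
    z = np.atleast_2d(np.asarray(neural, dtype=float))
    if not np.all(np.isfinite(z)):
        raise ParameterError("neural drive contains non-finite values")
    if dt_s <= 0:
        raise ParameterError("dt must be positive")
    n_t, n_r = z.shape

    s = np.zeros(n_r)
    f = np.ones(n_r)
    v = np.ones(n_r)
    q = np.ones(n_r)
    inv_alpha = 1.0 / p.alpha

    def deriv(state, zk):
        s_, f_, v_, q_ = state
        f_ = np.maximum(f_, 1e-9)
        v_ = np.maximum(v_, 1e-9)
        outflow = v_ ** inv_alpha
        ds = p.epsilon * zk - p.kappa * s_ - p.gamma * (f_ - 1.0)
        dv = (f_ - outflow) / p.tau0
        dq = (f_ * (1.0 - (1.0 - p.rho) ** (1.0 / f_)) / p.rho
              - outflow * q_ / v_) / p.tau0
        return np.array([ds, s_, dv, dq])

    k1c = 7.0 * p.rho
    k2c = 2.0
    k3c = 2.0 * p.rho - 0.2
    bold = np.empty((n_t, n_r))
    state = np.array([s, f, v, q])
    for k in range(n_t):
        vv = np.maximum(state[2], 1e-9)
        qq = state[3]
        bold[k] = 100.0 * p.V0 * (k1c * (1.0 - qq)
                                  + k2c * (1.0 - qq / vv)
                                  + k3c * (1.0 - vv))
        zk = z[k]
        a = deriv(state, zk)
        b = deriv(state + 0.5 * dt_s * a, zk)
        c = deriv(state + 0.5 * dt_s * b, zk)
        d = deriv(state + dt_s * c, zk)
        state = state + (dt_s / 6.0) * (a + 2 * b + 2 * c + d)

    if not np.all(np.isfinite(bold)):
        raise ParameterError("hemodynamic integration diverged")
    return BoldSignal(values=bold, tr_s=dt_s, drive=drive_name)


def sample_at_tr(bold: BoldSignal, tr_s: float) -> BoldSignal:
    """Decimate a dense BOLD series to the acquisition TR.

    Each output sample is the mean over the acquisition window
    [k TR, (k+1) TR) (anti-alias boxcar averaging); TR equal to the dense
    step is the identity.  Output length is floor(duration / TR).
    """
    dt = bold.tr_s
    if tr_s < dt - 1e-12:
        raise ParameterError(
            f"TR {tr_s}s is finer than the dense sampling {dt}s")
    per = int(round(tr_s / dt))
    if abs(per * dt - tr_s) > 1e-9 * tr_s:
        raise ParameterError("TR must be an integer multiple of the dense step")
    n_out = bold.values.shape[0] // per
    if n_out == 0:
        raise ParameterError("series shorter than one TR")
    trimmed = bold.values[:n_out * per]
    out = trimmed.reshape(n_out, per, -1).mean(axis=1)
    return BoldSignal(values=out, tr_s=tr_s, drive=bold.drive)


def sample_sparse(bold: BoldSignal, cycle_s: float,
                  window_s: float) -> BoldSignal:
    """Sparse-sampling acquisition: one volume per cycle.

    Emulates event-related sparse EPI: each cycle of ``cycle_s`` seconds
    yields a single volume averaged over the final ``window_s`` seconds
    (the image-acquisition gap that follows the task window), so the
    sample catches the hemodynamic response to the preceding activity.
    Output sampling interval is the cycle length.
    """
    dt = bold.tr_s
    if not (0 < window_s <= cycle_s):
        raise ParameterError("acquisition window must lie within the cycle")
    per = int(round(cycle_s / dt))
    win = max(1, int(round(window_s / dt)))
    if per < 1 or per > bold.values.shape[0]:
        raise ParameterError("series shorter than one cycle")
    n_out = bold.values.shape[0] // per
    out = np.empty((n_out, bold.values.shape[1]))
    for k in range(n_out):
        end = (k + 1) * per
        out[k] = bold.values[end - win:end].mean(axis=0)
    return BoldSignal(values=out, tr_s=cycle_s, drive=bold.drive)
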