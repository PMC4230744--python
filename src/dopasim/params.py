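"""Shared parameter and domain types for the dopamine-modulated neural mass model.

All model quantities use the (normalized) units of the source neural mass
model: membrane potentials in mV, conductances in mS/ms, firing rates in kHz,
time in ms, dopamine concentrations in mM.  These are model units, not
physiological ones, and are never rescaled internally.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "RegionSet",
    "CouplingMatrix",
    "NeuralState",
    "RegionalHeterogeneity",
    "TaskSchedule",
    "SolverConfig",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a model parameter violates its invariants."""


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the neural + dopamine model.

    Defaults are the published parameter table of the model.  The per-region
    heterogeneous couplings ``a_ie`` and ``a_ne`` are specified here as
    normal distributions (mean/sd); the printed numeric distribution
    parameters were not recoverable from the source table, so the means and
    spreads below are package defaults chosen to preserve regional
    desynchronization without destabilizing a node.
    """

    # -- calcium channels
    T_Ca: float = -0.01      # mean opening threshold (mV)
    delta_Ca: float = 0.15   # threshold dispersion (mV)
    g_Ca: float = 1.1        # max conductance (mS/ms)
    V_Ca: float = 1.0        # Nernst potential (mV)
    # -- potassium channels
    T_K: float = 0.0
    delta_K: float = 0.3
    g_K: float = 2.0
    V_K: float = -0.7
    # -- sodium channels
    T_Na: float = 0.3
    delta_Na: float = 0.15
    g_Na: float = 6.7
    V_Na: float = 0.53
    # -- leak
    V_L: float = -0.5
    g_L: float = 0.5
    # -- firing-rate sigmoids
    V_T: float = 0.54        # mean threshold of excitatory firing (mV)
    Z_T: float = 0.0         # mean threshold of inhibitory firing (mV)
    delta_V: float = 2.0     # excitatory firing dispersion (mV)
    delta_Z: float = 0.7     # inhibitory firing dispersion (mV)
    Q_V_max: float = 1.0     # max excitatory firing rate (kHz)
    Q_Z_max: float = 1.0     # max inhibitory firing rate (kHz)
    # -- synaptic couplings (mS)
    a_ee: float = 0.4        # excitatory-to-excitatory
    a_ei: float = 2.0        # excitatory-to-inhibitory
    a_ie_mean: float = 2.0   # inhibitory-to-excitatory (heterogeneous; default)
    a_ie_sd: float = 0.1
    a_ne_mean: float = 0.4   # non-specific-to-excitatory (heterogeneous; default)
    a_ne_sd: float = 0.05
    a_ni: float = 0.4        # non-specific-to-inhibitory
    # -- potassium relaxation
    phi: float = 0.7         # temperature scaling factor (dimensionless)
    tau_K: float = 1.0       # relaxation time (ms)
    # -- glutamate
    r_nmda: float = 0.25     # NMDA-to-AMPA receptor ratio
    # -- noise
    noise_amplitude: float = 0.3        # noise current amplitude delta (1/ms)
    inhibitory_noise_scale: float = 0.1  # extra scaling of inhibitory noise
    # -- dopamine block
    v_max_uptake: float = 0.004  # max re-uptake rate V_max (mM/ms)
    K_m: float = 0.125           # Michaelis-Menten constant (mM)
    c_0: float = 0.05            # tonic dopamine level (mM), initial condition
    beta_min: float = 0.0005     # min production rate (mM per unit firing)
    beta_max: float = 0.01       # max production rate (mM per unit firing)
    antagonism: float = 0.2      # antagonism parameter (1/mM)
    G_min: float = 1.0           # minimum dopamine gain
    G_max: float = 50.0          # maximum dopamine gain

    def __post_init__(self) -> None:
        positive = [
            "delta_Ca", "delta_K", "delta_Na", "delta_V", "delta_Z",
            "g_Ca", "g_K", "g_Na", "g_L",
            "Q_V_max", "Q_Z_max",
            "a_ee", "a_ei", "a_ie_mean", "a_ie_sd", "a_ne_mean", "a_ne_sd",
            "a_ni", "phi", "tau_K", "r_nmda",
            "v_max_uptake", "K_m", "beta_min", "beta_max", "antagonism",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.noise_amplitude < 0 or self.inhibitory_noise_scale < 0:
            raise ParameterError("noise amplitudes must be nonnegative")
        if self.G_min != 1.0:
            raise ParameterError("G_min must equal 1 (unity gain at zero dopamine)")
        if self.G_max < self.G_min:
            raise ParameterError("G_max must be >= G_min")
        if self.beta_max < self.beta_min:
            raise ParameterError("beta_max must be >= beta_min")
        if self.c_0 < 0:
            raise ParameterError("tonic dopamine level c_0 must be >= 0")

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RegionSet:
    """The parcellation: region labels plus the four special roles.

    ``lmc_left``/``lmc_right`` index the laryngeal motor cortex (dopamine
    target), ``snc_left``/``snc_right`` the substantia nigra pars compacta
    (dopamine source).
    """

    labels: tuple
    lmc_left: int
    lmc_right: int
    snc_left: int
    snc_right: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if n < 4:
            raise ParameterError("a region set needs at least 4 regions")
        if len(set(self.labels)) != n:
            raise ParameterError("duplicate region labels")
        special = (self.lmc_left, self.lmc_right, self.snc_left, self.snc_right)
        if len(set(special)) != 4:
            raise ParameterError("LMC/SNc indices must be four distinct regions")
        for idx in special:
            if not (0 <= idx < n):
                raise ParameterError(f"special index {idx} outside [0, {n})")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class CouplingMatrix:
    """Nonnegative N x N structural coupling weights.

    Entry ``c[i, j]`` weights the influence of region ``j``'s excitatory
    firing on region ``i``; the diagonal carries local excitatory input.
    ``largest_row_sum`` records the pre-normalization scale.
    """

    weights: np.ndarray
    largest_row_sum: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ParameterError(f"coupling matrix must be square, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ParameterError("coupling matrix contains non-finite entries")
        if np.any(w < 0):
            raise ParameterError("coupling matrix entries must be nonnegative")
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_raw(cls, raw: np.ndarray, diagonal: float = 1.0) -> "CouplingMatrix":
        """Set the local-input diagonal, then normalize by the largest row-sum."""
        w = np.array(raw, dtype=float)
        np.fill_diagonal(w, diagonal)
        if np.any(w < 0):
            raise ParameterError("raw coupling weights must be nonnegative")
        s = float(w.sum(axis=1).max())
        if s <= 0:
            raise ParameterError("coupling matrix has no positive row-sum")
        return cls(weights=w / s, largest_row_sum=s)


@dataclass
class NeuralState:
    """State of the full model: potentials, channel fractions, dopamine.

    The flattened layout (stable across all I/O) is the concatenation
    ``[V(N), Z(N), W(N), c(2)]`` of dimension ``3N + 2``:
    V — mean excitatory membrane potential per region (mV);
    Z — mean inhibitory membrane potential per region (mV);
    W — fraction of open potassium channels per region;
    c — dopamine concentration in (left, right) LMC (mM).
    """

    V: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        n = self.V.shape[0]
        if self.Z.shape != (n,) or self.W.shape != (n,):
            raise ParameterError("V, Z, W must share length N")
        if self.c.shape != (2,):
            raise ParameterError("dopamine state c must have exactly 2 components")
        for name in ("V", "Z", "W", "c"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ParameterError(f"non-finite entries in state component {name}")
        if np.any(self.c < 0):
            raise ParameterError("dopamine concentrations must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.V.shape[0]

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.V, self.Z, self.W, self.c])

    @classmethod
    def from_flat(cls, y: np.ndarray) -> "NeuralState":
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or (y.size - 2) % 3 != 0:
            raise ParameterError(f"flat state length {y.size} is not 3N+2")
        n = (y.size - 2) // 3
        return cls(V=y[:n], Z=y[n:2 * n], W=y[2 * n:3 * n], c=y[3 * n:])


@dataclass(frozen=True)
class RegionalHeterogeneity:
    """Per-region synaptic couplings a_ie and a_ne drawn once per experiment."""

    a_ie: np.ndarray
    a_ne: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        a_ie = np.asarray(self.a_ie, dtype=float)
        a_ne = np.asarray(self.a_ne, dtype=float)
        if a_ie.shape != a_ne.shape or a_ie.ndim != 1:
            raise ParameterError("a_ie and a_ne must be 1-d arrays of equal length")
        if np.any(a_ie <= 0) or np.any(a_ne <= 0):
            raise ParameterError("heterogeneous couplings must be strictly positive")
        object.__setattr__(self, "a_ie", a_ie)
        object.__setattr__(self, "a_ne", a_ne)

    @property
    def n_regions(self) -> int:
        return self.a_ie.shape[0]

    @classmethod
    def homogeneous(cls, p: ModelParameters, n: int) -> "RegionalHeterogeneity":
        """All regions at the distribution means (no regional variation)."""
        return cls(a_ie=np.full(n, p.a_ie_mean), a_ne=np.full(n, p.a_ne_mean),
                   seed=-1)


@dataclass(frozen=True)
class TaskSchedule:
    """Rest-vs-speech cycling of the dopamine production rate beta(t).

    In task mode each cycle of ``cycle_s`` seconds opens with a speech window
    of ``speech_s`` seconds during which beta = beta_max; outside the window
    (the image-acquisition gap) and in rest mode beta = beta_min.  The switch
    is a step function; the 0.1 ms integration step lets release set in
    gradually through the concentration dynamics, not through beta smoothing.
    """

    mode: str = "rest"          # "rest" | "task"
    cycle_s: float = 10.6
    speech_s: float = 8.6
    n_cycles: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("rest", "task"):
            raise ParameterError(f"schedule mode must be rest|task, got {self.mode!r}")
        if not (0 <= self.speech_s <= self.cycle_s):
            raise ParameterError("speech window must lie within the cycle")
        if self.n_cycles < 1:
            raise ParameterError("need at least one cycle")

    @property
    def duration_ms(self) -> float:
        return self.cycle_s * self.n_cycles * 1000.0


@dataclass(frozen=True)
class SolverConfig:
    """Time discretization of the SDE integration."""

    h: float = 0.1              # step size (ms)
    duration_ms: float = 1000.0
    scheme: str = "rk15"        # "rk15" | "milstein"
    seed: int = 0
    stride: int = 1             # store every `stride`-th step

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ParameterError("step size h must be positive")
        if self.duration_ms < self.h:
            raise ParameterError("duration must be at least one step")
        if self.scheme not in ("rk15", "milstein"):
            raise ParameterError(f"unknown scheme {self.scheme!r}")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(np.ceil(self.duration_ms / self.h))
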