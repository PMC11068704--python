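"""Conductance-based and polynomial neuron models that generate all data.

Four single-neuron models are provided, each driven by an applied current
``I_app`` swept over a physiological interval 𝓘 chosen around the
quiescent/spiking boundary:

* ``morris_lecar`` — 2D calcium/potassium model (v, w) in its class-I (SNIC)
  regime; 𝓘 = [20, 60] µA/cm².
* ``fhn`` — cubic polynomial FitzHugh–Nagumo (v, w) with excitability
  parameter ``a`` and recovery divisor ``gamma``; 𝓘 = [0.07, 0.09].
* ``fhn3d`` — FitzHugh–Nagumo–Rinzel: the 2D model plus a slow linear
  recovery current y, adding a second (slow) timescale; 𝓘 = [0.05, 0.07].
* ``wang`` — pyramidal-type spiking model (v, h, n) with instantaneous
  sodium activation and sharp action potentials; 𝓘 = [-3, 3] µA/cm².

Integration is explicit Euler on a fixed step (the same grid on which the
wavenet is later trained).  Multiplicative parameter noise
``kappa (1 + xi(t))``, ``xi ~ U[-xi_bar, xi_bar]`` redrawn every step, models
biological variability of the leak/potassium conductances (conductance
models) or of ``a`` and ``gamma`` (FitzHugh–Nagumo models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels

__all__ = [
    "ModelSpec",
    "Trajectory",
    "make_model",
    "rhs",
    "integrate_euler",
    "perturb_parameters",
    "draw_parameter_noise",
    "resting_state",
    "MODEL_NAMES",
]

MODEL_NAMES = ("morris_lecar", "fhn", "fhn3d", "wang")

_CODES = {
    "morris_lecar": _kernels.ML,
    "fhn": _kernels.FHN,
    "fhn3d": _kernels.FHN3D,
    "wang": _kernels.WANG,
}


@dataclass(frozen=True)
class ModelSpec:
    """A neuron model: equations' parameters plus its simulation protocol."""

    name: str
    state_names: tuple
    params: dict
    dt: float
    current_interval: tuple
    noisy_params: tuple
    training_duration_s: float
    xi_bar: float = 0.0
    noise_seed: int | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        lo, hi = self.current_interval
        if not lo < hi:
            raise ValueError("current_interval must satisfy lo < hi")
        if not self.state_names or len(set(self.state_names)) != len(self.state_names):
            raise ValueError("state_names must be non-empty and unique")
        if not set(self.noisy_params) <= set(self.params):
            raise ValueError("noisy_params must be a subset of params")
        if self.xi_bar < 0:
            raise ValueError("xi_bar must be non-negative")

    @property
    def n_state(self) -> int:
        return len(self.state_names)

    def param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in _PARAM_ORDER[self.name]], dtype=float)

    def noisy_indices(self) -> np.ndarray:
        order = _PARAM_ORDER[self.name]
        return np.array([order.index(k) for k in self.noisy_params], dtype=np.int64)


_PARAM_ORDER = {
    "morris_lecar": (
        "C", "g_L", "g_Ca", "g_K", "V_L", "V_Ca", "V_K", "V1", "V2", "V3", "V4", "phi",
    ),
    "fhn": ("a", "gamma", "eps"),
    "fhn3d": ("a", "gamma", "eps", "mu", "c", "b"),
    "wang": ("C", "g_L", "g_Na", "g_K", "E_L", "E_Na", "E_K", "phi"),
}

# Morris–Lecar in the class-I regime: a SNIC bifurcation sits inside
# 𝓘 = [20, 60], below the midpoint, so mid-interval currents spike and
# currents below the interval are quiescent.
_ML_PARAMS = {
    "C": 20.0, "g_L": 2.0, "g_Ca": 4.4, "g_K": 8.0,
    "V_L": -60.0, "V_Ca": 120.0, "V_K": -84.0,
    "V1": -1.2, "V2": 18.0, "V3": 12.0, "V4": 17.4, "phi": 1.0 / 15.0,
}

# FitzHugh–Nagumo with the cubic written as v(v-a)(1-v); gamma sets the slope
# of the linear recovery nullcline.  Onset of repetitive spiking ~0.072.
_FHN_PARAMS = {"a": 0.1, "gamma": 0.7, "eps": 0.02}

# FHN–Rinzel: adds dy/dt = mu (c - b v - y); the slow current y shifts the
# excitability on a ~1 s timescale and moves the spiking onset into
# 𝓘 = [0.05, 0.07].
_FHN3D_PARAMS = {"a": 0.1, "gamma": 0.7, "eps": 0.02, "mu": 0.001, "c": 0.034, "b": 0.02}

# Pyramidal-type (v, h, n) model with instantaneous m = m_inf(v); rheobase
# ~0.16 µA/cm², inside 𝓘 = [-3, 3].
_WANG_PARAMS = {
    "C": 1.0, "g_L": 0.1, "g_Na": 35.0, "g_K": 9.0,
    "E_L": -65.0, "E_Na": 55.0, "E_K": -90.0, "phi": 5.0,
}

_SPECS = {
    "morris_lecar": dict(
        state_names=("v", "w"), params=_ML_PARAMS, dt=0.05,
        current_interval=(20.0, 60.0), noisy_params=("g_L", "g_K"),
        training_duration_s=2500.0,
    ),
    "fhn": dict(
        state_names=("v", "w"), params=_FHN_PARAMS, dt=0.05,
        current_interval=(0.07, 0.09), noisy_params=("a", "gamma"),
        training_duration_s=2500.0,
    ),
    "fhn3d": dict(
        state_names=("v", "w", "y"), params=_FHN3D_PARAMS, dt=0.05,
        current_interval=(0.05, 0.07), noisy_params=("a", "gamma"),
        training_duration_s=375.0,
    ),
    "wang": dict(
        state_names=("v", "h", "n"), params=_WANG_PARAMS, dt=0.005,
        current_interval=(-3.0, 3.0), noisy_params=("g_L", "g_K"),
        training_duration_s=230.0,
    ),
}


def make_model(name: str) -> ModelSpec:
    """Return the fully populated :class:`ModelSpec` for a model name."""
    if name not in _SPECS:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        )
    return ModelSpec(name=name, **_SPECS[name])


def perturb_parameters(model: ModelSpec, xi_bar: float, seed=None) -> ModelSpec:
    """Variant whose noisy parameters get per-step multiplicative noise.

    During integration each noisy parameter ``kappa`` is replaced at every
    step by ``kappa (1 + xi)`` with ``xi ~ U[-xi_bar, xi_bar]`` freshly drawn;
    ``xi_bar = 0`` reproduces the unperturbed trajectory bit for bit.
    """
    if xi_bar < 0:
        raise ValueError("xi_bar must be non-negative")
    return replace(model, xi_bar=float(xi_bar), noise_seed=seed)


def draw_parameter_noise(model: ModelSpec, n_steps: int) -> np.ndarray:
    """Per-step relative deviations ``xi`` used during a noisy integration.

    Shape ``(n_steps, len(noisy_params))``; the integrator consumes exactly
    this array, so the realized multipliers are ``1 + xi``.
    """
    rng = np.random.default_rng(model.noise_seed)
    return rng.uniform(-model.xi_bar, model.xi_bar, size=(n_steps, len(model.noisy_params)))


def rhs(model: ModelSpec, state, i_app: float) -> np.ndarray:
    """Time derivative of the state at ``(state, i_app)``; a pure function."""
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_state,):
        raise ValueError(f"state must have {model.n_state} entries")
    if not (np.all(np.isfinite(state)) and np.isfinite(i_app)):
        raise ValueError("non-finite state or current")
    out = np.empty(model.n_state)
    _kernels.rhs_into(
        _CODES[model.name], state, float(i_app), model.param_vector(), out
    )
    return out


@dataclass
class Trajectory:
    """Uniformly sampled simulation output: states and the driving current."""

    t: np.ndarray
    states: np.ndarray
    i_app: np.ndarray
    dt: float
    model_name: str
    seed: int | None = None
    params: dict = field(default_factory=dict)
    state_names: tuple = ()

    def __post_init__(self):
        if not (len(self.t) == self.states.shape[0] == len(self.i_app)):
            raise ValueError("t, states and i_app must have equal length")

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 0]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=self.t)
            f.create_dataset("states", data=self.states)
            f.create_dataset("i_app", data=self.i_app)
            f.attrs["model_name"] = self.model_name
            f.attrs["dt"] = self.dt
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["params"] = json.dumps(self.params)
            f.attrs["state_names"] = json.dumps(list(self.state_names))

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            return cls(
                t=f["t"][:],
                states=f["states"][:],
                i_app=f["i_app"][:],
                dt=float(f.attrs["dt"]),
                model_name=str(f.attrs["model_name"]),
                seed=None if seed < 0 else seed,
                params=json.loads(f.attrs["params"]),
                state_names=tuple(json.loads(f.attrs.get("state_names", "[]"))),
            )

    def to_csv(self, path) -> None:
        header = "t," + ",".join(f"state_{i}" for i in range(self.states.shape[1]))
        data = np.column_stack([self.t, self.states, self.i_app])
        np.savetxt(path, data, delimiter=",", header=header + ",i_app", comments="")


def integrate_euler(
    model: ModelSpec,
    i_app_trace,
    x0,
    divergence_bound: float = 1e6,
) -> Trajectory:
    """Explicit Euler on the model's dt grid, driven sample-by-sample.

    ``states[m] = states[m-1] + dt * rhs(states[m-1], i_app[m-1])`` with
    ``states[0] = x0``; output length equals ``len(i_app_trace)``.  Raises on
    divergence (any state magnitude exceeding ``divergence_bound``), naming
    the offending step.
    """
    i_app_trace = np.ascontiguousarray(i_app_trace, dtype=float)
    x0 = np.ascontiguousarray(x0, dtype=float)
    if x0.shape != (model.n_state,):
        raise ValueError(f"x0 must have {model.n_state} entries")
    n = i_app_trace.shape[0]
    states = np.empty((n, model.n_state))
    if model.xi_bar > 0:
        noise = draw_parameter_noise(model, max(n - 1, 0))
        noisy_idx = model.noisy_indices()
    else:
        noise = np.empty((0, 0))
        noisy_idx = np.empty(0, dtype=np.int64)
    bad = _kernels.euler_loop(
        _CODES[model.name],
        model.param_vector(),
        x0,
        i_app_trace,
        model.dt,
        noise,
        noisy_idx,
        divergence_bound,
        states,
    )
    if bad >= 0:
        raise FloatingPointError(
            f"integration of {model.name} diverged at step {int(bad)} "
            f"(|state| > {divergence_bound:g})"
        )
    return Trajectory(
        t=np.arange(n) * model.dt,
        states=states,
        i_app=i_app_trace,
        dt=model.dt,
        model_name=model.name,
        seed=model.noise_seed,
        params=dict(model.params),
        state_names=model.state_names,
    )


_DEFAULT_X0 = {
    "morris_lecar": np.array([-50.0, 0.05]),
    "fhn": np.array([0.0, 0.0]),
    "fhn3d": np.array([0.0, 0.0, 0.0]),
    "wang": np.array([-64.0, 0.8, 0.1]),
}


def resting_state(model: ModelSpec, i_app: float | None = None, settle_ms: float = 500.0):
    """Near-equilibrium state after a settling run at constant current.

    Defaults to the lower end of the model's physiological interval, which is
    quiescent for every model, so transients are removed before experiments.
    """
    if i_app is None:
        i_app = model.current_interval[0]
    n = int(round(settle_ms / model.dt)) + 1
    clean = replace(model, xi_bar=0.0, noise_seed=None)
    traj = integrate_euler(clean, np.full(n, float(i_app)), _DEFAULT_X0[model.name])
    return traj.states[-1].copy()
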