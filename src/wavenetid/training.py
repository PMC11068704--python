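"""One-step datasets and ridge-regularized least-squares wavenet training.

The wavenet is linear in its weights: with design matrix ``G`` (one row of
frame-function activations per integration step, one column per wavelon),
training solves the regularized normal equations

    (G^T G + gamma I) sigma = G^T y,       gamma = mu * lambda_max(G^T G),

once per output variable, all outputs sharing the same ``G``.  ``G`` is never
materialized in full: ``A = G^T G`` and ``B = G^T Y`` are accumulated over
contiguous row chunks, so memory is bounded by the chunk size and ``J^2``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.linalg import blas as _blas

from .frame import FrameSpec, build_design_matrix, count_wavelons, normalization_from_data
from .neuron_models import Trajectory

__all__ = [
    "Dataset",
    "TrainingConfig",
    "WavenetModel",
    "build_dataset",
    "fit",
    "design_matrix_elements",
    "DEFAULT_MU",
]

DEFAULT_MU = 2e-16


@dataclass
class Dataset:
    """Supervised one-step pairs ``X -> Y`` extracted from a trajectory."""

    X: np.ndarray
    Y: np.ndarray
    paradigm: str
    n_lags: int
    input_names: tuple
    output_names: tuple
    dt: float

    def __post_init__(self):
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.paradigm not in ("I", "II"):
            raise ValueError("paradigm must be 'I' or 'II'")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.X.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.Y.shape[1]


def build_dataset(traj: Trajectory, paradigm: str = "I", n_lags: int = 1) -> Dataset:
    """Assemble the one-step regression problem from a simulated trajectory.

    Paradigm I feeds every state variable plus the current:
    row m = (states[m-1], i_app[m-1]) -> states[m].  Paradigm II feeds only a
    voltage history: row m = (v[m-1], ..., v[m-n_lags], i_app[m-1]) -> v[m],
    where ``n_lags`` counts the voltage samples per row; rows without enough
    history are dropped.
    """
    s = traj.states
    if paradigm == "I":
        if s.shape[0] < 2:
            raise ValueError("trajectory too short for a one-step dataset")
        X = np.column_stack([s[:-1], traj.i_app[:-1]])
        Y = s[1:].copy()
        names = tuple(traj.state_names) or tuple(f"x{i}" for i in range(s.shape[1]))
        return Dataset(
            X, Y, "I", 0, names + ("i_app",), names, traj.dt
        )
    if paradigm != "II":
        raise ValueError("paradigm must be 'I' or 'II'")
    if n_lags < 1:
        raise ValueError("Paradigm II needs n_lags >= 1 voltage samples")
    v = s[:, 0]
    if s.shape[0] < n_lags + 1:
        raise ValueError("trajectory too short for the requested lags")
    cols = [v[n_lags - 1 - q : len(v) - 1 - q] for q in range(n_lags)]
    cols.append(traj.i_app[n_lags - 1 : -1])
    X = np.column_stack(cols)
    Y = v[n_lags:, None].copy()
    in_names = tuple(f"v_lag{q}" for q in range(n_lags)) + ("i_app",)
    return Dataset(X, Y, "II", n_lags, in_names, ("v",), traj.dt)


@dataclass(frozen=True)
class TrainingConfig:
    """Regularizer multiplier and the chunking of the normal equations."""

    mu: float = DEFAULT_MU
    chunk_rows: int = 8192
    seed: int | None = None

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.chunk_rows < 1:
            raise ValueError("chunk_rows must be >= 1")


@dataclass
class WavenetModel:
    """A fitted wavenet: frame + one weight column per output variable."""

    frame: FrameSpec
    weights: np.ndarray  # (J, N_O)
    gamma: float
    paradigm: str
    n_lags: int
    output_names: tuple
    metadata: dict = field(default_factory=dict)
    training_mse: np.ndarray | None = None

    def __post_init__(self):
        if self.weights.shape[0] != count_wavelons(self.frame):
            raise ValueError("weight rows must equal the frame's wavelon count")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[1]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("weights", data=self.weights)
            if self.training_mse is not None:
                f.create_dataset("training_mse", data=self.training_mse)
            f.attrs["frame"] = self.frame.to_json()
            f.attrs["gamma"] = self.gamma
            f.attrs["paradigm"] = self.paradigm
            f.attrs["n_lags"] = self.n_lags
            f.attrs["output_names"] = json.dumps(list(self.output_names))
            f.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def load(cls, path) -> "WavenetModel":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                frame=FrameSpec.from_json(f.attrs["frame"]),
                weights=f["weights"][:],
                gamma=float(f.attrs["gamma"]),
                paradigm=str(f.attrs["paradigm"]),
                n_lags=int(f.attrs["n_lags"]),
                output_names=tuple(json.loads(f.attrs["output_names"])),
                metadata=json.loads(f.attrs["metadata"]),
                training_mse=f["training_mse"][:] if "training_mse" in f else None,
            )


def _accumulate_normal_equations(spec, X, Y, chunk_rows, warn):
    J = count_wavelons(spec)
    n_out = Y.shape[1]
    A = np.zeros((J, J), order="F")
    B = np.zeros((J, n_out))
    yty = np.zeros(n_out)
    for start in range(0, X.shape[0], chunk_rows):
        sl = slice(start, min(start + chunk_rows, X.shape[0]))
        G = build_design_matrix(spec, X, rows=sl, warn=warn)
        # rank-k update of the upper triangle: A += G^T G
        A = _blas.dsyrk(1.0, G, trans=1, beta=1.0, c=A, overwrite_c=1, lower=0)
        B += G.T @ Y[sl]
        yty += np.einsum("ij,ij->j", Y[sl], Y[sl])
        warn = False  # one warning is enough
    A = np.triu(A) + np.triu(A, 1).T
    return A, B, yty


def fit(
    frame: FrameSpec,
    data: Dataset,
    cfg: TrainingConfig | None = None,
    metadata: dict | None = None,
) -> WavenetModel:
    """Train the wavenet by chunked, ridge-regularized normal equations.

    If the frame carries no normalization bounds they are fixed here from the
    training inputs (range expanded by 5% per side).  The largest eigenvalue
    of ``A = G^T G`` sets ``gamma = mu * lambda_max``; the symmetric
    positive-definite system is solved by Cholesky factorization, with a
    symmetric-indefinite fallback when dead (never-activated) wavelons make
    ``A`` numerically singular.
    """
    cfg = cfg or TrainingConfig()
    if data.n_inputs != frame.n_inputs:
        raise ValueError(
            f"dataset has {data.n_inputs} inputs but frame expects {frame.n_inputs}"
        )
    if not (np.all(np.isfinite(data.X)) and np.all(np.isfinite(data.Y))):
        raise ValueError("training data must be finite")
    if frame.normalization is None:
        frame = frame.with_normalization(normalization_from_data(data.X))
    A, B, yty = _accumulate_normal_equations(
        frame, data.X, data.Y, cfg.chunk_rows, warn=True
    )
    J = A.shape[0]
    lam_max = float(
        scipy.linalg.eigh(A, eigvals_only=True, subset_by_index=[J - 1, J - 1])[0]
    )
    gamma = cfg.mu * lam_max
    M = A + gamma * np.eye(J)
    try:
        c, low = scipy.linalg.cho_factor(M)
        sigma = scipy.linalg.cho_solve((c, low), B)
    except np.linalg.LinAlgError:
        if cfg.mu == 0:
            raise np.linalg.LinAlgError(
                "normal equations are singular with gamma=0; set mu > 0"
            )
        warnings.warn(
            "Cholesky factorization failed; falling back to a symmetric solver",
            stacklevel=2,
        )
        sigma = scipy.linalg.lstsq(M, B, lapack_driver="gelsd")[0]
    n_e = data.n_rows
    mse = (yty - 2.0 * np.einsum("jo,jo->o", sigma, B)
           + np.einsum("jo,jk,ko->o", sigma, A, sigma)) / n_e
    mse = np.maximum(mse, 0.0)
    meta = dict(metadata or {})
    meta.setdefault("n_rows", int(n_e))
    meta.setdefault("mu", cfg.mu)
    return WavenetModel(
        frame=frame,
        weights=sigma,
        gamma=gamma,
        paradigm=data.paradigm,
        n_lags=data.n_lags,
        output_names=data.output_names,
        metadata=meta,
        training_mse=mse,
    )


def design_matrix_elements(n_segments: int, steps_per_segment: int, spec: FrameSpec) -> int:
    """Element count of the full design matrix: rows x wavelons.

    Rows are integration steps: ``n_segments * steps_per_segment``; columns
    are the frame's wavelons.
    """
    return n_segments * steps_per_segment * count_wavelons(spec)
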