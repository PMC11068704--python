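"""Multiresolution wavelet frame used as the wavenet's activation-function bank.

The frame is built from a compactly supported spline scaling function
:math:`\\phi` satisfying the two-scale refinement equation
:math:`\\phi(x) = \\sum_n p_n \\phi(2x - n)` with :math:`\\sum_n p_n = 2`.
Three ingredients make up the one-dimensional family on the unit interval:

* ``N_S`` *displaced scaling functions* :math:`\\phi_k`, rescaled copies of
  :math:`\\phi` whose centres :math:`1 - k/(N_S-1)` sweep the domain so that
  approximation quality is equalised near the boundaries;
* the *wavelets* :math:`\\psi^{(k)}_{r,n}(x) = 2^{r/2}\\psi_k(2^r x - n)`
  derived from each displaced family's mother wavelet
  :math:`\\psi_k(x) = \\sum_n (-1)^n p_n \\phi_k(2x - n)`;
* the *identity* of selected input channels (linear bypass terms).

Multi-input frames are tensor products of per-input choices, level by level,
always excluding the all-scaling product at wavelet levels.  All frame
functions are restricted to :math:`\\Omega = [0,1]^{N_I}` and vanish outside.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels

__all__ = [
    "ScalingFamily",
    "FrameSpec",
    "WavelonIndex",
    "get_family",
    "eval_scaling",
    "eval_displaced_scaling",
    "eval_mother_wavelet",
    "eval_wavelet",
    "enumerate_frame",
    "count_wavelons",
    "normalize_inputs",
    "normalization_from_data",
    "build_design_matrix",
    "iter_design_chunks",
]


@dataclass(frozen=True)
class ScalingFamily:
    """A compactly supported spline scaling function.

    Attributes
    ----------
    name:
        ``"quadratic_spline"`` or ``"bicubic_spline"``.
    support_length:
        Length ``d`` of the natural support ``[0, d]``.
    interscale_coeffs:
        Refinement coefficients ``p_n`` (sum to 2).
    """

    name: str
    support_length: int
    interscale_coeffs: tuple

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.interscale_coeffs, dtype=float)

    def phi_natural(self, u):
        """Scaling function on its natural support ``[0, d]``; 0 elsewhere."""
        u = np.asarray(u, dtype=float)
        if self.name == "quadratic_spline":
            return _quadratic_spline(u)
        return _cubic_bspline(u)

    def psi_natural(self, u):
        """Mother wavelet on ``[0, d]`` built with alternating-sign coefficients."""
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        for n, pn in enumerate(self.p):
            out += ((-1) ** n) * pn * self.phi_natural(2.0 * u - n)
        return out


def _quadratic_spline(u: np.ndarray) -> np.ndarray:
    # piecewise: u^2/2 ; -u^2+3u-3/2 ; u^2/2-3u+9/2 on [0,1),[1,2),[2,3]
    out = np.zeros_like(u)
    m = (u >= 0.0) & (u < 1.0)
    out[m] = 0.5 * u[m] * u[m]
    m = (u >= 1.0) & (u < 2.0)
    out[m] = -u[m] * u[m] + 3.0 * u[m] - 1.5
    m = (u >= 2.0) & (u <= 3.0)
    out[m] = 0.5 * u[m] * u[m] - 3.0 * u[m] + 4.5
    return out


def _cubic_bspline(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    m = (u >= 0.0) & (u < 1.0)
    out[m] = u[m] ** 3 / 6.0
    m = (u >= 1.0) & (u < 2.0)
    out[m] = (-3.0 * u[m] ** 3 + 12.0 * u[m] ** 2 - 12.0 * u[m] + 4.0) / 6.0
    m = (u >= 2.0) & (u < 3.0)
    out[m] = (3.0 * u[m] ** 3 - 24.0 * u[m] ** 2 + 60.0 * u[m] - 44.0) / 6.0
    m = (u >= 3.0) & (u <= 4.0)
    out[m] = (4.0 - u[m]) ** 3 / 6.0
    return out


_FAMILIES = {
    "quadratic_spline": ScalingFamily(
        "quadratic_spline", 3, (0.25, 0.75, 0.75, 0.25)
    ),
    # the bicubic spline is the cubic B-spline, the next order on the same
    # ladder as the quadratic one: support [0,4], p_n = 2^{-3} binom(4,n)
    "bicubic_spline": ScalingFamily(
        "bicubic_spline", 4, (0.125, 0.5, 0.75, 0.5, 0.125)
    ),
}


def get_family(name: str) -> ScalingFamily:
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown scaling family {name!r}; valid: {sorted(_FAMILIES)}"
        ) from None


def _displacement(k: int, n_superpositions: int) -> float:
    """Offset added to x so that phi_k is centred at 1 - k/(N_S-1)."""
    if n_superpositions == 1:
        return 0.0  # degenerate: single, undisplaced function centred at 1/2
    return k / (n_superpositions - 1) - 0.5


def eval_scaling(family: ScalingFamily, x) -> np.ndarray:
    """Support-rescaled scaling function on [0,1]; exactly 0 outside."""
    x = np.asarray(x, dtype=float)
    d = family.support_length
    out = family.phi_natural(d * x)
    out[(x < 0.0) | (x > 1.0)] = 0.0
    return out


def eval_displaced_scaling(family: ScalingFamily, k: int, n_superpositions: int, x):
    """Displaced scaling function ``phi_k`` with centre ``1 - k/(N_S-1)``."""
    if not 0 <= k <= n_superpositions - 1:
        raise ValueError(f"displacement index k={k} out of range for N_S={n_superpositions}")
    x = np.asarray(x, dtype=float)
    out = eval_scaling(family, x + _displacement(k, n_superpositions))
    out[(x < 0.0) | (x > 1.0)] = 0.0
    return out


def eval_mother_wavelet(family: ScalingFamily, k: int, n_superpositions: int, x):
    """Displaced mother wavelet ``psi_k`` on [0,1]; 0 outside."""
    if not 0 <= k <= n_superpositions - 1:
        raise ValueError(f"displacement index k={k} out of range for N_S={n_superpositions}")
    x = np.asarray(x, dtype=float)
    d = family.support_length
    u = x + _displacement(k, n_superpositions)
    out = family.psi_natural(d * u)
    out[(x < 0.0) | (x > 1.0)] = 0.0
    return out


def eval_wavelet(family: ScalingFamily, k: int, r: int, n: int, n_superpositions: int, x):
    """Wavelet ``psi^(k)_{r,n}(x) = 2^{r/2} psi_k(2^r x - n)``; 0 outside [0,1]."""
    if r < 0:
        raise ValueError(f"resolution level r={r} must be >= 0")
    if not 0 <= n <= 2**r - 1:
        raise ValueError(f"translation index n={n} out of range for r={r}")
    x = np.asarray(x, dtype=float)
    out = 2.0 ** (r / 2.0) * eval_mother_wavelet(
        family, k, n_superpositions, (2.0**r) * x - n
    )
    out[(x < 0.0) | (x > 1.0)] = 0.0
    return out


# ---------------------------------------------------------------------------
# frame specification and enumeration


@dataclass(frozen=True)
class WavelonIndex:
    """One frame member: identity of an input, or a tensor product of selectors.

    ``selectors`` is ``None`` for identity wavelons; otherwise a tuple with one
    entry per input: ``("scaling", k)`` or ``("wavelet", k, r, n)``.
    """

    kind: str  # "identity" or "product"
    input_index: int = -1  # identity wavelons only
    level: int = -1  # -1 = scaling level, r >= 0 = wavelet level
    selectors: tuple | None = None


@dataclass(frozen=True)
class FrameSpec:
    """Full description of a multi-input wavelet frame.

    Parameters
    ----------
    n_inputs:
        Input dimension ``N_I``.
    n_superpositions:
        ``N_S`` displaced scaling functions per input.
    n_levels:
        ``N_R`` wavelet resolution levels (``r = 0..N_R-1``); ``0`` keeps the
        scaling level only.
    family:
        Scaling-family name.
    identity_inputs:
        0-based indices of inputs carrying identity wavelons.
    normalization:
        Per-input affine bounds ``((lo, hi), ...)`` mapping each raw input
        channel onto [0,1], or ``None`` if not yet fixed.
    """

    n_inputs: int
    n_superpositions: int
    n_levels: int
    family: str = "quadratic_spline"
    identity_inputs: tuple = ()
    normalization: tuple | None = None

    def __post_init__(self):
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.n_superpositions < 1:
            raise ValueError("n_superpositions must be >= 1")
        if self.n_levels < 0:
            raise ValueError("n_levels must be >= 0")
        ids = tuple(self.identity_inputs)
        if any(not 0 <= i < self.n_inputs for i in ids):
            raise ValueError("identity_inputs must be valid 0-based input indices")
        if len(set(ids)) != len(ids):
            raise ValueError("identity_inputs must be unique")
        get_family(self.family)
        if self.normalization is not None:
            norm = tuple((float(lo), float(hi)) for lo, hi in self.normalization)
            if len(norm) != self.n_inputs:
                raise ValueError("normalization needs one (lo, hi) pair per input")
            if any(hi <= lo for lo, hi in norm):
                raise ValueError("normalization intervals must be non-degenerate")
            object.__setattr__(self, "normalization", norm)
        object.__setattr__(self, "identity_inputs", ids)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "n_inputs": self.n_inputs,
                "n_superpositions": self.n_superpositions,
                "n_levels": self.n_levels,
                "family": self.family,
                "identity_inputs": list(self.identity_inputs),
                "normalization": None
                if self.normalization is None
                else [list(b) for b in self.normalization],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FrameSpec":
        d = json.loads(text)
        norm = d.get("normalization")
        return cls(
            n_inputs=d["n_inputs"],
            n_superpositions=d["n_superpositions"],
            n_levels=d["n_levels"],
            family=d["family"],
            identity_inputs=tuple(d.get("identity_inputs", ())),
            normalization=None if norm is None else tuple(tuple(b) for b in norm),
        )

    def with_normalization(self, bounds) -> "FrameSpec":
        return replace(self, normalization=tuple(tuple(b) for b in bounds))


def _level_selectors(spec: FrameSpec, r: int) -> list:
    """Per-input selector list at wavelet level r: scalings then wavelets."""
    sel = [("scaling", k) for k in range(spec.n_superpositions)]
    sel += [
        ("wavelet", k, r, n)
        for k in range(spec.n_superpositions)
        for n in range(2**r)
    ]
    return sel


def enumerate_frame(spec: FrameSpec) -> list:
    """Deterministic, duplicate-free wavelon ordering.

    Identities first, then the scaling level, then wavelet levels in
    increasing ``r``; within a level, lexicographic over the per-input
    selector multi-index.  At each wavelet level the all-scaling product
    (already present in the scaling level) is excluded.
    """
    out = [WavelonIndex("identity", input_index=i) for i in spec.identity_inputs]
    scal = [("scaling", k) for k in range(spec.n_superpositions)]
    for combo in itertools.product(scal, repeat=spec.n_inputs):
        out.append(WavelonIndex("product", level=-1, selectors=combo))
    for r in range(spec.n_levels):
        sel = _level_selectors(spec, r)
        for combo in itertools.product(sel, repeat=spec.n_inputs):
            if all(s[0] == "scaling" for s in combo):
                continue
            out.append(WavelonIndex("product", level=r, selectors=combo))
    return out


def count_wavelons(spec: FrameSpec) -> int:
    """Closed-form size of the frame.

    ``|identities| + N_S^{N_I} + sum_r N_S^{N_I} ((1 + 2^r)^{N_I} - 1)``,
    since level ``r`` offers ``N_S`` scalings plus ``N_S 2^r`` wavelets per
    input, minus the all-scaling product.
    """
    ns, ni = spec.n_superpositions, spec.n_inputs
    total = len(spec.identity_inputs) + ns**ni
    for r in range(spec.n_levels):
        total += ns**ni * ((1 + 2**r) ** ni - 1)
    return total


# ---------------------------------------------------------------------------
# vectorized design-matrix construction


def normalization_from_data(X: np.ndarray, margin: float = 0.05) -> tuple:
    """Per-input (lo, hi) bounds: data range expanded by ``margin`` per side."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return tuple(
        (float(l - margin * s), float(h + margin * s))
        for l, h, s in zip(lo, hi, span)
    )


def normalize_inputs(spec: FrameSpec, X: np.ndarray, warn: bool = True) -> np.ndarray:
    """Affine map of raw inputs onto [0,1]^{N_I} using the frame's bounds."""
    if spec.normalization is None:
        raise ValueError("FrameSpec has no normalization bounds")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns, frame expects {spec.n_inputs}"
        )
    bounds = np.asarray(spec.normalization)
    Xn = (X - bounds[:, 0]) / (bounds[:, 1] - bounds[:, 0])
    if warn:
        n_out = int(np.count_nonzero((Xn < 0.0).any(axis=1) | (Xn > 1.0).any(axis=1)))
        if n_out:
            warnings.warn(
                f"{n_out}/{Xn.shape[0]} rows fall outside the normalization box; "
                "frame activations are zero there (identity terms excepted)",
                stacklevel=2,
            )
    return Xn


def _atom_index(spec: FrameSpec, selector) -> int:
    """Flat per-input atom index: scalings 0..N_S-1, then wavelets by (r, k, n)."""
    ns = spec.n_superpositions
    if selector[0] == "scaling":
        return selector[1]
    _, k, r, n = selector
    return ns + ns * (2**r - 1) + k * 2**r + n


def _selector_matrix(spec: FrameSpec):
    """(identity input list, J_frame x N_I int array of per-input atom indices)."""
    wavelons = enumerate_frame(spec)
    identity = [w.input_index for w in wavelons if w.kind == "identity"]
    prods = [w for w in wavelons if w.kind == "product"]
    sel = np.empty((len(prods), spec.n_inputs), dtype=np.int64)
    for j, w in enumerate(prods):
        for i, s in enumerate(w.selectors):
            sel[j, i] = _atom_index(spec, s)
    return identity, sel


def _atom_matrix(spec: FrameSpec, xcol: np.ndarray) -> np.ndarray:
    """All 1-D atoms (scalings + wavelets of every level) on one input column."""
    fam = get_family(spec.family)
    ns = spec.n_superpositions
    n_atoms = ns + ns * (2**spec.n_levels - 1)
    A = np.empty((xcol.shape[0], n_atoms))
    for k in range(ns):
        A[:, k] = eval_displaced_scaling(fam, k, ns, xcol)
    col = ns
    for r in range(spec.n_levels):
        for k in range(ns):
            for n in range(2**r):
                A[:, col] = eval_wavelet(fam, k, r, n, ns, xcol)
                col += 1
    return A


def build_design_matrix(
    spec: FrameSpec,
    X: np.ndarray,
    rows: slice | None = None,
    warn: bool = True,
) -> np.ndarray:
    """Evaluate every frame function on (a contiguous row block of) ``X``.

    Columns follow :func:`enumerate_frame` order.  Identity columns equal the
    normalized input channel; all other columns are tensor products of 1-D
    atoms.  Row blocks are independent, so chunked construction is bit
    identical to monolithic construction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if rows is not None:
        X = X[rows]
    Xn = normalize_inputs(spec, X, warn=warn)
    identity, sel = _selector_matrix(spec)
    n = Xn.shape[0]
    J = len(identity) + sel.shape[0]
    # build G^T row-contiguously; the transposed view is Fortran-ordered,
    # which is what the BLAS rank-k update in training wants
    GT = np.empty((J, n))
    for c, i in enumerate(identity):
        GT[c] = Xn[:, i]
    atoms = np.stack(
        [np.ascontiguousarray(_atom_matrix(spec, Xn[:, i]).T) for i in range(spec.n_inputs)]
    )
    off = len(identity)
    _kernels.tensor_products(atoms, sel, GT[off:])
    return GT.T


def iter_design_chunks(spec: FrameSpec, X: np.ndarray, chunk_rows: int, warn: bool = True):
    """Yield ``(row_slice, G_block)`` pairs over contiguous row blocks."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    for start in range(0, X.shape[0], chunk_rows):
        sl = slice(start, min(start + chunk_rows, X.shape[0]))
        yield sl, build_design_matrix(spec, X, rows=sl, warn=warn)
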