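"""DICS spatial filters and source power mapping.

DICS is a linearly constrained minimum-variance beamformer in the
frequency domain.  The sensor CSD matrix C is regularized by diagonal
loading,

    lambda = alpha * trace(C) / N_s,      Chat^-1 = pinv(C + lambda I),

leadfields are norm-normalized to counter the depth bias, and for each
dipole (location + orientation) a filter

    A(r) = Lhat(r)^T Chat^-1 / (Lhat(r)^T Chat^-1 Lhat(r))

is computed individually, so the denominator is a scalar and no
rank-deficient source-level matrix needs inverting.  The source power
is P(r) = A C A^H, summarized either by its largest singular value
("max-power" orientation) or by its trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .csd import CSDMatrix
from .geometry import ForwardModel

__all__ = [
    "RegularizedInverse",
    "SpatialFilter",
    "PowerMap",
    "regularize_csd_inverse",
    "normalize_leadfield",
    "make_dics_filter",
    "apply_dics_power",
    "summarize_power",
    "power_map",
    "power_contrast",
]


@dataclass(frozen=True)
class RegularizedInverse:
    alpha: float
    lam: float  # diagonal loading, units of the CSD
    inv_matrix: np.ndarray  # N_s x N_s complex, Hermitian


@dataclass(frozen=True)
class SpatialFilter:
    weights: np.ndarray  # length-N_s complex
    source_id: int = -1
    orientation_index: int = 0


@dataclass(frozen=True)
class PowerMap:
    values: np.ndarray  # one non-negative scalar per source
    summary_mode: str
    vertex_ids: np.ndarray
    band: tuple = ()
    window: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "vertex_ids", np.asarray(self.vertex_ids, dtype=int))


def regularize_csd_inverse(csd: CSDMatrix, alpha: float = 0.05) -> RegularizedInverse:
    """Diagonally loaded Moore-Penrose pseudoinverse of the CSD.

    Typical ``alpha`` values are 0.01-0.1 (relative to the mean sensor
    power).  With alpha = 0 and a singular CSD the pseudoinverse is
    still returned, with a rank-deficiency warning.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    c = csd.matrix
    n = csd.n_sensors
    lam = alpha * np.trace(c.real) / n
    loaded = c + lam * np.eye(n)
    if alpha == 0 and np.linalg.matrix_rank(loaded) < n:
        warnings.warn("CSD is rank deficient with alpha=0; using pseudoinverse",
                      stacklevel=2)
    inv = np.linalg.pinv(loaded, hermitian=True)
    return RegularizedInverse(alpha=alpha, lam=float(lam), inv_matrix=inv)


def normalize_leadfield(L: np.ndarray) -> np.ndarray:
    """L / ||L||; counters the beamformer's bias toward superficial sources."""
    L = np.asarray(L, dtype=float)
    norm = np.linalg.norm(L)
    if norm == 0:
        raise ValueError("degenerate zero leadfield")
    return L / norm


def make_dics_filter(L_hat: np.ndarray, inv: RegularizedInverse,
                     source_id: int = -1, orientation_index: int = 0) -> SpatialFilter:
    """Per-dipole unit-gain minimum-variance filter A = L^T Cinv / (L^T Cinv L)."""
    num = L_hat @ inv.inv_matrix
    den = num @ L_hat
    if abs(den) < 1e-300:
        raise ValueError("singular filter denominator")
    return SpatialFilter(weights=num / den, source_id=source_id,
                         orientation_index=orientation_index)


def apply_dics_power(filters: list[SpatialFilter], csd: CSDMatrix) -> np.ndarray:
    """P = A C A^H for the dipoles of one source; Hermitian, PSD diagonal."""
    a = np.array([f.weights for f in filters])
    return a @ csd.matrix @ a.conj().T


def summarize_power(P: np.ndarray, mode: str = "max_power") -> float:
    """Scalar source power: largest singular value or real trace of P."""
    P = np.atleast_2d(np.asarray(P))
    if mode == "max_power":
        return float(np.linalg.svd(P, compute_uv=False)[0])
    if mode == "trace":
        return float(np.trace(P).real)
    raise ValueError(f"unknown summary mode {mode!r}")


def power_map(fwd: ForwardModel, csd: CSDMatrix, reg: float = 0.05,
              mode: str = "max_power") -> PowerMap:
    """DICS source power at every source point of ``fwd``.

    Per source: normalize each orientation's leadfield, build the
    per-dipole filters against the shared regularized inverse, form
    P = A C A^H and summarize.
    """
    if fwd.leadfields.shape[2] != csd.n_sensors:
        raise ValueError("forward model and CSD sensor counts differ")
    if mode not in ("max_power", "trace"):
        raise ValueError(f"unknown summary mode {mode!r}")
    inv = regularize_csd_inverse(csd, reg)
    lf = fwd.leadfields
    norms = np.linalg.norm(lf, axis=2, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero leadfield row in forward model")
    l_hat = lf / norms  # (n_src, n_orient, n_sens)
    num = np.einsum("sok,kl->sol", l_hat, inv.inv_matrix)
    den = np.einsum("sol,sol->so", num, l_hat)
    a = num / den[:, :, None]  # per-dipole filters
    p = np.einsum("sok,kl,sml->som", a, csd.matrix, a.conj())
    values = np.array([summarize_power(p[s], mode) for s in range(len(p))])
    return PowerMap(
        values=values, summary_mode=mode,
        vertex_ids=fwd.source_space.vertex_ids,
        band=tuple(csd.frequencies), window=(csd.tmin, csd.tmax),
    )


def power_contrast(p_a: PowerMap, p_b: PowerMap, p_baseline: PowerMap) -> PowerMap:
    """Elementwise (a - b) / baseline, e.g. (condition A - B) / pre-stimulus."""
    for other in (p_b, p_baseline):
        if (not np.array_equal(p_a.vertex_ids, other.vertex_ids)
                or p_a.summary_mode != other.summary_mode):
            raise ValueError("power maps must share source space and mode")
    zero = np.nonzero(p_baseline.values == 0)[0]
    if len(zero):
        raise ZeroDivisionError(
            f"baseline power is zero at vertex {p_a.vertex_ids[zero[0]]}"
        )
    return PowerMap(
        values=(p_a.values - p_b.values) / p_baseline.values,
        summary_mode=p_a.summary_mode, vertex_ids=p_a.vertex_ids,
        band=p_a.band, window=p_a.window,
    )
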