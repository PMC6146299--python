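"""All-to-all canonical coherence between distance-thresholded source pairs.

Because MEG field spread makes nearby sources spuriously coherent, only
pairs farther apart than ``min_dist`` are evaluated.  Each source is a
two-dipole tangential equivalent current dipole (ECD); the leadfield of
an ECD at in-plane angle theta is

    Lhat(r, theta) = sin(theta) Lhat(r_1) + cos(theta) Lhat(r_2).

Canonical coherence between two source points is the maximum, over a
grid of orientation angles at both ends, of

    |Lhat(r1,t1)^T Chat^-1 Lhat(r2,t2)|^2
    -------------------------------------------------------------
    [Lhat(r1,t1)^T Chat^-1 Lhat(r1,t1)] [Lhat(r2,t2)^T Chat^-1 Lhat(r2,t2)]

which by the Cauchy-Schwarz inequality lies in [0, 1] and is invariant
to rescaling either source's leadfield.  The objective is pi-periodic
in each angle, so the grid spans [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np

from .csd import CSDMatrix
from .dics import RegularizedInverse, regularize_csd_inverse
from .geometry import ForwardModel, SourceSpace

__all__ = [
    "ConnectivityPairs",
    "ConnectivityEstimate",
    "all_to_all_connectivity_pairs",
    "sensor_coherence",
    "oriented_leadfield",
    "canonical_coherence",
    "dics_connectivity",
    "connectivity_contrast",
    "connectivity_grand_average",
    "to_common_pair_order",
]


@dataclass(frozen=True)
class ConnectivityPairs:
    """Canonically ordered (i < j, lexicographic) list of vertex-id pairs."""

    pairs: np.ndarray  # (n_pairs, 2) int vertex ids, i < j
    min_dist: float
    positions: dict  # vertex id -> 3D position (common order reference)

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if len(p) and not np.all(p[:, 0] < p[:, 1]):
            raise ValueError("pairs must be canonically ordered i < j")
        if len(np.unique(p, axis=0)) != len(p):
            raise ValueError("duplicate pairs")
        object.__setattr__(self, "pairs", p)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ConnectivityEstimate:
    """Per-pair canonical coherence (or a signed contrast of coherences)."""

    pairs: ConnectivityPairs
    coherence: np.ndarray
    band: tuple = ()
    window: tuple = ()
    condition: str = ""
    n_angles: int = 0
    is_contrast: bool = False

    def __post_init__(self):
        coh = np.asarray(self.coherence, dtype=float)
        if len(coh) != self.pairs.n_pairs:
            raise ValueError("coherence length must match pair count")
        if not self.is_contrast and len(coh) and (
            coh.min() < -1e-9 or coh.max() > 1 + 1e-9
        ):
            raise ValueError("raw coherence must lie in [0, 1]")
        object.__setattr__(self, "coherence", coh)

    def __sub__(self, other: "ConnectivityEstimate") -> "ConnectivityEstimate":
        return connectivity_contrast(self, other)


def all_to_all_connectivity_pairs(
    src: SourceSpace, min_dist: float = 0.04
) -> ConnectivityPairs:
    """Every source pair strictly farther apart than ``min_dist`` (meters).

    Pairs at exactly ``min_dist`` are excluded: points closer than or at
    the threshold are removed from the analysis.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be non-negative")
    vids = src.vertex_ids
    diff = src.points[:, None, :] - src.points[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu, ju = np.triu_indices(src.n_vertices, k=1)
    ok = dist[iu, ju] > min_dist
    raw = np.column_stack([vids[iu[ok]], vids[ju[ok]]])
    lo = np.minimum(raw[:, 0], raw[:, 1])
    hi = np.maximum(raw[:, 0], raw[:, 1])
    pairs = np.column_stack([lo, hi])
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    if len(pairs) == 0:
        warnings.warn("no source pairs beyond min_dist", stacklevel=2)
    return ConnectivityPairs(
        pairs=pairs, min_dist=min_dist,
        positions={int(v): src.points[k] for k, v in enumerate(vids)},
    )


def sensor_coherence(csd: CSDMatrix, i: int, j: int) -> float:
    """Magnitude-squared coherence |C(i,j)|^2 / (C(i,i) C(j,j)) between sensors."""
    c = csd.matrix
    pii, pjj = c[i, i].real, c[j, j].real
    if pii <= 0 or pjj <= 0:
        raise ValueError("degenerate sensor power on the CSD diagonal")
    return float(abs(c[i, j]) ** 2 / (pii * pjj))


def oriented_leadfield(rows: np.ndarray, theta: float) -> np.ndarray:
    """ECD leadfield at in-plane angle theta: sin(theta) row1 + cos(theta) row2."""
    rows = np.asarray(rows)
    return np.sin(theta) * rows[0] + np.cos(theta) * rows[1]


def _angle_grid(n_angles: int) -> np.ndarray:
    return np.arange(n_angles) * np.pi / n_angles


def _pair_matrices(rows_i, rows_j, inv_matrix):
    """2x2 cross (G) and auto (Qi, Qj) quadratic forms through Chat^-1."""
    ti = rows_i @ inv_matrix  # (2, N_s) complex
    g = ti @ rows_j.T
    qi = ti @ rows_i.T
    qj = (rows_j @ inv_matrix) @ rows_j.T
    return g, qi, qj


def _coherence_surface(g, qi, qj, u):
    """Coherence on the angle grid; u is (n_angles, 2) = [sin, cos]."""
    num = np.abs(u @ g @ u.T) ** 2
    den_i = np.einsum("ai,ij,aj->a", u, qi, u).real
    den_j = np.einsum("ai,ij,aj->a", u, qj, u).real
    return num, den_i, den_j


def canonical_coherence(
    rows_i: np.ndarray,
    rows_j: np.ndarray,
    inv: RegularizedInverse,
    n_angles: int = 50,
) -> tuple[float, float, float]:
    """Maximum coherence over the orientation grid for one source pair.

    Parameters are the two sources' normalized tangential leadfield
    rows, each of shape (2, N_s).  Returns (coherence, theta_i, theta_j)
    with ties broken toward the lexicographically smallest angle pair.
    """
    if n_angles < 2:
        raise ValueError("n_angles must be >= 2")
    rows_i = np.asarray(rows_i, dtype=float)
    rows_j = np.asarray(rows_j, dtype=float)
    thetas = _angle_grid(n_angles)
    u = np.column_stack([np.sin(thetas), np.cos(thetas)])
    g, qi, qj = _pair_matrices(rows_i, rows_j, inv.inv_matrix)
    num, den_i, den_j = _coherence_surface(g, qi, qj, u)
    den = den_i[:, None] * den_j[None, :]
    valid = den > 0
    if not valid.any():
        raise ValueError("all oriented leadfields degenerate for this pair")
    coh = np.where(valid, num / np.where(valid, den, 1.0), -np.inf)
    flat = np.argmax(coh)  # argmax scans row-major: lexicographic tie-break
    a, b = np.unravel_index(flat, coh.shape)
    return float(coh[a, b]), float(thetas[a]), float(thetas[b])


def dics_connectivity(
    pairs: ConnectivityPairs,
    fwd_tan: ForwardModel,
    csd: CSDMatrix,
    reg: float = 0.05,
    n_angles: int = 50,
    condition: str = "",
) -> ConnectivityEstimate:
    """Canonical coherence for every pair, sharing one regularized inverse.

    Vectorized over pairs: per source the 2 x N_s normalized leadfield
    is propagated through Chat^-1 once, and the angle-grid maximization
    works on the resulting 2x2 quadratic forms.
    """
    if fwd_tan.n_orient != 2:
        raise ValueError("connectivity requires a tangential forward model")
    if fwd_tan.leadfields.shape[2] != csd.n_sensors:
        raise ValueError("forward model and CSD sensor counts differ")
    inv = regularize_csd_inverse(csd, reg)
    vids = fwd_tan.source_space.vertex_ids
    index_of = {int(v): k for k, v in enumerate(vids)}
    lf = fwd_tan.leadfields
    l_hat = lf / np.linalg.norm(lf, axis=2, keepdims=True)
    t = np.einsum("sok,kl->sol", l_hat, inv.inv_matrix)  # (n_src, 2, N_s)
    q = np.einsum("sol,spl->sop", t, l_hat)  # (n_src, 2, 2) auto forms
    ii = np.array([index_of[int(a)] for a in pairs.pairs[:, 0]])
    jj = np.array([index_of[int(b)] for b in pairs.pairs[:, 1]])
    thetas = _angle_grid(n_angles)
    u = np.column_stack([np.sin(thetas), np.cos(thetas)])
    den_auto = np.einsum("ao,som,am->sa", u, q, u).real  # (n_src, n_angles)
    coh = np.empty(len(ii))
    chunk = max(1, int(2e7) // (n_angles * n_angles))  # bound peak memory
    for lo in range(0, len(ii), chunk):
        sl = slice(lo, lo + chunk)
        g = np.einsum("pol,pml->pom", t[ii[sl]], l_hat[jj[sl]])
        num = np.abs(np.einsum("ao,pom,bm->pab", u, g, u)) ** 2
        den = den_auto[ii[sl]][:, :, None] * den_auto[jj[sl]][:, None, :]
        coh[sl] = (num / den).reshape(g.shape[0], -1).max(axis=1)
    return ConnectivityEstimate(
        pairs=pairs, coherence=np.clip(coh, 0.0, 1.0),
        band=tuple(csd.frequencies), window=(csd.tmin, csd.tmax),
        condition=condition, n_angles=n_angles,
    )


def connectivity_contrast(
    con_a: ConnectivityEstimate, con_b: ConnectivityEstimate
) -> ConnectivityEstimate:
    """Elementwise coherence difference over an identical pair list."""
    if not np.array_equal(con_a.pairs.pairs, con_b.pairs.pairs):
        raise ValueError("connectivity estimates have different pair lists")
    return ConnectivityEstimate(
        pairs=con_a.pairs,
        coherence=con_a.coherence - con_b.coherence,
        band=con_a.band, window=con_a.window,
        condition=f"{con_a.condition}-{con_b.condition}",
        n_angles=con_a.n_angles, is_contrast=True,
    )


def connectivity_grand_average(
    cons: list[ConnectivityEstimate],
) -> ConnectivityEstimate:
    """Mean of per-subject estimates sharing one pair list (sum / len)."""
    first = cons[0]
    for c in cons[1:]:
        if not np.array_equal(c.pairs.pairs, first.pairs.pairs):
            raise ValueError("connectivity estimates have different pair lists")
    mean = np.mean([c.coherence for c in cons], axis=0)
    return replace(first, coherence=mean, condition="grand-average")


def to_common_pair_order(
    con: ConnectivityEstimate, mapping: dict[int, int]
) -> ConnectivityEstimate:
    """Re-express pairs in common vertex ids and re-canonicalize.

    ``mapping`` sends each subject-local vertex id to its common id.
    Pairs are rewritten, stored with the smaller id first, and sorted
    lexicographically; coherence values follow their pairs.
    """
    vals = set(mapping.values())
    if len(vals) != len(mapping):
        raise ValueError("vertex mapping must be a bijection")
    old = con.pairs.pairs
    try:
        remapped = np.array(
            [[mapping[int(a)], mapping[int(b)]] for a, b in old]
        ).reshape(-1, 2)
    except KeyError as e:
        raise ValueError(f"unmapped vertex id {e.args[0]}") from None
    lo = np.minimum(remapped[:, 0], remapped[:, 1])
    hi = np.maximum(remapped[:, 0], remapped[:, 1])
    pairs = np.column_stack([lo, hi])
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    new_positions = {
        mapping[v]: pos for v, pos in con.pairs.positions.items() if v in mapping
    }
    new_pairs = ConnectivityPairs(
        pairs=pairs[order], min_dist=con.pairs.min_dist, positions=new_positions
    )
    return replace(con, pairs=new_pairs, coherence=con.coherence[order])
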