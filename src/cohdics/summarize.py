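"""Degree maps and parcel-level connectivity summaries.

After statistical pruning, the surviving connections are summarized as
a per-vertex *degree map* (number of incident connections) and as a
parcel x parcel matrix counting connections between regions — the data
behind a circular connectogram.  Because vertices and parcels differ in
how many connections they *could* have had after distance thresholding,
both summaries can be corrected for this degree bias by dividing by the
corresponding count in the pre-statistics candidate pair list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2

from .connectivity import ConnectivityEstimate, ConnectivityPairs
from .geometry import SourceSpace

__all__ = [
    "Parcellation",
    "ParcelConnectome",
    "degree_map",
    "parcellate_connectivity",
    "make_synthetic_parcellation",
    "export_connectogram_table",
]


@dataclass(frozen=True)
class Parcellation:
    """Parcel assignment per vertex (common order) with unique parcel names."""

    parcel_of: dict  # vertex id -> parcel index
    names: tuple

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("parcel names must be unique")
        object.__setattr__(self, "names", tuple(self.names))
        bad = [p for p in self.parcel_of.values()
               if not 0 <= p < len(self.names)]
        if bad:
            raise ValueError("parcel index out of range")

    @property
    def n_parcels(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class ParcelConnectome:
    matrix: np.ndarray  # parcel x parcel, symmetric, non-negative
    names: tuple
    weighted: bool  # True when degree-bias corrected

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("parcel matrix must be symmetric")
        if m.min() < 0:
            raise ValueError("parcel matrix must be non-negative")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "names", tuple(self.names))


def _incidence_counts(pairs: np.ndarray, vertex_ids) -> dict:
    counts = {int(v): 0 for v in vertex_ids}
    for a, b in pairs:
        counts[int(a)] += 1
        counts[int(b)] += 1
    return counts


def degree_map(
    con: ConnectivityEstimate,
    vertex_ids,
    weight_by_degree: bool = False,
    possible_pairs: ConnectivityPairs | None = None,
) -> np.ndarray:
    """Connections incident to each vertex, optionally bias-corrected.

    Raw: the count of surviving connections touching the vertex.
    Corrected: that count divided by the number of candidate
    connections touching the vertex in ``possible_pairs`` (0/0 -> 0),
    giving the *fraction* of possible connections that survived.
    """
    vertex_ids = np.asarray(vertex_ids, dtype=int)
    observed = _incidence_counts(con.pairs.pairs, vertex_ids)
    raw = np.array([observed[int(v)] for v in vertex_ids], dtype=float)
    if not weight_by_degree:
        return raw
    if possible_pairs is None:
        raise ValueError("bias correction needs the candidate pair list")
    possible = _incidence_counts(possible_pairs.pairs, vertex_ids)
    denom = np.array([possible[int(v)] for v in vertex_ids], dtype=float)
    if np.any((denom == 0) & (raw > 0)):
        raise ValueError("observed connection at a vertex with no candidates")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def _parcel_matrix(pairs: np.ndarray, parc: Parcellation) -> np.ndarray:
    n = parc.n_parcels
    m = np.zeros((n, n))
    for a, b in pairs:
        try:
            pa, pb = parc.parcel_of[int(a)], parc.parcel_of[int(b)]
        except KeyError as e:
            raise ValueError(f"vertex {e.args[0]} not assigned to a parcel")
        if pa == pb:
            m[pa, pa] += 1  # within-parcel, counted once on the diagonal
        else:
            m[pa, pb] += 1
            m[pb, pa] += 1
    return m


def parcellate_connectivity(
    con: ConnectivityEstimate,
    parc: Parcellation,
    weight_by_degree: bool = False,
    possible_pairs: ConnectivityPairs | None = None,
) -> ParcelConnectome:
    """Parcel x parcel connection counts, optionally bias-corrected.

    Entry (P, Q) counts surviving connections with one endpoint in each
    parcel (within-parcel connections on the diagonal, counted once);
    corrected values divide by the number of candidate connections
    between P and Q, yielding fractions in [0, 1].
    """
    m = _parcel_matrix(con.pairs.pairs, parc)
    if not weight_by_degree:
        return ParcelConnectome(matrix=m, names=parc.names, weighted=False)
    if possible_pairs is None:
        raise ValueError("bias correction needs the candidate pair list")
    denom = _parcel_matrix(possible_pairs.pairs, parc)
    if np.any((denom == 0) & (m > 0)):
        raise ValueError("observed parcel connection with no candidates")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    return ParcelConnectome(matrix=out, names=parc.names, weighted=True)


def make_synthetic_parcellation(
    src: SourceSpace, n_parcels: int, seed: int = 0
) -> Parcellation:
    """Deterministic spatial partition of the source grid into parcels.

    K-means on the source coordinates with a fixed seed; every vertex is
    assigned to exactly one parcel.  Stands in for an anatomical atlas.
    """
    if not 1 <= n_parcels <= src.n_vertices:
        raise ValueError("n_parcels must be in [1, n_vertices]")
    if n_parcels == 1:
        labels = np.zeros(src.n_vertices, dtype=int)
    else:
        _, labels = kmeans2(
            src.points, n_parcels, minit="++", seed=seed, missing="warn"
        )
        # relabel to consecutive indices in case a cluster came up empty
        uniq, labels = np.unique(labels, return_inverse=True)
        n_parcels = len(uniq)
    names = tuple(f"parcel-{k:03d}" for k in range(n_parcels))
    return Parcellation(
        parcel_of={int(v): int(l) for v, l in zip(src.vertex_ids, labels)},
        names=names,
    )


def export_connectogram_table(pc: ParcelConnectome, path=None) -> pd.DataFrame:
    """Long-format (parcel_a, parcel_b, value) table, upper triangle + diagonal."""
    rows = []
    n = len(pc.names)
    for i in range(n):
        for j in range(i, n):
            rows.append((pc.names[i], pc.names[j], pc.matrix[i, j]))
    df = pd.DataFrame(rows, columns=["parcel_a", "parcel_b", "value"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
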