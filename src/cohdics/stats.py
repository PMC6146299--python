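"""Group-level inference on connection-wise condition differences.

For every connection a paired t statistic compares the two conditions
across subjects.  Connections with |t| below ``cluster_threshold`` are
pruned; survivors are grouped into *bundles* — clusters in the
six-dimensional space formed by concatenating the xyz coordinates of a
connection's two endpoints — separately for positive and negative t.
Each bundle's statistic is the sum of its members' |t|.  Significance
is assessed with a max-statistic permutation test: condition labels are
flipped per subject at random, the whole prune-and-cluster pipeline is
re-run, and only the maximum bundle statistic of each permutation
enters the null distribution, which controls the family-wise error
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .connectivity import ConnectivityEstimate

__all__ = [
    "SubjectConnectivitySet",
    "BundleResult",
    "paired_t",
    "threshold_connections",
    "connection_position",
    "cluster_bundles",
    "bundle_t",
    "cluster_permutation_test",
]


@dataclass(frozen=True)
class SubjectConnectivitySet:
    """Per-subject estimates for two conditions over one shared pair list."""

    condition_a: list[ConnectivityEstimate]
    condition_b: list[ConnectivityEstimate]
    subject_ids: tuple = ()

    def __post_init__(self):
        if len(self.condition_a) != len(self.condition_b):
            raise ValueError("conditions must have the same subjects")
        if len(self.condition_a) < 2:
            raise ValueError("group statistics need at least 2 subjects")
        ref = self.condition_a[0].pairs.pairs
        for con in list(self.condition_a) + list(self.condition_b):
            if not np.array_equal(con.pairs.pairs, ref):
                raise ValueError("all estimates must share one pair list "
                                 "in common order")
        if not self.subject_ids:
            object.__setattr__(
                self, "subject_ids",
                tuple(f"sub{i:03d}" for i in range(len(self.condition_a))),
            )

    @property
    def n_subjects(self) -> int:
        return len(self.condition_a)

    @property
    def pairs(self):
        return self.condition_a[0].pairs

    def differences(self) -> np.ndarray:
        """(n_subjects, n_connections) condition differences a - b."""
        a = np.array([c.coherence for c in self.condition_a])
        b = np.array([c.coherence for c in self.condition_b])
        return a - b


@dataclass(frozen=True)
class BundleResult:
    t_values: np.ndarray
    surviving_idx: np.ndarray
    bundles: list  # list of (member connection indices, sign) tuples
    bundle_t: np.ndarray
    null_max: np.ndarray
    p_values: np.ndarray
    significant_idx: np.ndarray
    cluster_threshold: float
    max_spread: float
    n_permutations: int
    alpha: float
    seed: int

    @property
    def significant_bundles(self) -> list:
        return [
            b for b, p in zip(self.bundles, self.p_values) if p <= self.alpha
        ]


def _t_rows(diff: np.ndarray) -> np.ndarray:
    """Vectorized paired t over the subject axis of (n_subjects, n_conn).

    Zero-variance rows give +/-inf for a nonzero mean and 0 for an
    all-zero difference.
    """
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    t[degenerate & (mean > 0)] = np.inf
    t[degenerate & (mean < 0)] = -np.inf
    t[degenerate & (mean == 0)] = 0.0
    return t


def paired_t(values_a, values_b) -> float:
    """Paired t statistic, t = mean(d) / (sd(d)/sqrt(n)), d = a - b."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need >= 2 paired observations")
    return float(_t_rows((a - b)[:, None])[0])


def threshold_connections(t_values, cluster_threshold: float) -> np.ndarray:
    """Ascending indices of connections with |t| >= cluster_threshold."""
    if cluster_threshold <= 0:
        raise ValueError("cluster_threshold must be positive")
    t = np.asarray(t_values, dtype=float)
    return np.nonzero(np.abs(t) >= cluster_threshold)[0]


def connection_position(pair, positions: dict) -> np.ndarray:
    """6D coordinate of a connection: xyz of endpoint i then of endpoint j."""
    i, j = int(pair[0]), int(pair[1])
    return np.concatenate([positions[i], positions[j]])


def _flip_aware_distances(p6: np.ndarray) -> np.ndarray:
    """Pairwise 6D distances treating a connection and its reversal as equal."""
    swapped = np.concatenate([p6[:, 3:], p6[:, :3]], axis=1)
    return np.minimum(cdist(p6, p6), cdist(p6, swapped))


def cluster_bundles(
    surviving_idx: np.ndarray,
    t_signs: np.ndarray,
    positions6: np.ndarray,
    max_spread: float = 0.01,
) -> list:
    """Group surviving connections into sign-homogeneous bundles.

    Within each sign group, bundles are the connected components of the
    graph linking two connections whose (flip-aware) 6D distance is
    <= ``max_spread`` — i.e. single-linkage clustering cut at
    ``max_spread``.  Returns (member indices, sign) tuples ordered by
    smallest member index.
    """
    if max_spread <= 0:
        raise ValueError("max_spread must be positive")
    surviving_idx = np.asarray(surviving_idx, dtype=int)
    bundles = []
    for sign in (1, -1):
        sel = surviving_idx[np.asarray(t_signs) == sign]
        if len(sel) == 0:
            continue
        d = _flip_aware_distances(positions6[sel])
        adj = csr_matrix(d <= max_spread)
        n_comp, labels = connected_components(adj, directed=False)
        for comp in range(n_comp):
            members = sel[labels == comp]
            bundles.append((members, sign))
    bundles.sort(key=lambda b: int(b[0].min()))
    return bundles


def bundle_t(members, t_values, cap: float | None = None) -> float:
    """Bundle statistic: sum of |t| over member connections.

    Infinite sentinels (zero-variance differences) contribute ``cap``
    when given, keeping bundle statistics finite.
    """
    members = np.asarray(members, dtype=int)
    if len(members) == 0:
        raise ValueError("empty bundle")
    abs_t = np.abs(np.asarray(t_values, dtype=float)[members])
    if cap is not None:
        abs_t = np.minimum(abs_t, cap)
    return float(abs_t.sum())


def _prune_and_cluster(diff, positions6, cluster_threshold, max_spread):
    """t -> threshold -> bundles -> bundle statistics, for one labelling."""
    t = _t_rows(diff)
    surv = threshold_connections(t, cluster_threshold)
    if len(surv) == 0:
        return t, surv, [], np.empty(0)
    signs = np.where(t[surv] >= 0, 1, -1)
    bundles = cluster_bundles(surv, signs, positions6, max_spread)
    cap = 10.0 * cluster_threshold
    bt = np.array([bundle_t(m, t, cap=cap) for m, _ in bundles])
    return t, surv, bundles, bt


def cluster_permutation_test(
    con_set: SubjectConnectivitySet,
    cluster_threshold: float = 5.0,
    max_spread: float = 0.01,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BundleResult:
    """Max-statistic permutation test over connection bundles.

    Each permutation independently flips each subject's condition labels
    with probability 1/2, reruns the prune-and-cluster pipeline, and
    records the maximum bundle statistic (0 when nothing survives).
    Bundle p-values use the add-one convention
    p = (1 + #{null >= bundle_t}) / (1 + n_permutations); bundles with
    p <= alpha are significant.
    """
    if n_permutations < 1 or alpha <= 0 or alpha > 1:
        raise ValueError("invalid permutation parameters")
    diff = con_set.differences()
    pairs = con_set.pairs
    positions6 = np.array([
        connection_position(p, pairs.positions) for p in pairs.pairs
    ])
    t, surv, bundles, bt = _prune_and_cluster(
        diff, positions6, cluster_threshold, max_spread
    )
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for perm in range(n_permutations):
        signs = np.where(rng.random(con_set.n_subjects) < 0.5, -1.0, 1.0)
        _, _, _, bt_perm = _prune_and_cluster(
            signs[:, None] * diff, positions6, cluster_threshold, max_spread
        )
        null_max[perm] = bt_perm.max() if len(bt_perm) else 0.0
    if len(bt):
        p_values = (1.0 + (null_max[None, :] >= bt[:, None]).sum(axis=1)) / (
            1.0 + n_permutations
        )
    else:
        p_values = np.empty(0)
    sig_mask = p_values <= alpha if len(bt) else np.empty(0, dtype=bool)
    significant_idx = (
        np.unique(np.concatenate([
            m for (m, _), s in zip(bundles, sig_mask) if s
        ])) if sig_mask.any() else np.empty(0, dtype=int)
    )
    return BundleResult(
        t_values=t, surviving_idx=surv, bundles=bundles, bundle_t=bt,
        null_max=null_max, p_values=p_values, significant_idx=significant_idx,
        cluster_threshold=cluster_threshold, max_spread=max_spread,
        n_permutations=n_permutations, alpha=alpha, seed=seed,
    )
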