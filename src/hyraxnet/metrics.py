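"""Node- and group-level traits of day/night association networks.

Traits: degree (binary connections), strength (sum of SRI weights),
eigenvector centrality (leading eigenvector of the weighted matrix, scaled
to max 1), edge density within a group, individual selectivity (CV of a
node's weights to all its group-mates, structural zeros included), group
social differentiation (CV of all within-group dyadic weights), Jaccard
neighbour stability between consecutive periods, and within-group SDs of
node traits.  Betweenness and closeness are deliberately absent: daily
networks are too sparse for them to be meaningful.

Undefined values (empty graphs, zero-mean CVs, singleton groups) are
returned as NaN; table builders carry an explicit ``defined`` flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .netbuild import AssociationMatrix


def _cv(values, ddof: int = 1) -> float:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=ddof) / m)


def eigenvector_scores(weights: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a symmetric nonneg matrix, scaled to max 1.

    Computed on the full (possibly disconnected) matrix: the dominant
    component carries the mass.  All-zero matrix -> all zeros.
    """
    if not np.allclose(weights, weights.T):
        raise ValueError("matrix must be symmetric")
    if not np.any(weights):
        return np.zeros(weights.shape[0])
    vals, vecs = np.linalg.eigh(weights)
    lead = np.abs(vecs[:, -1])
    m = lead.max()
    return lead / m if m > 0 else lead


def node_centralities(matrix: AssociationMatrix) -> pd.DataFrame:
    """Degree, strength and eigenvector centrality per node.

    On an empty graph all three are zero by convention (flagged via the
    ``defined`` column).
    """
    w = matrix.weights
    binary = (w > 0).astype(float)
    empty = not np.any(w)
    df = pd.DataFrame(
        {
            "node": list(matrix.roster),
            "degree": binary.sum(axis=1).astype(int),
            "strength": w.sum(axis=1),
            "eigenvector": eigenvector_scores(w),
        }
    )
    df["defined"] = not empty
    return df


def edge_density(matrix: AssociationMatrix, roster_subset=None) -> float:
    """Existing ties / potential ties among the subset; NaN for < 2 nodes."""
    subset = list(roster_subset) if roster_subset is not None else list(matrix.roster)
    k = len(subset)
    if k < 2:
        return float("nan")
    idx = [matrix.index_of(v) for v in subset]
    sub = matrix.weights[np.ix_(idx, idx)]
    ties = int(np.count_nonzero(np.triu(sub, k=1)))
    return ties / (k * (k - 1) / 2)


def selectivity_cv(matrix: AssociationMatrix, node, group, ddof: int = 1) -> float:
    """CV of a node's weights to ALL its group-mates (zeros included).

    NaN when the group has < 3 members or the node has no weight at all.
    """
    mates = [v for v in group if v != node]
    if len(mates) < 2:
        return float("nan")
    i = matrix.index_of(node)
    w = np.array([matrix.weights[i, matrix.index_of(m)] for m in mates])
    return _cv(w, ddof=ddof)


def social_differentiation(matrix: AssociationMatrix, group, ddof: int = 1) -> float:
    """CV over all within-group dyadic weights (zeros included)."""
    members = list(group)
    if len(members) < 3:
        return float("nan")
    idx = [matrix.index_of(v) for v in members]
    sub = matrix.weights[np.ix_(idx, idx)]
    iu = np.triu_indices(len(members), k=1)
    return _cv(sub[iu], ddof=ddof)


def neighbour_stability(
    net_t: AssociationMatrix, net_next: AssociationMatrix, node
) -> float:
    """Jaccard overlap of a node's (binarized) neighbours across periods.

    Both-empty neighbour sets are undefined (NaN) and should be excluded
    from averages; disjoint nonempty sets give 0.
    """
    if net_t.roster != net_next.roster:
        raise ValueError("rosters must be conformable")
    i = net_t.index_of(node)
    n1 = set(np.flatnonzero(net_t.weights[i]).tolist())
    n2 = set(np.flatnonzero(net_next.weights[i]).tolist())
    if not n1 and not n2:
        return float("nan")
    return len(n1 & n2) / len(n1 | n2)


def group_sd(values, ddof: int = 1) -> float:
    """Sample SD of defined trait values within one group; NaN if < 2."""
    v = np.asarray([x for x in values if not np.isnan(x)], dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=ddof))


# ---------------------------------------------------------------------------
# fast batch evaluators over stacks of weight matrices (periods x n x n);
# used by the permutation workflow where thousands of null networks are
# re-measured


def stack_mean_strength(W: np.ndarray) -> np.ndarray:
    """Mean node strength per period; shape (P,)."""
    return W.sum(axis=2).mean(axis=1)


def stack_mean_degree(W: np.ndarray) -> np.ndarray:
    return (W > 0).sum(axis=2).mean(axis=1)


def stack_mean_eigenvector(W: np.ndarray) -> np.ndarray:
    out = np.zeros(W.shape[0])
    for p in range(W.shape[0]):
        out[p] = eigenvector_scores(W[p]).mean() if np.any(W[p]) else 0.0
    return out


def stack_mean_selectivity(W: np.ndarray, group_members: dict, roster, ddof=1) -> np.ndarray:
    """Mean individual selectivity CV per period (undefined nodes excluded)."""
    index = {v: i for i, v in enumerate(roster)}
    P = W.shape[0]
    per_node = []
    for members in group_members.values():
        ids = [index[v] for v in members]
        if len(ids) < 3:
            continue
        for i in ids:
            mates = [j for j in ids if j != i]
            w = W[:, i, mates]  # (P, k)
            m = w.mean(axis=1)
            sd = w.std(axis=1, ddof=ddof)
            cv = np.divide(sd, m, out=np.full(P, np.nan), where=m > 0)
            per_node.append(cv)
    if not per_node:
        return np.full(P, np.nan)
    arr = np.vstack(per_node)
    with np.errstate(invalid="ignore"):
        return np.nanmean(arr, axis=0)


def stack_mean_differentiation(W: np.ndarray, group_members: dict, roster, ddof=1) -> np.ndarray:
    index = {v: i for i, v in enumerate(roster)}
    P = W.shape[0]
    per_group = []
    for members in group_members.values():
        ids = [index[v] for v in members]
        if len(ids) < 3:
            continue
        iu = np.triu_indices(len(ids), k=1)
        sub = W[np.ix_(range(P), ids, ids)][:, iu[0], iu[1]]
        m = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=ddof)
        per_group.append(np.divide(sd, m, out=np.full(P, np.nan), where=m > 0))
    if not per_group:
        return np.full(P, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(per_group), axis=0)


def stack_density(W: np.ndarray) -> np.ndarray:
    n = W.shape[1]
    iu = np.triu_indices(n, k=1)
    return (W[:, iu[0], iu[1]] > 0).mean(axis=1)


STACK_TRAITS = {
    "strength": lambda W, gm, roster: stack_mean_strength(W),
    "degree": lambda W, gm, roster: stack_mean_degree(W),
    "eigenvector": lambda W, gm, roster: stack_mean_eigenvector(W),
    "selectivity": stack_mean_selectivity,
    "differentiation": stack_mean_differentiation,
    "density": lambda W, gm, roster: stack_density(W),
}
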