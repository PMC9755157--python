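"""Aggregate proximity events into simple-ratio-index association networks.

With continuously recording proximity loggers every 5-minute slot of a
period is a sampling unit for every dyad, so the simple ratio index
x / (x + y_AB + y_A + y_B) collapses to

    weight(i, j) = slots with an i-j event / total slots in the period.

Matrices share a fixed roster ordering so that networks from different
periods and contexts stay conformable for cosine comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

ALL = "all"


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric weighted association network for one period and context."""

    roster: tuple
    weights: np.ndarray
    period_id: object = None
    context: str = ALL
    n_slots: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != len(self.roster):
            raise ValueError("weights must be square and match the roster")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.roster)

    def index_of(self, node) -> int:
        return self.roster.index(node)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.roster)
        ii, jj = np.nonzero(np.triu(self.weights))
        for i, j in zip(ii, jj):
            g.add_edge(self.roster[i], self.roster[j], weight=self.weights[i, j])
        return g


def sri_counts(a_idx, b_idx, n: int) -> np.ndarray:
    """Symmetric slot-count matrix from event endpoint index arrays."""
    m = np.zeros((n, n))
    np.add.at(m, (a_idx, b_idx), 1.0)
    np.add.at(m, (b_idx, a_idx), 1.0)
    return m


def build_sri(
    events: pd.DataFrame,
    period_id,
    context: str,
    roster,
    n_slots: int,
) -> AssociationMatrix:
    """Simple-ratio-index network for one aggregation period and context.

    ``events`` may contain other periods'/contexts' rows only if the
    relevant columns are present for filtering; rows claiming the requested
    period must genuinely lie in it.
    """
    if n_slots <= 0:
        raise ValueError("n_slots must be positive")
    roster = tuple(roster)
    ev = events
    if "period" in ev.columns and period_id is not None:
        ev = ev[ev["period"] == period_id]
    if context != ALL and "context" in ev.columns:
        ev = ev[ev["context"] == context]
    index = {ind: i for i, ind in enumerate(roster)}
    unknown = (set(ev["dyad_a"]) | set(ev["dyad_b"])) - set(roster) if len(ev) else set()
    if unknown:
        raise ValueError(f"events reference individuals off the roster: {sorted(unknown)}")
    n = len(roster)
    if len(ev) == 0:
        return AssociationMatrix(roster, np.zeros((n, n)), period_id, context, n_slots)
    # events are unique per (dyad, slot) after preprocessing; guard anyway
    ev = ev.drop_duplicates(["dyad_a", "dyad_b", "interval_index"])
    a = ev["dyad_a"].map(index).to_numpy()
    b = ev["dyad_b"].map(index).to_numpy()
    counts = sri_counts(a, b, n)
    if counts.max() > n_slots:
        raise ValueError("more events than slots in period: events outside period?")
    return AssociationMatrix(roster, counts / n_slots, period_id, context, n_slots)


def binarize(matrix: AssociationMatrix) -> AssociationMatrix:
    return replace(matrix, weights=(matrix.weights > 0).astype(float))


def vectorize_upper(matrix: AssociationMatrix) -> np.ndarray:
    """Row-major above-diagonal weights; length n(n-1)/2."""
    n = matrix.n
    iu = np.triu_indices(n, k=1)
    return matrix.weights[iu]


def check_conformable(matrices) -> None:
    rosters = {m.roster for m in matrices}
    if len(rosters) > 1:
        raise ValueError("matrices in one comparison set must share the roster")


def upper_indices(n: int):
    return np.triu_indices(n, k=1)
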