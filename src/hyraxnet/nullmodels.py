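"""Data-stream permutation null model and permutation p-values.

The null hypothesis is that sociality reduces to random associations among
individuals sharing space and time: proximity events are rewired only
*within* (date, group) blocks, where groups come from the link-community
detection on the full-study network.  Sampling is sequential: each null
sample is obtained from the previous one by a fixed number of elementary
dyad swaps (see :mod:`hyraxnet._swaps`), after an equal burn-in from the
observed stream.  Cross-group events are frozen and never swapped.

Permutation p-values follow the convention
p = #(observed > null) / n_perm (ties count as "not larger"), read as
significant at either 5% tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._swaps import swap_pass
from .communities import GroupAssignment


@dataclass(frozen=True)
class PermConfig:
    n_perm: int = 1000
    swaps_per_step: int | None = None  # default: number of swappable events
    burn_in: int | None = None  # default: swaps_per_step
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.swaps_per_step is not None and self.swaps_per_step < 1:
            raise ValueError("swaps_per_step must be >= 1")


@dataclass
class NullEnsemble:
    """Ordered permuted event sets sharing the observed margins.

    Dyad endpoints are stored per sample as roster-index arrays; slots,
    dates, periods, phases and contexts are identical across samples (they
    travel with the event position, not the dyad).
    """

    roster: tuple
    slot: np.ndarray
    period: np.ndarray
    date_code: np.ndarray
    context: np.ndarray  # str array, 'active'/'passive'
    phase: np.ndarray
    block: np.ndarray  # (date, group) block id; -1 = frozen cross-group event
    samples: list  # list of (a_idx, b_idx) arrays
    observed: tuple  # (a_idx, b_idx) of the observed stream
    config: PermConfig = None
    accepted: list = field(default_factory=list)

    @property
    def n_perm(self) -> int:
        return len(self.samples)

    def sample_frame(self, r: int) -> pd.DataFrame:
        a, b = self.samples[r]
        return pd.DataFrame(
            {
                "dyad_a": [self.roster[i] for i in a],
                "dyad_b": [self.roster[i] for i in b],
                "interval_index": self.slot,
                "period": self.period,
                "phase": self.phase,
                "context": self.context,
            }
        )


def encode_events(events: pd.DataFrame, roster, groups: GroupAssignment):
    """Roster-index arrays + (date, group) block ids for the swap kernel."""
    index = {v: i for i, v in enumerate(roster)}
    a = events["dyad_a"].map(index).to_numpy(dtype=np.int64)
    b = events["dyad_b"].map(index).to_numpy(dtype=np.int64)
    if np.any(a == b):
        raise ValueError("self-loop event")
    ga = events["dyad_a"].map(groups.group_of).to_numpy()
    gb = events["dyad_b"].map(groups.group_of).to_numpy()
    dates = pd.factorize(events["date"])[0]
    n_groups = int(max(groups.groups) + 1)
    within = ga == gb
    block = np.where(within, dates * n_groups + ga, -1).astype(np.int64)
    # relabel blocks densely
    uniq = np.unique(block[block >= 0])
    remap = {int(bv): i for i, bv in enumerate(uniq)}
    block = np.array([remap[int(v)] if v >= 0 else -1 for v in block], dtype=np.int64)
    return a, b, block


def datastream_permute(
    events: pd.DataFrame,
    groups: GroupAssignment,
    config: PermConfig,
    roster=None,
) -> NullEnsemble:
    """Sequential focal data-stream permutation within (date, group) blocks."""
    if roster is None:
        roster = tuple(sorted(set(events["dyad_a"]) | set(events["dyad_b"])))
    roster = tuple(roster)
    n = len(roster)
    ev = events.reset_index(drop=True)
    a, b, block = encode_events(ev, roster, groups)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    a, b = lo, hi
    slot = ev["interval_index"].to_numpy(dtype=np.int64)
    slot0 = slot - slot.min() if len(slot) else slot
    n_slots_total = int(slot0.max()) + 1 if len(slot0) else 1

    # blocks with < 2 events can never host a swap: keep them, they are
    # simply never accepted (e1 == e2 rejection)
    swappable = np.flatnonzero(block >= 0).astype(np.int64)
    order = np.argsort(block[swappable], kind="stable")
    block_idx = swappable[order]
    n_blocks = int(block.max()) + 1 if np.any(block >= 0) else 0
    block_ptr = np.zeros(n_blocks + 1, dtype=np.int64)
    if n_blocks:
        counts = np.bincount(block[swappable], minlength=n_blocks)
        block_ptr[1:] = np.cumsum(counts)

    occ = np.zeros(n * n * n_slots_total, dtype=np.uint8)
    code = (a * n + b) * n_slots_total + slot0
    if len(code) != len(set(code.tolist())):
        raise ValueError("duplicate (dyad, slot) events in input stream")
    occ[code] = 1

    swaps = config.swaps_per_step if config.swaps_per_step is not None else max(
        1, len(swappable)
    )
    burn = config.burn_in if config.burn_in is not None else swaps
    rng = np.random.default_rng(config.seed)

    cur_a = a.copy()
    cur_b = b.copy()
    samples = []
    accepted = []

    def run(n_swaps):
        if n_swaps == 0 or len(swappable) == 0:
            return 0
        e1_pick = rng.integers(0, len(swappable), size=n_swaps)
        u2 = rng.random(n_swaps)
        coin = rng.random(n_swaps)
        return swap_pass(
            cur_a, cur_b, slot0, swappable, block, block_ptr, block_idx,
            occ, n, n_slots_total, e1_pick, u2, coin,
        )

    run(burn)
    for _ in range(config.n_perm):
        acc = run(swaps)
        accepted.append(acc)
        samples.append((cur_a.copy(), cur_b.copy()))

    return NullEnsemble(
        roster=roster,
        slot=slot,
        period=ev["period"].to_numpy() if "period" in ev else np.zeros(len(ev), int),
        date_code=pd.factorize(ev["date"])[0] if "date" in ev else np.zeros(len(ev), int),
        context=ev["context"].to_numpy() if "context" in ev else np.array(["all"] * len(ev)),
        phase=ev["phase"].to_numpy() if "phase" in ev else np.array([""] * len(ev)),
        block=block,
        samples=samples,
        observed=(a, b),
        config=config,
        accepted=accepted,
    )


def conservation_report(ensemble: NullEnsemble) -> dict:
    """Verify the permutation's conservation laws on every sample.

    Checks, per sample: total event count; per-individual event count per
    block; (dyad, slot) uniqueness; frozen cross-group events untouched;
    slot multiset trivially shared (slots are common storage).
    """
    a0, b0 = ensemble.observed
    n = len(ensemble.roster)
    n_ev = len(a0)
    frozen = ensemble.block < 0

    def margins(a, b):
        out = {}
        for blk in np.unique(ensemble.block[ensemble.block >= 0]):
            mask = ensemble.block == blk
            out[int(blk)] = np.bincount(
                np.concatenate([a[mask], b[mask]]), minlength=n
            )
        return out

    ref = margins(a0, b0)
    ok = True
    failures = []
    for r, (a, b) in enumerate(ensemble.samples):
        if len(a) != n_ev:
            ok = False
            failures.append((r, "event count"))
            continue
        if not (
            np.array_equal(a[frozen], a0[frozen])
            and np.array_equal(b[frozen], b0[frozen])
        ):
            ok = False
            failures.append((r, "frozen events moved"))
        cur = margins(a, b)
        for blk, counts in ref.items():
            if not np.array_equal(cur[blk], counts):
                ok = False
                failures.append((r, f"margins block {blk}"))
                break
        key = set(zip((a * n + b).tolist(), ensemble.slot.tolist()))
        if len(key) != n_ev:
            ok = False
            failures.append((r, "duplicate (dyad, slot)"))
    return {"ok": ok, "n_samples": ensemble.n_perm, "failures": failures}


def perm_pvalue(observed: float, nulls) -> float:
    """p = #(observed > null) / n_perm; strict inequality, ties not larger."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("nulls must be nonempty")
    return float(np.sum(observed > nulls) / nulls.size)


def upper_pvalue(observed: float, nulls) -> float:
    """Upper-tail companion: fraction of nulls at least as large as observed."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("nulls must be nonempty")
    return float(np.sum(nulls >= observed) / nulls.size)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
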