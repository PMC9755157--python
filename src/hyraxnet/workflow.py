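"""End-to-end building blocks: simulate -> preprocess -> networks ->
strata -> null ensemble -> statistics.

These functions are the computational core shared by the numbered analysis
drivers, the test suite and the acceptance script.  They favour array
representations so that re-measuring thousands of permuted networks stays
cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import compare, metrics
from .communities import detect_groups
from .netbuild import AssociationMatrix, build_sri
from .nullmodels import NullEnsemble, PermConfig, datastream_permute
from .preprocess import ACTIVE, DAY, PhaseConfig, preprocess_records
from .simulate import SimConfig, simulate_study


@dataclass
class StudyData:
    """One fully pre-processed (synthetic or ingested) study."""

    records: pd.DataFrame
    events: pd.DataFrame
    roster: tuple
    phase_config: PhaseConfig
    truth: object = None
    cover: object = None
    groups: object = None

    @property
    def slots_per_period(self) -> np.ndarray:
        pc = self.phase_config
        return np.array([pc.n_slots(p) for p in range(pc.n_periods)], dtype=float)


def prepare_study(
    config: SimConfig, seed_dedup: int | None = None, threshold_s: int = 1500
) -> StudyData:
    """Simulate a study and run it through pre-processing and strata detection."""
    records, truth = simulate_study(config)
    pc = config.phase_config()
    roster = config.roster
    retrieved = set(roster) - set(config.lost_loggers)
    if seed_dedup is None:
        seed_dedup = config.seed + 1
    events = preprocess_records(
        records, retrieved, pc, seed=seed_dedup, threshold_s=threshold_s
    )
    data = StudyData(
        records=records, events=events, roster=roster, phase_config=pc, truth=truth
    )
    if len(events):
        data.cover, data.groups = detect_groups(events, roster, pc)
    return data


def build_period_networks(
    data: StudyData, context: str = ACTIVE
) -> list[AssociationMatrix]:
    """One network per aggregation period (day 0, night 0, ...)."""
    pc = data.phase_config
    return [
        build_sri(data.events, p, context, data.roster, pc.n_slots(p))
        for p in range(pc.n_periods)
    ]


def make_ensemble(data: StudyData, perm_config: PermConfig) -> NullEnsemble:
    if data.groups is None:
        raise ValueError("no permutation strata: study has no events")
    return datastream_permute(data.events, data.groups, perm_config, roster=data.roster)


# ---------------------------------------------------------------------------
# fast re-measurement of permuted streams


def _weight_stack(a, b, period, mask, n_periods, n, slots_per_period) -> np.ndarray:
    W = np.zeros((n_periods, n, n))
    pa = period[mask].astype(np.int64)
    np.add.at(W, (pa, a[mask], b[mask]), 1.0)
    np.add.at(W, (pa, b[mask], a[mask]), 1.0)
    W /= np.asarray(slots_per_period)[:, None, None]
    return W


def observed_weight_stack(
    data: StudyData, context: str = ACTIVE
) -> np.ndarray:
    """(periods, n, n) stack of SRI weights from the observed stream."""
    ev = data.events if context == "all" else data.events[data.events["context"] == context]
    index = {v: i for i, v in enumerate(data.roster)}
    a = ev["dyad_a"].map(index).to_numpy(dtype=np.int64)
    b = ev["dyad_b"].map(index).to_numpy(dtype=np.int64)
    period = ev["period"].to_numpy(dtype=np.int64)
    return _weight_stack(
        a, b, period, np.ones(len(ev), bool),
        data.phase_config.n_periods, len(data.roster), data.slots_per_period,
    )


def period_weight_stack(
    ensemble: NullEnsemble, r: int, n_periods: int, slots_per_period,
    context: str = ACTIVE,
) -> np.ndarray:
    """(periods, n, n) SRI stack for one null sample."""
    a, b = ensemble.samples[r]
    mask = (
        np.ones(len(a), bool) if context == "all" else ensemble.context == context
    )
    return _weight_stack(
        a, b, ensemble.period, mask, n_periods, len(ensemble.roster), slots_per_period
    )


def context_weight_stack(ensemble: NullEnsemble, r: int, labels, slots: dict) -> np.ndarray:
    """Stack of the four phase x context full-study networks for one sample."""
    a, b = ensemble.samples[r]
    n = len(ensemble.roster)
    out = np.zeros((len(labels), n, n))
    for li, lab in enumerate(labels):
        phase, context = lab.split("_")
        mask = (ensemble.phase == phase) & (ensemble.context == context)
        np.add.at(out[li], (a[mask], b[mask]), 1.0)
        np.add.at(out[li], (b[mask], a[mask]), 1.0)
        out[li] /= slots[lab]
    return out


def build_context_networks(data: StudyData) -> dict:
    """The four full-study phase x context SRI networks."""
    pc = data.phase_config
    day_slots = sum(pc.n_slots(p) for p in range(0, pc.n_periods, 2))
    night_slots = sum(pc.n_slots(p) for p in range(1, pc.n_periods, 2))
    out = {}
    for phase, n_slots in (("day", day_slots), ("night", night_slots)):
        for context in ("active", "passive"):
            ev = data.events[
                (data.events["phase"] == phase) & (data.events["context"] == context)
            ]
            out[f"{phase}_{context}"] = build_sri(
                ev, None, "all", data.roster, n_slots
            )
    return out


# ---------------------------------------------------------------------------
# day/night trait contrasts


def trait_series_observed(data: StudyData, traits, context: str = ACTIVE) -> dict:
    W = observed_weight_stack(data, context)
    gm = {g: members for g, members in data.groups.groups.items()} if data.groups else {}
    return {t: metrics.STACK_TRAITS[t](W, gm, data.roster) for t in traits}


def trait_series_null(
    data: StudyData, ensemble: NullEnsemble, traits, context: str = ACTIVE
) -> dict:
    pc = data.phase_config
    slots = data.slots_per_period
    gm = {g: members for g, members in data.groups.groups.items()}
    out = {t: [] for t in traits}
    for r in range(ensemble.n_perm):
        W = period_weight_stack(ensemble, r, pc.n_periods, slots, context)
        for t in traits:
            out[t].append(metrics.STACK_TRAITS[t](W, gm, data.roster))
    return {t: np.vstack(v) for t, v in out.items()}


def daynight_trait_analysis(
    data: StudyData,
    perm_config: PermConfig,
    traits=("strength", "degree", "eigenvector", "selectivity", "differentiation", "density"),
    context: str = ACTIVE,
) -> dict:
    """Per-trait consecutive day/night contrast with combined p-values."""
    ensemble = make_ensemble(data, perm_config)
    obs = trait_series_observed(data, traits, context)
    nulls = trait_series_null(data, ensemble, traits, context)
    results = {}
    for t in traits:
        results[t] = compare.daynight_contrast(obs[t], nulls[t])
    return results


def phase_means(series: np.ndarray) -> tuple[float, float]:
    """(day mean, night mean) of a per-period series (day = even periods)."""
    s = np.asarray(series, dtype=float)
    day = s[0::2]
    night = s[1::2]
    return float(np.nanmean(day)), float(np.nanmean(night))


def fixture_config(seed: int, **overrides) -> SimConfig:
    """Small-scale study design used for tests and power studies:
    12 individuals in 3 groups over 6 days, default rates and the default
    day/night selectivity contrast (Dirichlet 5 by day vs 0.2 by night)."""
    kw = dict(n_individuals=12, n_groups=3, n_days=6, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def null_calibration_config(seed: int, **overrides) -> SimConfig:
    """Fixture-scale study drawn from the permutation null's own hypothesis
    class: no partner preference (uniform within group), identical day and
    night rates and durations, and encounters contained in single 5-minute
    slots so that proximity events are slot-wise exchangeable.

    The permutation null treats events within a (date, group) block as
    exchangeable given individual margins; calibration means simulating
    data for which that hypothesis is true.  See the methods note for the
    behaviour under multi-slot encounters.
    """
    kw = dict(
        n_individuals=12,
        n_groups=3,
        n_days=6,
        rate_day=3.5,
        rate_night=3.5,
        p_passive_day=0.0,
        p_passive_night=0.0,
        dur_active=(60.0, 0.3),
        selectivity_day=np.inf,
        selectivity_night=np.inf,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def selectivity_contrast_pipeline(
    sim_config: SimConfig, n_perm: int, seed: int
) -> dict:
    """Simulate one study and run the day/night selectivity contrast.

    Convenience wrapper used by the calibration and power studies; returns
    the combined p plus day/night mean selectivity.
    """
    data = prepare_study(sim_config)
    if data.groups is None:
        raise ValueError("simulated study produced no events")
    res = daynight_trait_analysis(
        data, PermConfig(n_perm=n_perm, seed=seed), traits=("selectivity",)
    )["selectivity"]
    obs = trait_series_observed(data, ("selectivity",))["selectivity"]
    day_mean, night_mean = phase_means(obs)
    return {
        "combined_p": res.combined_p,
        "day_mean_selectivity": day_mean,
        "night_mean_selectivity": night_mean,
        "n_transitions": len(res.transitions),
    }
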