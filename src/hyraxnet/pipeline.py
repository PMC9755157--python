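"""Run orchestration: config file, input validation, staged pipeline, manifest.

The run configuration is a plain ``key = value`` text file (hash comments
allowed).  Recognised keys:

    records, roster, out_dir          paths (records optional if simulating)
    simulate                          true/false: generate synthetic records
    start_date, n_days                study span (YYYY-MM-DD, int)
    day_start, day_end                clock times HH:MM
    interval_s, threshold_s           discretization / context parameters
    n_perm, swaps_per_step            permutation settings
    seed                              master seed
    n_individuals, n_groups, rate_day, rate_night, selectivity_day,
    selectivity_night, p_between_group    simulation settings

Stages write TSV outputs under ``out_dir`` and a JSON manifest recording
the seed, a hash of the parsed config and per-output SHA-256 checksums, so
two runs with the same config and seed are verifiably identical.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, metrics
from .communities import detect_groups
from .netbuild import binarize
from .nullmodels import PermConfig
from .preprocess import PhaseConfig, preprocess_records, validate_records
from .simulate import SimConfig, simulate_study, write_records_csv, read_records_csv
from .workflow import (
    StudyData,
    build_context_networks,
    build_period_networks,
    daynight_trait_analysis,
    make_ensemble,
)

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


@dataclass
class RunConfig:
    out_dir: Path
    records: Path | None = None
    roster: Path | None = None
    simulate: bool = True
    seed: int = 0
    n_perm: int = 100
    swaps_per_step: int | None = None
    interval_s: int = 300
    threshold_s: int = 1500
    start_date: dt.date = dt.date(2017, 7, 1)
    n_days: int = 27
    day_start: dt.time = dt.time(6, 0)
    day_end: dt.time = dt.time(19, 30)
    sim_kwargs: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            raw[k] = v
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        kw: dict = {"out_dir": Path(raw.pop("out_dir", "runs"))}
        sim_kwargs = {}
        for k, v in raw.items():
            if k in ("records", "roster"):
                kw[k] = Path(v)
            elif k == "simulate":
                kw[k] = _BOOL[v.lower()]
            elif k in ("seed", "n_perm", "swaps_per_step", "interval_s",
                       "threshold_s", "n_days"):
                kw[k] = int(v)
            elif k == "start_date":
                kw[k] = dt.date.fromisoformat(v)
            elif k in ("day_start", "day_end"):
                kw[k] = dt.time.fromisoformat(v)
            elif k in ("n_individuals", "n_groups"):
                sim_kwargs[k] = int(v)
            elif k in ("rate_day", "rate_night", "selectivity_day",
                       "selectivity_night", "p_between_group",
                       "p_passive_day", "p_passive_night"):
                sim_kwargs[k] = float(v)
            else:
                raise ValueError(f"unknown config key {k!r}")
        kw["sim_kwargs"] = sim_kwargs
        return cls(**kw)

    def phase_config(self) -> PhaseConfig:
        return PhaseConfig(
            start_date=self.start_date,
            n_days=self.n_days,
            day_start=self.day_start,
            day_end=self.day_end,
        )

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_days=self.n_days,
            start_date=self.start_date,
            day_start=self.day_start,
            day_end=self.day_end,
            seed=self.seed,
            **self.sim_kwargs,
        )

    def digest(self) -> str:
        payload = {
            k: str(v)
            for k, v in sorted(self.__dict__.items())
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def validate_inputs(records_path, roster_path=None, phase_config: PhaseConfig | None = None) -> dict:
    """Schema / cross-reference / span checks; machine-readable report."""
    issues = []
    try:
        records = read_records_csv(records_path)
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        return {"ok": False, "issues": [f"cannot read records: {exc}"]}
    roster = None
    if roster_path is not None:
        roster_df = pd.read_csv(roster_path)
        roster = set(roster_df["individual"])
    self_rows = records.index[records["reporter"] == records["partner"]].tolist()
    issues.extend(f"row {r}: reporter == partner" for r in self_rows)
    short = records.index[records["duration_s"] < 11].tolist()
    issues.extend(f"row {r}: duration below the 11 s logger floor" for r in short)
    if roster is not None:
        ids = set(records["reporter"]) | set(records["partner"])
        for unk in sorted(ids - roster):
            issues.append(f"unknown individual {unk!r}")
    if phase_config is not None:
        starts = pd.to_datetime(records["start"])
        early = records.index[starts < phase_config.epoch].tolist()
        late = records.index[starts >= phase_config.span_end].tolist()
        issues.extend(f"row {r}: record before study start" for r in early)
        issues.extend(f"row {r}: record after study end" for r in late)
    return {"ok": not issues, "issues": issues, "n_records": int(len(records))}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the run manifest (also written to disk).

    Stage failures raise :class:`StageError` tagged with the stage name;
    outputs of completed stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pc = config.phase_config()
    outputs: dict[str, Path] = {}

    # -- stage: acquire records ------------------------------------------
    if config.simulate:
        try:
            records, truth = simulate_study(config.sim_config())
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
        path = out / "records.csv"
        write_records_csv(records, path)
        truth.to_json(out / "truth.json")
        outputs["records"] = path
        outputs["truth"] = out / "truth.json"
        roster = config.sim_config().roster
        retrieved = set(roster) - set(config.sim_config().lost_loggers)
    else:
        if config.records is None or not Path(config.records).exists():
            raise StageError("ingest", f"records path missing: {config.records}")
        records = read_records_csv(config.records)
        try:
            validate_records(records)
        except ValueError as exc:
            raise StageError("ingest", str(exc)) from exc
        roster = tuple(sorted(set(records["reporter"]) | set(records["partner"])))
        retrieved = set(roster)

    # -- stage: preprocess ------------------------------------------------
    try:
        events = preprocess_records(
            records, retrieved, pc, seed=config.seed + 1,
            interval_s=config.interval_s, threshold_s=config.threshold_s,
        )
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    path = out / "events.tsv"
    events.to_csv(path, sep="\t", index=False)
    outputs["events"] = path

    data = StudyData(records=records, events=events, roster=tuple(roster), phase_config=pc)

    # -- stage: communities ----------------------------------------------
    try:
        data.cover, data.groups = detect_groups(events, data.roster, pc)
    except Exception as exc:
        raise StageError("communities", str(exc)) from exc
    rows = [
        {"node": v, "community": c, "share": s}
        for v, shares in data.cover.membership_fraction.items()
        for c, s in sorted(shares.items())
    ]
    path = out / "communities.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    outputs["communities"] = path
    path = out / "groups.tsv"
    pd.DataFrame(
        sorted(data.groups.group_of.items()), columns=["node", "group"]
    ).to_csv(path, sep="\t", index=False)
    outputs["groups"] = path

    # -- stage: networks --------------------------------------------------
    try:
        nets = build_period_networks(data)
    except Exception as exc:
        raise StageError("networks", str(exc)) from exc
    edge_rows = []
    for net in nets:
        ii, jj = np.nonzero(np.triu(net.weights))
        for i, j in zip(ii, jj):
            edge_rows.append(
                {
                    "period": net.period_id,
                    "node_a": net.roster[i],
                    "node_b": net.roster[j],
                    "weight": net.weights[i, j],
                }
            )
    path = out / "active_period_edges.tsv"
    pd.DataFrame(edge_rows, columns=["period", "node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )
    outputs["networks"] = path

    # -- stage: metrics ---------------------------------------------------
    try:
        trait_rows = []
        for net in nets:
            cent = metrics.node_centralities(net)
            for _, row in cent.iterrows():
                for trait in ("degree", "strength", "eigenvector"):
                    trait_rows.append(
                        {
                            "period": net.period_id,
                            "unit": row["node"],
                            "trait": trait,
                            "value": row[trait],
                            "defined": bool(row["defined"]),
                        }
                    )
    except Exception as exc:
        raise StageError("metrics", str(exc)) from exc
    path = out / "node_traits.tsv"
    pd.DataFrame(trait_rows).to_csv(path, sep="\t", index=False)
    outputs["metrics"] = path

    # -- stage: permutation contrasts ------------------------------------
    try:
        perm = PermConfig(
            n_perm=config.n_perm, swaps_per_step=config.swaps_per_step,
            seed=config.seed + 2,
        )
        contrasts = daynight_trait_analysis(data, perm)
    except Exception as exc:
        raise StageError("permute", str(exc)) from exc
    rows = [
        {
            "trait": t,
            "combined_p": res.combined_p,
            "n_transitions": len(res.transitions),
        }
        for t, res in contrasts.items()
    ]
    path = out / "daynight_contrasts.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    outputs["contrasts"] = path

    # -- stage: compare (context + temporal similarity) -------------------
    try:
        ensemble = make_ensemble(
            data, PermConfig(n_perm=config.n_perm, seed=config.seed + 3)
        )
        ctx = build_context_networks(data)
        ctx_sim = compare.context_correlations(ctx, ensemble)
        simW = compare.temporal_similarity(nets, "weighted", ensemble)
        simB = compare.temporal_similarity(nets, "binary", ensemble)
        wb_p = compare.weighted_vs_binary_test(simW, simB, seed=config.seed + 4)
    except Exception as exc:
        raise StageError("compare", str(exc)) from exc
    path = out / "context_similarity.tsv"
    pd.DataFrame(ctx_sim.cosine, index=ctx_sim.labels, columns=ctx_sim.labels).to_csv(
        path, sep="\t"
    )
    outputs["context_similarity"] = path
    path = out / "similarity_summary.tsv"
    pd.DataFrame(
        [
            {"mode": "weighted", "mean_cosine": float(np.nanmean(simW.cosine)), **simW.counts},
            {"mode": "binary", "mean_cosine": float(np.nanmean(simB.cosine)), **simB.counts},
        ]
    ).to_csv(path, sep="\t", index=False)
    outputs["similarity_summary"] = path

    manifest = {
        "seed": config.seed,
        "config_sha256": config.digest(),
        "n_perm": config.n_perm,
        "weighted_vs_binary_p": wb_p,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
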