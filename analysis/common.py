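"""Shared setup for the numbered analysis drivers.

Every driver analyses the same full-scale synthetic deployment (28
individuals, 4 groups, 27 days) under one master seed, writes small
summary tables to ``results/`` and larger intermediates to ``scratch/``
(not tracked).
"""

from __future__ import annotations

from pathlib import Path

from hyraxnet.simulate import SimConfig
from hyraxnet.workflow import StudyData, prepare_study

SEED = 20170701
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def study_config() -> SimConfig:
    return SimConfig(seed=SEED)


def get_study() -> StudyData:
    return prepare_study(study_config())


def outdir(kind: str) -> Path:
    d = RESULTS if kind == "results" else SCRATCH
    d.mkdir(parents=True, exist_ok=True)
    return d
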