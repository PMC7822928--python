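"""YAML configuration loading.

A config file may carry any of the top-level keys ``pileup``, ``render``,
``dataset``, ``train`` and ``sim``; each maps onto the corresponding config
dataclass, with unknown keys rejected.  ``pileup.genome_order_file`` names a
one-genome-id-per-line file consumed into ``PileupConfig.genome_order``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .classifier import TrainConfig
from .compare_region import PileupConfig
from .render import RenderConfig
from .simulate import SimConfig


@dataclasses.dataclass
class DatasetConfig:
    balance: bool = True
    seed: int = 0
    mode: str = "train"


@dataclasses.dataclass
class PipelineConfig:
    pileup: PileupConfig = dataclasses.field(default_factory=PileupConfig)
    render: RenderConfig = dataclasses.field(default_factory=RenderConfig)
    dataset: DatasetConfig = dataclasses.field(default_factory=DatasetConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)


def _build(cls, payload: dict[str, Any], base_dir: Path):
    if payload is None:
        payload = {}
    if cls is PileupConfig and "genome_order_file" in payload:
        order_file = base_dir / payload.pop("genome_order_file")
        payload["genome_order"] = [
            line.strip() for line in order_file.read_text().splitlines() if line.strip()
        ]
        payload.setdefault("distance_mode", "provided_order")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    # YAML lists become tuples where the dataclass default is a tuple
    coerced = {}
    defaults = {f.name: f.default for f in dataclasses.fields(cls)}
    for k, v in payload.items():
        if isinstance(v, list) and isinstance(defaults.get(k), tuple):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return PipelineConfig(
        pileup=_build(PileupConfig, raw.get("pileup"), path.parent),
        render=_build(RenderConfig, raw.get("render"), path.parent),
        dataset=_build(DatasetConfig, raw.get("dataset"), path.parent),
        train=_build(TrainConfig, raw.get("train"), path.parent),
        sim=_build(SimConfig, raw.get("sim"), path.parent),
    )
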