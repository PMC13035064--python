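"""Run configuration: serializable parameters for a full pipeline run.

A run is reproducible from (config, seed); the seed is mandatory and every
stage derives its random streams deterministically from it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .simulate import BehaviorModelConfig, DrugEffect

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything needed to rerun a screen end to end."""

    seed: int
    assay: str = "screen"
    n_days: int = 2
    compounds_per_day: int = 4
    group_size: int = 32
    dose_um: float = 1.0
    alpha: float = 0.01
    enrichment_alpha: float = 0.05
    fdr_q: float = 0.00005
    hit_direction: str = "increase"
    readouts: tuple[str, ...] = ("hab_pct_41_50", "hab_pct_51_60", "ppi_pct")
    class_sizes: dict[str, int] = field(default_factory=dict)
    behavior: BehaviorModelConfig = field(default_factory=BehaviorModelConfig)
    outdir: str = "out"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required for reproducibility")
        self.seed = int(self.seed)

    def to_dict(self) -> dict[str, Any]:
        doc = dataclasses.asdict(self)
        doc["readouts"] = list(self.readouts)
        return doc

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=str)

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Any]) -> "RunConfig":
        doc = dict(doc)
        if "seed" not in doc or doc["seed"] is None:
            raise ValueError(
                "config must set an explicit integer 'seed' for reproducibility"
            )
        behavior_doc = doc.pop("behavior", None)
        behavior = BehaviorModelConfig()
        if behavior_doc:
            effects_doc = behavior_doc.pop("drug_effects", None)
            behavior = BehaviorModelConfig(**behavior_doc)
            if effects_doc:
                behavior.drug_effects = {
                    cid: DrugEffect(**eff) for cid, eff in effects_doc.items()
                }
        readouts = doc.pop("readouts", None)
        cfg = cls(behavior=behavior, **doc)
        if readouts is not None:
            cfg.readouts = tuple(readouts)
        return cfg


def load_config(path) -> RunConfig:
    """Load a run configuration from a YAML or JSON file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            doc = json.load(fh)
        else:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_mapping(doc)
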