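"""Run configuration: a serializable record of everything a run needs.

A :class:`RunConfig` round-trips losslessly through dict / JSON / YAML, so
the report emitted by a run is sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import ModelConfig
from .solver import HyperParams


@dataclass
class RunConfig:
    """Full configuration of one command-line run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    k: int = 5
    repeats: int = 1
    seed: int = 0
    x_path: str | None = None
    y_path: str | None = None
    graph_x_path: str | None = None
    graph_y_path: str | None = None
    out_dir: str = "fglgn_out"
    standardize: bool = True
    dialect: str = "labeled_tsv"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        m = dict(d.pop("model", {}))
        hp = HyperParams(**m.pop("hp", {}))
        edges = m.pop("graph_edges", None)
        if edges is not None:
            edges = [(int(i), int(j), float(w)) for i, j, w in edges]
        model = ModelConfig(hp=hp, graph_edges=edges, **m)
        return cls(model=model, **d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
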