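"""Shared configuration and ground-truth containers for the generators."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence


@dataclass(frozen=True)
class SimConfig:
    """Reproducible generator configuration.

    ``groups`` maps a clade name to the taxon labels it contains; taxa may
    not be repeated across clades.  ``params`` holds per-generator rates
    and sizes (probabilities must lie in [0, 1], sizes must be positive).
    """

    seed: int = 0
    groups: Mapping[str, Sequence[str]] = field(default_factory=dict)
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for clade, taxa in self.groups.items():
            for t in taxa:
                if t in seen:
                    raise ValueError(f"duplicate taxon label: {t!r}")
                seen.add(t)
        for key, value in self.params.items():
            if key.endswith(("_prob", "_rate")) and not 0.0 <= value <= 1.0:
                raise ValueError(f"{key}={value} outside [0, 1]")
            if key.endswith(("_length", "_count", "_size", "_depth")) and value <= 0:
                raise ValueError(f"{key}={value} must be positive")

    @property
    def taxa(self) -> list[str]:
        return [t for taxa in self.groups.values() for t in taxa]


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset.

    ``kind`` names the generator; ``data`` is a JSON-serializable record
    of the planted events/columns/pairs/lengths.  Written as a sidecar
    ``*.truth.json`` next to the generated files.
    """

    kind: str
    seed: int
    data: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "data": self.data},
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def read(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(kind=obj["kind"], seed=obj["seed"], data=obj["data"])


def _jsonable(obj):
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
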