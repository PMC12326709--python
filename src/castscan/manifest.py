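"""Machine-readable ground truth for simulated sequencing runs.

The manifest makes every downstream stage testable: it records the seed and
full parameter set, the list of integration events, and a per-read truth
entry for every emitted read. Regenerating with the same parameters and
seed reproduces the manifest byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidArgumentError
from .types import IntegrationEvent


@dataclass
class TruthManifest:
    seed: int
    parameters: dict
    events: list = field(default_factory=list)
    reads: dict = field(default_factory=dict)

    def event_by_id(self, event_id: str) -> IntegrationEvent:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "parameters": self.parameters,
            "events": [ev.to_dict() for ev in self.events],
            "reads": self.reads,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            parameters=d["parameters"],
            events=[IntegrationEvent.from_dict(e) for e in d["events"]],
            reads=d["reads"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        return cls.from_json(Path(path).read_text())

    def validate_against_reads(self, read_ids: list[str]) -> None:
        """Check the read-conservation invariant: emitted ids and manifest
        entries are the same multiset, each appearing exactly once."""
        if len(set(read_ids)) != len(read_ids):
            raise InvalidArgumentError("duplicate read ids in emitted output")
        if set(read_ids) != set(self.reads):
            raise InvalidArgumentError("manifest and emitted read ids differ")
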