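"""Run manifests: everything needed to reproduce a run exactly."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("camtube")
    except Exception:
        return "unknown"


@dataclass
class RunManifest:
    """Inputs, overrides and provenance of one run; JSON round-trippable."""

    command: str
    inputs: dict = field(default_factory=dict)
    parameter_overrides: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    tool_version: str = field(default_factory=_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def write_into(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        self.save(path)
        return path
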