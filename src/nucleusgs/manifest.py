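"""Run manifests: everything needed to replay a run exactly."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunManifest"]


@dataclass
class RunManifest:
    """Config snapshot, seeds and output inventory of one CLI run."""

    command: str
    config: dict
    root_seed: int
    package_version: str
    child_seeds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return self

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "command": self.command,
            "config": self.config,
            "root_seed": self.root_seed,
            "package_version": self.package_version,
            "child_seeds": self.child_seeds,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path
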