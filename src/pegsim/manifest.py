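"""Run manifests: enough provenance to reproduce any simulation stage."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .config import RunConfig

__all__ = ["RunManifest", "write_manifest", "read_manifest"]


@dataclass
class RunManifest:
    stage: str
    seed: int
    config: dict
    outputs: dict[str, str]
    package_version: str = __version__
    started_at: str = ""
    finished_at: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def write_manifest(
    out_dir: Path, stage: str, config: RunConfig, outputs: dict[str, str],
    started_at: float, finished_at: float,
) -> Path:
    manifest = RunManifest(
        stage=stage,
        seed=config.seed,
        config=config.model_dump(),
        outputs=outputs,
        started_at=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime(started_at)),
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime(finished_at)),
    )
    path = Path(out_dir) / "manifest.json"
    path.write_text(manifest.to_json() + "\n")
    return path


def read_manifest(path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
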