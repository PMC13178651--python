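"""Run configuration and output manifests shared by the CLI stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from . import __version__
from .tracks import DEFAULT_COLUMN_MAP, PulseProtocol

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    """Shared configuration: units, column maps, gas preset, protocol, seed.

    Position units are micrometres and times seconds for track tables;
    diameters are millimetres and flows L/min at the interface boundary
    (SI internally).
    """

    gas_preset: str = "body"
    flow_lpm: float = 15.0
    diameter_table: Optional[str] = None
    column_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    position_units: str = "um"
    time_units: str = "s"
    frame_rate: Optional[float] = None
    protocol: PulseProtocol = field(default_factory=PulseProtocol)
    decay_correct: bool = False
    rate_window: tuple[float, float] = (0.0, 5.0)
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "protocol" in data:
            data["protocol"] = PulseProtocol(**data["protocol"])
        if "rate_window" in data:
            data["rate_window"] = tuple(data["rate_window"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["column_map"] = dict(self.column_map)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(
    outdir: str | Path,
    command: str,
    config: RunConfig,
    inputs: list[str],
    outputs: list[str],
) -> Path:
    """Write a JSON manifest sufficient to reproduce the run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "inputs": inputs,
        "outputs": outputs,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
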