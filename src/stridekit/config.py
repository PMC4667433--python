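"""Run configuration shared by the CLI subcommands.

Precedence: command-line flags > config file > defaults.  The config
file is flat YAML/JSON key-value (keys matching the field names).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline knobs.

    gamma : acceptance threshold on the normalized subsequence cost
        (<= 0 means "calibrate from the training walks").
    tau : half-window (frames) for the progression-axis estimate.
    shrinkage : covariance shrinkage weight toward the scaled identity.
    """

    gamma: float = 1.0
    tau: int = 3
    shrinkage: float = 0.1
    frame_rate: float | None = None
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        values: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
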