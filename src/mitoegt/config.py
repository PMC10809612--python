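"""Run configuration: one YAML file, flag overrides, one top-level seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

log = logging.getLogger("mitoegt")


@dataclass
class RunConfig:
    seed: int = 0
    tree: Optional[str] = None
    matrix: Optional[str] = None
    calls: Optional[str] = None
    outdir: str = "mitoegt_out"
    log_level: str = "INFO"
    cost_transfer: float = 1.0
    cost_loss: float = 1.0
    consensus_k: int = 2
    simulator: dict[str, Any] = field(default_factory=dict)
    budsim: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def load(cls, path: Optional[str], **overrides) -> "RunConfig":
        data: dict[str, Any] = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def ensure_outdir(self) -> Path:
        p = Path(self.outdir)
        p.mkdir(parents=True, exist_ok=True)
        return p

    def setup_logging(self) -> None:
        logging.basicConfig(
            level=getattr(logging, self.log_level.upper(), logging.INFO),
            format="%(asctime)s %(name)s %(levelname)s %(message)s",
        )
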