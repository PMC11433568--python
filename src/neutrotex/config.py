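"""Run configuration shared by the CLI subcommands.

Precedence is CLI flags > config file > defaults; every run logs its
resolved configuration so artifacts are reproducible from (inputs, config,
seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import List, Optional

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Parameters governing extraction, retrieval and the noise protocol."""

    w: int = 3
    scales: Optional[List[int]] = None  # None -> resolved from image size
    normalize: bool = True
    eta: int = 100
    exclude_self: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError(f"w must be an odd integer >= 3, got {self.w}")
        if self.eta < 1:
            raise ValueError(f"eta must be >= 1, got {self.eta}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def override(self, **kwargs) -> "RunConfig":
        """New config with any non-None keyword applied on top of this one."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", asdict(self))
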