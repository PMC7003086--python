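"""Run configuration loading with schema checking and manifest round trips."""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .genetics import ConfigurationError

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one seeded run.

    Every stochastic run records its seed and the fully resolved parameter
    set in a manifest, so `manifest + seed` regenerates every output byte-
    identically.
    """

    seed: int = 0
    scheme: Optional[str] = None
    architecture: Optional[str] = None
    promoter: str = "BicC"
    n_replicates: int = 3
    n_progeny: int = 200
    n_collect: int = 10
    out_dir: str = "."
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_progeny < 1:
            raise ConfigurationError("replicate and progeny counts must be >= 1")


_KNOWN = {f.name for f in fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Parse a YAML run config; unknown keys are rejected with a suggestion."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a key-value mapping")
    unknown = sorted(set(raw) - _KNOWN)
    if unknown:
        hints = []
        for key in unknown:
            close = difflib.get_close_matches(key, _KNOWN, n=1)
            hints.append(f"{key!r}" + (f" (did you mean {close[0]!r}?)" if close else ""))
        raise ConfigurationError("unknown config keys: " + ", ".join(hints))
    return RunConfig(**raw)


def write_manifest(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
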