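"""Run configuration: defaults, YAML loading, validation.

A config file supplies any subset of the known keys; command-line flags
override file values; unknown keys are rejected up front so typos cannot
silently fall back to defaults.  The effective configuration is echoed into
every output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    # edge inference
    r_threshold: float = 0.8
    fdr_threshold: float = 0.05
    activity_alpha: float = 0.05
    aucell_top_fraction: float = 0.05
    target_sum: float = 10_000.0
    # annotation
    candidates_k: int = 3
    n_markers: int = 10
    temperature: float = 0.5
    workers: int = 4
    batch_size: int = 4
    explain: bool = True
    prompt_style: str = "neutral"
    strict_candidates: bool = True
    include_marker_edges: bool = False
    backend: str = "mock"
    retries: int = 2
    # shared
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 1 <= self.candidates_k <= 5:
            raise ConfigurationError("candidates_k must be in 1..5")
        if self.prompt_style not in ("neutral", "kg_biased", "llm_biased"):
            raise ConfigurationError(f"unknown prompt_style {self.prompt_style!r}")
        if self.backend not in ("mock", "remote"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")
        if not 0 < self.aucell_top_fraction <= 1:
            raise ConfigurationError("aucell_top_fraction must be in (0, 1]")
        for key in ("r_threshold", "fdr_threshold", "activity_alpha"):
            if not 0 <= getattr(self, key) <= 1:
                raise ConfigurationError(f"{key} must be in [0, 1]")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        values: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(raw, dict):
                raise ConfigurationError(f"{path}: config must be a key-value mapping")
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(raw) - known
            if unknown:
                raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
            values.update(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def echo(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "effective_config.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path
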