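"""Run configuration: schema, validation and manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_validate_config", "run_manifest"]

COMMANDS = ("restore-mci", "restore-mixed", "simulate", "metrics", "diagnostics")

DEFAULTS = {
    "epsilon": 0.99,
    "iters": 6000,
    "burn_in": 4000,
    "seed": 0,
    "kernel": "mala",
    "wavelet": "sym3",
    "levels": 3,
    "variant": "auxv1",
    "delta_L": 0.01,
}


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class RunConfig:
    command: str = "restore-mixed"
    input: str | None = None
    output: str | None = None
    kernel_file: str | None = None
    sigma2: float | None = None
    epsilon: float = DEFAULTS["epsilon"]
    iters: int = DEFAULTS["iters"]
    burn_in: int = DEFAULTS["burn_in"]
    seed: int = DEFAULTS["seed"]
    kernel: str = DEFAULTS["kernel"]
    wavelet: str = DEFAULTS["wavelet"]
    levels: int = DEFAULTS["levels"]
    variant: str = DEFAULTS["variant"]
    delta_L: float = DEFAULTS["delta_L"]
    extra: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        problems = []
        if self.command not in COMMANDS:
            problems.append(f"unknown command {self.command!r}")
        if not 0.0 < self.epsilon < 1.0:
            problems.append(f"epsilon must lie in (0, 1), got {self.epsilon}")
        if self.iters < 1:
            problems.append("iters must be >= 1")
        if not 0 <= self.burn_in < self.iters:
            problems.append(
                f"burn_in ({self.burn_in}) must satisfy 0 <= burn_in < iters ({self.iters})"
            )
        if self.kernel not in ("rw", "mala"):
            problems.append(f"kernel must be 'rw' or 'mala', got {self.kernel!r}")
        if self.variant not in ("auxv1", "auxv2"):
            problems.append(f"variant must be 'auxv1' or 'auxv2', got {self.variant!r}")
        if self.levels < 1:
            problems.append("levels must be >= 1")
        if self.delta_L <= 0:
            problems.append("delta_L must be positive")
        if self.sigma2 is not None and self.sigma2 < 0:
            problems.append("sigma2 must be nonnegative")
        if problems:
            raise ConfigError(problems)
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_validate_config(source: str | Path | dict | None = None, **overrides) -> RunConfig:
    """Build a validated RunConfig from a YAML/JSON file, a dict, or flags.

    Defaults are filled first, then file values, then explicit overrides.
    All violations are reported at once.
    """
    data: dict = {}
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(["config file must contain a mapping"])
    elif isinstance(source, dict):
        data = dict(source)
    data.update({k: v for k, v in overrides.items() if v is not None})
    extra = dict(data.pop("extra", {}) or {})
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    fields = {k: v for k, v in data.items() if k in known}
    extra.update({k: v for k, v in data.items() if k not in known})
    cfg = RunConfig(**fields, extra=extra)
    return cfg.validate()


def run_manifest(
    config: RunConfig, outputs: dict[str, str], base_dir: str | Path | None = None
) -> dict:
    """Reproducibility manifest: config, seed, package version, and a hash
    covering the run parameters plus the *content* of every output file
    (paths are excluded so identical seeded runs hash identically)."""
    from . import __version__

    cfg = config.to_dict()
    volatile = {"input", "output", "kernel_file"}
    hashed_cfg = {k: v for k, v in cfg.items() if k not in volatile}
    content_hashes = {}
    for name, rel in outputs.items():
        p = Path(base_dir) / rel if base_dir is not None else Path(rel)
        if p.exists():
            content_hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    payload = {
        "config": cfg,
        "version": __version__,
        "outputs": outputs,
        "output_hashes": content_hashes,
    }
    digest = hashlib.sha256(
        json.dumps(
            {"config": hashed_cfg, "version": __version__, "outputs": content_hashes},
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()
    payload["manifest_hash"] = digest
    return payload
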