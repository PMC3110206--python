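"""Run configuration: YAML loading, key validation, provenance stamping.

A config file is a nested key-value document; unknown keys are rejected
so typos fail loudly.  Every CLI run writes a provenance JSON (config
snapshot + seed + package version) beside its outputs, and a single
global seed fans out to per-stage seeds by a fixed derivation so each
stage is individually reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import UnknownConfigKey
from .vc_solver import SolverConfig

KNOWN_KEYS = {
    "kernel": {"h"},
    "solver": {
        "lambda2_grid", "n_lambda1", "lambda1_min_ratio", "delta",
        "max_iter", "tol", "max_sweeps", "standardize",
    },
    "cv": {"folds", "h_grid"},
    "modulator": {"correlation_floor", "min_size", "desired_sign"},
    "effects": {"max_path_length", "method", "p_lo", "p_hi"},
    "gsa": {"max_path_length", "bh_family", "use_p"},
}
KNOWN_TOP = set(KNOWN_KEYS) | {"seed", "log_level", "out_dir"}


@dataclass
class RunConfig:
    """Validated configuration tree plus run-level settings."""

    sections: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str | None = None

    def get(self, section: str, key: str, default=None):
        return self.sections.get(section, {}).get(key, default)

    def solver_config(self) -> SolverConfig:
        s = self.sections.get("solver", {})
        kwargs = {}
        if "lambda2_grid" in s:
            kwargs["lambda2_grid"] = tuple(float(v) for v in s["lambda2_grid"])
        for k in ("n_lambda1", "max_iter", "max_sweeps"):
            if k in s:
                kwargs[k] = int(s[k])
        for k in ("lambda1_min_ratio", "delta", "tol"):
            if k in s:
                kwargs[k] = float(s[k])
        if "standardize" in s:
            kwargs["standardize"] = str(s["standardize"])
        return SolverConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise UnknownConfigKey(f"config root must be a mapping, got {type(raw)}")
    sections: dict = {}
    run: dict = {}
    for top, value in raw.items():
        if top not in KNOWN_TOP:
            raise UnknownConfigKey(f"unknown config key {top!r}")
        if top in KNOWN_KEYS:
            if not isinstance(value, dict):
                raise UnknownConfigKey(f"section {top!r} must be a mapping")
            for key in value:
                if key not in KNOWN_KEYS[top]:
                    raise UnknownConfigKey(f"unknown config key {top}.{key}")
            sections[top] = dict(value)
        else:
            run[top] = value
    return RunConfig(
        sections=sections,
        seed=int(run.get("seed", 0)),
        log_level=str(run.get("log_level", "INFO")),
        out_dir=run.get("out_dir"),
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed, stable derivation of a per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def write_provenance(out_path: str | Path, config: RunConfig,
                     stage: str, extra: dict | None = None) -> Path:
    """Write a provenance JSON next to an output file or directory."""
    from . import __version__

    out_path = Path(out_path)
    if out_path.is_dir():
        prov_path = out_path / "provenance.json"
    else:
        prov_path = out_path.with_name(out_path.name + ".provenance.json")
    record = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": config.sections,
    }
    if extra:
        record.update(extra)
    prov_path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return prov_path
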