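"""Run configuration: YAML parsing with validated, defaulted parameter sections."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import DesignParams
from .signals import DetectionParams
from .simulate import SimParams

logger = logging.getLogger(__name__)

VALID_COMMANDS = ("design", "simulate", "analyze", "diff", "profile")

_TOP_KEYS = {"command", "inputs", "outputs", "seed", "log_level",
             "design", "detection", "sim"}


@dataclass
class RunConfig:
    """A fully validated pipeline run configuration."""

    command: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    design: DesignParams = field(default_factory=DesignParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    sim: SimParams = field(default_factory=SimParams)


def _build_section(cls, raw: dict, name: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    return cls(**raw)


def parse_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, filling published defaults.

    Defaults: probe length 25, Tm window 46–64 °C, complexity 10, pure-mode
    SNR thresholds (3, 6) or complex-mode (2, 2), positive fraction 0.65.
    Unknown keys and invariant violations raise with the offending name.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    command = raw.get("command")
    if command not in VALID_COMMANDS:
        raise ValueError(f"command must be one of {VALID_COMMANDS}, got {command!r}")

    seed = int(raw.get("seed", 0))
    design_raw = dict(raw.get("design", {}))
    design_raw.setdefault("seed", seed)
    sim_raw = dict(raw.get("sim", {}))
    sim_raw.setdefault("seed", seed)
    cfg = RunConfig(
        command=command,
        inputs={k: str(v) for k, v in (raw.get("inputs") or {}).items()},
        outputs={k: str(v) for k, v in (raw.get("outputs") or {}).items()},
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        design=_build_section(DesignParams, design_raw, "design"),
        detection=_build_section(DetectionParams, dict(raw.get("detection", {})), "detection"),
        sim=_build_section(SimParams, sim_raw, "sim"),
    )
    for name, p in cfg.inputs.items():
        if not Path(p).exists():
            raise ValueError(f"input '{name}' does not exist: {p}")
    logger.info(
        "config: detection thresholds 25-mer=%.1f composite=%.1f fraction=%.2f (%s mode); "
        "probe length %d, Tm [%.0f, %.0f], complexity >= %d",
        cfg.detection.snr_threshold_25, cfg.detection.snr_threshold_54,
        cfg.detection.positive_fraction, cfg.detection.mode,
        cfg.design.probe_length, cfg.design.tm_min, cfg.design.tm_max,
        cfg.design.complexity_threshold,
    )
    return cfg
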