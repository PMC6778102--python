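"""Flat run configuration: one section per pipeline stage.

Every default equals the value the method fixes where one is fixed
(neighbor count 5, window 11, clamp 2xMAD, essentiality threshold -0.4,
smoothing bandwidth 10 AA, 100 ensemble members, 5% resampling, merge gap
below 3 AA, 10 AA minimum predicted-region length); the remaining knobs
carry the package's own documented defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .calling import CallingParams
from .denoise import DenoiseParams
from .io import DEFAULT_ESSENTIAL_THRESHOLD
from .segmentation import TGUHParams


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


@dataclass
class PredictionConfig:
    n_members: int = 100
    sample_frac: float = 0.05
    kernel: str = "rbf"
    bandwidth: float = 10.0
    merge_gap: int = 2
    min_length: int = 10


@dataclass
class SimulateConfig:
    protein_length: int = 600
    baseline: float = -0.2
    noise_sd: float = 0.4
    sgrna_density: float = 0.5
    inactive_frac: float = 1.0 / 3.0
    outlier_frac: float = 0.02
    outlier_scale: float = 5.0


@dataclass
class RunConfig:
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    tguh: TGUHParams = field(default_factory=TGUHParams)
    calling: CallingParams = field(default_factory=CallingParams)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    essential_threshold: float = DEFAULT_ESSENTIAL_THRESHOLD
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _apply_section(obj, updates: dict, section: str) -> None:
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in updates.items():
        if key not in valid:
            raise ConfigError(f"unknown config key '{section}.{key}'")
        setattr(obj, key, value)
    # re-validate dataclass invariants
    post = getattr(obj, "__post_init__", None)
    if post is not None:
        post()


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file and apply flat overrides.

    Unknown keys raise ConfigError naming the offending key.  Overrides
    use the same nested mapping shape as the file and win over it.
    """
    cfg = RunConfig()
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for source in (data, overrides or {}):
        for section, updates in source.items():
            if not hasattr(cfg, section):
                raise ConfigError(f"unknown config section '{section}'")
            target = getattr(cfg, section)
            if dataclasses.is_dataclass(target):
                if not isinstance(updates, dict):
                    raise ConfigError(f"section '{section}' must be a mapping")
                _apply_section(target, updates, section)
            else:
                setattr(cfg, section, updates)
    return cfg


def setup_logging(level: str = "INFO") -> logging.Logger:
    logger = logging.getLogger("ckhs")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger
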