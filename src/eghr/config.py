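"""Plain-text experiment configuration.

One YAML file describes a full experiment: the rule, the source spec, the
prior, the mixing matrix, the schedule, and the initial weights.  Configs
echo back to disk verbatim next to the run outputs together with the seed
and library versions, so any run can be reproduced bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .learning import Schedule
from .priors import Prior
from .sources import MixingModel, SourceSpec, make_mixing

__all__ = ["ExperimentConfig", "load_config", "PRESETS", "preset_path"]

_PRESET_DIR = Path(__file__).parent / "presets"
PRESETS = ("fig1", "fig3a", "fig3b", "fig4", "fig5", "fig6-synthetic", "fig2-grid")


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Validated experiment description (mirrors the YAML schema)."""

    experiment: str = "train"     # train | velocity_map | grid | images
    rule: str = "eghr"
    source: SourceSpec = field(default_factory=SourceSpec)
    prior: Prior = field(default_factory=lambda: Prior(family="laplace"))
    mixing: MixingModel | None = None
    schedule: Schedule = field(default_factory=Schedule)
    W0: np.ndarray | None = None
    seed: int = 0
    E0: float | None = None
    raw: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def echo(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)


def _parse_number(v):
    # allow "pi/6"-style angles in configs
    if isinstance(v, str):
        ns = {"pi": math.pi}
        return float(eval(v, {"__builtins__": {}}, ns))  # noqa: S307 - arithmetic only
    return float(v)


def load_config(path_or_dict) -> ExperimentConfig:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    try:
        src = SourceSpec(**raw.get("source", {}))
        pr_block = dict(raw.get("prior", {"family": src.family}))
        pr_block.setdefault("family", src.family)
        prior = Prior(**pr_block)
        mix_block = dict(raw.get("mixing", {}))
        mixing = None
        if mix_block:
            kind = mix_block.pop("kind")
            if "theta" in mix_block:
                mix_block["theta"] = _parse_number(mix_block["theta"])
            if "A" in mix_block:
                mix_block["A"] = np.array(mix_block["A"], dtype=float)
            mixing = make_mixing(kind, **mix_block)
        sched = Schedule(**raw.get("schedule", {}))
        W0 = np.array(raw["W0"], dtype=float) if raw.get("W0") is not None else None
        cfg = ExperimentConfig(
            experiment=raw.get("experiment", "train"),
            rule=raw.get("rule", "eghr"),
            source=src, prior=prior, mixing=mixing, schedule=sched,
            W0=W0, seed=int(raw.get("seed", 0)),
            E0=(float(raw["E0"]) if raw.get("E0") is not None else None),
            raw=raw, extra=raw.get("extra", {}),
        )
    except (TypeError, ValueError, KeyError) as err:
        raise ConfigError(f"invalid config: {err}") from err
    if cfg.rule not in ("eghr", "amari", "bell_sejnowski", "cichocki", "linsker", "foldiak"):
        raise ConfigError(f"unknown rule {cfg.rule!r}")
    if cfg.experiment not in ("train", "velocity_map", "grid", "images"):
        raise ConfigError(f"unknown experiment {cfg.experiment!r}")
    return cfg


def preset_path(name: str) -> Path:
    p = _PRESET_DIR / f"{name}.yaml"
    if not p.exists():
        raise ConfigError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    return p
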