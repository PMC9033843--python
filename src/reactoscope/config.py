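"""Experiment configuration: TOML schema, validation, defaults.

The configuration fully determines a run (scenario, cadences, sample,
model, controller, targeting, master seed), so identical config + seed
reproduce identical outputs. Unknown keys are rejected with a suggestion;
cross-field consistency (period divisibility, channel names) is checked
before any acquisition.
"""

from __future__ import annotations

import difflib
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .microscope import CHANNELS

__all__ = ["ExperimentConfig", "validate_config", "load_config", "ConfigError"]

SCENARIOS = ("adaptive_exposure", "characterization", "mpc_comparison",
             "recombination_ring", "recombination_islets")


class ConfigError(ValueError):
    """Raised for invalid experiment configurations, naming the bad key."""


# section -> key -> default (None = required)
_SCHEMA: dict[str, dict[str, object]] = {
    "": {
        "scenario": None,
        "duration_min": 180.0,
        "seed": 0,
        "output_dir": "out",
        "save_images": False,
    },
    "periods": {
        "brightfield_min": 3.0,
        "fluorescence_min": 6.0,
    },
    "positions": {
        "count": 1,
    },
    "channels": {
        "imaging": ["brightfield", "GFP"],
        "exposure_ms": 100.0,
    },
    "sample": {
        "n_cells": 50,
        "image_shape": [256, 256],
        "background_level": 100.0,
        "read_noise_sd": 2.0,
        "shot_noise": True,
        "dye_decay_rate": math.log(2) / 180.0,
        "bleed_psf_sigma": 2.0,
        "intensity_gain": 0.01,
        "initial_dye": 0.0,
        "growth_rate": math.log(2) / 90.0,
        "division_area": 220.0,
        "jitter_px": 0.2,
        "cell_radius_px": 7.0,
    },
    "model": {
        "k": 20.0,
        "b0": 0.5,
        "gamma": math.log(2) / 90.0,
        "tau": 36.0,
        "alpha": 1.0,
        "sigma_meas": 50.0,
        "extrinsic_cv": 0.0,  # lognormal cell-to-cell CV of the induced rate k
        "fsp_truncation": 0,  # 0 = use default_truncation()
    },
    "controller": {
        "target": 3000.0,
        "deadband": 150.0,
        "step": 10.0,
        "e_min": 1.0,
        "e_max": 1000.0,
        "horizon_steps": 4,
        "step_min": 6.0,
        "pulse_ms": 1000.0,
        "n_cells": 100,
        "n_steps": 30,
    },
    "targeting": {
        "ring_center": [128.0, 128.0],
        "ring_inner": 60.0,
        "ring_outer": 90.0,
        "d_min": 60.0,
        "max_new_per_tick": 1,
        "erosion_radius": 2,
        "p_rec": 0.9,
        "p_spont": 0.0,
        "dose_threshold": 100.0,
        "reporter_delay": 24.0,
        "reporter_plateau": 100.0,
        "reporter_ramp_min": 30.0,
        "growth_factor_post": 0.3,
        "threshold": 50.0,
    },
}


@dataclass
class ExperimentConfig:
    """Fully resolved experiment configuration (flat sections of plain values)."""

    scenario: str
    duration_min: float
    seed: int
    output_dir: str
    save_images: bool
    periods: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)
    channels: dict = field(default_factory=dict)
    sample: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    controller: dict = field(default_factory=dict)
    targeting: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min / self.periods["brightfield_min"]))

    def resolved(self) -> dict:
        return {
            "scenario": self.scenario, "duration_min": self.duration_min,
            "seed": self.seed, "output_dir": self.output_dir,
            "save_images": self.save_images,
            "periods": dict(self.periods), "positions": dict(self.positions),
            "channels": dict(self.channels), "sample": dict(self.sample),
            "model": dict(self.model), "controller": dict(self.controller),
            "targeting": dict(self.targeting),
        }


def _reject_unknown(section: str, given: dict, known: dict) -> None:
    for key in given:
        if section == "" and key in _SCHEMA and isinstance(given[key], dict):
            continue
        if key not in known:
            hints = difflib.get_close_matches(
                key, list(known) + (list(_SCHEMA) if section == "" else []), n=1)
            hint = f"; did you mean {hints[0]!r}?" if hints else ""
            where = f"[{section}] " if section else ""
            raise ConfigError(f"unknown key {where}{key!r}{hint}")


def validate_config(raw: dict | str) -> ExperimentConfig:
    """Type-check, default, and cross-validate a raw configuration.

    Accepts a TOML string or an already-parsed mapping. Raises
    :class:`ConfigError` with the offending key on any problem.
    """
    if isinstance(raw, str):
        try:
            raw = tomllib.loads(raw)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"config is not valid TOML: {exc}") from exc
    top = {k: v for k, v in raw.items() if not isinstance(v, dict)}
    _reject_unknown("", raw, _SCHEMA[""])
    resolved_top = dict(_SCHEMA[""])
    resolved_top.update(top)
    if resolved_top["scenario"] is None:
        raise ConfigError("missing required key 'scenario'")
    if resolved_top["scenario"] not in SCENARIOS:
        hints = difflib.get_close_matches(resolved_top["scenario"], SCENARIOS, n=1)
        hint = f"; did you mean {hints[0]!r}?" if hints else ""
        raise ConfigError(f"unknown scenario {resolved_top['scenario']!r}{hint}")
    if resolved_top["duration_min"] < 0:
        raise ConfigError("duration_min must be >= 0")

    sections: dict[str, dict] = {}
    for name, defaults in _SCHEMA.items():
        if name == "":
            continue
        given = raw.get(name, {})
        if not isinstance(given, dict):
            raise ConfigError(f"section [{name}] must be a table")
        _reject_unknown(name, given, defaults)
        merged = dict(defaults)
        merged.update(given)
        sections[name] = merged

    bf = sections["periods"]["brightfield_min"]
    fl = sections["periods"]["fluorescence_min"]
    if bf <= 0 or fl <= 0:
        raise ConfigError("periods must be > 0")
    if abs(fl / bf - round(fl / bf)) > 1e-9:
        raise ConfigError("fluorescence period must be a multiple of the "
                          f"brightfield period (got {fl} vs {bf})")
    dur = resolved_top["duration_min"]
    if dur > 0 and abs(dur / bf - round(dur / bf)) > 1e-9:
        raise ConfigError("brightfield period must divide duration_min")
    for ch in sections["channels"]["imaging"]:
        if ch not in CHANNELS:
            hints = difflib.get_close_matches(ch, CHANNELS, n=1)
            hint = f"; did you mean {hints[0]!r}?" if hints else ""
            raise ConfigError(f"unknown channel {ch!r}{hint}")
    shape = sections["sample"]["image_shape"]
    if len(shape) != 2 or min(shape) < 64:
        raise ConfigError("sample.image_shape must be two values >= 64")
    return ExperimentConfig(
        scenario=resolved_top["scenario"],
        duration_min=float(resolved_top["duration_min"]),
        seed=int(resolved_top["seed"]),
        output_dir=str(resolved_top["output_dir"]),
        save_images=bool(resolved_top["save_images"]),
        periods=sections["periods"], positions=sections["positions"],
        channels=sections["channels"], sample=sections["sample"],
        model=sections["model"], controller=sections["controller"],
        targeting=sections["targeting"],
    )


def load_config(path) -> ExperimentConfig:
    """Read and validate a TOML config file."""
    text = Path(path).read_text()
    return validate_config(text)
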