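"""Run configuration, defaults, and provenance stubs.

A single structured-text (YAML) config file drives the command-line
workflows. Keys carry their units in their names; missing keys fall
back to the reference defaults of the canonical tube configuration,
each fallback logged once. CLI flags override config values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources

import yaml

from . import __version__

__all__ = ["RunConfig", "load_config", "provenance_stub", "default_config_text"]

logger = logging.getLogger(__name__)

_DEFAULTS: dict = {
    "geometry": {"D_m": 0.0127, "h_m": 0.0026, "L_m": 0.0138},
    "fluid": {"nu_m2_s": 1.0e-6, "rho_kg_m3": 1000.0},
    "constitutive": {
        "eta_p_Pa_s": 2.1e4,
        "lambda_s": 6.0,
        "epsilon": 0.01,
        "zeta": 0.0,
    },
    "adhesion": {
        "n_stations": 16,
        "h_b_m": 70.0e-6,
        "phi": 0.8,
        "failure_cap": 148.4131591025766,  # e^5; replaced by calibration
    },
    "criterion": {"displacement_fraction": 0.05, "window_timescales": 10.0},
    "seed": 0,
    "output_dir": "emboclot-out",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (blocks mirror the YAML layout)."""

    geometry: dict = field(default_factory=lambda: dict(_DEFAULTS["geometry"]))
    fluid: dict = field(default_factory=lambda: dict(_DEFAULTS["fluid"]))
    constitutive: dict = field(default_factory=lambda: dict(_DEFAULTS["constitutive"]))
    adhesion: dict = field(default_factory=lambda: dict(_DEFAULTS["adhesion"]))
    criterion: dict = field(default_factory=lambda: dict(_DEFAULTS["criterion"]))
    seed: int = 0
    output_dir: str = "emboclot-out"

    def as_dict(self) -> dict:
        return asdict(self)

    def canonical_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _merge_block(name: str, user: dict | None) -> dict:
    merged = dict(_DEFAULTS[name])
    user = user or {}
    unknown = set(user) - set(merged)
    if unknown:
        raise ValueError(
            f"unknown keys in config block '{name}': {sorted(unknown)}; "
            f"expected keys (units embedded): {sorted(merged)}"
        )
    for key, default in merged.items():
        if key in user:
            merged[key] = user[key]
        else:
            logger.info("config: %s.%s missing, using default %r", name, key, default)
    return merged


def load_config(path: str | None = None) -> RunConfig:
    """Load a YAML config, filling missing keys with reference defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
    known = {"geometry", "fluid", "constitutive", "adhesion", "criterion",
             "seed", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        geometry=_merge_block("geometry", raw.get("geometry")),
        fluid=_merge_block("fluid", raw.get("fluid")),
        constitutive=_merge_block("constitutive", raw.get("constitutive")),
        adhesion=_merge_block("adhesion", raw.get("adhesion")),
        criterion=_merge_block("criterion", raw.get("criterion")),
        seed=int(raw.get("seed", _DEFAULTS["seed"])),
        output_dir=str(raw.get("output_dir", _DEFAULTS["output_dir"])),
    )


def default_config_text() -> str:
    """The packaged reference default config, as YAML text."""
    return resources.files("emboclot.data").joinpath("default_config.yaml").read_text()


def provenance_stub(config: RunConfig, seed: int | None = None,
                    command: str = "") -> dict:
    """Provenance record written next to every artifact."""
    import numpy
    import scipy

    return {
        "package": "emboclot",
        "version": __version__,
        "command": command,
        "config_hash": config.config_hash(),
        "seed": int(config.seed if seed is None else seed),
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
    }
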