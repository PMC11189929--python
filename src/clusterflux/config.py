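"""Configuration and preset loading for the reaction-diffusion model.

Model configs are YAML with blocks ``geometry{R0,R1,R2}``,
``kinetics{k,D,alpha0,beta,c0_star,N_total}``, ``mode{boundary,substrate}``
and ``units{k}``.  The catalytic efficiency may be given either in the
internal unit system (um^3 copies^-1 s^-1, ``units.k: internal``) or as a
conventional kcat/KM in uM^-1 s^-1 (``units.k: per_uM_per_s``), in which case
it is converted through Avogadro's number at load time.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .cluster_model import (
    BasinGeometry,
    KineticParams,
    ValidationError,
    catalytic_efficiency_to_internal,
)

_PRESET_FILE = "presets.yaml"


def _build_kinetics(block: dict, units: dict | None) -> KineticParams:
    units = units or {}
    k = block.get("k")
    if k is None:
        raise ValidationError("kinetics block must define k")
    if units.get("k", "per_uM_per_s") == "per_uM_per_s":
        k = catalytic_efficiency_to_internal(k)
    elif units.get("k") != "internal":
        raise ValidationError(f"unknown k unit {units.get('k')!r}")
    return KineticParams(
        k=float(k),
        D=float(block["D"]),
        alpha0=float(block["alpha0"]),
        beta=float(block["beta"]),
        c0_star=float(block["c0_star"]),
        N_total=float(block["N_total"]),
    )


def _build_geometry(block: dict) -> BasinGeometry:
    return BasinGeometry(
        R1=float(block["R1"]), R2=float(block["R2"]), R0=float(block["R0"])
    )


def load_model_config(path: str | Path) -> dict:
    """Load a solver config; returns geometry, kinetics and mode settings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "geometry" not in raw or "kinetics" not in raw:
        raise ValidationError("config must contain geometry and kinetics blocks")
    mode = raw.get("mode", {}) or {}
    return {
        "geometry": _build_geometry(raw["geometry"]),
        "kinetics": _build_kinetics(raw["kinetics"], raw.get("units")),
        "boundary": mode.get("boundary", "zero_flux"),
        "substrate_mode": mode.get("substrate", "full"),
    }


def _read_presets() -> dict:
    text = resources.files("clusterflux").joinpath(_PRESET_FILE).read_text()
    return yaml.safe_load(text)


def load_preset(name: str) -> tuple[BasinGeometry, KineticParams]:
    """Bundled geometry/kinetics presets (``in_vivo`` and ``in_vitro``)."""
    presets = _read_presets()
    if name not in presets:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    block = presets[name]
    return (
        _build_geometry(block["geometry"]),
        _build_kinetics(block["kinetics"], block.get("units")),
    )
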