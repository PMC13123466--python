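"""Configuration loading, serialisation and run manifests.

Configs are human-editable YAML with sections (``fluid``, ``worm``,
``behavior``, ``geometry``, ``sim``, ``measurements``); every physical
quantity may carry an explicit unit suffix ("0.5 mm/s"), parsed at the
boundary into strict SI.  Serialisation writes plain SI numbers, so
parse -> serialize -> parse is the identity.

Every CLI run writes exactly one manifest recording the full config echo
(defaults included), the seed, package/library versions, and SHA-256
hashes of the produced files.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import time
from pathlib import Path

import numpy as np
import scipy
import yaml

from . import __version__
from .errors import InvalidInputError
from .flow import SorterGeometry, build_geometry
from .physics import BehaviorParams, FluidMedium, WormBody
from .units import to_si

_FLUID_DIMS = {"density": "density", "dynamic_viscosity": "viscosity", "viscosity": "viscosity"}
_WORM_DIMS = {"volume": "volume", "density": "density", "stokes_radius": "length"}
_BEHAVIOR_DIMS = {
    "thrust_magnitude": "force",
    "thrust": "force",
    "reorientation_time": "time",
    "gait_frequency": "frequency",
}


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config root in {path} must be a mapping")
    return raw


def dump_config(config: dict, path) -> None:
    """Write a config of plain SI numbers (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _section(raw: dict, name: str) -> dict:
    sec = raw.get(name, {})
    if not isinstance(sec, dict):
        raise InvalidInputError(f"config section {name!r} must be a mapping")
    return sec


def fluid_from(raw: dict) -> FluidMedium:
    sec = _section(raw, "fluid")
    kwargs = {"label": str(sec.get("label", ""))}
    for key in ("density", "dynamic_viscosity", "viscosity"):
        if key in sec:
            target = "dynamic_viscosity" if key == "viscosity" else key
            kwargs[target] = to_si(sec[key], _FLUID_DIMS[key])
    missing = {"density", "dynamic_viscosity"} - set(kwargs)
    if missing:
        raise InvalidInputError(f"fluid section is missing {sorted(missing)}")
    return FluidMedium(**kwargs)


def worm_from(raw: dict) -> WormBody:
    sec = _section(raw, "worm")
    kwargs = {}
    for key, dim in _WORM_DIMS.items():
        if key in sec:
            kwargs[key] = to_si(sec[key], dim)
    missing = {"volume", "density"} - set(kwargs)
    if missing:
        raise InvalidInputError(f"worm section is missing {sorted(missing)}")
    return WormBody(**kwargs)


def behavior_from(raw: dict) -> BehaviorParams:
    sec = dict(_section(raw, "behavior"))
    kwargs = {}
    if "mode" in sec:
        kwargs["mode"] = str(sec.pop("mode"))
    if "reorientation_scheme" in sec:
        kwargs["reorientation_scheme"] = str(sec.pop("reorientation_scheme"))
    sec.pop("label", None)
    for key, value in sec.items():
        if key not in _BEHAVIOR_DIMS:
            raise InvalidInputError(f"unknown behavior key {key!r}")
        target = "thrust_magnitude" if key == "thrust" else key
        kwargs[target] = to_si(value, _BEHAVIOR_DIMS[key])
    return BehaviorParams(**kwargs)


def geometry_from(raw: dict) -> SorterGeometry:
    return build_geometry(_section(raw, "geometry"))


def echo_config(**objects) -> dict:
    """Flatten dataclasses into a plain-SI dict (defaults made explicit)."""
    out = {}
    for name, obj in objects.items():
        if obj is None:
            continue
        if hasattr(obj, "__dataclass_fields__"):
            out[name] = {
                k: getattr(obj, k)
                for k in obj.__dataclass_fields__
                if not hasattr(getattr(obj, k), "__dataclass_fields__")
            }
        else:
            out[name] = obj
    return out


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_manifest(
    out_dir,
    command: str,
    config_echo: dict,
    seed,
    outputs: list,
    started: float,
) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config_echo,
        "versions": {
            "taxisort": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "outputs": {str(p): sha256_file(p) for p in outputs},
        "wall_time_s": round(time.time() - started, 3),
    }
    path = out_dir / f"{command}_manifest.json"
    atomic_write_text(path, json.dumps(manifest, indent=2, default=str) + "\n")
    return path
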