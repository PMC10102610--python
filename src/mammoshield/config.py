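"""YAML configuration: one document describing materials, phantom, screens,
source, transport and tally options for a study run."""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources

import yaml

from . import materials as mat
from . import transport as tp
from .study import PhantomSpec, ScreenSpec


def default_config() -> dict:
    """The fully-worked default study configuration (shipped as YAML)."""
    with resources.files("mammoshield").joinpath("data/default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path=None) -> dict:
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = copy.deepcopy(v)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def library_from_config(cfg: dict) -> mat.MaterialLibrary:
    """Default library plus any material overrides from the config."""
    lib = mat.default_library()
    for entry in (cfg.get("materials") or {}).get("overrides") or []:
        name = entry["name"]
        density = float(entry["density"])
        provenance = entry.get("provenance", "config override")
        if "oxides" in entry:
            lib.register(mat.Material.from_oxides(name, density, entry["oxides"], provenance))
        else:
            lib.register(mat.Material.from_percents(name, density, entry["composition"], provenance))
    return lib


def phantom_from_config(cfg: dict) -> PhantomSpec:
    p = cfg["phantom"]
    return PhantomSpec(
        breast_size=tuple(p["breast_size_cm"]),
        skin_thickness=float(p["skin_thickness_cm"]),
        gap=float(p["gap_cm"]),
        layer_materials=tuple(p["layer_materials"]),
        body_size=tuple(p["body_size_cm"]),
        body_material=p["body_material"],
        source_image_distance=float(p["source_image_distance_cm"]),
        world_material=p["world_material"],
    )


def screen_specs_from_config(cfg: dict) -> dict:
    s = cfg["screen"]
    out = {}
    for name in s["options"]:
        out[name] = None if name in (None, "none") else ScreenSpec(
            name, tuple(s["face_cm"]), float(s["thickness_cm"]))
    return out


def transport_from_config(cfg: dict) -> tp.TransportConfig:
    t = cfg["transport"]
    return tp.TransportConfig(
        cutoff_keV=float(t["cutoff_keV"]),
        coherent_enabled=bool(t["coherent_enabled"]),
        max_interactions=int(t["max_interactions"]),
    )
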