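"""YAML configuration for model, filter and protocol.

File conventions: lengths in metres, angles in degrees (converted to radians
on load), torque coefficients on radian-based angles, times in seconds.  Any
omitted section or key falls back to the package default, so a configuration
file only needs to state what it overrides.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import yaml

from . import dynamics as dyn
from . import kinematics as kin
from . import muscle as mus
from . import simulation as sim


def _merge(base: dict, override: dict | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            out[key] = _merge(base[key], val)
        else:
            out[key] = val
    return out


def geometry_to_dict(geometry: kin.LowerLimbGeometry) -> dict:
    ax = geometry.axis
    return {
        "ankle_axis": {
            "alpha_tc_tla_deg": ax.alpha_tc_tla_deg,
            "alpha_tc_fml_deg": ax.alpha_tc_fml_deg,
            "x_trans": ax.x_trans,
            "y_trans": ax.y_trans,
        },
        "thigh_length": geometry.thigh_length,
        "shank_length": geometry.shank_length,
        "joint_ranges_deg": {
            j: [math.degrees(v) for v in getattr(geometry.ranges, j)]
            for j in ("hip", "knee", "ankle")
        },
        "muscle_paths": {
            name: {
                "points": [
                    {"frame": f, "xyz": [float(v) for v in p]}
                    for f, p in path.points
                ],
                "effective_origin": path.effective_origin,
                "effective_contact": path.effective_contact,
                "pennation_deg": path.pennation_deg,
                "joints": list(path.joints),
            }
            for name, path in geometry.paths.items()
        },
    }


def geometry_from_dict(cfg: dict | None) -> kin.LowerLimbGeometry:
    base = geometry_to_dict(kin.LowerLimbGeometry())
    cfg = _merge(base, cfg)
    axis = kin.AnkleAxisGeometry(**cfg["ankle_axis"])
    ranges = kin.JointRanges(
        **{
            j: tuple(math.radians(v) for v in cfg["joint_ranges_deg"][j])
            for j in ("hip", "knee", "ankle")
        }
    )
    paths = {
        name: kin.MusclePath(
            name=name,
            points=[(pt["frame"], pt["xyz"]) for pt in entry["points"]],
            effective_origin=entry["effective_origin"],
            effective_contact=entry["effective_contact"],
            pennation_deg=entry["pennation_deg"],
            joints=tuple(entry["joints"]),
        )
        for name, entry in cfg["muscle_paths"].items()
    }
    return kin.LowerLimbGeometry(
        axis=axis,
        paths=paths,
        ranges=ranges,
        thigh_length=cfg["thigh_length"],
        shank_length=cfg["shank_length"],
    )


def model_from_dict(cfg: dict | None) -> dyn.LowerExtremityModel:
    cfg = cfg or {}
    geometry = geometry_from_dict(cfg.get("geometry"))
    muscles = mus.default_muscle_params()
    for name, override in (cfg.get("muscles") or {}).items():
        muscles[name] = dataclasses.replace(muscles[name], **override)
    segments = dyn.SegmentParams()
    for seg_name, override in (cfg.get("segments") or {}).items():
        seg = getattr(segments, seg_name)
        setattr(segments, seg_name, dataclasses.replace(seg, **override))
    passive = dyn.PassiveTorqueParams(**(cfg.get("passive") or {}))
    return dyn.LowerExtremityModel(
        geometry=geometry,
        muscles=muscles,
        segments=segments,
        passive=passive,
        gravity=cfg.get("gravity", dyn.GRAVITY),
        tendon_ratio=cfg.get("tendon_ratio", 0.5),
        norm_length_neutral=cfg.get("norm_length_neutral", 0.85),
    )


def filter_from_dict(cfg: dict | None) -> sim.FilterConfig:
    return sim.FilterConfig(**(cfg or {}))


def protocol_from_dict(cfg: dict | None) -> sim.Protocol:
    cfg = dict(cfg or {})
    blocks = cfg.pop("blocks", None)
    noise = cfg.pop("noise", None)
    protocol = sim.Protocol(**cfg)
    if blocks is not None:
        protocol.blocks = [sim.ActivationBlock(**b) for b in blocks]
    if noise is not None:
        protocol.noise = dataclasses.replace(protocol.noise, **noise)
    return protocol


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def load_model(path: str | Path | None = None) -> dyn.LowerExtremityModel:
    cfg = load_config(path)
    return model_from_dict(cfg.get("model"))


def load_protocol(path: str | Path | None = None) -> sim.Protocol:
    cfg = load_config(path)
    return protocol_from_dict(cfg.get("protocol"))


def load_filter(path: str | Path | None = None) -> sim.FilterConfig:
    cfg = load_config(path)
    return filter_from_dict(cfg.get("filter"))


def dump_default_config(path: str | Path) -> None:
    """Write the complete default configuration for editing."""
    cfg = {
        "model": {
            "geometry": geometry_to_dict(kin.LowerLimbGeometry()),
            "muscles": {
                name: dataclasses.asdict(p)
                for name, p in mus.default_muscle_params().items()
            },
            "segments": {
                s: dataclasses.asdict(getattr(dyn.SegmentParams(), s))
                for s in ("thigh", "shank", "foot")
            },
            "passive": dataclasses.asdict(dyn.PassiveTorqueParams()),
            "gravity": dyn.GRAVITY,
            "tendon_ratio": 0.5,
            "norm_length_neutral": 0.85,
        },
        "filter": dataclasses.asdict(sim.FilterConfig()),
        "protocol": {
            **{
                k: v
                for k, v in dataclasses.asdict(sim.Protocol()).items()
                if k not in ("blocks", "noise")
            },
            "blocks": [dataclasses.asdict(b) for b in sim.default_blocks()],
            "noise": dataclasses.asdict(sim.NoiseScales()),
        },
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
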