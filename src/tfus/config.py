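"""YAML configuration loading.

A single YAML file can carry the blocks ``sonication:``, ``transducer:``
and ``skull_mapping:``; each block maps onto the corresponding domain
object.  The sonication block accepts exactly one amplitude key among
``ispta_w_cm2``, ``isppa_w_cm2`` and ``pr_kpa``.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .skull_model import PropertyMapping
from .sonication import InvalidParameterError, MediumConstants, PulseTrain
from .transducer import TransducerGeometry

__all__ = ["load_config", "pulse_train_from_config", "transducer_from_config", "mapping_from_config"]

_AMPLITUDE_KEYS = {"ispta_w_cm2": "ispta_w_cm2", "isppa_w_cm2": "isppa_w_cm2", "pr_kpa": "pr_pa"}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def pulse_train_from_config(block: dict) -> PulseTrain:
    present = [k for k in _AMPLITUDE_KEYS if k in block]
    if len(present) != 1:
        raise InvalidParameterError(
            f"sonication block needs exactly one of {sorted(_AMPLITUDE_KEYS)}, got {present}"
        )
    key = present[0]
    amplitude = float(block[key])
    if key == "pr_kpa":
        amplitude *= 1e3
    return PulseTrain(
        fundamental_frequency=float(block["ff_hz"]),
        pulse_duration=float(block["pd_s"]),
        pulse_repetition_frequency=float(block["prf_hz"]),
        sonication_duration=float(block["duration_s"]),
        amplitude=amplitude,
        amplitude_kind=_AMPLITUDE_KEYS[key],
    )


def transducer_from_config(block: dict) -> TransducerGeometry:
    return TransducerGeometry(
        aperture_diameter=float(block.get("aperture_diameter_mm", 28.0)) * 1e-3,
        curvature_radius=float(block.get("curvature_radius_mm", 22.0)) * 1e-3,
        position=tuple(float(v) * 1e-3 for v in block.get("position_mm", (0, 0, 0))),
        axis=tuple(float(v) for v in block.get("axis", (0, 0, 1))),
    )


def mapping_from_config(block: dict) -> PropertyMapping:
    kwargs = {}
    simple = (
        "soft_threshold_hu",
        "hu_max",
        "bone_density",
        "bone_speed",
        "alpha_water",
        "alpha_soft",
        "alpha_bone_min",
        "alpha_bone_max",
        "beta",
        "reference_frequency",
    )
    for key in simple:
        if key in block:
            kwargs[key] = float(block[key])
    if "water" in block:
        kwargs["water"] = MediumConstants(**block["water"])
    if "soft" in block:
        kwargs["soft"] = MediumConstants(**block["soft"])
    return PropertyMapping(**kwargs)
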