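"""YAML/JSON parameter configuration.

Keys mirror the conventional reporting names of the model parameters
(CL, V0, MTT, FOOD_MTT, VLMAX, VLA50, NTR, KGUT, KOUT, S, AGE_SLOPE,
AGE50, RUV_EARLY, RUV_LATE, RUV_RATE, RUV_ADD, IIV_CL, IIV_V0, IIV_MTT,
FU, KB).  Concentration I/O is fixed to ng/mL; amounts are mg.
"""

from __future__ import annotations

import json

import yaml

from .model import PopulationParameters

__all__ = ["load_params", "save_params", "params_to_dict", "params_from_dict"]

_KEYMAP = {
    "CL": "CL", "V0": "V0", "MTT": "MTT", "FOOD_MTT": "FOOD_MTT",
    "VLMAX": "VLmax", "VLA50": "VL_A50", "NTR": "Ntr", "KGUT": "Kgut",
    "KOUT": "Kout", "S": "S", "AGE_SLOPE": "AGE_slope", "AGE50": "AGE50",
    "WT_REF": "WT_ref", "WT_V0": "WT_V0_exp",
    "RUV_EARLY": "RUV_early", "RUV_LATE": "RUV_late",
    "RUV_RATE": "RUV_rate", "RUV_ADD": "RUV_add",
    "IIV_CL": "omega_CL", "IIV_V0": "omega_V0", "IIV_MTT": "omega_MTT",
    "FU": "fu", "KB": "Kb", "FOOD_MODE": "food_effect_mode",
}
_INVMAP = {v: k for k, v in _KEYMAP.items()}


def params_from_dict(data: dict) -> PopulationParameters:
    kwargs = {}
    for key, value in data.items():
        name = _KEYMAP.get(str(key).upper())
        if name is None:
            raise KeyError(f"unknown parameter key {key!r}")
        kwargs[name] = value
    return PopulationParameters(**kwargs)


def params_to_dict(theta: PopulationParameters) -> dict:
    return {_INVMAP[f]: getattr(theta, f) for f in _INVMAP}


def load_params(path) -> PopulationParameters:
    """Read a YAML or JSON parameter file (keys as in the module doc)."""
    with open(path) as fh:
        text = fh.read()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    return params_from_dict(data or {})


def save_params(theta: PopulationParameters, path) -> None:
    data = params_to_dict(theta)
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)
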