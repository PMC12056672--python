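"""Configuration: a single YAML file drives thermal parameters, crop and
density effects, engine switches and DE settings.

Schema (units in comments; ``bemipop config --write`` emits this template):

    seed: 0                      # global random seed
    survival_mode: power         # power: S=(1-m)^r | product: S=(1-m)*r
    adult_lethal_kill: false     # kill adults outside (LLT, ULT)?
    planting_offset: 17          # days from planting to first monitoring day
    extinction_eps: 1.0e-6       # cohort removal threshold (individuals)
    lethal: {LLT: 4.0, ULT: 36.0}            # lethal temperatures, degC
    stages:                      # per immature stage
      egg:
        TL: 10.0                 # lower developmental threshold, degC
        TU: 35.0                 # upper developmental threshold, degC
        dev_form: briere1        # development-rate form (registry name)
        dev_params: [1.1e-4]     # its parameters
        mort_form: quadratic     # mortality form
        mort_params: [0.02, 27.0, 0.001]   # (m_min, T_opt degC, curvature)
      nymph: {...}
      pupa: {...}
    adult:
      sex_ratio: 0.5             # fraction female
      repro_T_range: [4.0, 36.0] # egg-production range, degC
      ovi_form: briere1
      ovi_params: [4.4e-5]       # oviposition-rate parameters (day^-1 scale)
      cap_form: gaussian
      cap_params: [160.0, 27.0, 6.0]  # (eggs/female, T_opt degC, sigma degC)
      sen_form: linear
      sen_params: [-0.018, 0.0045]    # senescence rate a + b*T (day^-1)
    crop:
      K: 0.01                    # density-dependence strength (per nymph)
      cs_form: hill
      cs_params: [90.0, 4.0]     # (half-decline day, shape)
    de:                          # differential-evolution settings
      pop_size: null             # null -> 10 x dimension
      F: 0.8
      CR: 0.9
      max_generations: 500
      tol: 1.0e-8
      patience: 50
    weights: {adult: 1.0, nymph: 1.0}   # per-stage RSS weights

The shipped default parameter values are placeholders giving realistic
tropical whitefly dynamics; they are not calibrated to laboratory data.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Any, Dict, Optional

import yaml

from .cohorts import EngineConfig
from .fitting import DESettings
from .thermal import (AdultParams, CropParams, LethalLimits, StageParams,
                      default_adult_params, default_stage_params)


def default_config_dict() -> Dict[str, Any]:
    """The full default configuration as a plain dict (YAML-serialisable)."""
    stages = {}
    for name, sp in default_stage_params().items():
        stages[name] = {
            "TL": sp.TL, "TU": sp.TU,
            "dev_form": sp.dev_form, "dev_params": list(sp.dev_params),
            "mort_form": sp.mort_form, "mort_params": list(sp.mort_params),
        }
    ap = default_adult_params()
    return {
        "seed": 0,
        "survival_mode": "power",
        "adult_lethal_kill": False,
        "planting_offset": 17,
        "extinction_eps": 1e-6,
        "lethal": {"LLT": 4.0, "ULT": 36.0},
        "stages": stages,
        "adult": {
            "sex_ratio": ap.sex_ratio,
            "repro_T_range": list(ap.repro_T_range),
            "ovi_form": ap.ovi_form, "ovi_params": list(ap.ovi_params),
            "cap_form": ap.cap_form, "cap_params": list(ap.cap_params),
            "sen_form": ap.sen_form, "sen_params": list(ap.sen_params),
        },
        "crop": {"K": 0.01, "cs_form": "hill", "cs_params": [90.0, 4.0]},
        "de": {"pop_size": None, "F": 0.8, "CR": 0.9,
               "max_generations": 500, "tol": 1e-8, "patience": 50},
        "weights": {"adult": 1.0, "nymph": 1.0},
    }


def engine_config_from_dict(cfg: Dict[str, Any]) -> EngineConfig:
    """Validate and build the engine configuration from a config dict."""
    base = default_config_dict()
    known = set(base)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    merged = {**base, **cfg}

    stage_params = {}
    for name, sd in merged["stages"].items():
        stage_params[name] = StageParams(
            stage_name=name, TL=float(sd["TL"]), TU=float(sd["TU"]),
            dev_form=sd.get("dev_form", "briere1"),
            dev_params=tuple(sd.get("dev_params", ())),
            mort_form=sd.get("mort_form", "quadratic"),
            mort_params=tuple(sd.get("mort_params", ())))
    missing = {"egg", "nymph", "pupa"} - set(stage_params)
    if missing:
        raise ValueError(f"config missing stage block(s): {sorted(missing)}")

    ad = merged["adult"]
    adult = AdultParams(
        sex_ratio=float(ad["sex_ratio"]),
        repro_T_range=tuple(float(v) for v in ad["repro_T_range"]),
        ovi_form=ad.get("ovi_form", "briere1"),
        ovi_params=tuple(ad.get("ovi_params", ())),
        cap_form=ad.get("cap_form", "gaussian"),
        cap_params=tuple(ad.get("cap_params", ())),
        sen_form=ad.get("sen_form", "linear"),
        sen_params=tuple(ad.get("sen_params", ())))

    le = merged["lethal"]
    cr = merged["crop"]
    return EngineConfig(
        stage_params=stage_params, adult_params=adult,
        lethal=LethalLimits(float(le["LLT"]), float(le["ULT"])),
        crop=CropParams(K=float(cr["K"]), cs_form=cr.get("cs_form", "hill"),
                        cs_params=tuple(cr.get("cs_params", (90.0, 4.0)))),
        survival_mode=merged["survival_mode"],
        adult_lethal_kill=bool(merged["adult_lethal_kill"]),
        planting_offset=int(merged["planting_offset"]),
        extinction_eps=float(merged["extinction_eps"]))


def de_settings_from_dict(cfg: Dict[str, Any],
                          seed: Optional[int] = None) -> DESettings:
    d = {**default_config_dict()["de"], **cfg.get("de", {})}
    if seed is None:
        seed = int(cfg.get("seed", 0))
    pop = d["pop_size"]
    return DESettings(pop_size=None if pop is None else int(pop),
                      F=float(d["F"]), CR=float(d["CR"]),
                      max_generations=int(d["max_generations"]),
                      tol=float(d["tol"]), patience=int(d["patience"]),
                      seed=seed)


def load_config(path) -> Dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    engine_config_from_dict(cfg)  # validate eagerly
    return cfg


def dump_default_config(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(default_config_dict(), fh, sort_keys=False)
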