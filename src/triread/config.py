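"""Configuration: full-scale defaults, the desk-scale preset, YAML IO.

Every standard default is present and overridable: layer sizes (364 O /
200 P / 2,446 S, 500/500/300/300 hidden, 50-unit attractors, 4-unit
context via 10 hidden units), the 40/40/10/10 oral task mixture, the
75/25 - 50/50 - 25/75 reading exposures, learning rate 0.05, 8/12
trial timesteps and the 2M/1M trial budgets.  The ``scaled`` preset
substitutes the desk-scale study conditions (200-word lexicon,
~1/5-size layers, 50k oral / 30k reading trials).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .lexicon import EncodingSpec, Lexicon, LexiconParams, generate_lexicon
from .netcore import NetworkTopology
from .training import ORAL_MIXTURE, RegimenSpec

__all__ = ["default_config", "scaled_config", "load_config",
           "build_spec", "build_lexicon", "build_topology",
           "build_regimens"]


def default_config() -> dict:
    return {
        "lexicon": {
            "n_words": 200,
            "family_size_range": [3, 6],
            "prop_inconsistent": 0.3,
            "deviant_fraction": 0.34,
            "semantic_dim": 2446,
            "n_active_range": [5, 12],
            "n_homophone_families": 8,
            "homophone_family_size": 2,
            "zipf_exponent": 1.0,
            "encoding": "full",  # 14x26 letter slots, 8x25 phoneme slots
        },
        "topology": {
            "hidden_op": 500, "hidden_os": 500,
            "hidden_ps": 300, "hidden_sp": 300,
            "attractor": 50, "context": 4, "hidden_ctx": 10,
        },
        "training": {
            "learning_rate": 0.05,
            "oral_trials": 2_000_000,
            "reading_trials": 1_000_000,
            "oral_mixture": dict(ORAL_MIXTURE),
            "exposures": {"OP-focused": [0.75, 0.25],
                          "OP-OS balanced": [0.5, 0.5],
                          "OS-focused": [0.25, 0.75]},
            "oral_timesteps": 8,
            "reading_timesteps": 12,
            "share_oral_phase": True,
            "dtype": "float32",
        },
        "evaluation": {"frequency_compression": "log"},
        "analysis": {"sd_multiplier": 3.0, "discard_ceiling": 0.2},
    }


def scaled_config() -> dict:
    """Desk-scale preset: compact encoding, ~1/5-size layers, 50k oral
    and 30k reading trials."""
    cfg = default_config()
    cfg["lexicon"]["semantic_dim"] = 150
    cfg["lexicon"]["encoding"] = "scaled"
    cfg["topology"].update({"hidden_op": 100, "hidden_os": 100,
                            "hidden_ps": 60, "hidden_sp": 60,
                            "attractor": 10})
    # online updates at the full-scale rate oscillate at desk scale, so
    # the preset uses a cooler rate (full-scale default remains 0.05)
    cfg["training"].update({"oral_trials": 50_000,
                            "reading_trials": 30_000,
                            "learning_rate": 0.02})
    return cfg


def _deep_update(base: dict, over: dict) -> dict:
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path=None, scaled: bool = False,
                overrides: dict | None = None) -> dict:
    cfg = scaled_config() if scaled else default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, copy.deepcopy(overrides))
    return cfg


def build_spec(cfg: dict) -> EncodingSpec:
    lx = cfg["lexicon"]
    if lx["encoding"] == "scaled":
        return EncodingSpec.scaled(semantic_dim=lx["semantic_dim"])
    return EncodingSpec(semantic_dim=lx["semantic_dim"])


def build_lexicon(cfg: dict, seed: int = 0) -> Lexicon:
    lx = cfg["lexicon"]
    params = LexiconParams(
        n_words=lx["n_words"],
        family_size_range=tuple(lx["family_size_range"]),
        prop_inconsistent=lx["prop_inconsistent"],
        deviant_fraction=lx["deviant_fraction"],
        semantic_dim=lx["semantic_dim"],
        n_active_range=tuple(lx["n_active_range"]),
        n_homophone_families=lx["n_homophone_families"],
        homophone_family_size=lx["homophone_family_size"],
        zipf_exponent=lx["zipf_exponent"],
        spec=build_spec(cfg))
    return generate_lexicon(params, seed=seed)


def build_topology(cfg: dict) -> NetworkTopology:
    t = cfg["topology"]
    return NetworkTopology.triangle(
        build_spec(cfg), hidden_op=t["hidden_op"], hidden_os=t["hidden_os"],
        hidden_ps=t["hidden_ps"], hidden_sp=t["hidden_sp"],
        attractor=t["attractor"], context=t["context"],
        hidden_ctx=t["hidden_ctx"])


def build_regimens(cfg: dict, seeds) -> list[RegimenSpec]:
    tr = cfg["training"]
    out = []
    for seed in seeds:
        for name, (p_op, p_os) in tr["exposures"].items():
            out.append(RegimenSpec(
                name=name, p_op=p_op, p_os=p_os,
                reading_trials=tr["reading_trials"],
                oral_trials=tr["oral_trials"],
                oral_mixture=tuple(tr["oral_mixture"].items()),
                seed=int(seed)))
    return out
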