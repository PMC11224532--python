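"""The desk-scale replication study, end to end.

This module packages the full experimental protocol at desk scale: build
the synthetic quasi-regular lexicon, train the cohort of models (three
instructional regimens x several initial-weight seeds), measure semantic
reliance and polarity per model, and run the cleaning and statistical
analyses.  It also provides the independent numerical checks used to
validate the simulator itself (a finite-difference gradient oracle on
random small recurrent networks).

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import netcore
from .config import build_lexicon, build_regimens, build_topology, \
    scaled_config
from .experiments import (clean_trials, factorial_sr_test,
                          polarity_by_sr_summary, regression_sr_test,
                          run_cohort, sr_regimen_regression)

__all__ = ["run_scaled_study", "gradient_oracle_max_rel_err",
           "random_recurrent_network", "STUDY_N_SEEDS"]

#: Initial-weight seeds per regimen in the desk-scale cohort.
STUDY_N_SEEDS = 7

_ORDER = ("OP-focused", "OP-OS balanced", "OS-focused")


def run_scaled_study(seed: int = 1, n_seeds: int = STUDY_N_SEEDS,
                     progress=None) -> dict:
    """Train the scaled cohort and run every analysis.

    Returns a dict with the lexicon, per-model records, the raw and
    cleaned trial tables, SR group means and pairwise one-sided
    Mann-Whitney tests, the regimen regression, both mixed-model
    analyses, the polarity/SR summary and the per-model consistency
    checks.
    """
    seed = int(seed)
    cfg = scaled_config()
    lexicon = build_lexicon(cfg, seed=seed)
    topology = build_topology(cfg)
    regimens = build_regimens(
        cfg, seeds=[(seed * 1000 + i) % (2 ** 31) for i in range(n_seeds)])
    records, trials = run_cohort(
        lexicon, regimens, topology=topology,
        learning_rate=cfg["training"]["learning_rate"],
        share_oral_phase=cfg["training"]["share_oral_phase"],
        progress=progress)
    deviant = {e.word_id: bool(e.tags.get("deviant", False))
               for e in lexicon}
    trials["deviant"] = trials["word_id"].map(deviant)
    cleaned = clean_trials(trials,
                           sd_multiplier=cfg["analysis"]["sd_multiplier"])

    sr_means = records.groupby("regimen")["sr"].mean() \
        .reindex(list(_ORDER)).to_dict()
    mw = {}
    for hi, lo in (("OS-focused", "OP-OS balanced"),
                   ("OP-OS balanced", "OP-focused"),
                   ("OS-focused", "OP-focused")):
        u, p = mannwhitneyu(records.loc[records.regimen == hi, "sr"],
                            records.loc[records.regimen == lo, "sr"],
                            alternative="greater")
        mw[f"{hi} > {lo}"] = {"U": float(u), "p": float(p)}

    regimen_regression = sr_regimen_regression(records)
    factorial_effects, factorial_info = factorial_sr_test(cleaned)
    regression_effects, regression_info = regression_sr_test(cleaned)
    _, polarity = polarity_by_sr_summary(records)

    return {
        "seed": seed,
        "config": cfg,
        "lexicon": lexicon,
        "records": records,
        "trials": trials,
        "cleaned": cleaned,
        "sr_means": sr_means,
        "mannwhitney": mw,
        "regimen_regression": regimen_regression,
        "factorial_effects": factorial_effects,
        "factorial_info": factorial_info,
        "regression_effects": regression_effects,
        "regression_info": regression_info,
        "polarity": polarity,
        "consistency_by_model": _consistency_checks(cleaned),
    }


def _consistency_checks(cleaned: pd.DataFrame) -> dict:
    """Per-model consistency effects on cleaned trials.

    ``exception``: mean SSE of exception words (deviant family members,
    the *pint*-type items) minus consistent-family words.
    ``family``: the family-level version (all members of inconsistent
    families count as inconsistent).
    """
    out = {}
    sub = cleaned[cleaned["deviant"] | cleaned["consistent"]]
    exc = sub.groupby(["model_id", "deviant"])["phon_sse"].mean() \
        .unstack()
    out["exception"] = (exc[True] - exc[False]).to_dict()
    fam = cleaned.groupby(["model_id", "consistent"])["phon_sse"] \
        .mean().unstack()
    out["family"] = (fam[False] - fam[True]).to_dict()
    return out


# ---------------------------------------------------------------------------
# Gradient oracle
# ---------------------------------------------------------------------------


def random_recurrent_network(rng: np.random.Generator,
                             dtype=np.float64):
    """A random small recurrent topology with random weights, for
    validating BPTT against finite differences."""
    n_layers = int(rng.integers(2, 5))
    names = [f"l{i}" for i in range(n_layers)]
    sizes = [int(rng.integers(1, 11)) for _ in names]
    conns = [(names[i], names[i + 1]) for i in range(n_layers - 1)]
    for _ in range(int(rng.integers(0, 3))):
        a, b = (int(x) for x in rng.integers(0, n_layers, size=2))
        if a != b and b != 0 and (names[a], names[b]) not in conns:
            conns.append((names[a], names[b]))
    topo = netcore.NetworkTopology(layers=tuple(zip(names, sizes)),
                                   connections=tuple(conns))
    ws = netcore.init_network(topo, 0.7, seed=int(rng.integers(2 ** 31)),
                              bias_init=float(rng.uniform(-1, 0)),
                              dtype=dtype)
    return topo, ws


def gradient_oracle_max_rel_err(n_networks: int = 100, seed: int = 0,
                                eps: float = 1e-5,
                                params_per_net: int = 12) -> float:
    """Max relative disagreement between BPTT and central finite
    differences over random small networks (<= 10 units/layer, T <= 6),
    sampling weights and biases in each."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        topo, ws = random_recurrent_network(rng)
        in_layer = topo.input_layers[0]
        sizes = topo.layer_sizes
        others = [n for n, _ in topo.layers if n != in_layer]
        tgt = others[int(rng.integers(len(others)))]
        T = int(rng.integers(2, 7))
        trial = netcore.TrialSpec(
            clamps=[(in_layer, rng.random(sizes[in_layer]).round(), T)],
            timesteps=T, target_layer=tgt,
            target=rng.random(sizes[tgt]).round(),
            window=(max(1, T - 1), T),
            criterion="sse" if rng.random() < 0.3 else "ce")
        grads = netcore.bptt_gradients(ws, trial)

        def loss():
            return netcore.trial_loss(netcore.forward_trial(ws, trial),
                                      trial)

        for arr, g in ((ws.w, grads.gw), (ws.b, grads.gb)):
            k_idx = rng.choice(len(arr),
                               size=min(params_per_net, len(arr)),
                               replace=False)
            for k in k_idx:
                arr[k] += eps
                lp = loss()
                arr[k] -= 2 * eps
                lm = loss()
                arr[k] += eps
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd) + abs(g[k]), 1e-6)
                worst = max(worst, abs(fd - g[k]) / denom)
    return float(worst)
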