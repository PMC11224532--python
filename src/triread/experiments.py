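"""Cohort orchestration, trial cleaning and the statistical analyses.

A cohort is a grid of (regimen, seed) models trained on one lexicon.
For each model the pipeline records semantic reliance (SR), mean
phonological polarity, and a reading-aloud trial table (one row per
word per model with the phonological SSE, the correct flag and the
psycholinguistic predictors WF/ONS/RC/IMG).  Three analyses mirror the
individual-differences questions:

* ``sr_regimen_regression`` -- does instructional focus explain SR?
* ``factorial_sr_test`` -- a mixed model on the factorial design
  (high/low imageability x consistent/inconsistent), SR x consistency x
  imageability fixed effects, random intercepts for word and model.
* ``regression_sr_test`` -- the continuous-predictor mixed model with
  WF, ONS, RC, IMG, SR and the SR x RC x IMG interaction set.

Mixed models use random intercepts for item (word) and model version,
fitted as variance components; on non-convergence the pipeline falls
back to OLS with cluster-robust (by model) standard errors and flags
the result.  An effect is significant when |t| > 1.96.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import netcore
from .errors import AnalysisError
from .evaluation import evaluate_reading, mean_phon_polarity, sem_accuracy
from .lexicon import Lexicon
from .semantic_reliance import measure_sr
from .training import (READING_TASKS, CompiledLexicon, RegimenSpec,
                       run_oral_phase, run_reading_phase)

__all__ = [
    "EffectEstimate",
    "ModelRecord",
    "run_cohort",
    "clean_trials",
    "sr_regimen_regression",
    "factorial_sr_test",
    "regression_sr_test",
    "polarity_by_sr_summary",
    "simulate_trial_table",
]

logger = logging.getLogger("triread")

#: |t| threshold for calling an effect significant (p < 0.05, normal
#: approximation).
T_CRITICAL = 1.96


@dataclass
class EffectEstimate:
    term: str
    beta: float
    t: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        return abs(self.t) > T_CRITICAL


@dataclass
class ModelRecord:
    regimen: str
    seed: int
    model_id: str
    sr: float
    sse_via_os: float
    sse_via_ops: float
    polarity: float
    mean_phon_sse: float
    phon_accuracy: float
    sem_accuracy: float
    n_op_trials: int
    n_os_trials: int


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def run_cohort(lexicon: Lexicon, regimens: list[RegimenSpec], *,
               topology: netcore.NetworkTopology | None = None,
               learning_rate: float = 0.05,
               share_oral_phase: bool = True, common_streams: bool = True,
               dtype=np.float32, probe: bool = False,
               progress=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train every (regimen, seed) model and assemble cohort outputs.

    Returns ``(records, trial_table)``: one record per model (SR,
    polarity, accuracies) and one reading-aloud row per word per model.
    Model versions differ in their initial weights (the seed); with
    ``common_streams`` (default) all models additionally share one
    word/task sampling stream, so regimens differ only in the exposure
    threshold applied to the same task coin -- the common-random-numbers
    design.  The oral phase is shared across regimens within a seed by
    default (``share_oral_phase``), isolating the reading-instruction
    manipulation; per-model failures are logged and skipped.
    Fully deterministic given the regimen seeds.
    """
    from dataclasses import replace as _replace

    topology = topology or netcore.NetworkTopology.triangle_scaled(
        lexicon.spec)
    compiled = CompiledLexicon(lexicon, dtype=dtype)
    if common_streams and regimens:
        stream = regimens[0].seed
        regimens = [r if r.stream_seed is not None
                    else _replace(r, stream_seed=stream)
                    for r in regimens]
    records: list[ModelRecord] = []
    rows: list[dict] = []
    failures: list[dict] = []
    oral_cache: dict[int, netcore.WeightSet] = {}
    for regimen in regimens:
        try:
            key = regimen.seed
            if not share_oral_phase or key not in oral_cache:
                init = netcore.init_network(topology, 0.1,
                                            seed=regimen.seed, dtype=dtype)
                oral_ws, _ = run_oral_phase(
                    init, compiled, regimen,
                    learning_rate=learning_rate, probe=probe,
                    log_interval=max(regimen.oral_trials, 1))
                oral_cache[key] = oral_ws
            reading_ws, rlog = run_reading_phase(
                oral_cache[key], compiled, regimen,
                learning_rate=learning_rate, probe=probe,
                log_interval=max(regimen.reading_trials, 1))
            rec, word_rows = _evaluate_model(reading_ws, compiled,
                                             regimen, rlog)
            records.append(rec)
            rows.extend(word_rows)
            if progress is not None:
                progress(rec)
        except Exception as exc:  # cohort continues past a failed model
            logger.error("model %s seed %s failed: %s", regimen.name,
                         regimen.seed, exc)
            failures.append({"regimen": regimen.name,
                             "seed": regimen.seed, "error": str(exc)})
    records_df = pd.DataFrame([r.__dict__ for r in records])
    trial_table = pd.DataFrame(rows)
    records_df.attrs["failures"] = failures
    trial_table.attrs["failures"] = failures
    return records_df, trial_table


def _evaluate_model(weights: netcore.WeightSet, compiled: CompiledLexicon,
                    regimen: RegimenSpec, rlog
                    ) -> tuple[ModelRecord, list[dict]]:
    model_id = f"{regimen.name}|s{regimen.seed}"
    score = measure_sr(weights, compiled)
    polarity = mean_phon_polarity(weights, compiled)
    phon_results = evaluate_reading(weights, compiled)
    os_task = READING_TASKS["OS"]
    sem_ok = 0
    for i in range(len(compiled)):
        tr = netcore.forward_trial(weights, compiled.trial(i, os_task))
        sem_ok += sem_accuracy(tr, compiled, os_task.window, i).correct
    word_rows = []
    for i, res in enumerate(phon_results):
        e = compiled.lexicon[i]
        word_rows.append({
            "model_id": model_id, "regimen": regimen.name,
            "seed": regimen.seed, "word_id": e.word_id,
            "phon_sse": res.sse, "correct": bool(res.correct),
            "wf": e.features.wf, "ons": e.features.ons,
            "rc": e.features.rc, "img": e.features.img,
            "sr": score.sr,
            "consistent": bool(e.tags.get("consistent",
                                          e.features.rc >= 1.0)),
            "deviant": bool(e.tags.get("deviant", False)),
            "img_high": bool(e.tags.get("img_high", False)),
            "cell": e.tags.get("cell", ""),
        })
    rec = ModelRecord(
        regimen=regimen.name, seed=regimen.seed, model_id=model_id,
        sr=score.sr, sse_via_os=score.sse_via_os,
        sse_via_ops=score.sse_via_ops, polarity=polarity,
        mean_phon_sse=float(np.mean([r.sse for r in phon_results])),
        phon_accuracy=float(np.mean([r.correct for r in phon_results])),
        sem_accuracy=sem_ok / len(compiled),
        n_op_trials=rlog.task_counts.get("OP", 0),
        n_os_trials=rlog.task_counts.get("OS", 0))
    return rec, word_rows


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

_PREDICTORS = ("wf", "ons", "rc", "img", "sr")


def clean_trials(table: pd.DataFrame, sd_multiplier: float = 3.0,
                 discard_ceiling: float = 0.2) -> pd.DataFrame:
    """Outlier removal for the reading-aloud trial table.

    Drops misread words (``correct`` False), rows with missing
    predictors, and rows whose phonological SSE exceeds
    mean + ``sd_multiplier`` x SD, where mean and SD are computed on the
    pre-cleaning correct trials.  The discarded fraction is logged (and
    stored in ``.attrs['discard_fraction']``); a fraction above
    ``discard_ceiling`` raises a warning.
    """
    if len(table) == 0:
        raise AnalysisError("empty trial table")
    correct = table["correct"].astype(bool)
    base = table.loc[correct, "phon_sse"]
    cutoff = base.mean() + sd_multiplier * base.std(ddof=1) \
        if len(base) > 1 else np.inf
    keep = correct.copy()
    for p in _PREDICTORS:
        if p in table.columns:
            keep &= table[p].notna()
    keep &= table["phon_sse"] <= cutoff
    cleaned = table.loc[keep].copy()
    if len(cleaned) == 0:
        raise AnalysisError("no trials survive cleaning")
    frac = 1.0 - len(cleaned) / len(table)
    logger.info("clean_trials discarded %.1f%% of %d trials "
                "(SSE cutoff %.4g)", 100 * frac, len(table), cutoff)
    if frac > discard_ceiling:
        warnings.warn(
            f"clean_trials discarded {100 * frac:.1f}% of trials, above "
            f"the {100 * discard_ceiling:.0f}% ceiling", stacklevel=2)
    cleaned.attrs["discard_fraction"] = frac
    cleaned.attrs["sse_cutoff"] = float(cutoff)
    return cleaned


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def _zscore(s: pd.Series, name: str) -> pd.Series:
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise AnalysisError(f"predictor {name!r} is degenerate "
                            "(zero variance)")
    return (s - s.mean()) / sd


def _extract_effects(params, tvals, ses, terms) -> list[EffectEstimate]:
    out = []
    for term in terms:
        beta = float(params[term])
        se = float(ses[term])
        out.append(EffectEstimate(
            term=term, beta=beta, t=float(tvals[term]),
            ci_low=beta - T_CRITICAL * se, ci_high=beta + T_CRITICAL * se))
    return out


def _fit_mixed(df: pd.DataFrame, formula: str
               ) -> tuple[list[EffectEstimate], dict]:
    """Random-intercepts-for-word-and-model mixed model with an OLS +
    cluster-robust fallback on non-convergence."""
    import statsmodels.formula.api as smf

    data = df.copy()
    data["_grp"] = 1
    info = {"engine": "mixedlm", "converged": True,
            "n_word_levels": int(data["word_id"].nunique()),
            "n_model_levels": int(data["model_id"].nunique()),
            "n_obs": int(len(data))}
    fit = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, data, groups="_grp",
                             vc_formula={"word": "0 + C(word_id)",
                                         "model": "0 + C(model_id)"},
                             re_formula="0")
            fit = md.fit(reml=True, method="lbfgs", maxiter=200)
        if not fit.converged or not np.all(np.isfinite(fit.bse_fe)):
            fit = None
    except (np.linalg.LinAlgError, ValueError):
        fit = None
    if fit is not None:
        terms = [t for t in fit.fe_params.index if t != "Intercept"]
        tvals = fit.fe_params / fit.bse_fe
        return _extract_effects(fit.fe_params, tvals, fit.bse_fe,
                                terms), info
    # fallback: OLS with standard errors clustered by model version
    info["engine"] = "ols_cluster"
    info["converged"] = False
    ols = smf.ols(formula, data).fit(
        cov_type="cluster", cov_kwds={"groups": data["model_id"]})
    terms = [t for t in ols.params.index if t != "Intercept"]
    return _extract_effects(ols.params, ols.tvalues, ols.bse, terms), info


def factorial_sr_test(table: pd.DataFrame
                      ) -> tuple[list[EffectEstimate], dict]:
    """Mixed model on the factorial design: response = phonological SSE,
    fixed effects SR x consistency x imageability (all z-scored),
    random intercepts for word and for model version."""
    need = {"phon_sse", "sr", "consistent", "img_high", "word_id",
            "model_id"}
    missing = need - set(table.columns)
    if missing:
        raise AnalysisError(f"trial table lacks columns {sorted(missing)}")
    data = table.copy()
    data["z_sse"] = _zscore(data["phon_sse"].astype(float), "phon_sse")
    data["z_sr"] = _zscore(data["sr"].astype(float), "sr")
    data["z_cons"] = _zscore(data["consistent"].astype(float),
                             "consistent")
    data["z_img"] = _zscore(data["img_high"].astype(float), "img_high")
    return _fit_mixed(data, "z_sse ~ z_sr * z_cons * z_img")


def regression_sr_test(table: pd.DataFrame
                       ) -> tuple[list[EffectEstimate], dict]:
    """Mixed model with the continuous psycholinguistic predictors WF,
    ONS, RC, IMG, SR plus the SR x RC x IMG interaction set (all
    z-scored), random intercepts for word and model version."""
    need = {"phon_sse", "word_id", "model_id", *_PREDICTORS}
    missing = need - set(table.columns)
    if missing:
        raise AnalysisError(f"trial table lacks columns {sorted(missing)}")
    data = table.copy()
    data["z_sse"] = _zscore(data["phon_sse"].astype(float), "phon_sse")
    for p in _PREDICTORS:
        data[f"z_{p}"] = _zscore(data[p].astype(float), p)
    formula = ("z_sse ~ z_wf + z_ons + z_rc + z_img + z_sr"
               " + z_sr:z_rc + z_sr:z_img + z_rc:z_img"
               " + z_sr:z_rc:z_img")
    return _fit_mixed(data, formula)


def sr_regimen_regression(records: pd.DataFrame) -> dict:
    """Simple regression of SR on dummy-coded training focus.

    Returns R-squared, adjusted R-squared and the three pairwise regimen
    contrasts (balanced - OP, OS - balanced, OS - OP) as
    :class:`EffectEstimate` objects.
    """
    import statsmodels.api as sm

    counts = records.groupby("regimen")["sr"].count()
    if len(counts) < 2 or (counts < 2).any():
        raise AnalysisError("need >=2 regimens with >=2 models each")
    order = [n for n in ("OP-focused", "OP-OS balanced", "OS-focused")
             if n in counts.index]
    order += [n for n in counts.index if n not in order]
    dummies = pd.get_dummies(
        pd.Categorical(records["regimen"], categories=order),
        drop_first=True, dtype=float)
    X = sm.add_constant(dummies)
    fit = sm.OLS(records["sr"].astype(float), X).fit()
    contrasts = []
    k = len(order)
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(X.shape[1])
            if i > 0:
                c[i] = -1.0  # column i corresponds to order[i] vs base
            if j > 0:
                c[j] = 1.0
            tt = fit.t_test(c)
            beta = float(np.atleast_1d(tt.effect)[0])
            se = float(np.atleast_1d(tt.sd).ravel()[0])
            contrasts.append(EffectEstimate(
                term=f"{order[j]} - {order[i]}", beta=beta,
                t=float(np.atleast_1d(tt.tvalue).ravel()[0]),
                ci_low=beta - T_CRITICAL * se,
                ci_high=beta + T_CRITICAL * se))
    return {"r2": float(fit.rsquared),
            "adj_r2": float(fit.rsquared_adj),
            "f_pvalue": float(fit.f_pvalue),
            "contrasts": contrasts,
            "group_means": records.groupby("regimen")["sr"].mean()
            .reindex(order).to_dict()}


def polarity_by_sr_summary(records: pd.DataFrame
                           ) -> tuple[pd.DataFrame, dict]:
    """Polarity-vs-SR series per regimen plus rank correlations."""
    from scipy.stats import spearmanr

    summary = records[["regimen", "model_id", "sr", "polarity"]] \
        .sort_values(["regimen", "sr"]).reset_index(drop=True)
    per_regimen = {}
    for name, grp in summary.groupby("regimen"):
        if grp["polarity"].nunique() > 1 and grp["sr"].nunique() > 1:
            rho, p = spearmanr(grp["sr"], grp["polarity"])
        else:
            rho, p = 0.0, 1.0
        per_regimen[name] = {"rho": float(rho), "p": float(p),
                             "n": int(len(grp))}
    if summary["polarity"].nunique() > 1 and summary["sr"].nunique() > 1:
        rho, p = spearmanr(summary["sr"], summary["polarity"])
    else:
        rho, p = 0.0, 1.0
    return summary, {"per_regimen": per_regimen, "pooled_rho": float(rho),
                     "pooled_p": float(p)}


# ---------------------------------------------------------------------------
# Simulation utilities for engine calibration
# ---------------------------------------------------------------------------


def simulate_trial_table(n_models: int = 10, n_words: int = 40,
                         coefs: dict | None = None,
                         noise_sd: float = 1.0, word_re_sd: float = 0.3,
                         model_re_sd: float = 0.3,
                         seed: int = 0) -> pd.DataFrame:
    """Synthetic trial table with known fixed effects, for calibrating
    the statistical engine.

    ``coefs`` maps term names (``sr``, ``rc``, ``img``, ``wf``, ``ons``,
    ``consistent``, ``sr:consistent``, ``sr:img_high``,
    ``sr:consistent:img_high``, ...) to coefficients on z-scored
    predictors; omitted terms are zero.  The response adds random word
    and model intercepts and Gaussian noise.
    """
    coefs = coefs or {}
    rng = np.random.default_rng(seed)
    words = pd.DataFrame({
        "word_id": [f"w{i:04d}" for i in range(n_words)],
        "wf": rng.uniform(0, 1, n_words),
        "ons": rng.poisson(5, n_words).astype(float),
        "rc": np.clip(rng.beta(5, 1, n_words), 0, 1),
        "img": rng.uniform(0, 1, n_words),
        "consistent": rng.random(n_words) < 0.5,
    })
    words["img_high"] = words["img"] >= words["img"].median()
    models = pd.DataFrame({
        "model_id": [f"m{i:03d}" for i in range(n_models)],
        "sr": rng.normal(0.1, 0.03, n_models),
    })
    df = words.merge(models, how="cross")
    word_re = dict(zip(words["word_id"],
                       rng.normal(0, word_re_sd, n_words)))
    model_re = dict(zip(models["model_id"],
                        rng.normal(0, model_re_sd, n_models)))

    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v * 0.0

    zcols = {c: z(df[c]) for c in ("sr", "rc", "img", "wf", "ons")}
    zcols["consistent"] = z(df["consistent"].astype(float))
    zcols["img_high"] = z(df["img_high"].astype(float))
    y = np.zeros(len(df))
    for term, beta in coefs.items():
        parts = term.split(":")
        v = np.ones(len(df))
        for p in parts:
            v = v * zcols[p]
        y += beta * v
    y += df["word_id"].map(word_re).to_numpy()
    y += df["model_id"].map(model_re).to_numpy()
    y += rng.normal(0, noise_sd, len(df))
    df["phon_sse"] = y
    df["correct"] = True
    df["regimen"] = "simulated"
    df["seed"] = seed
    return df
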