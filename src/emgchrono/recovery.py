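"""Parameter-recovery simulations: simulate the full design from the
generative defaults, refit the specified mixed models, and summarize the
recovered estimated-marginal lexicality contrasts.

These drive both the package's acceptance checks and any power/robustness
exploration: because the generative fixed effects default to the published
estimates, the recovered word − pseudoword contrasts per bias level should
land on the published simple effects up to sampling noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inference
from .params import GenerativeParams
from .synthetic import build_design, simulate_trials

DEFAULT_N_PARTICIPANTS = 46


def _model_frame(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials.rename(columns={"participant_id": "participant",
                                 "stimulus_id": "item", "block": "bias"})
    out["participant"] = "s" + out["participant"].astype(str)
    return out


def simulate_analysis_tables(
    n_participants: int = DEFAULT_N_PARTICIPANTS,
    params: GenerativeParams | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate one full experiment and build per-measure analysis tables.

    Chronometric tables contain pure-correct experimental trials (the
    analysis population), with the simulated PMT/MT/RT as the measures; the
    accuracy table contains all responded experimental trials; the partial
    table the correct responded experimental trials.
    """
    params = params or GenerativeParams()
    design = build_design(n_participants, seed=seed)
    trials = simulate_trials(design, params, seed=seed + 1)
    exp = trials[~trials["is_filler"] & ~trials["timeout"]].copy()
    pure = exp[exp["correct"] & ~exp["partial"]].copy()
    pure["pmt"] = pure["true_pmt"]
    pure["mt"] = pure["true_mt"]
    pure["rt"] = pure["true_rt"]
    accuracy = exp.copy()
    accuracy["accuracy"] = accuracy["correct"].astype(int)
    partial = exp[exp["correct"]].copy()
    partial["partial_error"] = partial["partial"].astype(int)
    return {
        "chronometric": _model_frame(pure),
        "accuracy": _model_frame(accuracy),
        "partial_error": _model_frame(partial),
    }


def chronometric_spec(measure: str) -> inference.ModelSpec:
    return inference.ModelSpec(measure, family="gaussian")


def binary_spec(measure: str) -> inference.ModelSpec:
    return inference.ModelSpec(measure, family="binomial", reml=False)


def recover_lexicality_contrasts(
    measures: tuple[str, ...] = ("rt", "pmt", "mt"),
    n_participants: int = DEFAULT_N_PARTICIPANTS,
    n_replicates: int = 5,
    params: GenerativeParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate, fit and average recovered lexicality contrasts.

    Returns one row per (measure, bias level) with the across-replicate mean
    recovered word − pseudoword contrast, the mean model SE, and the
    generative truth implied by the parameter defaults.
    """
    params = params or GenerativeParams()
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n_replicates)]
    per_rep: list[pd.DataFrame] = []
    for rep_seed in seeds:
        tables = simulate_analysis_tables(n_participants, params, seed=rep_seed)
        for measure in measures:
            if measure in ("accuracy", "partial_error"):
                fitted = inference.fit(binary_spec(measure), tables[measure])
            else:
                fitted = inference.fit(chronometric_spec(measure),
                                       tables["chronometric"])
            con = inference.lexicality_contrasts(fitted).reset_index()
            con["measure"] = measure
            con["seed"] = rep_seed
            con["n_obs"] = fitted.n_obs
            per_rep.append(con)
    stacked = pd.concat(per_rep, ignore_index=True)
    agg = (
        stacked.groupby(["measure", "bias"], sort=False)
        .agg(estimate=("estimate", "mean"), se=("se", "mean"),
             n_obs=("n_obs", "mean"), n_replicates=("estimate", "size"))
        .reset_index()
    )
    agg["truth"] = [
        _generative_truth(params, m, b)
        for m, b in zip(agg["measure"], agg["bias"])
    ]
    return agg


def _generative_truth(params: GenerativeParams, measure: str, bias: str) -> float:
    if measure == "rt":  # RT = PMT + MT by construction
        return (params.pmt.fixed.lexicality_contrast(bias)
                + params.mt.fixed.lexicality_contrast(bias))
    return params.measure(measure if measure != "partial_error" else
                          "partial_error").fixed.lexicality_contrast(bias)


def null_interaction_replicates(
    n_replicates: int = 20,
    n_participants: int = 12,
    seed: int = 0,
    params: GenerativeParams | None = None,
) -> pd.DataFrame:
    """Behavior of the MT bias-by-lexicality interaction under a null truth.

    MT is simulated with both interaction coefficients set to 0; per
    replicate the interaction model and the additive model are fit by ML and
    compared: reports the largest interaction |t| and the BIC Bayes factor
    for the interaction (BF < 1 favoring the additive/null model).
    """
    from dataclasses import replace
    base = params or GenerativeParams()
    null_mt = replace(
        base.mt,
        fixed=replace(base.mt.fixed, bias_pseudoword_x_lexicality=0.0,
                      bias_word_x_lexicality=0.0),
    )
    null_params = replace(base, mt=null_mt)
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n_replicates)]
    rows = []
    for rep_seed in seeds:
        data = simulate_analysis_tables(n_participants, null_params,
                                        seed=rep_seed)["chronometric"]
        spec_with = inference.ModelSpec("mt", fixed="bias * lexicality", reml=False)
        spec_without = inference.ModelSpec("mt", fixed="bias + lexicality", reml=False)
        fit_with = inference.fit(spec_with, data)
        fit_without = inference.fit(spec_without, data)
        stats = fit_with.fixed_effects.loc[
            [t for t in fit_with.fixed_effects.index if ":" in t], "statistic"
        ]
        rows.append({
            "seed": rep_seed,
            "max_abs_t": float(stats.abs().max()),
            "bayes_factor": inference.bic_bayes_factor(fit_with, fit_without),
        })
    return pd.DataFrame(rows)
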