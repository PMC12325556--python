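"""Mixed-effects inference for chronometric and accuracy measures.

Models follow the published analysis contract: treatment-coded fixed effects
of lexicality (reference: word) by bias (reference: neutral), crossed
participant/item random effects, gaussian LMEs for chronometric measures and
binomial-logit GLMEs for accuracy/partial errors, significance at |t| or |z|
> 2, progressive simplification of the random structure, estimated-marginal
contrasts, and BIC-approximate Bayes factors (BF = exp(-dBIC/2)) for nested
comparisons.  Numerics delegate to lme4 (see :mod:`emgchrono._lme4`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from . import _lme4
from .params import BIAS_LEVELS, LEXICALITY_LEVELS

DEFAULT_FACTORS = {
    "bias": list(BIAS_LEVELS),
    "lexicality": list(LEXICALITY_LEVELS),
}


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects term: (1 + slopes | group) in lme4 notation;
    ``correlated=False`` uses the double-bar (uncorrelated) form."""

    group: str
    slopes: tuple[str, ...] = ()
    correlated: bool = True

    def to_formula(self) -> str:
        rhs = " + ".join(("1",) + self.slopes)
        bar = "|" if self.correlated or not self.slopes else "||"
        return f"({rhs} {bar} {self.group})"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description mapped onto an lme4 formula."""

    response: str
    family: str = "gaussian"  # or "binomial"
    fixed: str = "bias * lexicality"
    random: tuple[RandomTerm, ...] = (
        RandomTerm("participant"), RandomTerm("item"),
    )
    reml: bool = True
    optimizer: str = "bobyqa"
    maxfun: int = 200_000

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unsupported family {self.family!r}")

    def formula(self) -> str:
        parts = [self.fixed] + [t.to_formula() for t in self.random]
        return f"{self.response} ~ " + " + ".join(parts)


def maximal_spec(response: str, family: str = "gaussian",
                 fixed: str = "bias * lexicality",
                 participant_slopes: tuple[str, ...] = ("bias", "lexicality"),
                 item_slopes: tuple[str, ...] = ("bias",),
                 reml: bool = True) -> ModelSpec:
    """Maximal random structure: by-participant and by-item intercepts,
    slopes and correlations.  Items never get a lexicality slope (lexicality
    is a between-item property)."""
    return ModelSpec(
        response, family=family, fixed=fixed,
        random=(RandomTerm("participant", participant_slopes, True),
                RandomTerm("item", item_slopes, True)),
        reml=reml,
    )


def caf_spec(response: str = "accuracy") -> ModelSpec:
    """Conditional-accuracy-function GLME: lexicality x bias x quantile
    (second-order orthogonal polynomials), random intercepts only (slopes
    are omitted to aid convergence)."""
    return ModelSpec(
        response,
        family="binomial",
        fixed="bias * lexicality * (quantile_linear + quantile_quadratic)",
        random=(RandomTerm("participant"), RandomTerm("item")),
        reml=False,
    )


@dataclass
class FitResult:
    """Fixed effects, random-term variances and fit statistics."""

    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, statistic
    vcov: pd.DataFrame
    random_effects: pd.DataFrame  # grp, var1, var2, vcov, sdcor
    loglik: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool
    singular: bool
    is_reml: bool
    formula: str
    family: str
    messages: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def significant(self, term: str, threshold: float = 2.0) -> bool:
        """Published criterion: |t| or |z| above 2."""
        return abs(float(self.fixed_effects.loc[term, "statistic"])) > threshold

    def variance(self, group: str, term: str = "(Intercept)") -> float:
        re = self.random_effects
        hit = re[(re["grp"] == group) & (re["var1"] == term) & (re["var2"] == "")]
        if not len(hit):
            raise KeyError(f"no random term {term!r} for group {group!r}")
        return float(hit["vcov"].iloc[0])


def _expand_uncorrelated(
    spec: ModelSpec, data: pd.DataFrame, factors: dict[str, list[str]]
) -> tuple[pd.DataFrame, str]:
    """Rewrite uncorrelated random terms over numeric indicator columns.

    lme4's double-bar syntax only diagonalizes numeric covariates; factor
    slopes keep their within-factor correlations.  Factor slopes of
    uncorrelated terms are therefore expanded into treatment-coded 0/1
    columns (as afex does) before the formula reaches R.
    """
    needs = [t for t in spec.random if t.slopes and not t.correlated]
    if not needs:
        return data, spec.formula()
    data = data.copy()
    parts = [spec.fixed]
    for t in spec.random:
        if t.correlated or not t.slopes:
            parts.append(t.to_formula())
            continue
        cols: list[str] = []
        for slope in t.slopes:
            levels = factors.get(slope)
            if levels is None:
                cols.append(slope)  # already numeric
                continue
            for level in levels[1:]:
                dummy = f"{slope}_{level}"
                data[dummy] = (data[slope] == level).astype(int)
                cols.append(dummy)
        rhs = " + ".join(["1"] + cols)
        parts.append(f"({rhs} || {t.group})")
    return data, f"{spec.response} ~ " + " + ".join(parts)


def fit(spec: ModelSpec, data: pd.DataFrame,
        factors: dict[str, list[str]] | None = None) -> FitResult:
    """Fit one mixed model via lme4 and wrap the result.

    Gaussian models use REML when ``spec.reml``; binomial models use Laplace
    maximum likelihood with the bobyqa optimizer.  Non-convergence is
    reported through ``converged`` (never silently).
    """
    if not len(data):
        raise ValueError("empty data")
    missing = [c for c in _lme4._formula_columns(spec.formula(), data)
               if data[c].isna().any()]
    if missing:
        raise ValueError(f"NaNs in model columns {missing}")
    if factors is None:
        factors = {
            k: v for k, v in DEFAULT_FACTORS.items() if k in data.columns
        }
        for col in (spec.response, "participant", "item"):
            if col in data.columns and data[col].dtype == object \
                    and col not in factors:
                factors[col] = sorted(map(str, data[col].unique()))
    data, formula = _expand_uncorrelated(spec, data, factors)
    res = _lme4.run_lme4(
        formula, data, family=spec.family, reml=spec.reml,
        factors=factors, optimizer=spec.optimizer, maxfun=spec.maxfun,
    )
    def aslist(x):
        return x if isinstance(x, list) else [x]

    terms = [str(t) for t in aslist(res["terms"])]
    fe = pd.DataFrame(
        {"estimate": aslist(res["estimate"]), "se": aslist(res["se"]),
         "statistic": aslist(res["statistic"])},
        index=pd.Index(terms, name="term"),
    )
    vcov = pd.DataFrame(
        np.asarray(res["vcov"], dtype=float).reshape(len(terms), len(terms)),
        index=terms, columns=terms,
    )
    vc = res["varcorr"]
    re_df = pd.DataFrame({k: aslist(vc[k]) for k in
                          ("grp", "var1", "var2", "vcov", "sdcor")})
    return FitResult(
        fixed_effects=fe, vcov=vcov, random_effects=re_df,
        loglik=float(res["loglik"]), bic=float(res["bic"]),
        n_obs=int(res["n_obs"]), n_params=int(res["n_params"]),
        converged=bool(res["converged"]), singular=bool(res["singular"]),
        is_reml=bool(res["is_reml"]), formula=formula,
        family=spec.family, messages=[str(m) for m in aslist(res["messages"])],
    )


def _base_group(grp: str) -> str:
    """lme4 suffixes expanded uncorrelated terms as g, g.1, g.2 ..."""
    import re as _re
    return _re.sub(r"\.\d+$", "", grp)


def _zero_variance_terms(fit_result: FitResult, tol: float) -> list[tuple[str, str]]:
    re = fit_result.random_effects
    own = re[(re["var2"] == "") & (re["grp"] != "Residual")]
    scale = max(own["sdcor"].max(), 1.0) if len(own) else 1.0
    hits = own[own["sdcor"] <= tol * scale]
    return [(_base_group(r["grp"]), r["var1"]) for _, r in hits.iterrows()]


def _drop_term(spec: ModelSpec, group: str, var1: str) -> ModelSpec:
    """Remove one random term (a slope, or a group's intercept when it has
    no slopes left) from the spec."""
    new_terms = []
    for t in spec.random:
        if t.group != group:
            new_terms.append(t)
            continue
        if var1 == "(Intercept)":
            if t.slopes:
                new_terms.append(t)  # intercepts removed last
            continue
        kept = tuple(s for s in t.slopes if var1 != s and not var1.startswith(s))
        new_terms.append(replace(t, slopes=kept))
    return replace(spec, random=tuple(new_terms))


def simplify(
    spec: ModelSpec,
    data: pd.DataFrame,
    factors: dict[str, list[str]] | None = None,
    zero_var_tol: float = 1e-4,
    max_steps: int = 20,
) -> tuple[ModelSpec, FitResult, list[str]]:
    """Progressive random-structure simplification.

    Fit; on convergence remove random terms with (numerically) zero variance
    and refit; on non-convergence — or on a boundary (singular) fit whose
    degeneracy sits in the correlation structure — first remove correlations,
    then the slope with the smallest variance; random intercepts are removed
    last.  Returns
    the first converged fit without zero-variance terms together with the
    audit trail.  Raises when nothing converges even at intercepts only.
    """
    audit: list[str] = []
    current = spec
    last_fit = None
    for _ in range(max_steps):
        last_fit = fit(current, data, factors=factors)
        if last_fit.converged:
            zero = _zero_variance_terms(last_fit, zero_var_tol)
            if zero:
                reduced = current
                for grp, var1 in zero:
                    reduced = _drop_term(reduced, grp, var1)
                if reduced == current:
                    return current, last_fit, audit
                audit.append(f"removed zero-variance terms {zero}")
                current = reduced
                continue
            if not last_fit.singular:
                return current, last_fit, audit
            # singular without zero variances: degeneracy sits in the
            # correlation structure (|corr| at 1); treat like non-convergence
        if any(t.correlated and t.slopes for t in current.random):
            current = replace(current, random=tuple(
                replace(t, correlated=False) for t in current.random
            ))
            audit.append("removed random-effect correlations")
            continue
        slopes = last_fit.random_effects
        slopes = slopes[(slopes["var2"] == "") & (slopes["var1"] != "(Intercept)")]
        if len(slopes):
            smallest = slopes.sort_values("vcov").iloc[0]
            current = _drop_term(current, _base_group(smallest["grp"]),
                                 smallest["var1"])
            audit.append(
                f"removed smallest-variance slope {smallest['var1']!r}"
                f" for {smallest['grp']!r}"
            )
            continue
        break
    if last_fit is not None and last_fit.converged:
        return current, last_fit, audit
    raise RuntimeError(
        "no converged fit even at random intercepts only; "
        f"audit: {audit}; messages: {last_fit.messages if last_fit else []}"
    )


# ---------------------------------------------------------------------------
# Contrasts


@dataclass(frozen=True)
class Contrast:
    label: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    adjustment: str = "none"


def linear_contrast(fit_result: FitResult, weights: dict[str, float],
                    label: str = "") -> Contrast:
    """Estimate, SE and z for a linear combination of fixed effects."""
    terms = fit_result.fixed_effects.index
    c = np.zeros(len(terms))
    for term, w in weights.items():
        if term not in terms:
            raise ValueError(f"term {term!r} not in the fitted model")
        c[terms.get_loc(term)] = w
    est = float(c @ fit_result.fixed_effects["estimate"].to_numpy())
    se = float(np.sqrt(c @ fit_result.vcov.to_numpy() @ c))
    z = est / se
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return Contrast(label, est, se, z, p)


def _lex_term() -> str:
    return "lexicalitypseudoword"


def _bias_term(level: str) -> str:
    return f"bias{level}"


def lexicality_contrasts(fit_result: FitResult) -> pd.DataFrame:
    """Word − pseudoword contrast within each bias level.

    The sign convention matches the published simple effects (negative means
    words faster / lower).  With treatment coding the contrast within the
    reference (neutral) level is −(lexicality coefficient); within a biased
    level the corresponding interaction coefficient is added before negation.
    """
    rows = []
    for level in BIAS_LEVELS:
        weights = {_lex_term(): -1.0}
        if level != "neutral":
            weights[f"{_bias_term(level)}:{_lex_term()}"] = -1.0
        con = linear_contrast(fit_result, weights, label=f"word-pseudoword|{level}")
        rows.append({
            "bias": level, "estimate": con.estimate, "se": con.se,
            "statistic": con.statistic, "p_value": con.p_value,
        })
    return pd.DataFrame(rows).set_index("bias")


def pairwise_bias_contrasts(fit_result: FitResult, lexicality: str = "word",
                            adjust: str = "tukey") -> pd.DataFrame:
    """Pairwise bias-level comparisons within one lexicality level, with an
    optional Tukey (studentized-range, large-sample) adjustment."""
    if lexicality not in LEXICALITY_LEVELS:
        raise ValueError(f"unknown lexicality {lexicality!r}")

    def cell_weights(level: str) -> dict[str, float]:
        w: dict[str, float] = {}
        if level != "neutral":
            w[_bias_term(level)] = 1.0
            if lexicality == "pseudoword":
                w[f"{_bias_term(level)}:{_lex_term()}"] = 1.0
        return w

    k = len(BIAS_LEVELS)
    rows = []
    for i, a in enumerate(BIAS_LEVELS):
        for b in BIAS_LEVELS[i + 1:]:
            w = cell_weights(a)
            for term, v in cell_weights(b).items():
                w[term] = w.get(term, 0.0) - v
            if not w:
                continue
            con = linear_contrast(fit_result, w, label=f"{a}-{b}|{lexicality}")
            p = con.p_value
            if adjust == "tukey":
                p = float(scipy.stats.studentized_range.sf(
                    abs(con.statistic) * math.sqrt(2.0), k, 1e6))
            rows.append({
                "contrast": f"{a} - {b}", "lexicality": lexicality,
                "estimate": con.estimate, "se": con.se,
                "statistic": con.statistic, "p_value": p,
                "adjustment": adjust,
            })
    return pd.DataFrame(rows)


def bic_bayes_factor(fit_with: FitResult, fit_without: FitResult) -> float:
    """BIC-approximate Bayes factor for the extra term(s) in ``fit_with``:
    BF = exp(−(BIC_with − BIC_without)/2); BF < 1 favors the simpler model.

    Requires maximum-likelihood (not REML) fits on identical data.
    """
    if fit_with.is_reml or fit_without.is_reml:
        raise ValueError("BIC Bayes factors require ML (REML=False) fits")
    if fit_with.n_obs != fit_without.n_obs:
        raise ValueError("fits must be on identical data (n_obs differs)")
    return math.exp(-(fit_with.bic - fit_without.bic) / 2.0)
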