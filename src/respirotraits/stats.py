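"""Mixed-model inference on individual metabolic traits.

Gaussian linear mixed models with random intercepts — either nested
(fish within batch) or fish-only — fitted by REML for reporting and by ML
for likelihood-ratio term tests. Includes backward term reduction
respecting marginality, marginal/conditional R^2 from the variance
partition, percentage effect sizes from back-transformed equally weighted
marginal means, and the simple OLS growth-rate-vs-group-size regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LMMFit",
    "fit_lmm",
    "test_term",
    "backward_reduce",
    "r2_nakagawa",
    "effect_size_pct",
    "sgr_group_test",
    "fit_family",
    "FAMILIES",
]

logger = logging.getLogger(__name__)

# a variance component below this fraction of the residual variance is
# treated as collapsed; looser than lme4's boundary check because the
# profiled optimizers here stall at small positive values instead of 0,
# and a component this small is immaterial to the fit anyway
SINGULAR_TOL = 5e-3


@dataclass
class LMMFit:
    """A fitted mixed model plus everything needed to refit variants."""

    data: pd.DataFrame
    response: str
    terms: Tuple[str, ...]
    random: str  # "nested" | "fish" | "none"
    batch_col: str = "batch"
    fish_col: str = "fish_id"
    result: Optional[object] = None  # REML fit (or OLS for random="none")
    singular: bool = False
    requested_random: str = ""

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def refit(self, terms: Sequence[str], reml: bool = True) -> "LMMFit":
        return fit_lmm(
            self.data,
            self.response,
            terms,
            random=self.requested_random or self.random,
            reml=reml,
            batch_col=self.batch_col,
            fish_col=self.fish_col,
        )


def _fit_mixed(
    data: pd.DataFrame,
    formula: str,
    random: str,
    batch_col: str,
    fish_col: str,
    reml: bool,
):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if random == "nested":
            model = MixedLM.from_formula(
                formula,
                data,
                groups=data[batch_col],
                re_formula="1",
                vc_formula={"fish": f"0 + C({fish_col})"},
            )
        elif random == "fish":
            model = MixedLM.from_formula(
                formula, data, groups=data[fish_col], re_formula="1"
            )
        else:
            raise ValueError(f"unknown random structure {random!r}")
        last = None
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                result = model.fit(reml=reml, method=method, maxiter=1000)
            except Exception:
                continue
            last = result
            if result.converged and np.all(np.isfinite(result.params)):
                return result
        if last is not None:
            return last
        raise RuntimeError(f"all optimizers failed for {formula!r}")


def _is_singular(result) -> bool:
    scale = float(result.scale)
    comps = [float(np.asarray(result.cov_re).ravel()[0])] if result.cov_re.size else []
    if result.vcomp is not None:
        comps.extend(float(v) for v in np.atleast_1d(result.vcomp))
    return any(c < SINGULAR_TOL * max(scale, 1e-300) for c in comps)


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    random: str = "nested",
    reml: bool = True,
    batch_col: str = "batch",
    fish_col: str = "fish_id",
    allow_fallback: bool = True,
) -> LMMFit:
    """Fit a Gaussian LMM with the requested random-intercept structure.

    ``random='nested'`` puts a random intercept on batch and on fish
    within batch; ``'fish'`` keeps only the fish intercept. A singular
    nested fit (any variance component collapsing to zero) triggers a
    fallback to the fish-only structure when ``allow_fallback`` is true;
    the returned object records both the requested and the used structure.
    """
    data = data.dropna(subset=[response]).copy()
    fit = LMMFit(
        data=data,
        response=response,
        terms=tuple(terms),
        random=random,
        batch_col=batch_col,
        fish_col=fish_col,
        requested_random=random,
    )
    try:
        result = _fit_mixed(data, fit.formula, random, batch_col, fish_col, reml)
    except RuntimeError:
        if random != "nested" or not allow_fallback:
            raise
        logger.info("nested fit failed outright for %s; trying fish-only", fit.formula)
        fit.singular = True
        fit.random = "fish"
        fit.result = _fit_mixed(data, fit.formula, "fish", batch_col, fish_col, reml)
        return fit
    if not result.converged:
        if random == "nested" and allow_fallback:
            # a batch variance stuck at the boundary commonly stalls the
            # optimizer; the fish-only structure is the documented fallback
            fallback = _fit_mixed(data, fit.formula, "fish", batch_col, fish_col, reml)
            if fallback.converged:
                logger.info(
                    "nested fit did not converge for %s; using fish-only", fit.formula
                )
                fit.singular = True
                fit.random = "fish"
                fit.result = fallback
                return fit
        raise RuntimeError(
            f"LMM did not converge for {fit.formula!r} (random={random}); "
            "inspect the data or simplify the model"
        )
    if _is_singular(result):
        fit.singular = True
        if random == "nested" and allow_fallback:
            logger.info(
                "singular nested fit for %s; falling back to fish-only random effect",
                fit.formula,
            )
            result = _fit_mixed(data, fit.formula, "fish", batch_col, fish_col, reml)
            fit.random = "fish"
    fit.result = result
    return fit


# ---------------------------------------------------------------------------
# term tests
# ---------------------------------------------------------------------------


def _term_factors(term: str) -> frozenset:
    return frozenset(p.strip() for p in term.split(":"))


def _marginality_ok(term: str, terms: Iterable[str]) -> bool:
    """A term may be dropped only if no higher-order term contains it."""
    f = _term_factors(term)
    for other in terms:
        if other == term:
            continue
        if f < _term_factors(other):
            return False
    return True


def test_term(fit: LMMFit, term: str, flavor: str = "lrt") -> Tuple[float, int, float]:
    """Chi-square test of one fixed-effect term: ``(chi2, df, p)``.

    ``flavor='lrt'`` refits with and without the term by maximum
    likelihood and compares deviances; ``'wald'`` tests the term's
    coefficients in the full (ML) fit. Dropping a term still contained in
    an interaction is refused.
    """
    if term not in fit.terms:
        raise ValueError(f"term {term!r} not in model ({fit.terms})")
    if not _marginality_ok(term, fit.terms):
        raise ValueError(
            f"cannot test {term!r}: a higher-order interaction containing it is present"
        )
    full = fit.refit(fit.terms, reml=False)
    if flavor == "wald":
        design_info = full.result.model.data.design_info
        slices = design_info.term_name_slices
        if term not in slices:
            raise ValueError(f"term {term!r} missing from design ({list(slices)})")
        k_fe = len(full.result.fe_params)
        idx = np.arange(k_fe)[slices[term]]
        k_total = len(full.result.params)
        L = np.zeros((len(idx), k_total))
        for row, j in enumerate(idx):
            L[row, j] = 1.0
        wt = full.result.wald_test(L, scalar=False)
        chi2 = float(np.squeeze(wt.statistic))
        df = int(wt.df_denom) if hasattr(wt, "df_denom") else len(idx)
        df = len(idx)
        return chi2, df, float(scipy.stats.chi2.sf(chi2, df))
    if flavor != "lrt":
        raise ValueError("flavor must be 'lrt' or 'wald'")
    reduced_terms = tuple(t for t in fit.terms if t != term)
    reduced = fit.refit(reduced_terms, reml=False)
    ll_full = float(full.result.llf)
    ll_red = float(reduced.result.llf)
    df = len(full.result.fe_params) - len(reduced.result.fe_params)
    chi2 = max(2.0 * (ll_full - ll_red), 0.0)
    if df == 0:
        return 0.0, 0, 1.0
    return chi2, df, float(scipy.stats.chi2.sf(chi2, df))


def backward_reduce(
    fit: LMMFit,
    protected_terms: Sequence[str],
    alpha: float = 0.05,
    flavor: str = "lrt",
) -> Tuple[LMMFit, pd.DataFrame]:
    """Iteratively drop the least significant removable term with p >= alpha.

    Interactions are eligible before the main effects they contain
    (marginality); ``protected_terms`` are never dropped. Returns the
    reduced REML fit and the full elimination trace.
    """
    terms = list(fit.terms)
    trace: List[dict] = []
    step = 0
    current = fit
    while True:
        removable = [
            t
            for t in terms
            if t not in protected_terms and _marginality_ok(t, terms)
        ]
        if not removable:
            break
        pvals = {}
        for t in removable:
            chi2, df, p = test_term(current, t, flavor=flavor)
            pvals[t] = (chi2, df, p)
        worst = max(removable, key=lambda t: pvals[t][2])
        chi2, df, p = pvals[worst]
        if p < alpha:
            break
        step += 1
        terms.remove(worst)
        trace.append(
            {"step": step, "dropped": worst, "chi2": chi2, "df": df, "p": p}
        )
        current = current.refit(terms, reml=True)
    if current is fit:
        current = fit.refit(terms, reml=True)
    return current, pd.DataFrame(trace, columns=["step", "dropped", "chi2", "df", "p"])


# ---------------------------------------------------------------------------
# R^2 and effect sizes
# ---------------------------------------------------------------------------


def r2_nakagawa(fit: LMMFit) -> Tuple[float, float]:
    """Marginal and conditional R^2 of a Gaussian LMM (as proportions).

    Marginal: variance of the fixed-effect linear predictor over the data
    divided by that plus all random-intercept variances plus the residual
    variance. Conditional adds the random variances to the numerator.
    """
    res = fit.result
    X = res.model.exog
    var_f = float(np.var(X @ res.fe_params))
    var_r = 0.0
    if res.cov_re.size:
        var_r += float(np.asarray(res.cov_re).ravel()[0])
    if res.vcomp is not None:
        var_r += float(np.sum(np.atleast_1d(res.vcomp)))
    var_e = float(res.scale)
    denom = var_f + var_r + var_e
    return var_f / denom, (var_f + var_r) / denom


def _reference_grid(fit: LMMFit, at: Optional[Dict[str, object]] = None) -> pd.DataFrame:
    """Equal-weight grid over every categorical in the model; covariates at mean."""
    variables: set = set()
    for term in fit.terms:
        variables |= {v for v in _term_factors(term)}
    cols = {}
    cat_cols = []
    for v in variables:
        if v not in fit.data.columns:
            raise ValueError(f"model variable {v!r} not a data column")
        s = fit.data[v]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            cat_cols.append(v)
        else:
            cols[v] = [float(s.mean())]
    for v in cat_cols:
        levels = list(pd.unique(fit.data[v].dropna()))
        cols[v] = sorted(levels, key=str)
    from itertools import product

    names = list(cols)
    grid = pd.DataFrame(list(product(*[cols[n] for n in names])), columns=names)
    if at:
        for k, val in at.items():
            if k not in grid.columns:
                raise ValueError(f"'at' variable {k!r} not in model")
            grid = grid[grid[k] == val]
            if grid.empty:
                raise ValueError(f"level {val!r} not found for {k!r}")
    return grid.reset_index(drop=True)


def marginal_means(
    fit: LMMFit, factor: str, at: Optional[Dict[str, object]] = None
) -> pd.Series:
    """Model-scale estimated marginal means of ``factor`` levels.

    Levels of every other factor are averaged with equal weights;
    continuous covariates are held at their data mean.
    """
    grid = _reference_grid(fit, at=at)
    if factor not in grid.columns:
        raise ValueError(f"factor {factor!r} not in model")
    design_info = fit.result.model.data.design_info
    (X,) = patsy.build_design_matrices([design_info], grid)
    pred = np.asarray(X) @ fit.result.fe_params
    return pd.Series(pred).groupby(grid[factor].to_numpy()).mean()


def effect_size_pct(
    fit: LMMFit,
    factor: str,
    levels: Optional[Tuple[object, object]] = None,
    at: Optional[Dict[str, object]] = None,
) -> Tuple[float, Tuple[object, object]]:
    """Percentage effect between two factor levels, back-transformed.

    Assumes a log-transformed response: the effect is
    ``(exp(emm_a - emm_b) - 1) * 100`` for levels ``(a, b)`` (a relative
    to b). By default the last level is contrasted against the first in
    sorted order. ``at`` conditions the grid on levels of other factors.
    """
    emm = marginal_means(fit, factor, at=at)
    if levels is None:
        lv = list(emm.index)
        if len(lv) != 2:
            raise ValueError(
                f"factor {factor!r} has {len(lv)} levels; pass `levels` explicitly"
            )
        a, b = lv[1], lv[0]
    else:
        a, b = levels
    for lvl in (a, b):
        if lvl not in emm.index:
            raise ValueError(f"level {lvl!r} not found for factor {factor!r}")
    pct = (np.exp(emm[a] - emm[b]) - 1.0) * 100.0
    return float(pct), (a, b)


# ---------------------------------------------------------------------------
# growth regression
# ---------------------------------------------------------------------------


def sgr_group_test(sgr_table: pd.DataFrame) -> Dict[str, float]:
    """OLS regression of specific growth rate on group size.

    Expects columns ``sgr`` and ``group_size`` (one row per fish).
    Returns the slope p-value, adjusted R^2, and per-group means.
    """
    df = sgr_table.dropna(subset=["sgr"]).copy()
    groups = sorted(df["group_size"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two group sizes")
    df["group_size"] = df["group_size"].astype(float)
    res = smf.ols("sgr ~ group_size", df).fit()
    out = {
        "p": float(res.pvalues["group_size"]),
        "r2_adj": float(res.rsquared_adj),
        "slope": float(res.params["group_size"]),
        "n": int(res.nobs),
    }
    for g in groups:
        out[f"mean_sgr_group_{int(g)}"] = float(
            df.loc[df["group_size"] == float(g), "sgr"].mean()
        )
    return out


# ---------------------------------------------------------------------------
# model families (the paper-style analysis tables)
# ---------------------------------------------------------------------------


def _two_way(terms: Sequence[str]) -> List[str]:
    mains = list(terms)
    inter = [
        f"{a}:{b}" for i, a in enumerate(mains) for b in mains[i + 1 :]
    ]
    return mains + inter


#: family -> (source table, response column, main fixed effects, protected,
#:            random structure)
FAMILIES: Dict[str, dict] = {
    "night_mo2min": {
        "source": "mo2min_long",
        "photoperiod": "night",
        "response": "mo2min_adj",
        "mains": ["trial", "day", "shelter", "mass"],
        "protected": ["trial", "shelter"],
        "random": "nested",
    },
    "day_mo2min": {
        "source": "mo2min_long",
        "photoperiod": "day",
        "response": "mo2min_adj",
        "mains": ["trial", "day", "shelter", "mass"],
        "protected": ["trial", "shelter"],
        "random": "nested",
    },
    "smr": {
        "source": "traits",
        "response": "smr_adj",
        "mains": ["trial", "group_size", "shelter_avail", "mass"],
        "protected": ["trial", "group_size", "shelter_avail"],
        "random": "nested",
    },
    "mmr": {
        "source": "traits",
        "response": "mmr_adj",
        "mains": ["trial", "group_size", "shelter_avail", "mass"],
        "protected": ["trial", "group_size", "shelter_avail"],
        "random": "fish",
    },
    "as": {
        "source": "traits",
        "response": "aerobic_scope_adj",
        "mains": ["trial", "group_size", "shelter_avail", "mass"],
        "protected": ["trial", "group_size", "shelter_avail"],
        "random": "fish",
    },
}


def _family_frame(
    family: str, traits: Optional[pd.DataFrame], mo2min_long: Optional[pd.DataFrame]
) -> pd.DataFrame:
    spec = FAMILIES[family]
    if spec["source"] == "mo2min_long":
        if mo2min_long is None:
            raise ValueError(f"family {family!r} needs the windowed-minimum table")
        df = mo2min_long[mo2min_long["photoperiod"] == spec["photoperiod"]].copy()
        df = df[df["valid"].astype(bool)]
        df["day"] = df["trial_day"].map({1: "1", 2: "2"}).astype("category")
        df["shelter"] = (
            df["shelter_on"].astype(int).map({0: "absent", 1: "present"}).astype("category")
        )
        df["mass"] = df["mass_g"].astype(float)
        resp_src = spec["response"]
    else:
        if traits is None:
            raise ValueError(f"family {family!r} needs the traits table")
        df = traits.copy()
        df["group_size"] = df["group_size"].astype(int).astype(str).astype("category")
        df["shelter_avail"] = (
            df["shelter_available"].astype(int).map({0: "absent", 1: "present"}).astype("category")
        )
        df["mass"] = df["mass_g"].astype(float)
        resp_src = spec["response"]
    df["trial"] = pd.Categorical(df["trial"], categories=["initial", "final"])
    df = df[np.isfinite(df[resp_src].astype(float)) & (df[resp_src] > 0)]
    df["y"] = np.log(df[resp_src].astype(float))
    return df


def fit_family(
    family: str,
    traits: Optional[pd.DataFrame] = None,
    mo2min_long: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    flavor: str = "lrt",
    include_mass: bool = True,
    reduce: bool = True,
) -> Dict[str, object]:
    """Fit one analysis family end to end and assemble its report tables.

    Fits the full fixed structure (main effects plus all two-way
    interactions, log response), backward-reduces the removable terms,
    then reports per-term chi-square tests, marginal/conditional R^2 and
    percentage effect sizes for the categorical terms of the final model.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    spec = FAMILIES[family]
    df = _family_frame(family, traits, mo2min_long)
    mains = [m for m in spec["mains"] if include_mass or m != "mass"]
    terms = _two_way(mains)
    full = fit_lmm(df, "y", terms, random=spec["random"])
    if reduce:
        reduced, trace = backward_reduce(full, spec["protected"], alpha=alpha, flavor=flavor)
    else:
        reduced, trace = full, pd.DataFrame(columns=["step", "dropped", "chi2", "df", "p"])
    r2m, r2c = r2_nakagawa(reduced)
    rows = []
    for term in reduced.terms:
        if not _marginality_ok(term, reduced.terms):
            chi2, dfree, p = np.nan, 0, np.nan  # main effect shadowed by interaction
        else:
            chi2, dfree, p = test_term(reduced, term, flavor=flavor)
        rows.append(
            {
                "response": f"log {spec['response']}",
                "effect": term,
                "chi2": chi2,
                "df": dfree,
                "p": p,
                "r2_m_pct": 100 * r2m,
                "r2_c_pct": 100 * r2c,
            }
        )
    model_table = pd.DataFrame(rows)
    # contrast direction: later state relative to earlier/reference state
    preferred = {
        "trial": ("final", "initial"),
        "day": ("2", "1"),
        "shelter": ("present", "absent"),
        "shelter_avail": ("present", "absent"),
        "group_size": ("8", "4"),
    }
    effects = []
    cat_terms = [
        t
        for t in reduced.terms
        if ":" not in t and str(df[t].dtype) in ("category", "object")
    ]
    for t in cat_terms:
        try:
            pct, (a, b) = effect_size_pct(reduced, t, levels=preferred.get(t))
        except ValueError:
            continue
        effects.append({"factor": t, "level": str(a), "vs": str(b), "effect_pct": pct})
    return {
        "family": family,
        "data": df,
        "full": full,
        "model": reduced,
        "trace": trace,
        "model_table": model_table,
        "effects": pd.DataFrame(effects, columns=["factor", "level", "vs", "effect_pct"]),
        "r2": (r2m, r2c),
        "random_used": reduced.random,
        "singular_full": full.singular,
    }
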