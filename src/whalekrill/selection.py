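"""Covariate-selection protocol for the abundance models.

Three-stage procedure applied independently to each model part:

1. **Univariate screening.** Oceanographic and bathymetric covariates are
   tested on the polynomial ladder (linear → quartic) and enter the full
   model at the highest order whose top coefficient is significant
   (p < 0.05). Distance covariates are tested at four functional forms
   (linear, quadratic, log, inverse-log) and enter at the most significant
   form (smallest likelihood-ratio p against the null). Climate indices
   are tested at lags 0-3 months (quadratic form by default) and enter at
   the most significant lag. Covariates with no significant candidate are
   excluded.
2. **Backward stepwise elimination.** From the assembled full model the
   least significant droppable term is removed (a polynomial drops from
   its top order down — marginality is enforced), the model is refit, and
   the step is kept only if AIC decreases; elimination stops when every
   term is significant. Over the resulting path the final model is the
   lowest-AIC model when it beats the runner-up by more than 2 AIC units,
   otherwise the lowest-BIC model among those within 2 units.
3. **Year interactions.** For static (bathymetric/distance) covariates
   retained in the model, a year-interaction block is tested by likelihood
   ratio and kept when p < 0.05 with an AIC improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .glm import DesignSpec, Term

POLY_LADDER = ("linear", "quadratic", "cubic", "quartic")
DISTANCE_FORMS = ("linear", "quadratic", "log", "invlog")
_ORDER_OF = glm.POLY_ORDERS


def fit_family(spec: DesignSpec, data: pd.DataFrame):
    if spec.family == "logistic":
        return glm.fit_logistic(spec, data)
    if spec.family == "negbin":
        return glm.fit_negbin(spec, data)
    if spec.family == "trunc-negbin":
        return glm.fit_truncated_negbin(spec, data)
    raise ValueError(f"unknown family {spec.family!r}")


def default_variable_class(covariate: str) -> str:
    from .synthetic import CLIMATE_INDICES, DISTANCE_VARS, OCEAN_VARS

    if covariate in OCEAN_VARS or covariate in ("depth", "contour_index"):
        return "polynomial"
    if covariate in DISTANCE_VARS:
        return "distance"
    if covariate in CLIMATE_INDICES:
        return "climate"
    raise ValueError(f"no default class for covariate {covariate!r}")


@dataclass
class ScreenResult:
    """Univariate screening outcome for one covariate."""

    covariate: str
    var_class: str
    candidates: pd.DataFrame  # label, p_value, aic per candidate
    chosen: Term | None  # None => excluded from the full model


def screen_variable(
    covariate: str,
    var_class: str,
    data: pd.DataFrame,
    response: str,
    family: str,
    offset: str | None = None,
    alpha: float = 0.05,
    climate_form: str = "quadratic",
) -> ScreenResult:
    """Univariate functional-form / lag screening for one covariate.

    ``var_class``: "polynomial" (oceanographic/bathymetric ladder),
    "distance" (four transforms, most significant wins), or "climate"
    (lags 0-3 at ``climate_form``, most significant wins).
    """
    rows: list[dict] = []
    chosen: Term | None = None
    if var_class == "polynomial":
        for form in POLY_LADDER:
            term = Term(covariate, form)
            p, aic = _wald_top_p(term, data, response, family, offset)
            rows.append(dict(label=form, p_value=p, aic=aic))
        # highest order whose top coefficient is significant
        for form in reversed(POLY_LADDER):
            p = next(r["p_value"] for r in rows if r["label"] == form)
            if np.isfinite(p) and p < alpha:
                chosen = Term(covariate, form)
                break
    elif var_class == "distance":
        for form in DISTANCE_FORMS:
            term = Term(covariate, form)
            p, aic = _block_lrt_p(term, data, response, family, offset)
            rows.append(dict(label=form, p_value=p, aic=aic))
        chosen = _most_significant(rows, alpha, lambda lbl: Term(covariate, lbl))
    elif var_class == "climate":
        for lag in range(4):
            term = Term(covariate, climate_form, lag=lag)
            p, aic = _block_lrt_p(term, data, response, family, offset)
            rows.append(dict(label=f"lag{lag}", p_value=p, aic=aic))
        chosen = _most_significant(
            rows, alpha, lambda lbl: Term(covariate, climate_form, lag=int(lbl[3:]))
        )
    else:
        raise ValueError(f"unknown variable class {var_class!r}")
    return ScreenResult(covariate, var_class, pd.DataFrame(rows), chosen)


def _most_significant(rows, alpha, make_term):
    ok = [r for r in rows if np.isfinite(r["p_value"]) and r["p_value"] < alpha]
    if not ok:
        return None
    best = min(ok, key=lambda r: (r["p_value"], r["aic"]))
    return make_term(best["label"])


def _wald_top_p(term, data, response, family, offset):
    spec = DesignSpec(response, [term], offset, family)
    try:
        fit = fit_family(spec, data)
    except Exception:
        return np.nan, np.nan
    top = term.design_columns()[-1]
    return float(fit.pvalues[top]), float(fit.aic)


def _block_lrt_p(term, data, response, family, offset):
    spec = DesignSpec(response, [term], offset, family)
    null_spec = DesignSpec(response, [], offset, family)
    try:
        fit = fit_family(spec, data)
        null = fit_family(null_spec, data)
    except Exception:
        return np.nan, np.nan
    df = len(term.design_columns())
    lr = 2.0 * (fit.llf - null.llf)
    return float(stats.chi2.sf(max(lr, 0.0), df)), float(fit.aic)


def screen_all(
    covariates: dict[str, str],
    data: pd.DataFrame,
    response: str,
    family: str,
    offset: str | None = None,
    alpha: float = 0.05,
    climate_form: str = "quadratic",
) -> tuple[list[ScreenResult], DesignSpec]:
    """Screen every covariate ({name: class}) and assemble the full design."""
    results = [
        screen_variable(c, cls, data, response, family, offset, alpha, climate_form)
        for c, cls in covariates.items()
    ]
    terms = [r.chosen for r in results if r.chosen is not None]
    return results, DesignSpec(response, terms, offset, family)


# --------------------------------------------------------------------------
# Backward stepwise


@dataclass
class StepwisePath:
    """Record of the backward elimination and the selection rule applied."""

    steps: pd.DataFrame  # step, action, aic, bic, n_columns
    models: list[DesignSpec]
    final: DesignSpec
    final_fit: object
    rule: str  # "delta_aic_gt2" | "bic_tiebreak"
    deadlock: bool = False
    deadlock_terms: list[str] = field(default_factory=list)
    aic_conflicts: list[str] = field(default_factory=list)  # forced drops


def _droppable(term: Term) -> tuple[str, Term | None]:
    """Top design column to test and the reduced term (None = removal)."""
    cols = term.design_columns()
    top = cols[-1]
    if term.transform in _ORDER_OF and _ORDER_OF[term.transform] > 1:
        ladder = list(_ORDER_OF)
        reduced = replace(term, transform=ladder[_ORDER_OF[term.transform] - 2])
        return top, reduced
    return top, None


def backward_stepwise(
    full_design: DesignSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> StepwisePath:
    """Manual-style backward elimination with the ΔAIC-2 / BIC rule.

    Marginality is enforced: a polynomial sheds its top order first.
    Elimination continues until every term is significant: at each step
    the drop that reduces AIC is preferred (candidates tried in order of
    decreasing p), but when no candidate reduces AIC the least significant
    term is still removed and the step is recorded in ``aic_conflicts`` —
    the ΔAIC-2 / BIC rule over the whole path then adjudicates between the
    larger and the fully-pruned model. ``deadlock`` is reported only when
    a forced removal cannot be fit at all.
    """
    if not full_design.terms:
        raise ValueError("full design has no terms")
    design = full_design
    fit = fit_family(design, data)
    models = [design]
    fits = [fit]
    steps = [dict(step=0, action="full model", aic=fit.aic, bic=fit.bic,
                  n_columns=fit.k_params)]
    deadlock = False
    deadlock_terms: list[str] = []
    aic_conflicts: list[str] = []
    while design.terms:
        candidates = []
        for i, term in enumerate(design.terms):
            top, reduced = _droppable(term)
            p = float(fit.pvalues[top])
            if np.isnan(p) or p >= alpha:
                candidates.append((p, i, top, reduced))
        if not candidates:
            break
        # least significant first; ties break lexicographically by column.
        # A drop is kept only if AIC decreases; otherwise the next most
        # non-significant candidate is tried. Deadlock when none works.
        candidates.sort(key=lambda c: (c[0], c[2]), reverse=True)
        accepted = forced = None
        for p, i, top, reduced in candidates:
            new_terms = list(design.terms)
            if reduced is None:
                new_terms.pop(i)
            else:
                new_terms[i] = reduced
            new_design = replace(design, terms=new_terms)
            try:
                new_fit = fit_family(new_design, data)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if new_fit.aic < fit.aic:
                accepted = (new_design, new_fit, top)
                break
            if forced is None:
                forced = (new_design, new_fit, top)
        if accepted is None and forced is None:
            deadlock, deadlock_terms = True, [c[2] for c in candidates]
            warnings.warn(
                "stepwise deadlock: no droppable non-significant term can be "
                f"refit ({deadlock_terms})"
            )
            break
        if accepted is None:
            design, fit, top = forced
            aic_conflicts.append(top)
            action = f"drop {top} (AIC increased)"
        else:
            design, fit, top = accepted
            action = f"drop {top}"
        models.append(design)
        fits.append(fit)
        steps.append(dict(step=len(steps), action=action, aic=fit.aic,
                          bic=fit.bic, n_columns=fit.k_params))

    aics = np.array([f.aic for f in fits])
    finite = [i for i in range(len(aics)) if np.isfinite(aics[i])]
    if not finite:  # every fit on the path failed to converge
        best, rule = len(aics) - 1, "delta_aic_gt2"
    else:
        order = sorted(finite, key=lambda i: aics[i])
        if len(order) == 1 or aics[order[1]] - aics[order[0]] > 2.0:
            best, rule = order[0], "delta_aic_gt2"
        else:
            within = [i for i in finite if aics[i] - aics[order[0]] <= 2.0]
            best = min(within, key=lambda i: fits[i].bic)
            rule = "bic_tiebreak"
    return StepwisePath(
        pd.DataFrame(steps), models, models[best], fits[best], rule,
        deadlock, deadlock_terms, aic_conflicts,
    )


# --------------------------------------------------------------------------
# Year interactions


def year_interaction_test(
    base_design: DesignSpec,
    data: pd.DataFrame,
    static_vars: list[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, DesignSpec]:
    """Likelihood-ratio test of a year interaction for each static covariate.

    Each candidate must already be in the base design (contract). Year
    enters as a categorical factor on the covariate's linear column. Year
    levels with fewer than 2 observations cause that interaction to be
    skipped with a warning. Returns the per-variable LRT table and the
    design augmented with every retained interaction.
    """
    base_fit = fit_family(base_design, data)
    in_design = {t.covariate: i for i, t in enumerate(base_design.terms)}
    counts = data["year"].value_counts()
    rows = []
    keep: list[str] = []
    for var in static_vars:
        if var not in in_design:
            raise ValueError(f"static variable {var!r} is not in the base model")
        if (counts < 2).any():
            warnings.warn(
                f"year levels with <2 observations "
                f"({counts[counts < 2].index.tolist()}); "
                f"interaction with {var!r} skipped"
            )
            rows.append(dict(variable=var, lr=np.nan, df=np.nan, p_value=np.nan,
                             aic=np.nan, retained=False))
            continue
        aug = _augment(base_design, in_design[var])
        fit = fit_family(aug, data)
        df = fit.k_params - base_fit.k_params
        lr = 2.0 * (fit.llf - base_fit.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df))
        retained = bool(p < alpha and fit.aic < base_fit.aic)
        rows.append(dict(variable=var, lr=float(lr), df=df, p_value=p,
                         aic=float(fit.aic), retained=retained))
        if retained:
            keep.append(var)
    augmented = base_design
    for var in keep:
        idx = {t.covariate: i for i, t in enumerate(augmented.terms)}[var]
        augmented = _augment(augmented, idx)
    return pd.DataFrame(rows), augmented


def _augment(design: DesignSpec, term_index: int) -> DesignSpec:
    terms = list(design.terms)
    terms[term_index] = replace(terms[term_index], by_year=True)
    return replace(design, terms=terms)
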