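"""Covariate term evaluation shared by the generator and the GLM engine.

A *term* is a string naming a single design-matrix column built from one
covariate column of a bin/cell table:

- ``"depth"``                plain (linear) value
- ``"depth^2"`` .. ``"^4"``  pure power of the covariate
- ``"log(dist_200m)"``       ln(1 + x), defined for x >= 0
- ``"invlog(dist_200m)"``    1 / (1 + ln(1 + x)), a bounded decreasing
                             transform of distance
- ``"soi_lag2"``             climate index columns are ordinary columns
- ``"contour_index:year"``   interaction of the linear covariate with
                             categorical year (expands to one column per
                             non-reference year level)

Linear predictors for simulation truth are dicts ``{term: coefficient}``
with ``"1"`` as the intercept key.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

_POWER_RE = re.compile(r"^(?P<name>[A-Za-z_][A-Za-z0-9_]*)\^(?P<power>[234])$")
_FUNC_RE = re.compile(r"^(?P<func>log|invlog)\((?P<name>[A-Za-z_][A-Za-z0-9_]*)\)$")


def log1p_transform(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log transform requires non-negative covariate values")
    return np.log1p(x)


def invlog_transform(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + log1p_transform(x))


def base_covariate(term: str) -> str:
    """The covariate column a term is built from (intercept -> '1')."""
    if term == "1":
        return "1"
    if ":" in term:
        return term.split(":", 1)[0]
    m = _POWER_RE.match(term)
    if m:
        return m.group("name")
    m = _FUNC_RE.match(term)
    if m:
        return m.group("name")
    return term


def eval_term(df: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate a non-interaction term to a single column."""
    if term == "1":
        return np.ones(len(df))
    m = _POWER_RE.match(term)
    if m:
        name, power = m.group("name"), int(m.group("power"))
        _require(df, name, term)
        return np.asarray(df[name], dtype=float) ** power
    m = _FUNC_RE.match(term)
    if m:
        func, name = m.group("func"), m.group("name")
        _require(df, name, term)
        x = np.asarray(df[name], dtype=float)
        return log1p_transform(x) if func == "log" else invlog_transform(x)
    _require(df, term, term)
    return np.asarray(df[term], dtype=float)


def linear_predictor(df: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """Sum coefficient * term over a {term: coef} dict (incl. '1')."""
    eta = np.zeros(len(df))
    for term, coef in coefs.items():
        eta += coef * eval_term(df, term)
    return eta


def _require(df: pd.DataFrame, column: str, term: str) -> None:
    if column not in df.columns:
        raise KeyError(
            f"term {term!r} needs covariate column {column!r}, "
            f"which is not present in the data"
        )
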