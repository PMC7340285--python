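"""Model-fitting core: logistic, NB2, zero-truncated NB2, hurdle, ZINB.

Count families use the NB2 parameterization (variance μ + μ²/θ); fitting
is backed by statsmodels (Logit, NegativeBinomial,
TruncatedLFNegativeBinomialP, ZeroInflatedNegativeBinomialP) behind a
uniform :class:`ModelFit` surface. The two-part hurdle — a logistic model
for zero vs positive and a zero-truncated NB2 conditional on positivity —
is estimated by maximizing the two orthogonal likelihoods independently;
the effort offset (log acoustic volume for krill, log survey area for
whales) enters the count part with fixed coefficient 1.

Also provides the diagnostic battery: Vuong non-nested comparison, VIF,
Moran's I on residuals, Nagelkerke pseudo-R², and repeated k-fold CV.

AIC/BIC are computed here as 2k − 2ℓ and k·log(n) − 2ℓ with k counting
every estimated parameter including dispersion θ and any zero-inflation
coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.discrete.discrete_model import Logit, NegativeBinomial, Poisson
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

from .terms import eval_term

POLY_ORDERS = {"linear": 1, "quadratic": 2, "cubic": 3, "quartic": 4}
TRANSFORMS = tuple(POLY_ORDERS) + ("log", "invlog")


# --------------------------------------------------------------------------
# Design specification


@dataclass
class Term:
    """One covariate's entry in a design.

    ``transform`` ∈ {linear, quadratic, cubic, quartic, log, invlog};
    polynomial transforms include all lower orders. ``lag`` (0-3) selects a
    climate index lag column ``{covariate}_lag{lag}``. ``by_year`` adds an
    interaction of the linear covariate with categorical year.
    """

    covariate: str
    transform: str = "linear"
    lag: int | None = None
    by_year: bool = False

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.lag is not None and self.lag not in (0, 1, 2, 3):
            raise ValueError("lag must be in 0-3")

    @property
    def column(self) -> str:
        return f"{self.covariate}_lag{self.lag}" if self.lag is not None else self.covariate

    def design_columns(self, year_levels: list | None = None) -> list[str]:
        col = self.column
        if self.transform in POLY_ORDERS:
            order = POLY_ORDERS[self.transform]
            cols = [col] + [f"{col}^{p}" for p in range(2, order + 1)]
        else:
            cols = [f"{self.transform}({col})"]
        if self.by_year:
            if not year_levels:
                raise ValueError(f"term {col}: year interaction needs year levels")
            cols += [f"{col}:year[{lev}]" for lev in year_levels[1:]]
        return cols


@dataclass
class DesignSpec:
    """Response, term list, offset and family for one model part."""

    response: str
    terms: list[Term]
    offset: str | None = None  # effort column; enters as log(column) with coef 1
    family: str = "negbin"  # logistic | negbin | trunc-negbin

    def __post_init__(self) -> None:
        seen = [t.column for t in self.terms]
        if len(seen) != len(set(seen)):
            raise ValueError(f"duplicate covariates in design: {seen}")

    def build(
        self, data: pd.DataFrame, year_levels: list | None = None
    ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray | None]:
        """Return (y, X with intercept, offset array or None)."""
        if year_levels is None and any(t.by_year for t in self.terms):
            year_levels = sorted(data["year"].unique())
        cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
        for t in self.terms:
            for name in t.design_columns(year_levels):
                cols[name] = _design_column(data, name)
        X = pd.DataFrame(cols, index=data.index)
        y = np.asarray(data[self.response], dtype=float)
        off = None
        if self.offset is not None:
            eff = np.asarray(data[self.offset], dtype=float)
            if np.any(eff <= 0):
                raise ValueError(f"offset column {self.offset!r} must be positive")
            off = np.log(eff)
        return y, X, off


def _design_column(data: pd.DataFrame, name: str) -> np.ndarray:
    if ":year[" in name:
        base, lev = name.split(":year[")
        lev = lev.rstrip("]")
        year = data["year"].astype(str)
        return eval_term(data, base) * (year == lev).to_numpy().astype(float)
    return eval_term(data, name)


# --------------------------------------------------------------------------
# Fit container


@dataclass
class ModelFit:
    """Uniform wrapper over a fitted model part."""

    family: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    converged: bool
    theta: float | None = None
    spec: DesignSpec | None = None
    loglikeobs: np.ndarray | None = field(default=None, repr=False)
    null_llf: float | None = None

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.n) - 2.0 * self.llf

    def linpred(self, data: pd.DataFrame, offset_value: float | None = None) -> np.ndarray:
        """Linear predictor on new data; ``offset_value`` overrides the
        log-offset (0 gives per-unit-effort predictions)."""
        if self.spec is None:
            raise ValueError("fit has no design spec; cannot predict on new data")
        year_levels = _year_levels_from_params(self.params)
        cols = {"const": np.ones(len(data))}
        for name in self.params.index:
            if name != "const" and name != "alpha":
                cols[name] = _design_column(data, name)
        eta = np.zeros(len(data))
        for name, beta in self.params.items():
            if name == "alpha":
                continue
            eta += beta * cols[name]
        if self.spec.offset is not None:
            if offset_value is None:
                eta += np.log(np.asarray(data[self.spec.offset], dtype=float))
            else:
                eta += offset_value
        return eta

    def predict(self, data: pd.DataFrame, offset_value: float | None = None) -> np.ndarray:
        """Response-scale prediction (probability, NB mean, or ZTNB mean)."""
        eta = self.linpred(data, offset_value)
        if self.family == "logistic":
            return 1.0 / (1.0 + np.exp(-eta))
        mu = np.exp(eta)
        if self.family == "trunc-negbin":
            return mu / (1.0 - nb_zero_prob(mu, self.theta))
        return mu


def _year_levels_from_params(params: pd.Series) -> list[str]:
    return [n.split(":year[")[1].rstrip("]") for n in params.index if ":year[" in n]


# --------------------------------------------------------------------------
# NB2 / hurdle distribution helpers


def nb_zero_prob(mu, theta: float) -> np.ndarray:
    """P(Y = 0) for NB2 with mean mu and dispersion theta."""
    mu = np.asarray(mu, dtype=float)
    return (theta / (theta + mu)) ** theta


def ztnb_pmf(y, mu, theta: float) -> np.ndarray:
    """Zero-truncated NB2 pmf over y >= 1."""
    y = np.asarray(y)
    p = theta / (theta + mu)
    base = stats.nbinom.pmf(y, theta, p)
    out = base / (1.0 - stats.nbinom.pmf(0, theta, p))
    return np.where(y < 1, 0.0, out)


def hurdle_mean(presence_p, mu, theta: float) -> np.ndarray:
    """E[Y] of the hurdle: π · μ / (1 − NB(0; μ, θ))."""
    return np.asarray(presence_p) * np.asarray(mu) / (1.0 - nb_zero_prob(mu, theta))


# --------------------------------------------------------------------------
# Fitting


def _standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score non-intercept columns for optimizer stability.

    Raw-scale polynomial columns (e.g. salinity³) condition the Hessian
    terribly; every fit runs on standardized columns and the results are
    mapped back to the natural scale afterwards.
    """
    Xs = X.copy()
    scale: dict[str, tuple[float, float]] = {}
    for col in X.columns:
        if col == "const":
            continue
        m = float(X[col].mean())
        s = float(X[col].std(ddof=0))
        if not np.isfinite(s) or s == 0.0:
            m, s = 0.0, 1.0
        Xs[col] = (X[col] - m) / s
        scale[col] = (m, s)
    return Xs, scale


def _raw_scale_results(res, blocks) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Map standardized-scale MLE results back to the natural scale.

    The standardization is affine per column, so coefficients transform
    linearly (β_raw = T β_std) and the covariance as T Σ Tᵀ. ``blocks`` is
    a list of (intercept name, {column: (mean, sd)}) — one block per
    linear predictor (the ZINB has two).
    """
    names = list(res.params.index)
    beta = np.asarray(res.params, dtype=float)
    T = np.eye(len(beta))
    idx = {n: i for i, n in enumerate(names)}
    for const_name, scale in blocks:
        ci = idx[const_name]
        for col, (m, s) in scale.items():
            j = idx[col]
            T[j, j] = 1.0 / s
            T[ci, j] = -m / s
    raw = T @ beta
    try:
        cov = np.asarray(res.cov_params())
    except (ValueError, np.linalg.LinAlgError):
        # degenerate Hessian (non-converged fit): diagonal fallback keeps
        # the report usable; SEs of such fits are unreliable regardless
        cov = np.diag(np.square(np.asarray(res.bse, dtype=float)))
    if not np.all(np.isfinite(cov)):
        cov = np.where(np.isfinite(cov), cov, 0.0)
    bse = np.sqrt(np.maximum(np.diag(T @ cov @ T.T), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bse > 0, raw / bse, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return (
        pd.Series(raw, index=names),
        pd.Series(bse, index=names),
        pd.Series(pvals, index=names),
    )


def _check_response(y: np.ndarray, family: str) -> None:
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError(f"{family}: response must be non-negative integers")
    if np.all(y == 0):
        raise ValueError(f"{family}: response is all zeros; no finite MLE")


def fit_logistic(spec: DesignSpec, data: pd.DataFrame) -> ModelFit:
    y, X, off = spec.build(data)
    y = (y > 0).astype(float)
    if y.min() == y.max():
        raise ValueError("logistic: response has a single class")
    Xs, scale = _standardize(X)
    model = Logit(y, Xs, offset=off)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # singular Hessian (collinear design / separation): quasi-Newton
            res = model.fit(disp=0, maxiter=500, method="bfgs")
    params, bse, pvalues = _raw_scale_results(res, [("const", scale)])
    return ModelFit(
        "logistic", params, bse, pvalues, float(res.llf), int(res.nobs),
        bool(res.mle_retvals.get("converged", True)), None, spec,
        model.loglikeobs(np.asarray(res.params)), float(res.llnull),
    )


def fit_negbin(spec: DesignSpec, data: pd.DataFrame) -> ModelFit:
    """NB2 GLM with log link; start values from a Poisson fit plus a
    method-of-moments dispersion estimate (reproducible by construction)."""
    y, X, off = spec.build(data)
    _check_response(y, "negbin")
    Xs, scale = _standardize(X)
    start = _nb_start(y, Xs, off)
    model = NegativeBinomial(y, Xs, offset=off, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start, disp=0, maxiter=500, method="bfgs")
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=res.params, disp=0, maxiter=500, method="nm")
            res = model.fit(start_params=res.params, disp=0, maxiter=500, method="bfgs")
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        warnings.warn("negbin fit did not converge; flagged")
    alpha = float(res.params["alpha"])
    theta = 1.0 / alpha if alpha > 0 else np.inf
    params, bse, pvalues = _raw_scale_results(res, [("const", scale)])
    return ModelFit(
        "negbin", params, bse, pvalues, float(res.llf), int(res.nobs),
        converged, theta, spec, model.loglikeobs(np.asarray(res.params)),
    )


def _nb_start(y, X, off) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = Poisson(y, X, offset=off)
        try:
            pois = model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            pois = model.fit(disp=0, maxiter=500, method="bfgs")
    mu = pois.predict()
    resid2 = (y - mu) ** 2
    denom = float(np.sum(mu**2))
    alpha = max(float(np.sum(resid2 - mu) / denom), 0.01) if denom > 0 else 0.1
    return np.append(pois.params, alpha)


def fit_truncated_negbin(spec: DesignSpec, data: pd.DataFrame) -> ModelFit:
    """Zero-truncated NB2 on the positive observations only."""
    pos = data[np.asarray(data[spec.response], dtype=float) > 0]
    if len(pos) == 0:
        raise ValueError("trunc-negbin: no positive observations")
    y, X, off = spec.build(pos)
    _check_response(y, "trunc-negbin")
    Xs, scale = _standardize(X)
    start = _nb_start(y, Xs, off)
    model = TruncatedLFNegativeBinomialP(y, Xs, offset=off, truncation=0, p=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start, disp=0, maxiter=500, method="bfgs")
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=res.params, disp=0, maxiter=500, method="nm")
            res = model.fit(start_params=res.params, disp=0, maxiter=500, method="bfgs")
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        warnings.warn("trunc-negbin fit did not converge; flagged")
    alpha = float(res.params["alpha"])
    theta = 1.0 / alpha if alpha > 0 else np.inf
    params, bse, pvalues = _raw_scale_results(res, [("const", scale)])
    return ModelFit(
        "trunc-negbin", params, bse, pvalues, float(res.llf),
        int(res.nobs), converged, theta, spec, model.loglikeobs(np.asarray(res.params)),
    )


@dataclass
class HurdleFit:
    """Two-part hurdle: logistic presence × zero-truncated NB2 abundance.

    The parts are estimated independently (their likelihoods are
    orthogonal); combined AIC/BIC use the summed log-likelihood, the total
    parameter count, and the full number of observations. A degenerate
    part (no zeros, or no positives) is recorded as an error string while
    the other part still fits.
    """

    zero: ModelFit | None
    count: ModelFit | None
    n: int
    errors: dict = field(default_factory=dict)

    @property
    def llf(self) -> float:
        return sum(p.llf for p in (self.zero, self.count) if p is not None)

    @property
    def k_params(self) -> int:
        return sum(p.k_params for p in (self.zero, self.count) if p is not None)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.n) - 2.0 * self.llf

    @property
    def converged(self) -> bool:
        return all(p.converged for p in (self.zero, self.count) if p is not None)

    def predict(self, data: pd.DataFrame, offset_value: float | None = None) -> np.ndarray:
        if self.zero is None or self.count is None:
            raise ValueError(f"hurdle has a degenerate part: {self.errors}")
        p = self.zero.predict(data)
        mu = np.exp(self.count.linpred(data, offset_value))
        return hurdle_mean(p, mu, self.count.theta)


def fit_hurdle(
    zero_spec: DesignSpec, count_spec: DesignSpec, data: pd.DataFrame
) -> HurdleFit:
    if zero_spec.response != count_spec.response:
        raise ValueError("hurdle parts must share a response")
    zero = count = None
    errors = {}
    y = np.asarray(data[zero_spec.response], dtype=float)
    try:
        if np.all(y > 0):
            raise ValueError("hurdle zero part: data contain no zeros")
        zero = fit_logistic(zero_spec, data)
    except ValueError as exc:
        errors["zero"] = str(exc)
    try:
        count = fit_truncated_negbin(count_spec, data)
    except ValueError as exc:
        errors["count"] = str(exc)
    if zero is None and count is None:
        raise ValueError(f"both hurdle parts degenerate: {errors}")
    return HurdleFit(zero, count, len(data), errors)


def fit_zinb(
    count_spec: DesignSpec,
    data: pd.DataFrame,
    zero_terms: list[Term] | None = None,
) -> ModelFit:
    """Zero-inflated NB2 by joint ML. ``zero_terms`` build the inflation
    design (e.g. detection covariates); default intercept-only. A boundary
    solution (inflation → 0) is reported, not failed."""
    y, X, off = count_spec.build(data)
    _check_response(y, "zinb")
    if zero_terms:
        infl_spec = DesignSpec(count_spec.response, zero_terms, None, "logistic")
        _, X_infl, _ = infl_spec.build(data)
    else:
        X_infl = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    Xs, scale = _standardize(X)
    Xs_infl, scale_infl = _standardize(X_infl)
    model = ZeroInflatedNegativeBinomialP(y, Xs, exog_infl=Xs_infl, offset=off, p=2)
    nb_start = _nb_start(y, Xs, off)
    start = np.concatenate([np.full(Xs_infl.shape[1], -2.0), nb_start])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start, disp=0, maxiter=500, method="bfgs")
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=res.params, disp=0, maxiter=1000, method="nm")
            res = model.fit(start_params=res.params, disp=0, maxiter=500, method="bfgs")
    converged = bool(res.mle_retvals.get("converged", False))
    alpha = float(res.params["alpha"])
    theta = 1.0 / alpha if alpha > 0 else np.inf
    blocks = [
        ("inflate_const", {f"inflate_{c}": ms for c, ms in scale_infl.items()}),
        ("const", scale),
    ]
    params, bse, pvalues = _raw_scale_results(res, blocks)
    return ModelFit(
        "zinb", params, bse, pvalues, float(res.llf), int(res.nobs),
        converged, theta, count_spec, model.loglikeobs(np.asarray(res.params)),
    )


def zinb_inflation_probs(fit: ModelFit, data: pd.DataFrame | None = None):
    """Structural-zero probability implied by a ZINB fit's inflation block
    (parameters prefixed ``inflate_``). With no data, the inflation design
    must be intercept-only and a scalar is returned."""
    infl = fit.params[[c for c in fit.params.index if c.startswith("inflate_")]]
    if data is None:
        if set(infl.index) != {"inflate_const"}:
            raise ValueError("covariate inflation needs data to evaluate")
        return float(1.0 / (1.0 + np.exp(-infl["inflate_const"])))
    eta = np.zeros(len(data))
    for name, b in infl.items():
        col = name.removeprefix("inflate_")
        eta += b * (np.ones(len(data)) if col == "const" else _design_column(data, col))
    return 1.0 / (1.0 + np.exp(-eta))


# --------------------------------------------------------------------------
# Diagnostics


def vuong_test(fit_a, fit_b, alpha: float = 0.05) -> tuple[float, float, str]:
    """Vuong non-nested comparison from per-observation log-likelihoods.

    z = √n · mean(mᵢ) / sd(mᵢ), mᵢ = ℓ_a,i − ℓ_b,i; two-sided normal p.
    ``preferred`` is "a" / "b" only when p < alpha, else "neither".
    """
    la, lb = np.asarray(fit_a.loglikeobs), np.asarray(fit_b.loglikeobs)
    if la.shape != lb.shape:
        raise ValueError("fits compare different observation sets")
    m = la - lb
    n = len(m)
    sd = m.std(ddof=1)
    if sd == 0.0:
        return 0.0, 1.0, "neither"
    z = np.sqrt(n) * m.mean() / sd
    p = 2.0 * stats.norm.sf(abs(z))
    if p < alpha:
        return float(z), float(p), "a" if z > 0 else "b"
    return float(z), float(p), "neither"


def vif(model_matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per non-intercept column.

    VIF_j = 1 / (1 − R²_j) from regressing column j on the others (with
    intercept). Perfect collinearity reports inf explicitly.
    """
    X = model_matrix.drop(columns=[c for c in ("const",) if c in model_matrix])
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 non-intercept columns")
    out = {}
    arr = X.to_numpy(dtype=float)
    ones = np.ones((len(X), 1))
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        Xo = np.hstack([ones, np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0.0 or ss_res <= 1e-12 * max(ss_tot, 1.0):
            out[name] = np.inf
        else:
            out[name] = 1.0 / (ss_res / ss_tot)
    return pd.Series(out, name="vif")


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float
    defined: bool = True


def morans_i(
    residuals: np.ndarray,
    locations: np.ndarray,
    weights: str | float = "inverse_distance",
    band_km: float | None = None,
) -> MoranResult:
    """Global Moran's I with normality-based inference.

    ``weights``: "inverse_distance" (1/d, zero diagonal) or a numeric
    fixed band in km (binary within-band). E[I] = −1/(n−1).
    """
    res = np.asarray(residuals, dtype=float)
    loc = np.asarray(locations, dtype=float)
    n = len(res)
    if n < 10:
        raise ValueError("Moran's I needs >= 10 locations")
    if np.ptp(res) == 0.0:
        return MoranResult(np.nan, -1.0 / (n - 1), np.nan, np.nan, np.nan, False)
    d = cdist(loc, loc)
    if isinstance(weights, (int, float)):
        w = ((d > 0) & (d <= float(weights))).astype(float)
    elif weights == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = np.where(d > 0, 1.0 / d, 0.0)
    else:
        raise ValueError(f"unknown weight scheme {weights!r}")
    if band_km is not None:
        w[d > band_km] = 0.0
    z = res - res.mean()
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("weight matrix is empty (band too small?)")
    I = (n / s0) * float(z @ w @ z) / float(z @ z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    zscore = (I - e_i) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(float(I), e_i, float(var), float(zscore), float(p))


def nagelkerke_r2(llf: float, null_llf: float, n: int) -> float:
    """Nagelkerke pseudo-R² = (1 − e^{2(ℓ₀−ℓ₁)/n}) / (1 − e^{2ℓ₀/n})."""
    num = 1.0 - np.exp(2.0 * (null_llf - llf) / n)
    den = 1.0 - np.exp(2.0 * null_llf / n)
    if llf < null_llf:
        warnings.warn(
            "fitted log-likelihood below null; negative pseudo-R² signals an "
            "optimizer failure"
        )
    return float(num / den)


# --------------------------------------------------------------------------
# k-fold cross-validation


@dataclass
class CVReport:
    k: int
    runs: int
    rmse_training: float
    rmse_test: float
    mae_training: float
    mae_test: float
    per_run_rmse: list[float]
    per_run_mae: list[float]
    skipped_folds: int = 0


def kfold_cv(
    fitter,
    data: pd.DataFrame,
    response: str,
    k: int = 10,
    runs: int = 20,
    seed: int = 0,
) -> CVReport:
    """Repeated k-fold CV on the response scale.

    ``fitter(frame)`` must return an object with ``.predict(frame)``.
    Training RMSE/MAE come from the full-data fit; test metrics aggregate
    held-out predictions per run, then average over runs. Fold assignment
    derives from ``seed + run`` for reproducibility. A fold whose training
    complement loses a response class (e.g. all positives) is skipped with
    a warning.
    """
    n = len(data)
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    y = np.asarray(data[response], dtype=float)
    full = fitter(data)
    train_pred = np.asarray(full.predict(data), dtype=float)
    rmse_tr = float(np.sqrt(np.mean((train_pred - y) ** 2)))
    mae_tr = float(np.mean(np.abs(train_pred - y)))

    run_rmse, run_mae = [], []
    skipped = 0
    for run in range(runs):
        rng = np.random.default_rng(seed + run)
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        pred = np.full(n, np.nan)
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            train = data.iloc[mask.nonzero()[0]]
            try:
                fit = fitter(train)
            except ValueError as exc:
                warnings.warn(f"fold skipped in run {run}: {exc}")
                skipped += 1
                continue
            pred[fold] = np.asarray(fit.predict(data.iloc[fold]), dtype=float)
        ok = ~np.isnan(pred)
        run_rmse.append(float(np.sqrt(np.mean((pred[ok] - y[ok]) ** 2))))
        run_mae.append(float(np.mean(np.abs(pred[ok] - y[ok]))))
    return CVReport(
        k, runs, rmse_tr, float(np.mean(run_rmse)), mae_tr, float(np.mean(run_mae)),
        run_rmse, run_mae, skipped,
    )
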