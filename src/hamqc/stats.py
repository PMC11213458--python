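"""Correlation and multivariate regression of meat-quality variables.

Links the instrument-based quality measures (Py from bioimpedance,
ultimate pH, CIELAB L* a* b*) to the subjective DES score: pairwise
Pearson correlations with t-based significance, classic forward-backward
stepwise ordinary least squares over linear, squared and two-way
interaction terms, and prediction-error (RMSE / MAE) evaluation.  The DES
average (0-3 in 0.5 steps) is treated as a continuous response.

A frozen reference model is provided by :func:`printed_model`: the ten-term
equation relating the DES score to pH_u, L*, a*, b* and Py (AD muscle)
with squared and interaction terms, fitted on 136 animals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import DegenerateDataError, InputError
from .scoring import DesRank, rank_from_average

QUALITY_VARIABLES = ("py_ad", "ph_u", "l_star", "a_star", "b_star")


@dataclass
class QualityRecord:
    """One animal's quality measurements and DES scores.

    ``py_ad`` / ``py_sm`` are the Py statistics for the adductor and
    semimembranosus muscles; ``joint`` marks training samples scored
    jointly by both observers.
    """

    sample_id: str
    py_ad: float
    ph_u: float
    l_star: float
    a_star: float
    b_star: float
    des_obs1: int
    des_obs2: int
    des_avg: float
    des_rank: DesRank
    joint: bool = False
    py_sm: float | None = None

    def __post_init__(self):
        if not (0.0 < self.py_ad < 100.0):
            raise InputError(f"py_ad must be in (0, 100), got {self.py_ad}")
        if self.py_sm is not None and not (0.0 < self.py_sm < 100.0):
            raise InputError(f"py_sm must be in (0, 100), got {self.py_sm}")
        if not (4.5 < self.ph_u < 7.5):
            raise InputError(f"ph_u must be in (4.5, 7.5), got {self.ph_u}")
        if self.des_obs1 not in (0, 1, 2, 3) or self.des_obs2 not in (0, 1, 2, 3):
            raise InputError("observer scores must be integers in 0..3")
        expected = (self.des_obs1 + self.des_obs2) / 2.0
        if abs(self.des_avg - expected) > 1e-12:
            raise InputError(
                f"des_avg {self.des_avg} inconsistent with observer scores "
                f"({self.des_obs1}, {self.des_obs2})"
            )
        if self.des_rank != rank_from_average(self.des_avg):
            raise InputError(
                f"des_rank {self.des_rank} inconsistent with des_avg {self.des_avg}"
            )


def records_to_frame(records) -> pd.DataFrame:
    """Quality records as a DataFrame (des_rank stored by name, e.g. 'DES1')."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "py_ad": r.py_ad,
                "py_sm": r.py_sm,
                "ph_u": r.ph_u,
                "l_star": r.l_star,
                "a_star": r.a_star,
                "b_star": r.b_star,
                "des_obs1": r.des_obs1,
                "des_obs2": r.des_obs2,
                "des_avg": r.des_avg,
                "des_rank": r.des_rank.name,
                "joint": r.joint,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two variables with t-based p-value."""

    var_x: str
    var_y: str
    r: float
    p_value: float
    n: int

    @property
    def r_squared_pct(self) -> float:
        return self.r**2 * 100.0


def pearson_with_p(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Pearson r with a two-sided p-value.

    The p-value comes from t = r*sqrt((n-2)/(1-r^2)) against a Student t
    distribution with n-2 degrees of freedom (the standard exact test
    under bivariate normality).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 4:
        raise InputError(f"need at least 4 pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError(
            f"zero variance in {'x' if np.std(x) == 0 else 'y'} ({var_x}-{var_y})"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(var_x=var_x, var_y=var_y, r=r, p_value=p, n=n)


def correlation_matrix(records, variables) -> list[CorrelationResult]:
    """Pairwise Pearson correlations over all unordered variable pairs."""
    df = records_to_frame(records)
    if len(df) < 4:
        raise InputError(f"need at least 4 records, got {len(df)}")
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise InputError(f"missing variable column(s): {missing}")
    out = []
    for vx, vy in itertools.combinations(variables, 2):
        sub = df[[vx, vy]].dropna()
        try:
            out.append(
                pearson_with_p(sub[vx].to_numpy(), sub[vy].to_numpy(), vx, vy)
            )
        except (InputError, DegenerateDataError) as exc:
            raise type(exc)(f"pair ({vx}, {vy}): {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Regression terms and models


@dataclass(frozen=True)
class Term:
    """A regression term: a variable, its square, or a two-way product."""

    kind: str  # "linear" | "square" | "interaction"
    vars: tuple

    def __post_init__(self):
        if self.kind not in ("linear", "square", "interaction"):
            raise InputError(f"unknown term kind {self.kind!r}")
        n_expected = 2 if self.kind == "interaction" else 1
        if len(self.vars) != n_expected:
            raise InputError(f"{self.kind} term needs {n_expected} variable(s)")

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.vars[0]
        if self.kind == "square":
            return f"{self.vars[0]}^2"
        return f"{self.vars[0]}*{self.vars[1]}"

    def value(self, data) -> np.ndarray | float:
        try:
            if self.kind == "linear":
                return _col(data, self.vars[0])
            if self.kind == "square":
                v = _col(data, self.vars[0])
                return v * v
            return _col(data, self.vars[0]) * _col(data, self.vars[1])
        except KeyError as exc:
            raise InputError(f"missing variable {exc.args[0]!r} for term {self.name}") from None


def _col(data, name):
    if isinstance(data, pd.DataFrame):
        if name not in data.columns:
            raise KeyError(name)
        return data[name].to_numpy(dtype=float)
    if isinstance(data, dict):
        if name not in data:
            raise KeyError(name)
        return np.asarray(data[name], dtype=float)
    # fall back to attribute access (QualityRecord-like)
    if not hasattr(data, name):
        raise KeyError(name)
    return np.asarray(getattr(data, name), dtype=float)


def build_terms(
    variables, include_squares: bool = False, include_interactions: bool = False
) -> list[Term]:
    """Candidate term list: linear always, then squares, then all two-way
    products; each block in alphabetical order (deterministic)."""
    if not variables:
        raise InputError("need at least one variable")
    vs = sorted(variables)
    terms = [Term("linear", (v,)) for v in vs]
    if include_squares:
        terms += [Term("square", (v,)) for v in vs]
    if include_interactions:
        terms += [Term("interaction", pair) for pair in itertools.combinations(vs, 2)]
    return terms


@dataclass
class RegressionModel:
    """An OLS model over terms: intercept-first coefficients plus diagnostics.

    ``r_multiple`` is the correlation between fitted and observed response;
    ``prediction_error`` the in-sample RMSE of the residuals (with MAE
    alongside).
    """

    response: str
    terms: list
    coefficients: np.ndarray  # length len(terms) + 1; intercept first
    n: int
    r_multiple: float | None = None
    prediction_error: float | None = None
    mae: float | None = None
    p_values: np.ndarray | None = None  # per coefficient, intercept first
    skipped_terms: list = field(default_factory=list)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.terms) + 1:
            raise InputError(
                f"need {len(self.terms) + 1} coefficients for {len(self.terms)} terms, "
                f"got {len(self.coefficients)}"
            )

    @property
    def intercept_only(self) -> bool:
        return len(self.terms) == 0

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def equation(self) -> str:
        parts = [f"{self.intercept:+.4g}"]
        for t, c in zip(self.terms, self.coefficients[1:]):
            parts.append(f"{c:+.4g}({t.name})")
        return f"{self.response} = " + " ".join(parts)


def design_matrix(data, terms) -> np.ndarray:
    """Intercept-first design matrix for the given terms."""
    df = records_to_frame(data) if not isinstance(data, (pd.DataFrame, dict)) else data
    n = len(df) if isinstance(df, pd.DataFrame) else len(next(iter(df.values())))
    cols = [np.ones(n)]
    for t in terms:
        cols.append(np.asarray(t.value(df), dtype=float))
    return np.column_stack(cols)


def _ols(y, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.OLS(y, X).fit()


def fit_ols_model(data, response: str, terms) -> RegressionModel:
    """Fit OLS with the given fixed term list and attach diagnostics."""
    df = records_to_frame(data)
    y = _col(df, response)
    X = design_matrix(df, terms)
    res = _ols(y, X)
    fitted = X @ res.params
    resid = y - fitted
    if np.std(fitted) > 0 and np.std(y) > 0:
        r_mult = float(np.corrcoef(fitted, y)[0, 1])
    else:
        r_mult = 0.0
    return RegressionModel(
        response=response,
        terms=list(terms),
        coefficients=res.params,
        n=len(y),
        r_multiple=r_mult,
        prediction_error=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        p_values=np.asarray(res.pvalues, dtype=float),
    )


def stepwise_regression(
    data,
    response: str,
    candidates,
    alpha_enter: float = 0.15,
    alpha_remove: float = 0.15,
    force_hierarchy: bool = False,
) -> RegressionModel:
    """Classic forward-backward stepwise OLS term selection.

    Repeatedly adds the candidate term with the smallest partial-F
    p-value (equivalently, the t-test p-value of its coefficient in the
    augmented model) if below ``alpha_enter``, then removes any included
    term whose p-value exceeds ``alpha_remove``, until no move is
    possible.  Ties break on candidate order.  Terms whose addition makes
    the design rank-deficient are skipped with a warning.  If nothing
    enters, the intercept-only model is returned (``intercept_only`` set).

    ``force_hierarchy`` restricts squares/interactions to enter only once
    their parent linear terms are in the model (off by default).
    """
    df = records_to_frame(data)
    candidates = list(candidates)
    n = len(df)
    if n <= len(candidates) + 1:
        raise InputError(
            f"need n > number of candidates + 1; got n={n}, candidates={len(candidates)}"
        )
    y = _col(df, response)
    term_cols = {t: np.asarray(t.value(df), dtype=float) for t in candidates}

    included: list[Term] = []
    skipped: list[str] = []
    seen_states = set()

    def build_X(terms):
        return np.column_stack([np.ones(n)] + [term_cols[t] for t in terms])

    while True:
        state = tuple(t.name for t in included)
        if state in seen_states:
            break  # cycle guard
        seen_states.add(state)
        changed = False

        # forward step
        best_p, best_term = None, None
        for t in candidates:
            if t in included:
                continue
            if force_hierarchy and t.kind != "linear":
                parents = {Term("linear", (v,)) for v in t.vars}
                if not parents.issubset(set(included)):
                    continue
            X = build_X(included + [t])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                if t.name not in skipped:
                    skipped.append(t.name)
                    warnings.warn(
                        f"term {t.name} makes the design singular; skipped",
                        stacklevel=2,
                    )
                continue
            res = _ols(y, X)
            p = float(res.pvalues[-1])
            if best_p is None or p < best_p:
                best_p, best_term = p, t
        if best_term is not None and best_p < alpha_enter:
            included.append(best_term)
            changed = True

        # backward sweep
        while included:
            X = build_X(included)
            res = _ols(y, X)
            pvals = np.asarray(res.pvalues[1:], dtype=float)  # skip intercept
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                included.pop(worst)
                changed = True
            else:
                break

        if not changed:
            break

    model = fit_ols_model(df, response, included)
    model.skipped_terms = skipped
    return model


# ---------------------------------------------------------------------------
# The reference ten-term DES prediction model (fitted on 136 animals).

_PRINTED_TERMS = [
    Term("linear", ("ph_u",)),
    Term("linear", ("l_star",)),
    Term("linear", ("a_star",)),
    Term("linear", ("b_star",)),
    Term("linear", ("py_ad",)),
    Term("square", ("l_star",)),
    Term("square", ("a_star",)),
    Term("interaction", ("ph_u", "l_star")),
    Term("interaction", ("ph_u", "py_ad")),
    Term("interaction", ("l_star", "py_ad")),
]

_PRINTED_COEFFICIENTS = np.array(
    [-82.0, 17.3, 2.33, 0.854, 0.211, 0.834, 0.0054, -0.035, -0.54, 0.1165, 0.0034]
)


def printed_model() -> RegressionModel:
    """The frozen ten-term DES prediction equation (N = 136)::

        Score = -82.0 + 17.3 pH_u + 2.33 L* + 0.854 a* + 0.211 b*
                + 0.834 Py + 0.0054 L*^2 - 0.035 a*^2
                - 0.54 pH_u*L* + 0.1165 pH_u*Py + 0.0034 L**Py

    Py here is the adductor-muscle value (column ``py_ad``).  The stored
    diagnostics are the multiple correlation 0.71 and prediction error
    (RMSE) 0.76 reported for the original 136-animal fit.
    """
    return RegressionModel(
        response="des_avg",
        terms=list(_PRINTED_TERMS),
        coefficients=_PRINTED_COEFFICIENTS.copy(),
        n=136,
        r_multiple=0.71,
        prediction_error=0.76,
    )


def evaluate_model(model: RegressionModel, values, clamp: bool = False):
    """Linear predictor of a model at given variable values.

    ``values`` may be a dict of scalars/arrays, a DataFrame, or a
    :class:`QualityRecord`.  Returns a scalar for scalar input, else an
    array.  The raw predictor is not clamped to the 0-3 score range
    unless ``clamp=True``; outside the fitted data manifold the equation
    can stray far off-scale.
    """
    pred = np.asarray(model.coefficients[0], dtype=float)
    for t, c in zip(model.terms, model.coefficients[1:]):
        pred = pred + c * np.asarray(t.value(values), dtype=float)
    if clamp:
        pred = np.clip(pred, 0.0, 3.0)
    if np.ndim(pred) == 0:
        return float(pred)
    return pred


@dataclass(frozen=True)
class PredictionErrors:
    """RMSE (the headline prediction error) with MAE alongside."""

    rmse: float
    mae: float
    n: int


def prediction_error(model: RegressionModel, records, response: str | None = None) -> PredictionErrors:
    """RMSE and MAE of model predictions against the observed response."""
    df = records_to_frame(records)
    if len(df) == 0:
        raise InputError("no records to evaluate")
    resp = response or model.response
    if resp not in df.columns:
        raise InputError(f"missing response column {resp!r}")
    y = _col(df, resp)
    pred = evaluate_model(model, df)
    resid = np.asarray(pred) - y
    return PredictionErrors(
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        n=len(y),
    )


def loo_rmse(data, response: str, terms) -> float:
    """Leave-one-out cross-validated RMSE for a fixed term set.

    Uses the closed-form hat-matrix identity e_i / (1 - h_ii) for OLS, so
    no refitting is needed.
    """
    df = records_to_frame(data)
    y = _col(df, response)
    X = design_matrix(df, terms)
    res = _ols(y, X)
    resid = y - X @ res.params
    h = np.einsum(
        "ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X
    )
    loo = resid / (1.0 - h)
    return float(np.sqrt(np.mean(loo**2)))
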