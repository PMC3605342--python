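"""Predictor bases, PLS cross-validation, and stepwise least squares.

The quasi-stiffnesses and propulsive work admit low-order polynomial
predictors in body size (weight W, height H), gait speed V, and the phase
excursions Γ. Each response has a derived basis of monomial terms
W^a·H^b·V^c·Γ_x^d; because the terms are strongly collinear, the number of
informative directions is first established by partial-least-squares
regression under leave-one-subject-out cross-validation, and the final
reported model is a backward-eliminated ordinary-least-squares fit keeping
only significant terms.

The dual-flexion excursion enters the bases *signed* (positive below the
singular speed, negative above), which keeps the generative relations
exactly linear in the basis; the dorsi- and plantar-flexion excursions are
magnitudes (they are sign-constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.outliers_influence import OLSInfluence

from .types import DomainError, JointSummary, SubjectProfile, cohort_by_id

RESPONSES = ("K_df", "K_dl", "K_pf", "E")


class DegenerateModelError(DomainError):
    """Stepwise elimination removed every term."""


# ---------------------------------------------------------------------------
# Basis terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """Monomial basis term W^w · H^h · V^v · Γ_phase^g_exp.

    ``phase`` ∈ {None, "df", "dl", "pf"}; the dual excursion is signed.
    """

    w: int = 0
    h: int = 0
    v: int = 0
    phase: str | None = None
    g_exp: int = 0

    @property
    def name(self) -> str:
        if self == Term():
            return "1"
        num, den = [], []
        for sym, exp in (("W", self.w), ("H", self.h), ("V", self.v)):
            if exp > 0:
                num.append(sym if exp == 1 else f"{sym}^{exp}")
            elif exp < 0:
                den.append(sym if exp == -1 else f"{sym}^{-exp}")
        if self.phase is not None and self.g_exp != 0:
            sym = f"G{self.phase}"
            (num if self.g_exp > 0 else den).append(
                sym if abs(self.g_exp) == 1 else f"{sym}^{abs(self.g_exp)}"
            )
        out = "*".join(num) if num else "1"
        if den:
            out += "/" + "*".join(den)
        return out

    def evaluate(self, W: float, H: float, V: float, gammas: dict[str, float]) -> float:
        val = W**self.w * H**self.h * V**self.v
        if self.phase is not None and self.g_exp != 0:
            g = gammas.get(self.phase)
            if g is None:
                raise DomainError(f"term {self.name} needs excursion '{self.phase}'")
            if g == 0 and self.g_exp < 0:
                raise ZeroDivisionError(f"zero excursion in term {self.name}")
            val *= g**self.g_exp
        return float(val)

    def to_dict(self) -> dict:
        return {"w": self.w, "h": self.h, "v": self.v, "phase": self.phase,
                "g_exp": self.g_exp}


INTERCEPT = Term()


@dataclass(frozen=True)
class BasisSpec:
    """Ordered term list for one response; term names must be unique."""

    response: str
    terms: tuple[Term, ...]
    include_intercept: bool = False

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise DomainError(f"unknown response {self.response!r}")
        names = [t.name for t in self.all_terms]
        if len(names) != len(set(names)):
            raise DomainError(f"duplicate term names in basis: {names}")

    @property
    def all_terms(self) -> tuple[Term, ...]:
        return ((INTERCEPT,) if self.include_intercept else ()) + tuple(self.terms)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.all_terms]


def default_basis(response: str) -> BasisSpec:
    """Derived basis for each response.

    K_df comes from M_c ~ W·H·(1, V) and K_df = M_c/Γ_df; the dual and
    plantar stiffnesses from M_d ~ W·H·(1, V, V²); the work basis from
    the loop-area closed form (9 terms W·H·Γ_x·V^k, no intercept).
    """
    wh = {"w": 1, "h": 1}
    if response == "K_df":
        terms = (
            Term(**wh, phase="df", g_exp=-1),
            Term(**wh, v=1, phase="df", g_exp=-1),
            Term(**wh),
            Term(**wh, v=1),
        )
        return BasisSpec(response, terms, include_intercept=True)
    if response in ("K_dl", "K_pf"):
        ph = "dl" if response == "K_dl" else "pf"
        terms = (
            Term(**wh, phase=ph, g_exp=-1),
            Term(**wh, v=1, phase=ph, g_exp=-1),
            Term(**wh, v=2, phase=ph, g_exp=-1),
            Term(**wh),
            Term(**wh, v=1),
            Term(**wh, v=2),
            Term(v=1),
        )
        return BasisSpec(response, terms, include_intercept=True)
    if response == "E":
        terms = tuple(
            Term(**wh, v=k, phase=ph, g_exp=1)
            for ph in ("df", "dl", "pf")
            for k in (0, 1, 2)
        )
        return BasisSpec(response, terms, include_intercept=False)
    raise DomainError(f"unknown response {response!r}")


def _summary_gammas(s: JointSummary) -> dict[str, float]:
    return {"df": s.Gamma_df, "dl": s.Gamma_dl_signed, "pf": s.Gamma_pf}


def _summary_response(s: JointSummary, response: str) -> float:
    return {"K_df": s.K_df, "K_dl": s.K_dl, "K_pf": s.K_pf, "E": s.E_loop}[response]


def build_basis(
    summaries: Sequence[JointSummary],
    cohort: Sequence[SubjectProfile],
    spec: BasisSpec,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray, list[tuple[int, str]]]:
    """Evaluate a basis over trial summaries.

    Returns ``(X, y, groups, dropped)``: design matrix with columns in spec
    order, response vector, subject-id group labels, and the (row, reason)
    list of excluded rows. Rows flagged singular are dropped for the dual
    response, as are rows where a term would divide by a zero excursion.
    """
    subjects = cohort_by_id(cohort)
    rows, yvals, groups, dropped = [], [], [], []
    for i, s in enumerate(summaries):
        if s.subject_id not in subjects:
            raise DomainError(f"summary row {i}: unknown subject {s.subject_id!r}")
        if spec.response == "K_dl" and s.singular:
            dropped.append((i, "singular dual-flexion trial"))
            continue
        subj = subjects[s.subject_id]
        gammas = _summary_gammas(s)
        try:
            row = [
                t.evaluate(subj.weight, subj.height, s.speed, gammas)
                for t in spec.all_terms
            ]
        except ZeroDivisionError as exc:
            dropped.append((i, str(exc)))
            continue
        yv = _summary_response(s, spec.response)
        if not np.isfinite(yv):
            dropped.append((i, f"non-finite response {spec.response}"))
            continue
        rows.append(row)
        yvals.append(yv)
        groups.append(s.subject_id)
    X = pd.DataFrame(rows, columns=spec.term_names, dtype=float)
    y = pd.Series(yvals, name=spec.response, dtype=float)
    return X, y, np.asarray(groups, dtype=object), dropped


# ---------------------------------------------------------------------------
# PLS with leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------


def pls_loso_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    groups: Sequence,
    max_components: int | None = None,
) -> dict:
    """Select the PLS component count by leave-one-subject-out CV.

    For each component count the held-out predictions over all folds form
    PRESS; predicted R² = 1 − PRESS/SS_tot. The returned count maximizes
    predicted R²; ``r2`` is the in-sample R² of a refit on all data at that
    count. Percentages (0–100).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DomainError("X and y have incompatible shapes")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise DomainError("cross-validation needs >= 2 groups")
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    k_max = min(max_components or rank, rank, X.shape[1])
    if k_max < 1:
        raise DomainError("design matrix has rank 0")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    logo = LeaveOneGroupOut()
    folds = list(logo.split(X, y, groups))
    press = np.zeros(k_max)
    for train, test in folds:
        k_fold = min(k_max, int(np.linalg.matrix_rank(X[train] - X[train].mean(0))))
        for k in range(1, k_max + 1):
            pls = PLSRegression(n_components=min(k, k_fold), scale=True)
            pls.fit(X[train], y[train])
            resid = y[test] - pls.predict(X[test]).ravel()
            press[k - 1] += float(np.sum(resid**2))
    predicted_r2 = 1.0 - press / ss_tot
    # smallest component count within numerical noise of the maximum
    # (breaks the tie that an exactly low-rank response produces)
    best = float(np.max(predicted_r2))
    n_comp = int(np.argmax(predicted_r2 >= best - 1e-8)) + 1

    pls = PLSRegression(n_components=n_comp, scale=True)
    pls.fit(X, y)
    resid = y - pls.predict(X).ravel()
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return {
        "n_components": n_comp,
        "r2": 100.0 * r2,
        "predicted_r2": 100.0 * float(predicted_r2[n_comp - 1]),
        "predicted_r2_by_k": (100.0 * predicted_r2).tolist(),
    }


# ---------------------------------------------------------------------------
# Stepwise backward-eliminated OLS
# ---------------------------------------------------------------------------


class StepwiseOLS(BaseEstimator, RegressorMixin):
    """Backward-eliminating ordinary least squares.

    Repeatedly fits OLS and removes the term with the largest p-value while
    that p-value is ≥ ``alpha`` (ties broken by dropping the later column).
    An (almost) exact fit stops elimination immediately: with zero residual
    variance p-values are undefined and every term is kept.

    Attributes set by :meth:`fit`: ``retained_`` (column names),
    ``coef_`` (aligned with ``retained_``), ``pvalues_``, ``r2_``,
    ``feature_names_in_``, ``results_`` (the statsmodels fit).
    """

    def __init__(self, alpha: float = 0.05, exact_tol: float = 1e-12):
        self.alpha = alpha
        self.exact_tol = exact_tol

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xa.shape[1])]
        ya = np.asarray(y, dtype=float).ravel()
        if Xa.shape[0] <= Xa.shape[1] + 2:
            raise DomainError(
                f"need n rows > n columns + 2 (got {Xa.shape[0]} x {Xa.shape[1]})"
            )
        keep = list(range(Xa.shape[1]))
        while True:
            res = sm.OLS(ya, Xa[:, keep]).fit()
            if 1.0 - res.rsquared < self.exact_tol:
                break  # exact fit: residual variance ~ 0, p-values undefined
            pvals = np.asarray(res.pvalues)
            worst = np.where(pvals == np.nanmax(pvals))[0][-1]
            if not pvals[worst] >= self.alpha:
                break
            if len(keep) == 1:
                raise DegenerateModelError(
                    "stepwise elimination removed every term "
                    f"(last term p={pvals[worst]:.3g} >= alpha={self.alpha})"
                )
            keep.pop(worst)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.keep_idx_ = list(keep)
        self.retained_ = [names[i] for i in keep]
        self.coef_ = np.asarray(res.params, dtype=float)
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)
        self.r2_ = float(res.rsquared)
        self.results_ = res
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(
            X, dtype=float
        )
        return Xa[:, self.keep_idx_] @ self.coef_


class MeanBaseline(BaseEstimator, RegressorMixin):
    """Constant predictor: the training mean of the response."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(np.asarray(y, dtype=float)))
        return self

    def predict(self, X):
        check_is_fitted(self, "mean_")
        n = len(X)
        return np.full(n, self.mean_)


def stepwise_ols(X, y, alpha: float = 0.05) -> StepwiseOLS:
    """Functional wrapper over :class:`StepwiseOLS`."""
    return StepwiseOLS(alpha=alpha).fit(X, y)


def baseline_mean_model(values: Sequence[float]) -> MeanBaseline:
    """Constant cohort-mean predictor for a response."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 1:
        raise DomainError("baseline needs >= 1 value")
    return MeanBaseline().fit(np.empty((vals.size, 0)), vals)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def flag_outliers(model: StepwiseOLS, X, y, threshold: float = 3.0) -> list:
    """Rows whose externally studentized residual exceeds ``threshold``.

    Returns index labels when X is a DataFrame, positional indices otherwise.
    """
    check_is_fitted(model, "coef_")
    if not np.isfinite(threshold):
        return []
    if isinstance(X, pd.DataFrame):
        labels = list(X.index)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        labels = list(range(Xa.shape[0]))
    ya = np.asarray(y, dtype=float).ravel()
    res = sm.OLS(ya, Xa[:, model.keep_idx_]).fit()
    if 1.0 - res.rsquared < 1e-12:
        return []
    t_ext = OLSInfluence(res).resid_studentized_external
    return [labels[i] for i in np.where(np.abs(t_ext) > threshold)[0]]


def mean_pct_error(y_true, y_pred, exclude: Sequence[int] = ()) -> float:
    """Mean of 100·|ŷ − y|/|y| over included, nonzero-response rows."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    mask = np.ones(y_true.size, dtype=bool)
    mask[list(exclude)] = False
    mask &= y_true != 0
    if not np.any(mask):
        raise DomainError("no usable rows for percent error")
    return float(np.mean(100.0 * np.abs(y_pred[mask] - y_true[mask]) / np.abs(y_true[mask])))


# ---------------------------------------------------------------------------
# Fitted-model record
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """A fitted general-form model for one response, with quality metrics."""

    basis: BasisSpec
    coefficients: dict[str, float]
    p_values: dict[str, float]
    n_components_cv: int
    pls_r2: float  # %
    pls_predicted_r2: float  # %
    r2: float  # %, OLS fit on retained terms
    mean_pct_error: float  # %, excluding outliers
    outlier_ids: list = field(default_factory=list)
    alpha: float = 0.05

    def predict_point(
        self, W: float, H: float, V: float, gammas: dict[str, float]
    ) -> float:
        terms = {t.name: t for t in self.basis.all_terms}
        return float(
            sum(
                c * terms[name].evaluate(W, H, V, gammas)
                for name, c in self.coefficients.items()
            )
        )

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        cols = list(self.coefficients)
        return X[cols].to_numpy() @ np.asarray(list(self.coefficients.values()))

    def to_dict(self) -> dict:
        return {
            "response": self.basis.response,
            "include_intercept": self.basis.include_intercept,
            "terms": [t.to_dict() for t in self.basis.terms],
            "coefficients": self.coefficients,
            "p_values": {
                k: (v if np.isfinite(v) else None) for k, v in self.p_values.items()
            },
            "n_components_cv": self.n_components_cv,
            "pls_r2_pct": self.pls_r2,
            "pls_predicted_r2_pct": self.pls_predicted_r2,
            "ols_r2_pct": self.r2,
            "mean_pct_error": self.mean_pct_error,
            "outlier_ids": list(self.outlier_ids),
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        basis = BasisSpec(
            d["response"],
            tuple(Term(**t) for t in d["terms"]),
            include_intercept=d["include_intercept"],
        )
        return cls(
            basis=basis,
            coefficients=dict(d["coefficients"]),
            p_values={
                k: (np.nan if v is None else v) for k, v in d["p_values"].items()
            },
            n_components_cv=d["n_components_cv"],
            pls_r2=d["pls_r2_pct"],
            pls_predicted_r2=d["pls_predicted_r2_pct"],
            r2=d["ols_r2_pct"],
            mean_pct_error=d["mean_pct_error"],
            outlier_ids=list(d["outlier_ids"]),
            alpha=d["alpha"],
        )


def predict(
    model: FittedModel,
    W: float,
    H: float,
    V: float,
    excursions: dict[str, float] | None = None,
) -> float:
    """Evaluate a fitted general-form model at one operating point.

    ``excursions`` maps phase codes ('df', 'dl', 'pf') to radians; the dual
    value is signed. Missing excursions required by the model raise an
    argument error.
    """
    gammas = dict(excursions or {})
    try:
        return model.predict_point(W, H, V, gammas)
    except (DomainError, ZeroDivisionError) as exc:
        raise DomainError(f"cannot evaluate model: {exc}") from exc


def fit_response(
    summaries: Sequence[JointSummary],
    cohort: Sequence[SubjectProfile],
    spec: BasisSpec | None = None,
    response: str | None = None,
    alpha: float = 0.05,
    outlier_threshold: float = 3.0,
    max_components: int | None = None,
) -> tuple[FittedModel, pd.DataFrame, pd.Series, np.ndarray]:
    """Full fitting pipeline for one response.

    Builds the basis, selects the PLS component count by LOSO-CV, fits the
    stepwise OLS model, flags outliers, and computes the mean percent error
    excluding them. Returns ``(model, X, y, groups)``.
    """
    if spec is None:
        if response is None:
            raise DomainError("either spec or response must be given")
        spec = default_basis(response)
    X, y, groups, _dropped = build_basis(summaries, cohort, spec)
    cv = pls_loso_cv(X, y, groups, max_components=max_components)
    ols = StepwiseOLS(alpha=alpha).fit(X, y)
    outliers = flag_outliers(ols, X, y, threshold=outlier_threshold)
    err = mean_pct_error(y, ols.predict(X), exclude=outliers)
    model = FittedModel(
        basis=spec,
        coefficients=dict(zip(ols.retained_, ols.coef_)),
        p_values=dict(zip(ols.retained_, ols.pvalues_)),
        n_components_cv=cv["n_components"],
        pls_r2=cv["r2"],
        pls_predicted_r2=cv["predicted_r2"],
        r2=100.0 * ols.r2_,
        mean_pct_error=err,
        outlier_ids=outliers,
        alpha=alpha,
    )
    return model, X, y, groups
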