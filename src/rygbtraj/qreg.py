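"""Quantile-regression fitting of the trajectory model by check-loss minimization.

The conditional :math:`\\tau`-quantile is estimated by minimizing the mean
check (pinball) loss :math:`\\rho_\\tau(r) = r(\\tau - \\mathbf{1}\\{r<0\\})`
over the centered trajectory basis. Minimization is an exact linear
program — split each residual into positive and negative parts ``u, v ≥ 0``
with ``Xβ + u − v = y`` and minimize ``(τ·Σu + (1−τ)·Σv)/n`` — solved with
a deterministic simplex/HiGHS backend. On flat optima (even-sized samples,
degenerate designs) a second LP minimizes the intercept subject to
optimality, giving the lowest-minimizer convention: for an intercept-only
design the fit is the classical lower sample quantile.

:class:`QuantileTrajectoryRegressor` wraps this in a scikit-learn estimator
(``fit``/``predict`` on raw ``[baseline BMI, age, months]`` columns);
:func:`fit_quantile` and :func:`fit_modelset` are the functional surface.
Repeated measures are pooled as independent observations in the loss by
default; per-patient inverse-frequency weighting is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    EmptyInputError,
    InvalidInputError,
    RankError,
    SchemaError,
)
from .model import (
    COEF_FIELDS,
    ModelSet,
    QuantileCoefficients,
    design_matrix,
)

__all__ = [
    "check_loss",
    "FitResult",
    "fit_quantile",
    "fit_modelset",
    "QuantileTrajectoryRegressor",
    "screen_covariates",
    "compare_fits",
]

#: relative slack allowed when constraining the second-stage (tie-break) LP
#: to the first stage's optimal loss
_TIE_TOL = 1e-11


def check_loss(residuals, tau: float) -> float:
    """Mean check loss ``mean(r·(τ − 1{r<0}))`` of a residual vector."""
    if not (0.0 < tau < 1.0):
        raise InvalidInputError(f"tau must lie in (0, 1), got {tau!r}")
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise EmptyInputError("check_loss of an empty residual vector is undefined")
    if not np.all(np.isfinite(r)):
        raise InvalidInputError("residuals must be finite")
    return float(np.mean(r * (tau - (r < 0))))


@dataclass(frozen=True)
class FitResult:
    """One fitted quantile model plus solver metadata."""

    tau: float
    beta: np.ndarray
    loss: float
    converged: bool
    n_obs: int
    n_patients: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> QuantileCoefficients:
        """The fit as :class:`QuantileCoefficients` (requires the 8-column basis)."""
        if self.beta.shape != (8,):
            raise ConfigurationError(
                f"fit has {self.beta.shape[0]} coefficients, not the 8-column trajectory basis"
            )
        return QuantileCoefficients.from_array(self.tau, self.beta)


#: problems up to this many rows use the two-stage primal LP whose second
#: stage enforces the lowest-intercept convention exactly; larger problems
#: use the equivalent dual LP (box-bounded, p equality rows), where the
#: optimum is almost surely unique for continuous responses
_PRIMAL_MAX_N = 2000


def _solve_dual_lp(X: np.ndarray, y: np.ndarray, tau: float, w: np.ndarray):
    """Dual of check-loss minimization: max yᵀa s.t. Xᵀa = 0, a ∈ [−(1−τ)w, τw].

    β is read off the equality-constraint marginals; the duality gap between
    the achieved primal loss and the dual objective certifies optimality.
    """
    n, p = X.shape
    res = linprog(
        -y,
        A_eq=sp.csr_matrix(X.T),
        b_eq=np.zeros(p),
        bounds=list(zip(-(1.0 - tau) * w, tau * w)),
        method="highs",
    )
    meta = {"status": res.status, "message": res.message, "solver": "dual"}
    if res.status != 0:
        raise ConvergenceError(f"LP solver did not certify optimality: {res.message}", meta)
    dual_obj = float(-res.fun)
    candidates = [-res.eqlin.marginals, res.eqlin.marginals]
    losses = []
    for beta in candidates:
        r = y - X @ beta
        losses.append(float(np.sum(w * np.abs(r) * np.where(r >= 0, tau, 1 - tau))))
    best = int(np.argmin(losses))
    beta, loss = candidates[best], losses[best]
    gap = abs(loss - dual_obj) / max(1.0, abs(dual_obj))
    meta["duality_gap"] = gap
    meta["achieved_loss"] = loss
    if gap > 1e-7:
        raise ConvergenceError(
            f"duality gap {gap:.2e} exceeds certification tolerance", meta
        )
    return beta, loss, meta


def _solve_lp(X: np.ndarray, y: np.ndarray, tau: float, w: np.ndarray, tie_break: bool):
    """Exact LP check-loss minimization; returns (beta, loss, metadata)."""
    n, p = X.shape
    if n > _PRIMAL_MAX_N:
        return _solve_dual_lp(X, y, tau, w)
    Xs = sp.csc_matrix(X)
    eye = sp.identity(n, format="csc")
    A_eq = sp.hstack([Xs, eye, -eye], format="csc")
    c = np.concatenate([np.zeros(p), tau * w, (1.0 - tau) * w])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    meta = {"status": res.status, "message": res.message, "nit": int(getattr(res, "nit", -1))}
    if res.status != 0:
        raise ConvergenceError(f"LP solver did not certify optimality: {res.message}", meta)
    beta = res.x[:p]
    loss = float(res.fun)
    if tie_break:
        # minimize the intercept over the optimal face: loss pinned to the
        # stage-1 optimum (tiny slack for solver arithmetic)
        cap = loss + _TIE_TOL * max(1.0, abs(loss))
        c2 = np.zeros(p + 2 * n)
        c2[0] = 1.0
        res2 = linprog(
            c2,
            A_eq=A_eq,
            b_eq=y,
            A_ub=c.reshape(1, -1),
            b_ub=[cap],
            bounds=bounds,
            method="highs",
        )
        if res2.status == 0:
            beta2 = res2.x[:p]
            r2 = y - X @ beta2
            loss2 = float(np.sum(w * np.abs(r2) * np.where(r2 >= 0, tau, 1 - tau)))
            if loss2 <= loss + 1e-8 * max(1.0, abs(loss)):
                beta, loss = beta2, loss2
                meta["tie_break"] = True
    achieved = float(np.sum(w * np.abs(y - X @ beta) * np.where(y - X @ beta >= 0, tau, 1 - tau)))
    meta["achieved_loss"] = achieved
    return beta, loss, meta


def fit_quantile(
    X,
    y,
    tau: float,
    *,
    sample_weight=None,
    tie_break: bool = True,
    n_patients: int | None = None,
) -> FitResult:
    """Minimize the mean check loss of ``y − Xβ`` over β.

    ``X`` is a design matrix (any full-column-rank basis; the trajectory
    model uses the centered 8-column basis). Deterministic given fixed
    inputs; on flat optima the lowest-intercept solution is returned.
    """
    if not (0.0 < tau < 1.0):
        raise InvalidInputError(f"tau must lie in (0, 1), got {tau!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError(f"X {X.shape} and y {y.shape} are not conformable")
    n, p = X.shape
    if n == 0:
        raise EmptyInputError("cannot fit on zero observations")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidInputError("design matrix and response must be finite")
    if n < p:
        raise RankError(f"need at least {p} observations for {p} coefficients, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise RankError("design matrix is rank deficient")
    if sample_weight is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(sample_weight, dtype=float).ravel()
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise InvalidInputError("sample_weight must be non-negative with positive total")
        w = w / w.sum()
    beta, loss, meta = _solve_lp(X, y, tau, w, tie_break)
    return FitResult(
        tau=tau,
        beta=beta,
        loss=loss,
        converged=True,
        n_obs=n,
        n_patients=n_patients,
        metadata=meta,
    )


class QuantileTrajectoryRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator fitting percentile BMI-trajectory curves.

    Parameters
    ----------
    taus : sequence of float
        Quantile levels, strictly increasing in (0, 1).
    tie_break : bool
        Resolve flat LP optima to the lowest-intercept solution.
    patient_weighting : bool
        Weight each measurement by 1/(measurements of its patient) so each
        patient contributes equally (requires ``patient_ids`` at fit time).
        Off by default: measurements are pooled as independent observations.

    After ``fit``, ``model_set_`` holds the fitted :class:`ModelSet` (validity
    ranges set from the data), ``coef_`` the (n_taus, 8) coefficient matrix,
    ``results_`` the per-tau :class:`FitResult` objects.
    """

    def __init__(self, taus=(0.25, 0.5, 0.75), tie_break=True, patient_weighting=False):
        self.taus = taus
        self.tie_break = tie_break
        self.patient_weighting = patient_weighting

    def _validate_taus(self):
        taus = tuple(float(t) for t in self.taus)
        if not taus:
            raise ConfigurationError("need at least one tau")
        if any(not (0 < t < 1) for t in taus):
            raise InvalidInputError(f"taus must lie in (0, 1): {taus}")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise SchemaError(f"taus must be strictly increasing without duplicates: {taus}")
        return taus

    def fit(self, X, y, patient_ids=None):
        """Fit one quantile regression per tau.

        ``X`` has columns ``[bmi_baseline, age, months_post_op]`` (raw,
        uncentered); ``y`` is measured BMI in kg/m².
        """
        taus = self._validate_taus()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 3:
            raise InvalidInputError(
                f"X must have 3 columns (bmi_baseline, age, months), got shape {X.shape}"
            )
        if X.shape[0] != y.shape[0]:
            raise InvalidInputError("X and y length mismatch")
        D = design_matrix(X[:, 0], X[:, 1], X[:, 2])
        weight = None
        n_patients = None
        if patient_ids is not None:
            patient_ids = np.asarray(patient_ids)
            n_patients = int(pd.unique(patient_ids).size)
            if self.patient_weighting:
                counts = pd.Series(patient_ids).map(pd.Series(patient_ids).value_counts())
                weight = 1.0 / counts.to_numpy(dtype=float)
        elif self.patient_weighting:
            raise ConfigurationError("patient_weighting requires patient_ids at fit time")
        results = []
        for tau in taus:
            try:
                results.append(
                    fit_quantile(
                        D,
                        y,
                        tau,
                        sample_weight=weight,
                        tie_break=self.tie_break,
                        n_patients=n_patients,
                    )
                )
            except (RankError, ConvergenceError) as exc:
                raise type(exc)(f"tau={tau}: {exc}") from exc
        self.results_ = results
        self.coef_ = np.vstack([r.beta for r in results])
        self.losses_ = np.array([r.loss for r in results])
        self.n_obs_ = int(y.shape[0])
        self.n_patients_ = n_patients
        self.model_set_ = ModelSet(
            tuple(r.coefficients for r in results),
            bmi_range=(float(X[:, 0].min()), float(max(X[:, 0].max(), X[:, 0].min() + 1e-6))),
            age_range=(float(X[:, 1].min()), float(max(X[:, 1].max(), X[:, 1].min() + 1e-6))),
            time_range=(0.0, float(max(X[:, 2].max(), 1e-6))),
        )
        return self

    def predict(self, X):
        """Predicted BMI, shape (n, n_taus), one column per fitted percentile."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_set_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise InvalidInputError("X must have 3 columns (bmi_baseline, age, months)")
        D = design_matrix(X[:, 0], X[:, 1], X[:, 2])
        return D @ self.coef_.T


def fit_modelset(
    cohort,
    taus: Sequence[float] = (0.25, 0.5, 0.75),
    *,
    patient_weighting: bool = False,
) -> ModelSet:
    """Fit the trajectory model to a cohort; returns the fitted :class:`ModelSet`.

    Every patient must carry baseline BMI and age and at least one
    post-operative measurement (guaranteed by the cohort reader).
    """
    est = QuantileTrajectoryRegressor(taus=taus, patient_weighting=patient_weighting)
    X, y, pid = cohort.regression_arrays()
    est.fit(X, y, patient_ids=pid)
    return est.model_set_


# covariate screening ------------------------------------------------------

_CANDIDATES = ("bmi_baseline", "age", "sex", "diabetes")


def _partial_effect(df: pd.DataFrame, outcome: str, covariate: str):
    """Standardized (partial-correlation) effect of a covariate on an outcome.

    OLS of the outcome on the covariate adjusting for baseline BMI and age
    (self-adjustment skipped); the effect size is the signed partial
    correlation r = t/sqrt(t² + df_resid), with the OLS two-sided p-value.
    """
    import statsmodels.api as sm

    adjusters = [c for c in ("bmi_baseline", "age") if c != covariate]
    cols = [outcome, covariate] + adjusters
    d = df[cols].dropna()
    if d.empty or d[covariate].nunique() <= 1:
        return float("nan"), float("nan"), 0
    Xd = sm.add_constant(d[[covariate] + adjusters].astype(float))
    fitted = sm.OLS(d[outcome].astype(float), Xd).fit()
    t = float(fitted.tvalues[covariate])
    r = t / np.sqrt(t**2 + fitted.df_resid) if fitted.df_resid > 0 else float("nan")
    return r, float(fitted.pvalues[covariate]), int(len(d))


def screen_covariates(cohort, threshold: float = 0.1) -> pd.DataFrame:
    """Screen candidate covariates against 6-month %EWL and nadir BMI.

    For each candidate (baseline BMI, age, sex, diabetes) the standardized
    effect on each outcome is the partial correlation after adjusting for
    baseline BMI and age. A covariate is retained when |effect| ≥ threshold
    on BOTH outcomes with a consistent direction of association with weight
    loss (the nadir-BMI effect is sign-flipped for the comparison: more loss
    means higher %EWL but lower nadir BMI).

    Returns a table with columns covariate, effect_6mo, effect_nadir,
    p_6mo, p_nadir, retained.
    """
    df = cohort.outcome_table()
    rows = []
    for cov in _CANDIDATES:
        if cov not in df.columns or df[cov].isna().all():
            rows.append(
                {
                    "covariate": cov,
                    "effect_6mo": float("nan"),
                    "effect_nadir": float("nan"),
                    "p_6mo": float("nan"),
                    "p_nadir": float("nan"),
                    "retained": False,
                }
            )
            continue
        e6, p6, _ = _partial_effect(df, "six_month_ewl", cov)
        en, pn, _ = _partial_effect(df, "nadir_bmi", cov)
        consistent = np.isfinite(e6) and np.isfinite(en) and (np.sign(e6) == -np.sign(en))
        retained = bool(
            consistent and abs(e6) >= threshold and abs(en) >= threshold
        )
        rows.append(
            {
                "covariate": cov,
                "effect_6mo": e6,
                "effect_nadir": en,
                "p_6mo": p6,
                "p_nadir": pn,
                "retained": retained,
            }
        )
    return pd.DataFrame(rows)


def compare_fits(
    ms_a: ModelSet,
    ms_b: ModelSet,
    *,
    bmi_baseline: float = 50.0,
    age: float = 50.0,
    times=None,
) -> pd.DataFrame:
    """Per-tau discrepancy between two fitted model sets on a reference profile.

    Default grid: baseline BMI 50, age 50, t ∈ [0, 36] in 0.5-month steps.
    Returns columns tau, max_abs_diff, mean_abs_diff (kg/m²).
    """
    if ms_a.taus != ms_b.taus:
        raise ConfigurationError(f"tau mismatch: {ms_a.taus} vs {ms_b.taus}")
    if times is None:
        times = np.arange(0.0, 36.0 + 0.25, 0.5)
    times = np.asarray(times, dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa = ms_a.predict(bmi_baseline, age, times, allow_extrapolation=True)
        pb = ms_b.predict(bmi_baseline, age, times, allow_extrapolation=True)
    diff = np.abs(pa - pb)
    return pd.DataFrame(
        {
            "tau": list(ms_a.taus),
            "max_abs_diff": diff.max(axis=0),
            "mean_abs_diff": diff.mean(axis=0),
        }
    )
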