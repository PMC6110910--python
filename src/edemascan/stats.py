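"""Longitudinal modeling of CSF volume after stroke.

The dynamic CSF model is a marginal (GEE) linear model

    E(y_ij) = b0 + b1·t_ij + b2·t_ij² + b3·age_i + b4·ced_i

for CSF volume y (ml) of subject i at time t (days from stroke onset),
age in years, and ced the dichotomized cerebral-edema indicator
(grade 3 vs 0–2).  Scans are irregularly spaced, so the working
correlation is the continuous-time Markov (exponential) structure

    corr(y_ij, y_ik) = a^|t_ij − t_ik|,   0 < a < 1,

the AR(1) analogue for irregular sampling: correlation decays with the
time gap.  Estimation alternates two stages — generalized least squares
for the mean coefficients given (a, σ²), then moment estimation of σ²
and least-squares estimation of a from residual cross-products — and
inference uses the robust (sandwich) covariance, so standard errors are
valid even if the working correlation is wrong.

Cross-sectional companions: the quadratic model of peak midline shift
against maximal CSF loss (midline shift stays near zero until roughly a
third of baseline CSF is exhausted, then rises steeply) and the linear
regression of baseline CSF fraction on age (brain atrophy).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps

from .core import EdemascanError

__all__ = [
    "GeeDesign",
    "GEEFit",
    "markov_working_correlation",
    "fit_gee_markov",
    "robust_covariance",
    "dichotomize_ced",
    "QuadraticMlsFit",
    "fit_quadratic_mls",
    "AgeModelFit",
    "fit_age_model",
]

COEF_NAMES = ("intercept", "time_days", "time_days_sq", "age_years", "ced3")
_A_BOUNDS = (1e-6, 1.0 - 1e-6)
_RIDGE = 1e-8


def dichotomize_ced(grade: int) -> int:
    """CED grade 3 (swelling with midline shift) vs grades 0–2."""
    if grade not in (0, 1, 2, 3):
        raise ValueError(f"CED grade must be one of 0,1,2,3, got {grade}")
    return int(grade == 3)


def markov_working_correlation(times: Sequence[float], a: float) -> np.ndarray:
    """R[j,k] = a^|t_j − t_k| for within-subject observation times (days)."""
    if not (0.0 < a < 1.0):
        raise ValueError(f"correlation parameter a must lie in (0, 1), got {a}")
    t = np.asarray(times, dtype=float)
    gaps = np.abs(t[:, None] - t[None, :])
    if np.any(gaps[~np.eye(len(t), dtype=bool)] == 0):
        raise ValueError("duplicate within-subject times")
    return a**gaps


@dataclasses.dataclass
class GeeDesign:
    """Stacked design for the dynamic CSF model.

    ``X`` columns are intercept, t, t², age, ced; ``groups`` maps each row
    to a subject index; within-subject times are strictly increasing and
    expressed in days.
    """

    X: np.ndarray
    y: np.ndarray
    times: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.X.shape[0] != len(self.y) or len(self.times) != len(self.y) or len(self.groups) != len(self.y):
            raise ValueError("X, y, times, groups must have matching first dimension")
        for idx in self.subject_indices():
            t = self.times[idx]
            if np.any(np.diff(t) <= 0):
                raise ValueError("within-subject times must be strictly increasing")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise EdemascanError("design matrix is rank deficient")

    def subject_indices(self) -> list[np.ndarray]:
        order = pd.unique(self.groups)
        return [np.flatnonzero(self.groups == g) for g in order]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        response: str = "csf_ml",
        time_col: str = "time_days",
        time_unit: str = "days",
    ) -> "GeeDesign":
        """Build from a tidy cohort table.

        Accepts either a ``ced3`` indicator column or a raw ``ced_grade``
        column (dichotomized here); ``time_unit='hours'`` converts to the
        model's day scale.
        """
        df = df.sort_values(["subject_id", time_col], kind="mergesort")
        t = df[time_col].to_numpy(dtype=float)
        if time_unit == "hours":
            t = t / 24.0
        elif time_unit != "days":
            raise ValueError("time_unit must be 'days' or 'hours'")
        if "ced3" in df.columns:
            ced = df["ced3"].to_numpy(dtype=float)
        elif "ced_grade" in df.columns:
            ced = np.array([dichotomize_ced(int(g)) for g in df["ced_grade"]], dtype=float)
        else:
            raise EdemascanError("need a ced3 or ced_grade column")
        X = np.column_stack([np.ones(len(df)), t, t**2, df["age_years"].to_numpy(dtype=float), ced])
        return cls(X=X, y=df[response].to_numpy(dtype=float), times=t, groups=df["subject_id"].to_numpy())


@dataclasses.dataclass
class GEEFit:
    """Converged GEE solution with robust (sandwich) inference."""

    b: np.ndarray
    a: float | None
    sigma2: float
    robust_cov: np.ndarray
    naive_cov: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    iterations: int
    converged: bool
    n_subjects: int
    n_obs: int
    coef_names: tuple[str, ...] = COEF_NAMES

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_names[: len(self.b)],
                "estimate": self.b,
                "robust_se": self.se,
                "z": self.z,
                "p": self.p,
            }
        )


def _subject_blocks(design: GeeDesign):
    return [
        (design.X[idx], design.y[idx], design.times[idx])
        for idx in design.subject_indices()
    ]


def _corr_inv(times: np.ndarray, a: float | None) -> np.ndarray:
    n = len(times)
    if a is None or n == 1:
        return np.eye(n)
    R = markov_working_correlation(times, a)
    if a > 1.0 - 1e-6 or np.min(np.diff(times)) < 1e-9:
        R = R + _RIDGE * np.eye(n)
    return np.linalg.inv(R)


def _gls_beta(blocks, a: float | None) -> np.ndarray:
    p = blocks[0][0].shape[1]
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    for X, y, t in blocks:
        Wi = _corr_inv(t, a)
        XtWX += X.T @ Wi @ X
        XtWy += X.T @ Wi @ y
    try:
        return np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:
        raise EdemascanError(f"GLS system singular: {exc}") from exc


def _estimate_a(blocks, b: np.ndarray, sigma2: float) -> float | None:
    """Least-squares fit of a^Δt to within-subject Pearson-residual products.

    Coarse 50-point log-spaced grid on (0, 1) followed by golden-section
    refinement between the best grid point's neighbors.
    """
    prods, gaps = [], []
    sig = np.sqrt(sigma2)
    for X, y, t in blocks:
        r = (y - X @ b) / sig
        n = len(t)
        for j in range(n - 1):
            for k in range(j + 1, n):
                prods.append(r[j] * r[k])
                gaps.append(t[k] - t[j])
    if not prods:
        return None
    prods = np.asarray(prods)
    gaps = np.asarray(gaps)

    def loss(a: float) -> float:
        return float(np.sum((prods - a**gaps) ** 2))

    grid = np.geomspace(_A_BOUNDS[0], _A_BOUNDS[1], 50)
    losses = [loss(a) for a in grid]
    i = int(np.argmin(losses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[i])
    res = optimize.minimize_scalar(loss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    return float(np.clip(res.x, *_A_BOUNDS))


def fit_gee_markov(
    design: GeeDesign,
    tol: float = 1e-6,
    max_iter: int = 50,
    fixed_a: float | None = None,
) -> GEEFit:
    """Two-stage GEE for the Markov working-correlation model.

    Stage 1 updates the coefficients by generalized least squares given
    (a, σ²); stage 2 re-estimates σ² by moments (denominator N − p) and a
    by least squares on residual cross-products.  Iterates until
    max|Δb| < tol·(1 + |b|).  With no within-subject pairs (one scan per
    subject) the working correlation is vacuous and the solution is
    exactly ordinary least squares, with ``a`` reported as None.

    ``fixed_a`` pins the working-correlation parameter instead of
    estimating it (e.g. to study a deliberately misspecified working
    correlation, against which the sandwich errors stay valid).
    """
    blocks = _subject_blocks(design)
    n_obs = len(design.y)
    p = design.X.shape[1]
    if n_obs <= p:
        raise EdemascanError("not enough observations for the 5-coefficient model")
    has_pairs = any(len(t) > 1 for _, _, t in blocks)

    b = _gls_beta(blocks, None)  # OLS start
    a: float | None = None
    sigma2 = _moment_sigma2(blocks, b, p)
    iterations = 0
    converged = not has_pairs
    if has_pairs:
        for iterations in range(1, max_iter + 1):
            a = fixed_a if fixed_a is not None else _estimate_a(blocks, b, sigma2)
            b_new = _gls_beta(blocks, a)
            sigma2 = _moment_sigma2(blocks, b_new, p)
            if np.all(np.abs(b_new - b) < tol * (1.0 + np.abs(b))):
                b = b_new
                converged = True
                break
            b = b_new
        else:
            converged = False
    if not converged:
        raise EdemascanError(f"GEE did not converge in {max_iter} iterations")

    robust, naive = robust_covariance(blocks, b, a, sigma2)
    se = np.sqrt(np.diag(robust))
    z = b / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return GEEFit(
        b=b,
        a=a,
        sigma2=sigma2,
        robust_cov=robust,
        naive_cov=naive,
        se=se,
        z=z,
        p=pvals,
        iterations=iterations,
        converged=converged,
        n_subjects=len(blocks),
        n_obs=n_obs,
    )


def _moment_sigma2(blocks, b: np.ndarray, p: int) -> float:
    rss = 0.0
    n = 0
    for X, y, _ in blocks:
        r = y - X @ b
        rss += float(r @ r)
        n += len(y)
    return rss / (n - p)


def robust_covariance(blocks, b: np.ndarray, a: float | None, sigma2: float):
    """Sandwich B⁻¹ M B⁻¹ and the model-based (naive) covariance B⁻¹.

    B = Σ XᵢᵀVᵢ⁻¹Xᵢ and M = Σ XᵢᵀVᵢ⁻¹rᵢrᵢᵀVᵢ⁻¹Xᵢ with Vᵢ = σ²Rᵢ(a); the
    sandwich is consistent for the true coefficient covariance whether or
    not the working correlation holds.
    """
    p = len(b)
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for X, y, t in blocks:
        Vinv = _corr_inv(t, a) / sigma2
        r = y - X @ b
        XtV = X.T @ Vinv
        B += XtV @ X
        u = XtV @ r
        M += np.outer(u, u)
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise EdemascanError(f"bread matrix singular: {exc}") from exc
    robust = Binv @ M @ Binv
    robust = (robust + robust.T) / 2.0
    return robust, Binv


# ---------------------------------------------------------------------------
# cross-sectional models


@dataclasses.dataclass
class QuadraticMlsFit:
    """MLS = c0 + c1·x + c2·x² against maximal CSF reduction x (%)."""

    coef: np.ndarray
    coef_p: np.ndarray
    quad_f: float
    quad_p: float
    result: object

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.coef[0] + self.coef[1] * x + self.coef[2] * x**2

    def mean_ci(self, x: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        Xg = np.column_stack([np.ones(len(x)), x, np.asarray(x) ** 2])
        pred = self.result.get_prediction(Xg)
        ci = pred.conf_int(alpha=alpha)
        return ci[:, 0], ci[:, 1]

    def decompensation_onset_pct(self, mls_threshold_mm: float = 1.0, x_max: float = 80.0) -> float:
        """Reduction (%) at which predicted MLS first exceeds the threshold
        on the rising branch of the parabola — the fitted compensation
        breakpoint.  (The left branch above the vertex is an artifact of
        fitting a parabola to a hinge-shaped relation and is ignored.)"""
        vertex = -self.coef[1] / (2.0 * self.coef[2]) if self.coef[2] > 0 else 0.0
        start = float(np.clip(vertex, 0.0, x_max))
        grid = np.linspace(start, x_max, 1601)
        above = self.predict(grid) > mls_threshold_mm
        if not above.any():
            return float("nan")
        return float(grid[int(np.argmax(above))])


def fit_quadratic_mls(reduction_pct: Sequence[float], mls_mm: Sequence[float]) -> QuadraticMlsFit:
    """Least-squares quadratic of peak midline shift on maximal CSF loss.

    Reports the coefficient table, the F-test of the quadratic term
    (nested comparison against the linear model) and a pointwise 95%
    mean-response band.
    """
    x = np.asarray(reduction_pct, dtype=float)
    y = np.asarray(mls_mm, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 subjects for the quadratic model")
    if np.ptp(x) == 0:
        raise EdemascanError("degenerate input: no variation in CSF reduction")
    X = sm.add_constant(np.column_stack([x, x**2]))
    res = sm.OLS(y, X).fit()
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    f_res = res.compare_f_test(lin)
    return QuadraticMlsFit(
        coef=np.asarray(res.params),
        coef_p=np.asarray(res.pvalues),
        quad_f=float(f_res[0]),
        quad_p=float(f_res[1]),
        result=res,
    )


@dataclasses.dataclass
class AgeModelFit:
    """Baseline CSF (% of cranial volume) vs age: OLS line + Pearson r."""

    intercept: float
    slope: float
    r: float
    p: float
    result: object

    def predict(self, age: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(age, dtype=float)

    def mean_ci(self, age: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        Xg = sm.add_constant(np.asarray(age, dtype=float))
        ci = self.result.get_prediction(Xg).conf_int(alpha=alpha)
        return ci[:, 0], ci[:, 1]


def fit_age_model(age_years: Sequence[float], baseline_csf_pct: Sequence[float]) -> AgeModelFit:
    x = np.asarray(age_years, dtype=float)
    y = np.asarray(baseline_csf_pct, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0:
        raise EdemascanError("degenerate input: no variation in age")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r, p = sps.pearsonr(x, y)
    return AgeModelFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r=float(r),
        p=float(p),
        result=res,
    )
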