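"""OLS engine and the three core regressions: cost, effect and net benefit.

The analysis regresses each outcome on a binary treatment indicator TX
(plus optional covariates):

    c_i  = b0 + b_TX TX_i + b1 x1_i + ... + e_i      (incremental cost  = b_TX)
    e_i  = b0 + b_TX TX_i + ...                      (incremental effect = b_TX)
    NB_i = b0 + b_TX TX_i + ...                      (incremental net benefit)

where the per-patient net benefit at willingness-to-pay lambda is
``NB_i = lambda * e_i - c_i``. Because NB is a linear combination of the cost
and effect outcomes, the treatment coefficient of the NB regression equals
``lambda * dE - dC`` exactly, and its residual variance composes as
``lambda^2 s2_E - 2 lambda s_EC + s2_C`` when all three fits share one design
matrix — which is why the NB regression's confidence interval correctly
reflects the cost-effect correlation that separate cost and effect intervals
ignore.

Classical homoskedastic OLS standard errors with t-based p-values are the
default; heteroskedasticity-robust (HC1) errors are available via
``robust=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ce_data import CEDataset
from .exceptions import (
    DomainError,
    InsufficientDataError,
    SchemaError,
    SingularDesignError,
)

TX_COEF = "tx"


@dataclass
class LinearFit:
    """A fitted linear model with everything downstream analyses need."""

    outcome_name: str
    coefficient_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    coef_covariance: np.ndarray
    residual_variance: float
    df_resid: int
    p_two_sided: np.ndarray
    n: int
    xtx_inv: np.ndarray          # inverse Gram matrix (X'X)^{-1}
    residuals: np.ndarray
    fitted: np.ndarray
    robust: bool = False

    def _idx(self, name: str) -> int:
        try:
            return self.coefficient_names.index(name)
        except ValueError:
            raise SchemaError(f"no coefficient named {name!r}") from None

    def coef(self, name: str = TX_COEF) -> float:
        return float(self.coefficients[self._idx(name)])

    def se(self, name: str = TX_COEF) -> float:
        return float(self.standard_errors[self._idx(name)])

    def p_value(self, name: str = TX_COEF) -> float:
        return float(self.p_two_sided[self._idx(name)])

    def cov(self, name_a: str, name_b: str) -> float:
        return float(self.coef_covariance[self._idx(name_a), self._idx(name_b)])

    def confint(self, name: str = TX_COEF, level: float = 0.95) -> tuple[float, float]:
        tcrit = float(stats.t.ppf(0.5 + level / 2.0, self.df_resid))
        b, s = self.coef(name), self.se(name)
        return b - tcrit * s, b + tcrit * s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.coefficient_names,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "p_two_sided": self.p_two_sided,
            }
        )

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "n": self.n,
            "df_resid": self.df_resid,
            "residual_variance": self.residual_variance,
            "robust_se": self.robust,
            "terms": self.to_frame().to_dict(orient="records"),
        }


@dataclass(frozen=True)
class NBVector:
    """Per-patient net benefit at one willingness-to-pay, in dataset row order."""

    wtp: float
    values: np.ndarray


def fit_ols(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    outcome_name: str = "y",
    robust: bool = False,
) -> LinearFit:
    """Ordinary least squares via SVD (stable orthogonal decomposition).

    Rank deficiency raises :class:`SingularDesignError` naming the columns
    involved in the collinearity; the cutoff is the machine-epsilon-scaled
    singular value threshold ``s_max * max(n, p) * eps``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise InsufficientDataError(
            f"{n} observations cannot support {p} coefficients (df_resid < 1)"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    cutoff = (s[0] if s.size else 0.0) * max(n, p) * np.finfo(float).eps
    rank = int((s > cutoff).sum())
    if rank < p:
        null = Vt[rank:]
        involved = [
            names[j] for j in range(p) if np.abs(null[:, j]).max() > 1e-8
        ]
        raise SingularDesignError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(involved)
        )

    coef = Vt.T @ ((U.T @ y) / s)
    fitted = X @ coef
    resid = y - fitted
    df = n - p
    rss = float(resid @ resid)
    # an exactly-fit outcome leaves only rounding noise in the residuals;
    # snap it to zero so degenerate cases report zero variance, not 1e-30
    scale = max(1.0, float(np.abs(y).max(initial=0.0)))
    if rss < n * (1e-12 * scale) ** 2:
        rss = 0.0
        resid = np.zeros_like(resid)
    s2 = rss / df
    xtx_inv = (Vt.T / s**2) @ Vt

    if robust:
        # HC1: (X'X)^-1 X' diag(r^2) X (X'X)^-1 * n/(n-p)
        meat = (X * resid[:, None] ** 2).T @ X
        cov = xtx_inv @ meat @ xtx_inv * (n / df)
    else:
        cov = s2 * xtx_inv
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    # degenerate (zero residual variance) outcomes get exact p-values
    zero_tol = 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    for j in range(p):
        if se[j] == 0.0:
            pvals[j] = 1.0 if abs(coef[j]) <= zero_tol else 0.0

    return LinearFit(
        outcome_name=outcome_name,
        coefficient_names=tuple(names),
        coefficients=coef,
        standard_errors=se,
        coef_covariance=cov,
        residual_variance=s2,
        df_resid=df,
        p_two_sided=pvals,
        n=n,
        xtx_inv=xtx_inv,
        residuals=resid,
        fitted=fitted,
        robust=robust,
    )


def build_design(
    ds: CEDataset,
    covariates: Sequence[str] = (),
    extra: Sequence[tuple[str, np.ndarray]] = (),
) -> tuple[np.ndarray, list[str]]:
    """Intercept + TX (+ dummy-coded covariates + extra columns) design.

    Categorical covariates use reference-level dummy coding with the
    first-appearance level as reference, so adjusted fits are reproducible
    regardless of sort order.
    """
    cols: list[np.ndarray] = [np.ones(ds.n), ds.tx.astype(float)]
    names: list[str] = ["const", TX_COEF]
    for name in covariates:
        spec = ds.covariate_spec(name)
        if spec.kind == "numeric":
            cols.append(ds.data[name].to_numpy(dtype=float))
            names.append(name)
        else:
            values = ds.data[name].astype(str).to_numpy()
            for level in spec.levels[1:]:
                cols.append((values == level).astype(float))
                names.append(f"{name}[{level}]")
    for name, col in extra:
        cols.append(np.asarray(col, dtype=float))
        names.append(name)
    return np.column_stack(cols), names


def fit_cost(ds: CEDataset, covariates: Sequence[str] = (), robust: bool = False) -> LinearFit:
    """Regress cost on TX (+ covariates); the TX coefficient estimates dC."""
    X, names = build_design(ds, covariates)
    return fit_ols(ds.cost, X, names, outcome_name="cost", robust=robust)


def fit_effect(ds: CEDataset, covariates: Sequence[str] = (), robust: bool = False) -> LinearFit:
    """Regress effect on TX (+ covariates); the TX coefficient estimates dE."""
    X, names = build_design(ds, covariates)
    return fit_ols(ds.effect, X, names, outcome_name="effect", robust=robust)


def compute_nb(ds: CEDataset, wtp: float) -> NBVector:
    """Per-patient net benefit ``wtp * e_i - c_i`` (dollars), row-aligned."""
    if wtp < 0:
        raise DomainError(f"willingness to pay must be non-negative; got {wtp}")
    return NBVector(wtp=float(wtp), values=wtp * ds.effect - ds.cost)


def fit_nb(
    ds: CEDataset,
    wtp: float,
    covariates: Sequence[str] = (),
    robust: bool = False,
) -> LinearFit:
    """Net-benefit regression at one WTP; the TX coefficient is the INB.

    Its confidence interval is the INB confidence interval at that WTP.
    """
    nb = compute_nb(ds, wtp)
    X, names = build_design(ds, covariates)
    return fit_ols(nb.values, X, names, outcome_name=f"nb@{wtp:g}", robust=robust)


def residual_cross_covariance(fit_a: LinearFit, fit_b: LinearFit) -> float:
    """Residual cross-covariance of two fits sharing one design matrix.

    For the cost and effect fits this is s_EC = sum(r_C r_E) / df_resid, the
    term that carries the cost-effect correlation into the net-benefit
    variance composition.
    """
    if fit_a.n != fit_b.n or fit_a.df_resid != fit_b.df_resid:
        raise ValueError("fits do not share a design (n or df_resid differ)")
    return float(fit_a.residuals @ fit_b.residuals) / fit_a.df_resid
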