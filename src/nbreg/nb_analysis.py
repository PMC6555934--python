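"""WTP sweeps, INB-by-WTP geometry, ICER quadrant policy and Fieller limits.

The incremental net benefit as a function of the willingness-to-pay threshold
lambda is the line

    INB(lambda) = lambda * dE - dC

with y-intercept -dC, slope dE and x-intercept dC/dE (the ICER). Its pointwise
standard error follows from the variance composition of the shared-design
regressions,

    Var[INB(lambda)] = lambda^2 Var(dE) - 2 lambda Cov(dC, dE) + Var(dC),

and the willingness-to-pay values where the INB confidence bounds cross zero
are exactly the Fieller's-theorem confidence limits for the ICER. Crossings
are located with a safeguarded scalar root-finder on the closed-form bound
functions, never by grid interpolation, so they do not depend on grid spacing.

The ICER itself is only reported in the sign-consistent quadrants of the
cost-effectiveness plane (more costly & more effective, or cost-saving & less
effective); in mixed-sign quadrants a negative ratio is misleading and the
dominance label is returned instead.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ce_data import CEDataset
from .exceptions import DomainError
from .regress import (
    TX_COEF,
    LinearFit,
    fit_cost,
    fit_effect,
    fit_nb,
    residual_cross_covariance,
)

#: WTP grid mirroring the $0-$500,000 tabulation in steps of $50,000.
DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 500_001, 50_000))


@dataclass(frozen=True)
class IncrementalSummary:
    """dC and dE from shared-design regressions, with the pieces the INB
    variance needs."""

    delta_cost: float
    se_cost: float
    p_cost: float
    delta_effect: float
    se_effect: float
    p_effect: float
    cov_delta: float          # Cov(dC_hat, dE_hat) = s_EC * [(X'X)^-1]_TX,TX
    n: int
    df_resid: int
    covariates_used: tuple[str, ...] = ()

    def inb(self, wtp: float) -> float:
        return wtp * self.delta_effect - self.delta_cost

    def inb_variance(self, wtp: float) -> float:
        return (
            wtp**2 * self.se_effect**2
            - 2.0 * wtp * self.cov_delta
            + self.se_cost**2
        )

    def inb_se(self, wtp: float) -> float:
        return math.sqrt(max(self.inb_variance(wtp), 0.0))


class Quadrant(enum.Enum):
    """Sign pattern of (dC, dE) on the cost-effectiveness plane."""

    TRADE_OFF = "trade-off"                                # dC > 0, dE > 0
    DOMINANT = "dominant"                                  # dC < 0, dE > 0
    DOMINATED = "dominated"                                # dC > 0, dE < 0
    COST_SAVING_LESS_EFFECTIVE = "cost-saving-less-effective"  # dC < 0, dE < 0


@dataclass(frozen=True)
class ICEREstimate:
    """ICER with quadrant policy: the ratio is reported only when its sign is
    interpretable (dC and dE of equal sign)."""

    ratio: float | None          # whole dollars per effect unit, or None
    ratio_exact: float | None    # unrounded quotient (internal precision)
    quadrant: Quadrant | None
    reportable: bool
    label: str


@dataclass(frozen=True)
class FiellerInterval:
    """ICER confidence limits from the INB bound zero-crossings.

    ``None`` means the corresponding bound never crosses zero on the
    non-negative WTP axis: the limit is unbounded (or negative, which is
    outside the decision-relevant domain).
    """

    lower: float | None
    upper: float | None
    level: float

    def contains(self, wtp: float) -> bool:
        lo = self.lower if self.lower is not None else -math.inf
        hi = self.upper if self.upper is not None else math.inf
        return lo <= wtp <= hi


@dataclass
class INBCurve:
    """INB point estimates, CI bounds and p-values over an ordered WTP grid."""

    grid: np.ndarray
    inb: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_two_sided: np.ndarray
    ci_level: float
    summary: IncrementalSummary
    zero_crossing: float | None
    ci_crossings: FiellerInterval
    fits: tuple[LinearFit, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.grid,
                "inb": self.inb,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_two_sided": self.p_two_sided,
            }
        )


def incremental_summary(
    ds: CEDataset, covariates: Sequence[str] = ()
) -> IncrementalSummary:
    """Estimate dC and dE from cost and effect regressions sharing one design."""
    fc = fit_cost(ds, covariates)
    fe = fit_effect(ds, covariates)
    s_ec = residual_cross_covariance(fc, fe)
    g_tx = float(fc.xtx_inv[fc.coefficient_names.index(TX_COEF),
                            fc.coefficient_names.index(TX_COEF)])
    return IncrementalSummary(
        delta_cost=fc.coef(),
        se_cost=fc.se(),
        p_cost=fc.p_value(),
        delta_effect=fe.coef(),
        se_effect=fe.se(),
        p_effect=fe.p_value(),
        cov_delta=s_ec * g_tx,
        n=fc.n,
        df_resid=fc.df_resid,
        covariates_used=tuple(covariates),
    )


def icer(inc: IncrementalSummary) -> ICEREstimate:
    """ICER = dC / dE with quadrant policy and whole-dollar display rounding."""
    dc, de = inc.delta_cost, inc.delta_effect
    if de == 0.0:
        return ICEREstimate(
            ratio=None,
            ratio_exact=None,
            quadrant=None,
            reportable=False,
            label="undefined (ΔE = 0)",
        )
    if de > 0:
        quadrant = Quadrant.TRADE_OFF if dc >= 0 else Quadrant.DOMINANT
    else:
        quadrant = Quadrant.DOMINATED if dc >= 0 else Quadrant.COST_SAVING_LESS_EFFECTIVE
    reportable = quadrant in (Quadrant.TRADE_OFF, Quadrant.COST_SAVING_LESS_EFFECTIVE)
    if not reportable:
        return ICEREstimate(
            ratio=None,
            ratio_exact=None,
            quadrant=quadrant,
            reportable=False,
            label=quadrant.value,
        )
    exact = dc / de
    return ICEREstimate(
        ratio=float(np.rint(exact)),
        ratio_exact=exact,
        quadrant=quadrant,
        reportable=True,
        label=quadrant.value,
    )


def sweep_inb(
    ds: CEDataset,
    grid: Sequence[float] = DEFAULT_WTP_GRID,
    covariates: Sequence[str] = (),
    ci_level: float = 0.95,
) -> INBCurve:
    """Run one net-benefit regression per WTP grid point.

    The grid is for tabulation and plotting only; the zero-crossing and the
    Fieller limits are computed from the closed-form line and SE function.
    """
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise DomainError("WTP grid must be non-empty")
    if (np.diff(grid_arr) <= 0).any():
        raise DomainError("WTP grid must be strictly increasing")
    if (grid_arr < 0).any():
        raise DomainError("WTP grid must be non-negative")
    if not 0 < ci_level < 1:
        raise DomainError(f"ci_level must be in (0, 1); got {ci_level}")

    fits = tuple(fit_nb(ds, w, covariates) for w in grid_arr)
    inc = incremental_summary(ds, covariates)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, inc.df_resid))

    inb = np.array([f.coef() for f in fits])
    se = np.array([f.se() for f in fits])
    pvals = np.array([f.p_value() for f in fits])

    de, dc = inc.delta_effect, inc.delta_cost
    zero_crossing = None
    if de != 0.0:
        x0 = dc / de
        if x0 >= 0:
            zero_crossing = x0

    return INBCurve(
        grid=grid_arr,
        inb=inb,
        se=se,
        ci_low=inb - tcrit * se,
        ci_high=inb + tcrit * se,
        p_two_sided=pvals,
        ci_level=ci_level,
        summary=inc,
        zero_crossing=zero_crossing,
        ci_crossings=fieller_ci(inc, ci_level),
        fits=fits,
    )


def fieller_ci(
    obj: INBCurve | IncrementalSummary, ci_level: float | None = None
) -> FiellerInterval:
    """ICER confidence limits as zero-crossings of the INB confidence bounds.

    The lower (upper) ICER limit is the WTP where the upper (lower) INB bound
    ``INB(lambda) +- t_crit * SE(lambda)`` crosses zero on ``lambda >= 0``,
    found by bracketing + Brent root-finding; a bound that never crosses is
    reported as unbounded (``None``). With SE identically zero the limits
    collapse to the point ICER.
    """
    if isinstance(obj, INBCurve):
        inc = obj.summary
        level = obj.ci_level if ci_level is None else ci_level
    else:
        inc = obj
        level = 0.95 if ci_level is None else ci_level
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, inc.df_resid))

    if inc.se_cost == 0.0 and inc.se_effect == 0.0:
        point = (
            inc.delta_cost / inc.delta_effect if inc.delta_effect != 0.0 else None
        )
        if point is not None and point >= 0:
            return FiellerInterval(lower=point, upper=point, level=level)
        return FiellerInterval(lower=None, upper=None, level=level)

    def bound(lam: float, sign: float) -> float:
        return inc.inb(lam) + sign * tcrit * inc.inb_se(lam)

    upper_cross = _first_crossing(lambda lam: bound(lam, +1.0), inc, tcrit, +1.0)
    lower_cross = _first_crossing(lambda lam: bound(lam, -1.0), inc, tcrit, -1.0)
    # upper INB bound crossing -> lower ICER limit; lower bound -> upper limit
    return FiellerInterval(lower=upper_cross, upper=lower_cross, level=level)


def _first_crossing(f, inc: IncrementalSummary, tcrit: float, sign: float):
    """First zero of an INB confidence bound on [0, inf), or None.

    The upper bound (sign = +1) is convex in lambda (line plus t times the
    square root of a non-negative quadratic) and the lower bound (sign = -1)
    is concave, so the bound has a single interior vertex and is monotone on
    either side of it. Locating the vertex and bracketing each side makes the
    search safeguarded against narrow double crossings that a plain geometric
    scan would skip.
    """
    scale = max(
        1.0,
        abs(inc.delta_cost / inc.delta_effect) if inc.delta_effect != 0.0 else 0.0,
        abs(inc.delta_cost),
    )
    res = optimize.minimize_scalar(
        lambda lam: sign * f(lam),
        bounds=(0.0, 1e9 * scale),
        method="bounded",
        options={"xatol": 1e-8 * scale},
    )
    vertex = float(res.x)
    big = max(10.0 * scale, 4.0 * vertex + 1.0)

    roots: list[float] = []
    pts = sorted({0.0, vertex, big})
    for a, b in zip(pts[:-1], pts[1:]):
        fa, fb = f(a), f(b)
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(
                float(optimize.brentq(f, a, b, xtol=1e-10, rtol=8.9e-16, maxiter=200))
            )
    if f(big) == 0.0:
        roots.append(big)

    if not roots:
        # beyond `big` the bound is monotone toward its asymptotic slope
        fbig = f(big)
        asym_slope = inc.delta_effect + sign * tcrit * inc.se_effect
        if fbig * asym_slope < 0:
            lo, hi = big, big * 2.0
            for _ in range(64):
                if f(hi) * fbig < 0:
                    roots.append(
                        float(
                            optimize.brentq(
                                f, lo, hi, xtol=1e-10, rtol=8.9e-16, maxiter=200
                            )
                        )
                    )
                    break
                lo, hi = hi, hi * 2.0
    return min(roots) if roots else None


def extrapolate_inb(
    inb_ref: float, wtp_ref: float, wtp_new: float, delta_effect: float
) -> int:
    """Slide an INB estimate along the line: each $1 of WTP adds dE dollars.

    Returns ``inb_ref + (wtp_new - wtp_ref) * delta_effect`` rounded to the
    nearest dollar for reporting, so a tabulated INB can be restated at any
    WTP without rerunning the regression.
    """
    value = inb_ref + (wtp_new - wtp_ref) * delta_effect
    return int(np.rint(value))
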