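"""Parametric and bootstrap uncertainty: CEACs and bootstrap INB intervals.

A cost-effectiveness acceptability curve (CEAC) plots, against the
willingness-to-pay threshold, the probability that the new treatment is
cost-effective — i.e. the portion of the INB sampling distribution above
zero. Two routes are provided:

* parametric — the two-sided p-value of the net-benefit regression's TX
  coefficient is folded into a one-sided probability:
  ``1 - p/2`` when the INB estimate is positive, ``p/2`` when negative and
  exactly 0.5 at zero (ties split);
* nonparametric — patients are resampled with replacement within arm
  (preserving the randomized arm sizes), dC and dE are recomputed per
  replicate, and the CEAC is the fraction of replicates with positive INB.

All resampling draws come from a named, seeded ``numpy.random.Generator``;
there is no global random state, and a repeated run with the same seed is
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ce_data import CEDataset
from .exceptions import DomainError
from .regress import LinearFit, build_design, fit_nb, fit_ols


@dataclass
class CEACCurve:
    """Probability cost-effective over a WTP grid, parametric or bootstrap."""

    grid: np.ndarray
    prob_ce: np.ndarray
    method: str                      # "parametric" | "bootstrap"
    B: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wtp": self.grid, "prob_ce": self.prob_ce})
        df["method"] = self.method
        df["B"] = self.B
        df["seed"] = self.seed
        return df


@dataclass
class BootstrapReplicates:
    """Within-arm resampled (dC, dE) pairs; regeneration from the seed is
    bit-exact."""

    B: int
    seed: int
    delta_cost_reps: np.ndarray
    delta_effect_reps: np.ndarray
    stratified_by_arm: bool = True
    degenerate: np.ndarray | None = None   # replicates with zero within-arm variance
    covariates_used: tuple[str, ...] = ()


def prob_ce_parametric(fit: LinearFit) -> float:
    """One-sided probability cost-effective from a net-benefit fit.

    Converts the TX coefficient's two-sided p-value: ``1 - p/2`` if the INB
    estimate is positive, ``p/2`` if negative, 0.5 at exactly zero.
    """
    b = fit.coef()
    p2 = fit.p_value()
    if b > 0:
        return 1.0 - p2 / 2.0
    if b < 0:
        return p2 / 2.0
    return 0.5


def ceac_parametric(
    ds: CEDataset,
    grid: Sequence[float],
    covariates: Sequence[str] = (),
) -> CEACCurve:
    """Parametric CEAC: one net-benefit regression per WTP grid point."""
    grid_arr = np.asarray(grid, dtype=float)
    probs = np.array(
        [prob_ce_parametric(fit_nb(ds, w, covariates)) for w in grid_arr]
    )
    return CEACCurve(grid=grid_arr, prob_ce=probs, method="parametric")


def bootstrap_replicates(
    ds: CEDataset,
    B: int,
    seed: int,
    covariates: Sequence[str] = (),
) -> BootstrapReplicates:
    """Resample patients with replacement within arm; recompute dC and dE.

    Unadjusted analyses use vectorized arm-mean differences; adjusted
    analyses refit the shared-design regressions per replicate. Replicates
    with zero within-arm variance in both outcomes are retained and flagged
    in ``degenerate`` rather than redrawn (redrawing would bias the
    resampling distribution).
    """
    if B < 1:
        raise DomainError(f"B must be >= 1; got {B}")
    rng = np.random.default_rng(seed)
    idx0_pool = np.flatnonzero(ds.tx == 0)
    idx1_pool = np.flatnonzero(ds.tx == 1)
    n0, n1 = idx0_pool.size, idx1_pool.size

    # arm tx=0 indices drawn first, then tx=1 (documented draw order)
    draws0 = idx0_pool[rng.integers(0, n0, size=(B, n0))]
    draws1 = idx1_pool[rng.integers(0, n1, size=(B, n1))]

    cost, effect = ds.cost, ds.effect
    if not covariates:
        c0, c1 = cost[draws0], cost[draws1]
        e0, e1 = effect[draws0], effect[draws1]
        dc = c1.mean(axis=1) - c0.mean(axis=1)
        de = e1.mean(axis=1) - e0.mean(axis=1)
        degen = (
            (c0.std(axis=1) == 0) & (c1.std(axis=1) == 0)
            & (e0.std(axis=1) == 0) & (e1.std(axis=1) == 0)
        )
    else:
        X, names = build_design(ds, covariates)
        tx_col = names.index("tx")
        dc = np.empty(B)
        de = np.empty(B)
        degen = np.zeros(B, dtype=bool)
        for b in range(B):
            rows = np.concatenate([draws0[b], draws1[b]])
            Xb = X[rows]
            fc = fit_ols(cost[rows], Xb, names, outcome_name="cost")
            fe = fit_ols(effect[rows], Xb, names, outcome_name="effect")
            dc[b] = fc.coefficients[tx_col]
            de[b] = fe.coefficients[tx_col]
            degen[b] = (
                fc.residual_variance == 0.0 and fe.residual_variance == 0.0
            )

    return BootstrapReplicates(
        B=B,
        seed=seed,
        delta_cost_reps=dc,
        delta_effect_reps=de,
        degenerate=degen,
        covariates_used=tuple(covariates),
    )


def ceac_bootstrap(reps: BootstrapReplicates, grid: Sequence[float]) -> CEACCurve:
    """Bootstrap CEAC: fraction of replicates with positive INB at each WTP.

    Replicates with INB exactly zero count one half (symmetry; measure zero
    under continuous data).
    """
    grid_arr = np.asarray(grid, dtype=float)
    inb = (
        grid_arr[:, None] * reps.delta_effect_reps[None, :]
        - reps.delta_cost_reps[None, :]
    )
    probs = ((inb > 0).sum(axis=1) + 0.5 * (inb == 0).sum(axis=1)) / reps.B
    return CEACCurve(
        grid=grid_arr,
        prob_ce=probs,
        method="bootstrap",
        B=reps.B,
        seed=reps.seed,
    )


def bootstrap_ci_inb(
    reps: BootstrapReplicates, wtp: float, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap interval for the INB at one WTP."""
    if not 0 < level < 1:
        raise DomainError(f"level must be in (0, 1); got {level}")
    if reps.B < 100:
        warnings.warn(
            f"percentile intervals from only B={reps.B} replicates are unstable; "
            "use B >= 100",
            stacklevel=2,
        )
    inb = wtp * reps.delta_effect_reps - reps.delta_cost_reps
    alpha = 1.0 - level
    lo, hi = np.quantile(inb, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
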