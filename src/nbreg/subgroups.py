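"""Treatment-by-subgroup interaction models and stratified WTP sweeps.

Two equivalent routes answer "is the treatment more cost-effective in one
subgroup than another?":

* an interaction model — net benefit regressed on TX, the subgroup indicator
  G, and TX x G; the TX coefficient is the INB in the reference stratum and
  TX + TX x G is the INB in the other stratum;
* stratification — a separate net-benefit regression per stratum.

Without extra covariates the interaction model is saturated in (TX, G), so
point estimates from both routes coincide exactly; standard errors differ
(pooled versus per-stratum residual variance), which is expected, not a bug.
The interaction route also extends to continuous moderators, where
stratification is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ce_data import CEDataset
from .exceptions import SchemaError, ValidationError
from .nb_analysis import INBCurve, sweep_inb
from .regress import LinearFit, build_design, compute_nb, fit_ols


@dataclass
class InteractionFitResult:
    """Net-benefit interaction fit at one WTP.

    ``base_fit`` holds b_TX (reference-stratum INB), b_G (subgroup main
    effect) and b_TXxG (between-stratum INB difference); ``combined_inb`` is
    the non-reference stratum's INB, b_TX + moderator_value * b_TXxG, with a
    delta-method SE read off the coefficient covariance.
    """

    wtp: float
    base_fit: LinearFit
    subgroup: str
    reference_level: str | None
    other_level: str | None
    moderator_value: float
    tx_term: str
    interaction_term: str
    combined_inb: float
    combined_se: float
    combined_p: float
    covariates_used: tuple[str, ...] = ()

    @property
    def b_tx(self) -> float:
        return self.base_fit.coef(self.tx_term)

    @property
    def b_interaction(self) -> float:
        return self.base_fit.coef(self.interaction_term)


def interaction_fit(
    ds: CEDataset,
    subgroup: str,
    wtp: float,
    covariates: Sequence[str] = (),
    reference_level: str | None = None,
    moderator_value: float = 1.0,
) -> InteractionFitResult:
    """Net-benefit regression with a TX-by-subgroup interaction term.

    ``subgroup`` may be the dataset's subgroup column, a binary categorical
    covariate, or a numeric covariate (continuous moderator). For a
    categorical moderator the reference level defaults to first appearance
    and ``moderator_value`` is fixed at 1 (the dummy); for a numeric
    moderator the combined INB is reported at ``moderator_value``.
    """
    g, ref, other, is_numeric = _moderator_column(ds, subgroup, reference_level)
    if not is_numeric:
        moderator_value = 1.0

    nb = compute_nb(ds, wtp)
    g_name = subgroup if is_numeric else f"{subgroup}[{other}]"
    inter_name = f"tx:{g_name}"
    X, names = build_design(
        ds,
        covariates,
        extra=[(g_name, g), (inter_name, ds.tx.astype(float) * g)],
    )
    fit = fit_ols(nb.values, X, names, outcome_name=f"nb@{wtp:g}")

    b_tx = fit.coef("tx")
    b_int = fit.coef(inter_name)
    combined = b_tx + moderator_value * b_int
    var = (
        fit.cov("tx", "tx")
        + moderator_value**2 * fit.cov(inter_name, inter_name)
        + 2.0 * moderator_value * fit.cov("tx", inter_name)
    )
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(combined / se), fit.df_resid))
    else:
        p = 1.0 if combined == 0.0 else 0.0

    return InteractionFitResult(
        wtp=float(wtp),
        base_fit=fit,
        subgroup=subgroup,
        reference_level=None if is_numeric else ref,
        other_level=None if is_numeric else other,
        moderator_value=float(moderator_value),
        tx_term="tx",
        interaction_term=inter_name,
        combined_inb=float(combined),
        combined_se=se,
        combined_p=p,
        covariates_used=tuple(covariates),
    )


def stratified_analysis(
    ds: CEDataset,
    subgroup: str,
    grid: Sequence[float],
    covariates: Sequence[str] = (),
    ci_level: float = 0.95,
) -> dict[str, INBCurve]:
    """Independent INB sweep per subgroup level.

    Every level must contain both arms; a stratum missing an arm raises a
    validation error naming it.
    """
    levels = _categorical_levels(ds, subgroup)
    out: dict[str, INBCurve] = {}
    for level in levels:
        try:
            sub = _restrict(ds, subgroup, level)
        except ValidationError as err:
            raise ValidationError(f"stratum {level!r}: {err}") from None
        out[level] = sweep_inb(sub, grid, covariates, ci_level)
    return out


# -- helpers -----------------------------------------------------------------

def _categorical_levels(ds: CEDataset, subgroup: str) -> tuple[str, ...]:
    if ds.subgroup is not None and subgroup == ds.subgroup:
        levels = ds.subgroup_levels()
    else:
        spec = ds.covariate_spec(subgroup)
        if spec.kind != "categorical":
            raise SchemaError(
                f"{subgroup!r} is numeric; stratification needs a categorical "
                "moderator (use interaction_fit for continuous ones)"
            )
        levels = spec.levels
    if len(levels) < 2:
        raise ValidationError(
            f"subgroup {subgroup!r} has a single level {levels[0]!r}"
        )
    return levels


def _restrict(ds: CEDataset, subgroup: str, level: str) -> CEDataset:
    if ds.subgroup is not None and subgroup == ds.subgroup:
        return ds.filter_subgroup(level)
    mask = ds.data[subgroup].astype(str) == str(level)
    sub = ds.data.loc[mask].reset_index(drop=True)
    counts = sub["tx"].value_counts()
    for arm in (0, 1):
        if counts.get(arm, 0) < 2:
            raise ValidationError(f"fewer than 2 records in arm tx={arm}")
    from dataclasses import replace

    return replace(ds, data=sub)


def _moderator_column(
    ds: CEDataset, subgroup: str, reference_level: str | None
) -> tuple[np.ndarray, str | None, str | None, bool]:
    """Return (column, reference level, other level, is_numeric)."""
    if ds.subgroup is not None and subgroup == ds.subgroup:
        levels = ds.subgroup_levels()
        values = ds.data[subgroup].astype(str).to_numpy()
    else:
        spec = ds.covariate_spec(subgroup)
        if spec.kind == "numeric":
            return ds.data[subgroup].to_numpy(dtype=float), None, None, True
        levels = spec.levels
        values = ds.data[subgroup].astype(str).to_numpy()
    if len(levels) < 2:
        raise ValidationError(
            f"subgroup {subgroup!r} has a single level {levels[0]!r}"
        )
    if len(levels) > 2:
        raise ValidationError(
            f"subgroup {subgroup!r} has {len(levels)} levels; interaction_fit "
            "requires a binary moderator (stratify instead)"
        )
    ref = reference_level if reference_level is not None else levels[0]
    if ref not in levels:
        raise ValidationError(f"{ref!r} is not a level of {subgroup!r}")
    other = next(l for l in levels if l != ref)
    return (values == other).astype(float), ref, other, False
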