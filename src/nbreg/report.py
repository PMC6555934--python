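"""Table builders and writers for the standard outputs.

Two renderings of each table are produced: a tidy, full-precision frame for
machines, and a formatted frame for humans (dollars to whole units, QALYs to
four decimals, p-values to four decimals). Display rounding never feeds back
into computation.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ce_data import CEDataset
from .nb_analysis import (
    FiellerInterval,
    ICEREstimate,
    INBCurve,
    IncrementalSummary,
    fieller_ci,
    icer,
    incremental_summary,
    sweep_inb,
)
from .subgroups import interaction_fit, stratified_analysis
from .uncertainty import CEACCurve, bootstrap_replicates, ceac_bootstrap, ceac_parametric


def _groups(ds: CEDataset, subgroup: str | None):
    """Yield (label, sub-dataset): each stratum first, then the pooled sample."""
    if subgroup is not None:
        for level in (
            ds.subgroup_levels()
            if subgroup == ds.subgroup
            else ds.covariate_spec(subgroup).levels
        ):
            yield level, _restrict_group(ds, subgroup, level)
    yield "ALL", ds


def _restrict_group(ds: CEDataset, subgroup: str, level: str) -> CEDataset:
    if subgroup == ds.subgroup:
        return ds.filter_subgroup(level)
    from .subgroups import _restrict

    return _restrict(ds, subgroup, level)


def incremental_table(
    ds: CEDataset,
    grid: Sequence[float],
    covariates: Sequence[str] = (),
    subgroup: str | None = None,
) -> pd.DataFrame:
    """Tidy per-group estimates of dE, dC and INB across the WTP grid.

    Columns: group, n, quantity ("effect" | "cost" | "nb"), wtp (NaN except
    for nb rows), estimate, se, p_two_sided.
    """
    rows = []
    for label, sub in _groups(ds, subgroup):
        inc = incremental_summary(sub, covariates)
        rows.append(
            dict(group=label, n=inc.n, quantity="effect", wtp=np.nan,
                 estimate=inc.delta_effect, se=inc.se_effect, p_two_sided=inc.p_effect)
        )
        rows.append(
            dict(group=label, n=inc.n, quantity="cost", wtp=np.nan,
                 estimate=inc.delta_cost, se=inc.se_cost, p_two_sided=inc.p_cost)
        )
        curve = sweep_inb(sub, grid, covariates)
        for w, b, s, p in zip(curve.grid, curve.inb, curve.se, curve.p_two_sided):
            rows.append(
                dict(group=label, n=inc.n, quantity="nb", wtp=w,
                     estimate=b, se=s, p_two_sided=p)
            )
    return pd.DataFrame(rows)


def format_incremental_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Human-readable wide table: one row per group, 'estimate(p)' cells."""
    out = []
    for group, block in tidy.groupby("group", sort=False):
        row: dict[str, object] = {"group": group, "n": int(block["n"].iloc[0])}
        for _, r in block.iterrows():
            if r["quantity"] == "effect":
                row["effect"] = f"{r['estimate']:.4f}({_fmt_p(r['p_two_sided'])})"
            elif r["quantity"] == "cost":
                row["cost"] = f"{r['estimate']:,.0f}({_fmt_p(r['p_two_sided'])})"
            else:
                row[f"nb@{r['wtp']:g}"] = (
                    f"{r['estimate']:,.0f}({_fmt_p(r['p_two_sided'])})"
                )
        out.append(row)
    return pd.DataFrame(out)


def _fmt_p(p: float) -> str:
    return "< 0.0001" if p < 1e-4 else f"{p:.4f}"


def icer_report(
    ds: CEDataset,
    covariates: Sequence[str] = (),
    subgroup: str | None = None,
    ci_level: float = 0.95,
) -> dict:
    """ICER point estimates with quadrant labels and Fieller limits per group."""
    report: dict[str, dict] = {}
    for label, sub in _groups(ds, subgroup):
        inc = incremental_summary(sub, covariates)
        est = icer(inc)
        fieller = fieller_ci(inc, ci_level)
        report[label] = {
            "n": inc.n,
            "delta_cost": inc.delta_cost,
            "delta_effect": inc.delta_effect,
            "quadrant": est.quadrant.value if est.quadrant else None,
            "reportable": est.reportable,
            "icer": est.ratio,
            "icer_exact": est.ratio_exact,
            "label": est.label,
            "fieller_lower": fieller.lower,
            "fieller_upper": fieller.upper,
            "ci_level": ci_level,
        }
    return report


def inb_curve_table(
    ds: CEDataset,
    grid: Sequence[float],
    covariates: Sequence[str] = (),
    subgroup: str | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Tidy INB curves (per group if a subgroup is named): wtp, inb, CI, p."""
    frames = []
    for label, sub in _groups(ds, subgroup):
        curve = sweep_inb(sub, grid, covariates, ci_level)
        frame = curve.to_frame()
        frame.insert(0, "group", label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def ceac_table(
    ds: CEDataset,
    grid: Sequence[float],
    covariates: Sequence[str] = (),
    subgroup: str | None = None,
    bootstrap_B: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy CEACs per group; parametric always, bootstrap when B is given."""
    frames = []
    for label, sub in _groups(ds, subgroup):
        curves: list[CEACCurve] = [ceac_parametric(sub, grid, covariates)]
        if bootstrap_B:
            if seed is None:
                from .exceptions import DomainError

                raise DomainError("bootstrap CEACs require an explicit seed")
            reps = bootstrap_replicates(sub, bootstrap_B, seed, covariates)
            curves.append(ceac_bootstrap(reps, grid))
        for curve in curves:
            frame = curve.to_frame()
            frame.insert(0, "group", label)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def interaction_table(
    ds: CEDataset,
    subgroup: str,
    grid: Sequence[float],
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Interaction-model summary across the WTP grid.

    One row per (wtp, term) with term in {tx, subgroup main effect,
    tx-by-subgroup interaction, combined INB for the non-reference stratum}.
    """
    rows = []
    for w in grid:
        res = interaction_fit(ds, subgroup, w, covariates)
        fit = res.base_fit
        for term, pretty in (
            ("tx", "tx"),
            (res.interaction_term.split("tx:", 1)[1], "subgroup"),
            (res.interaction_term, "tx:subgroup"),
        ):
            rows.append(
                dict(wtp=w, term=pretty, column=term,
                     estimate=fit.coef(term), se=fit.se(term),
                     p_two_sided=fit.p_value(term))
            )
        rows.append(
            dict(wtp=w, term="combined_inb", column=res.interaction_term,
                 estimate=res.combined_inb, se=res.combined_se,
                 p_two_sided=res.combined_p)
        )
    return pd.DataFrame(rows)


def format_interaction_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Wide 'estimate [se] (p)' rendering: rows = terms, columns = WTP."""
    out = []
    for term, block in tidy.groupby("term", sort=False):
        row: dict[str, object] = {"term": term}
        for _, r in block.iterrows():
            row[f"nb@{r['wtp']:g}"] = (
                f"{r['estimate']:,.0f} [{r['se']:,.0f}] ({_fmt_p(r['p_two_sided'])})"
            )
        out.append(row)
    return pd.DataFrame(out)


def write_json(obj: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)!r}")
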