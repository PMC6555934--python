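"""Person-level cost-effectiveness datasets: container, validation and CSV I/O.

The universal input of the package is one row per trial participant carrying a
binary treatment indicator ``tx`` (1 = new treatment, 0 = usual care), a cost
``c_i`` in currency units, a health effect ``e_i`` (typically QALYs), an
optional subgroup label and optional covariates. Units are carried as labels
only; the arithmetic is unit-agnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError, ValidationError

REQUIRED_COLUMNS = ("tx", "cost", "effect")


@dataclass(frozen=True)
class CovariateSpec:
    """Declared type of one covariate column.

    ``levels`` is the deterministic first-appearance level ordering for a
    categorical covariate (the first level is the dummy-coding reference);
    it is ``None`` for numeric covariates.
    """

    name: str
    kind: Literal["numeric", "categorical"]
    levels: tuple[str, ...] | None = None


@dataclass(frozen=True)
class PatientRecord:
    """A single participant row (convenience view; storage is columnar)."""

    id: str
    tx: int
    cost: float
    effect: float
    subgroup: str | None = None
    covariates: Mapping[str, object] = field(default_factory=dict)


@dataclass
class CEDataset:
    """Validated person-level cost-effectiveness data.

    Parameters
    ----------
    data
        One row per patient with at least the columns ``id``, ``tx``,
        ``cost`` and ``effect``; optionally a subgroup column and covariate
        columns. Row order is preserved and meaningful (net-benefit vectors
        align to it).
    covariates
        Declared covariate schema; every listed column must exist.
    subgroup
        Name of the subgroup column, if any.
    allow_negative_cost
        Negative costs are rejected by default (likely data errors in trial
        costing); set True to accept credits.
    cost_unit, effect_unit
        Reporting labels only.
    """

    data: pd.DataFrame
    covariates: tuple[CovariateSpec, ...] = ()
    subgroup: str | None = None
    allow_negative_cost: bool = False
    cost_unit: str = "$"
    effect_unit: str = "QALY"

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        tx: Sequence[int],
        cost: Sequence[float],
        effect: Sequence[float],
        ids: Sequence[str] | None = None,
        subgroup: Sequence[str] | None = None,
        covariates: Mapping[str, Sequence] | None = None,
        **kwargs,
    ) -> "CEDataset":
        """Build a dataset from parallel arrays (main programmatic entry)."""
        n = len(tx)
        cols: dict[str, object] = {
            "id": list(ids) if ids is not None else [str(i + 1) for i in range(n)],
            "tx": np.asarray(tx, dtype=int),
            "cost": np.asarray(cost, dtype=float),
            "effect": np.asarray(effect, dtype=float),
        }
        sub_name = None
        if subgroup is not None:
            cols["subgroup"] = list(subgroup)
            sub_name = "subgroup"
        specs: list[CovariateSpec] = []
        if covariates:
            for name, values in covariates.items():
                arr = np.asarray(values)
                cols[name] = arr
                specs.append(_infer_spec(name, pd.Series(arr)))
        df = pd.DataFrame(cols)
        return cls(df, covariates=tuple(specs), subgroup=sub_name, **kwargs)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        for col in ("id",) + REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} is missing")
        if self.subgroup is not None and self.subgroup not in df.columns:
            raise SchemaError(f"subgroup column {self.subgroup!r} is missing")
        for spec in self.covariates:
            if spec.name not in df.columns:
                raise SchemaError(f"covariate column {spec.name!r} is missing")

        for col in ("cost", "effect"):
            vals = df[col]
            if vals.isna().any():
                row = int(vals.index[vals.isna()][0]) + 1
                raise ValidationError(f"missing {col} value at data row {row}")
            if not np.isfinite(vals.to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite {col} value present")

        tx = df["tx"]
        if tx.isna().any() or not set(np.unique(tx)).issubset({0, 1}):
            bad = sorted(set(tx.dropna().unique()) - {0, 1})
            raise ValidationError(
                f"tx must be 0 or 1; found {bad if bad else 'missing values'}"
            )
        if not self.allow_negative_cost and (df["cost"] < 0).any():
            row = int(df.index[df["cost"] < 0][0]) + 1
            raise ValidationError(
                f"negative cost at data row {row}; pass allow_negative_cost=True "
                "to accept credits"
            )
        counts = df["tx"].value_counts()
        for arm in (0, 1):
            if counts.get(arm, 0) < 2:
                raise ValidationError(
                    f"need at least 2 records in arm tx={arm}; found {counts.get(arm, 0)}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_per_arm(self) -> dict[int, int]:
        counts = self.data["tx"].value_counts()
        return {0: int(counts.get(0, 0)), 1: int(counts.get(1, 0))}

    @property
    def tx(self) -> np.ndarray:
        return self.data["tx"].to_numpy(dtype=int)

    @property
    def cost(self) -> np.ndarray:
        return self.data["cost"].to_numpy(dtype=float)

    @property
    def effect(self) -> np.ndarray:
        return self.data["effect"].to_numpy(dtype=float)

    def covariate_spec(self, name: str) -> CovariateSpec:
        for spec in self.covariates:
            if spec.name == name:
                return spec
        raise SchemaError(f"unknown covariate {name!r}")

    def subgroup_levels(self) -> tuple[str, ...]:
        if self.subgroup is None:
            raise SchemaError("dataset has no subgroup column")
        return tuple(dict.fromkeys(self.data[self.subgroup].astype(str)))

    def filter_subgroup(self, level: str) -> "CEDataset":
        """Restrict to one subgroup level, keeping the covariate schema."""
        if self.subgroup is None:
            raise SchemaError("dataset has no subgroup column")
        mask = self.data[self.subgroup].astype(str) == str(level)
        if not mask.any():
            raise ValidationError(f"no records in subgroup level {level!r}")
        sub = self.data.loc[mask].reset_index(drop=True)
        counts = sub["tx"].value_counts()
        for arm in (0, 1):
            if counts.get(arm, 0) < 2:
                raise ValidationError(
                    f"subgroup level {level!r} has fewer than 2 records in arm tx={arm}"
                )
        return replace(self, data=sub)

    def records(self) -> Iterable[PatientRecord]:
        cov_names = [s.name for s in self.covariates]
        for _, row in self.data.iterrows():
            yield PatientRecord(
                id=str(row["id"]),
                tx=int(row["tx"]),
                cost=float(row["cost"]),
                effect=float(row["effect"]),
                subgroup=(str(row[self.subgroup]) if self.subgroup else None),
                covariates={k: row[k] for k in cov_names},
            )

    def metadata(self) -> dict:
        """JSON-serializable dataset description (n per arm, schema, units)."""
        return {
            "n": self.n,
            "n_per_arm": {str(k): v for k, v in self.n_per_arm.items()},
            "subgroup": self.subgroup,
            "subgroup_levels": list(self.subgroup_levels()) if self.subgroup else None,
            "covariates": [
                {"name": s.name, "kind": s.kind,
                 "levels": list(s.levels) if s.levels else None}
                for s in self.covariates
            ],
            "cost_unit": self.cost_unit,
            "effect_unit": self.effect_unit,
        }


def _infer_spec(name: str, values: pd.Series) -> CovariateSpec:
    if pd.api.types.is_numeric_dtype(values):
        return CovariateSpec(name, "numeric")
    levels = tuple(dict.fromkeys(values.astype(str)))
    return CovariateSpec(name, "categorical", levels)


# -- delimited-text I/O ----------------------------------------------------

def read_ce_csv(
    path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
    covariates: Sequence[str] = (),
    covariate_types: Mapping[str, str] | None = None,
    subgroup: str | None = None,
    allow_negative_cost: bool = False,
) -> CEDataset:
    """Read a person-level cost-effectiveness CSV.

    Parameters
    ----------
    schema
        Mapping from canonical names (``tx``, ``cost``, ``effect``,
        optionally ``id``) to the file's column names. Unmapped canonical
        names default to themselves.
    covariates
        File column names to carry as covariates; types are inferred
        (numeric dtype -> numeric, otherwise categorical with
        first-appearance level order) unless overridden in
        ``covariate_types``.
    subgroup
        File column name holding the subgroup label.

    Raises
    ------
    SchemaError
        A mapped column does not exist in the file.
    ParseError
        A cost/effect cell is empty or non-numeric (reports the 1-based
        data row).
    ValidationError
        A dataset invariant fails (tx outside {0,1}, arm counts, ...).
    """
    mapping = {k: k for k in ("id",) + REQUIRED_COLUMNS}
    if schema:
        mapping.update(schema)

    raw = pd.read_csv(path, sep=delimiter, dtype=object, keep_default_na=True)
    for canon in REQUIRED_COLUMNS:
        if mapping[canon] not in raw.columns:
            raise SchemaError(
                f"column {mapping[canon]!r} (mapped to {canon!r}) not found in {path}"
            )
    for col in list(covariates) + ([subgroup] if subgroup else []):
        if col not in raw.columns:
            raise SchemaError(f"column {col!r} not found in {path}")

    out = pd.DataFrame(index=raw.index)
    if mapping["id"] in raw.columns:
        out["id"] = raw[mapping["id"]].astype(str)
    else:
        out["id"] = [str(i + 1) for i in range(len(raw))]

    for canon in ("cost", "effect"):
        col = raw[mapping[canon]]
        # to_numeric only flags unparseable cells; astype(float) does the
        # actual conversion because it is correctly rounded (round-trip exact)
        bad = pd.to_numeric(col, errors="coerce").isna()
        if bad.any():
            row = int(bad.index[bad][0]) + 1
            cell = col.iloc[row - 1]
            what = "empty" if pd.isna(cell) else f"non-numeric value {cell!r}"
            raise ParseError(f"{canon} column, data row {row}: {what}")
        out[canon] = col.astype(float)

    tx_parsed = pd.to_numeric(raw[mapping["tx"]], errors="coerce")
    if tx_parsed.isna().any():
        row = int(tx_parsed.index[tx_parsed.isna()][0]) + 1
        raise ParseError(f"tx column, data row {row}: non-numeric value")
    out["tx"] = tx_parsed
    if not set(np.unique(tx_parsed)).issubset({0, 1}):
        bad_vals = sorted(set(tx_parsed.unique()) - {0, 1})
        raise ValidationError(f"tx must be 0 or 1; found {bad_vals}")
    out["tx"] = out["tx"].astype(int)

    sub_name = None
    if subgroup:
        out["subgroup"] = raw[subgroup].astype(str)
        sub_name = "subgroup"

    specs: list[CovariateSpec] = []
    for name in covariates:
        col = raw[name]
        declared = (covariate_types or {}).get(name)
        bad = pd.to_numeric(col, errors="coerce").isna()
        if declared == "numeric" or (declared is None and not bad.any()):
            if bad.any():
                row = int(bad.index[bad][0]) + 1
                raise ParseError(f"covariate {name!r}, data row {row}: non-numeric value")
            out[name] = col.astype(float)
            specs.append(CovariateSpec(name, "numeric"))
        else:
            if col.isna().any():
                row = int(col.index[col.isna()][0]) + 1
                raise ParseError(f"covariate {name!r}, data row {row}: empty cell")
            out[name] = col.astype(str)
            specs.append(_infer_spec(name, out[name]))

    return CEDataset(
        out,
        covariates=tuple(specs),
        subgroup=sub_name,
        allow_negative_cost=allow_negative_cost,
    )


def write_ce_csv(ds: CEDataset, path, delimiter: str = ",") -> None:
    """Write a dataset back to CSV at full float precision (round-trip safe)."""
    # repr() emits the shortest decimal string that reparses to the same double
    ds.data.to_csv(
        path, sep=delimiter, index=False, float_format=lambda v: repr(float(v))
    )


def arm_summaries(ds: CEDataset) -> pd.DataFrame:
    """Per-arm counts and arithmetic means of cost and effect.

    Returns a frame indexed by ``tx`` (0 = usual care, 1 = new treatment)
    with columns ``n``, ``mean_cost`` and ``mean_effect``. These are the
    average cost and average effect whose between-arm differences the
    unadjusted regressions reproduce.
    """
    rows = []
    for arm in (0, 1):
        mask = ds.tx == arm
        rows.append(
            {
                "tx": arm,
                "n": int(mask.sum()),
                "mean_cost": float(np.mean(ds.cost[mask])),
                "mean_effect": float(np.mean(ds.effect[mask])),
            }
        )
    return pd.DataFrame(rows).set_index("tx")


def export_metadata_json(ds: CEDataset, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ds.metadata(), fh, indent=2)


def _fsum_mean(values: Iterable[float]) -> float:
    """Compensated-summation mean (exposed for oracle checks)."""
    vals = list(values)
    return math.fsum(vals) / len(vals)
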