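"""CSV readers, schema validation, and report writers.

All tabular interchange is UTF-8 RFC-4180 CSV with a header row and dot
decimals. Validation collects every violation with its row number; the
pipeline refuses to run on errors and proceeds on warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

from .aggregation import DoseLedger, SurveyDesign
from .costing_core import (
    Activity,
    CapitalAsset,
    Context,
    CostingError,
    CostLineItem,
    CostType,
    Currency,
    Level,
    MonetaryAmount,
    activities_for,
)

__all__ = [
    "ValidationReport",
    "read_line_items",
    "read_capital",
    "read_dose_ledger",
    "read_design",
    "read_hr",
    "validate_line_items",
    "validate_capital",
    "validate_dose_ledger",
    "validate_design",
    "validate_study_dir",
    "round_usd",
]

LINE_ITEM_COLUMNS = [
    "unit_id", "level", "context", "activity", "cost_type",
    "quantity", "unit_cost_mwk", "opportunity_flag",
]
CAPITAL_COLUMNS = ["unit_id", "description", "price_mwk", "useful_life_years"]
DOSE_COLUMNS = ["unit_id", "intervention", "doses"]
DESIGN_COLUMNS = ["unit_id", "level", "stratum", "weight"]


def round_usd(value: float) -> float:
    """Round to cents, half-up — the reporting convention for all dollars."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class ValidationReport:
    """Schema violations (errors) and advisories (warnings), with row numbers."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def extend(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)

    def raise_on_errors(self) -> None:
        if self.errors:
            raise CostingError(
                "input validation failed:\n" + "\n".join(self.errors)
            )


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CostingError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CostingError(f"{path}: missing required columns {missing}")
    return df


def validate_line_items(df: pd.DataFrame) -> ValidationReport:
    report = ValidationReport()
    activities = {a.value for a in Activity}
    cost_types = {c.value for c in CostType}
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header line
        if row["activity"] not in activities:
            report.errors.append(f"line_items row {rowno}: unknown activity {row['activity']!r}")
            continue
        if row["cost_type"] not in cost_types:
            report.errors.append(f"line_items row {rowno}: unknown cost type {row['cost_type']!r}")
            continue
        try:
            context = Context(row["context"])
        except ValueError:
            report.errors.append(f"line_items row {rowno}: unknown context {row['context']!r}")
            continue
        if Activity(row["activity"]) not in activities_for(context):
            report.errors.append(
                f"line_items row {rowno}: activity {row['activity']!r} not "
                f"applicable in {context.value} context"
            )
        try:
            Level(row["level"])
        except ValueError:
            report.errors.append(f"line_items row {rowno}: unknown level {row['level']!r}")
        q = pd.to_numeric(row["quantity"], errors="coerce")
        c = pd.to_numeric(row["unit_cost_mwk"], errors="coerce")
        if pd.isna(q) or q < 0:
            report.errors.append(f"line_items row {rowno}: invalid quantity {row['quantity']!r}")
        if pd.isna(c) or c < 0:
            report.errors.append(f"line_items row {rowno}: invalid unit cost {row['unit_cost_mwk']!r}")
    return report


def validate_capital(df: pd.DataFrame) -> ValidationReport:
    report = ValidationReport()
    for i, row in df.iterrows():
        rowno = i + 2
        p = pd.to_numeric(row["price_mwk"], errors="coerce")
        l = pd.to_numeric(row["useful_life_years"], errors="coerce")
        if pd.isna(p) or p < 0:
            report.errors.append(f"capital row {rowno}: invalid price {row['price_mwk']!r}")
        if pd.isna(l) or l < 1:
            report.errors.append(
                f"capital row {rowno}: useful life must be >= 1 year, "
                f"got {row['useful_life_years']!r}"
            )
    return report


def validate_dose_ledger(df: pd.DataFrame) -> ValidationReport:
    report = ValidationReport()
    doses = pd.to_numeric(df["doses"], errors="coerce")
    for i in df.index[doses.isna() | (doses < 0)]:
        report.errors.append(f"doses row {i + 2}: invalid doses {df.loc[i, 'doses']!r}")
    zero_units = df.loc[doses.fillna(0) >= 0].groupby("unit_id")["doses"].sum()
    for uid in zero_units.index[zero_units == 0]:
        report.warnings.append(f"unit {uid!r} has zero total doses; excluded from per-dose estimates")
    return report


def validate_design(df: pd.DataFrame) -> ValidationReport:
    report = ValidationReport()
    w = pd.to_numeric(df["weight"], errors="coerce")
    for i in df.index[w.isna() | (w <= 0)]:
        report.errors.append(f"design row {i + 2}: weight must be > 0, got {df.loc[i, 'weight']!r}")
    for uid in df.loc[df["unit_id"].duplicated(), "unit_id"]:
        report.errors.append(f"design: duplicate unit {uid!r}")
    return report


def read_line_items(path: str | Path) -> list[CostLineItem]:
    """Read and validate a line-item CSV into typed records."""
    df = _read_csv(path, LINE_ITEM_COLUMNS)
    validate_line_items(df).raise_on_errors()
    items = []
    for _, row in df.iterrows():
        items.append(
            CostLineItem(
                unit_id=str(row["unit_id"]),
                level=Level(row["level"]),
                context=Context(row["context"]),
                activity=Activity(row["activity"]),
                cost_type=CostType(row["cost_type"]),
                quantity=float(row["quantity"]),
                unit_cost=MonetaryAmount(float(row["unit_cost_mwk"]), Currency.MWK),
                opportunity_flag=bool(row["opportunity_flag"]),
            )
        )
    return items


def read_capital(path: str | Path, discount_rate: float = 0.03) -> list[CapitalAsset]:
    df = _read_csv(path, CAPITAL_COLUMNS)
    validate_capital(df).raise_on_errors()
    return [
        CapitalAsset(
            unit_id=str(row["unit_id"]),
            description=str(row["description"]),
            price=MonetaryAmount(float(row["price_mwk"]), Currency.MWK),
            useful_life_years=int(row["useful_life_years"]),
            discount_rate=discount_rate,
        )
        for _, row in df.iterrows()
    ]


def read_dose_ledger(path: str | Path) -> DoseLedger:
    df = _read_csv(path, DOSE_COLUMNS)
    validate_dose_ledger(df).raise_on_errors()
    return DoseLedger(df)


def read_design(path: str | Path) -> SurveyDesign:
    df = _read_csv(path, DESIGN_COLUMNS)
    validate_design(df).raise_on_errors()
    return SurveyDesign(df)


def read_hr(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ["unit_id", "persons", "hired", "overtime_hours"])


def validate_study_dir(directory: str | Path) -> ValidationReport:
    """Validate a generated/collected study directory without computing."""
    directory = Path(directory)
    report = ValidationReport()
    checks = [
        ("line_items.csv", LINE_ITEM_COLUMNS, validate_line_items),
        ("capital.csv", CAPITAL_COLUMNS, validate_capital),
        ("doses.csv", DOSE_COLUMNS, validate_dose_ledger),
        ("design.csv", DESIGN_COLUMNS, validate_design),
    ]
    for name, columns, validator in checks:
        path = directory / name
        if not path.exists():
            if name == "capital.csv":
                report.warnings.append(f"{name} absent; no capital costs included")
                continue
            report.errors.append(f"missing input file: {path}")
            continue
        try:
            df = _read_csv(path, columns)
        except CostingError as exc:
            report.errors.append(str(exc))
            continue
        report.extend(validator(df))
    return report
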