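"""End-to-end orchestration: inputs -> matrices -> estimates -> report tables.

``run_campaign_analysis`` reproduces the integrated-campaign tables
(per-level cost matrices, dose totals, per-dose costs with design-weighted
CIs, and the combined all-levels estimate). ``run_routine_analysis``
produces the routine TCV delivery cost via dose-/volume-proportional
allocation, and ``run_scenarios`` the standalone-campaign scenarios.

Reported dollar values are rounded half-up to cents only in the report
tables; combination happens on unrounded values (required to reproduce
published cross-footing exactly).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as cio
from .aggregation import (
    DoseLedger,
    LevelEstimate,
    SurveyDesign,
    combine_levels,
    dose_totals,
    hr_burden_summary,
    level_cost_per_dose,
)
from .config import AnalysisConfig
from .costing_core import (
    CapitalAsset,
    Context,
    CostBasis,
    CostingError,
    CostLineItem,
    CostMatrix,
    Level,
    unit_cost_matrix,
)
from .routine_allocation import routine_tcv_level_estimate
from .scenario_engine import (
    ScenarioSpec,
    compute_shares,
    named_scenarios,
    scenario_cost_per_dose,
)

__all__ = [
    "StudyInputs",
    "CampaignResult",
    "RoutineResult",
    "load_study_dir",
    "build_unit_matrices",
    "run_campaign_analysis",
    "run_routine_analysis",
    "run_scenarios",
]

logger = logging.getLogger(__name__)

_CAMPAIGN_LEVELS = (Level.FACILITY, Level.DISTRICT, Level.NATIONAL)
_ROUTINE_LEVELS = (Level.FACILITY, Level.DISTRICT, Level.ZONE, Level.NATIONAL)


@dataclass
class StudyInputs:
    """Validated in-memory inputs for one program context."""

    context: Context
    line_items: list[CostLineItem]
    assets: list[CapitalAsset]
    ledger: DoseLedger
    design: SurveyDesign
    hr: pd.DataFrame | None = None


def load_study_dir(
    directory: str | Path, config: AnalysisConfig | None = None
) -> StudyInputs:
    """Load a study directory (the CSV schemas written by the generator)."""
    config = config or AnalysisConfig()
    directory = Path(directory)
    report = cio.validate_study_dir(directory)
    report.raise_on_errors()
    for message in report.warnings:
        logger.warning(message)
    items = cio.read_line_items(directory / "line_items.csv")
    assets = (
        cio.read_capital(directory / "capital.csv", config.discount_rate)
        if (directory / "capital.csv").exists()
        else []
    )
    ledger = cio.read_dose_ledger(directory / "doses.csv")
    design = cio.read_design(directory / "design.csv")
    hr = cio.read_hr(directory / "hr.csv") if (directory / "hr.csv").exists() else None
    contexts = {it.context for it in items}
    if len(contexts) != 1:
        raise CostingError(f"line items span contexts: {sorted(c.value for c in contexts)}")
    return StudyInputs(contexts.pop(), items, assets, ledger, design, hr)


def build_unit_matrices(
    inputs: StudyInputs, config: AnalysisConfig
) -> dict[Level, dict[str, CostMatrix]]:
    """One cost matrix per unit, grouped by level.

    Campaign capital is apportioned by ``campaign_capital_fraction``; a
    routine year carries the full annual equivalent.
    """
    fraction = (
        config.campaign_capital_fraction
        if inputs.context is Context.CAMPAIGN
        else 1.0
    )
    by_unit: dict[str, list[CostLineItem]] = defaultdict(list)
    level_of: dict[str, Level] = {}
    for it in inputs.line_items:
        by_unit[it.unit_id].append(it)
        level_of[it.unit_id] = it.level
    assets_of: dict[str, list[CapitalAsset]] = defaultdict(list)
    for asset in inputs.assets:
        assets_of[asset.unit_id].append(asset)

    matrices: dict[Level, dict[str, CostMatrix]] = defaultdict(dict)
    for uid, items in by_unit.items():
        matrix = unit_cost_matrix(
            items,
            assets_of.get(uid, ()),
            exchange_rate=config.exchange_rate_mwk_per_usd,
            capital_period_fraction=fraction,
        )
        matrices[level_of[uid]][uid] = matrix
    return dict(matrices)


def _estimates_frame(
    per_level: Mapping[CostBasis, Mapping[Level, LevelEstimate]],
    combined: Mapping[CostBasis, LevelEstimate],
) -> pd.DataFrame:
    rows = []
    for basis, levels in per_level.items():
        for level, e in levels.items():
            rows.append({
                "level": level.value,
                "basis": basis.value,
                "n_units": e.n_units,
                "mean_cost_usd": cio.round_usd(e.mean_cost),
                "mean_doses": e.mean_doses,
                "cost_per_dose_usd": cio.round_usd(e.cost_per_dose),
                "ci_low_usd": None if e.ci_low is None else cio.round_usd(e.ci_low),
                "ci_high_usd": None if e.ci_high is None else cio.round_usd(e.ci_high),
            })
    for basis, e in combined.items():
        rows.append({
            "level": "all_levels",
            "basis": basis.value,
            "n_units": e.n_units,
            "mean_cost_usd": None,
            "mean_doses": None,
            "cost_per_dose_usd": cio.round_usd(e.cost_per_dose),
            "ci_low_usd": None if e.ci_low is None else cio.round_usd(e.ci_low),
            "ci_high_usd": None if e.ci_high is None else cio.round_usd(e.ci_high),
        })
    return pd.DataFrame(rows)


def _level_matrix_sum(matrices: Mapping[str, CostMatrix]) -> CostMatrix:
    out = None
    for m in matrices.values():
        out = m if out is None else out + m
    return out


def _shares_frame(
    matrices_by_level: Mapping[Level, Mapping[str, CostMatrix]]
) -> pd.DataFrame:
    """Activity and cost-type shares of total cost per level and basis."""
    rows = []
    for level, matrices in matrices_by_level.items():
        total = _level_matrix_sum(matrices)
        for basis in CostBasis:
            for kind, shares in (
                ("activity", total.activity_shares(basis)),
                ("cost_type", total.cost_type_shares(basis)),
            ):
                for code, share in shares.items():
                    rows.append({
                        "level": level.value,
                        "basis": basis.value,
                        "dimension": kind,
                        "code": code,
                        "share": float(share),
                    })
    return pd.DataFrame(rows)


@dataclass
class CampaignResult:
    matrices_by_level: dict[Level, dict[str, CostMatrix]]
    level_estimates: dict[CostBasis, dict[Level, LevelEstimate]]
    combined: dict[CostBasis, LevelEstimate]
    dose_table: pd.DataFrame
    shares: pd.DataFrame
    hr_summary: pd.Series | None
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "campaign_cost_per_dose.csv", index=False)
        self.dose_table.to_csv(outdir / "campaign_doses.csv")
        self.shares.to_csv(outdir / "campaign_cost_shares.csv", index=False)
        for level, matrices in self.matrices_by_level.items():
            total = _level_matrix_sum(matrices)
            for basis in CostBasis:
                total.grid(basis).to_csv(
                    outdir / f"campaign_matrix_{level.value}_{basis.value}.csv"
                )
        if self.hr_summary is not None:
            self.hr_summary.to_frame("value").to_csv(outdir / "campaign_hr_summary.csv")


def run_campaign_analysis(
    inputs: StudyInputs, config: AnalysisConfig | None = None
) -> CampaignResult:
    """Integrated-campaign analysis: per-level and combined cost per dose."""
    config = config or AnalysisConfig()
    if inputs.context is not Context.CAMPAIGN:
        raise CostingError("campaign analysis requires campaign-context inputs")
    matrices_by_level = build_unit_matrices(inputs, config)

    level_estimates: dict[CostBasis, dict[Level, LevelEstimate]] = {}
    combined: dict[CostBasis, LevelEstimate] = {}
    for basis in CostBasis:
        per_level = {}
        for level in _CAMPAIGN_LEVELS:
            if level not in matrices_by_level:
                logger.warning("no %s-level records; partial report", level.value)
                continue
            matrices = matrices_by_level[level]
            per_level[level] = level_cost_per_dose(
                matrices,
                inputs.ledger.subset(matrices.keys()),
                inputs.design,
                level,
                basis,
                config.ci_confidence,
            )
        level_estimates[basis] = per_level
        combined[basis] = combine_levels(
            list(per_level.values()), method=config.combine_ci_method
        )

    hr = hr_burden_summary(inputs.hr) if inputs.hr is not None else None
    result = CampaignResult(
        matrices_by_level=matrices_by_level,
        level_estimates=level_estimates,
        combined=combined,
        dose_table=dose_totals(inputs.ledger),
        shares=_shares_frame(matrices_by_level),
        hr_summary=hr,
    )
    result.summary = _estimates_frame(level_estimates, combined)
    return result


@dataclass
class RoutineResult:
    matrices_by_level: dict[Level, dict[str, CostMatrix]]
    level_estimates: dict[CostBasis, dict[Level, LevelEstimate]]
    combined: dict[CostBasis, LevelEstimate]
    shares: pd.DataFrame
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "routine_tcv_cost_per_dose.csv", index=False)
        self.shares.to_csv(outdir / "routine_cost_shares.csv", index=False)
        for level, matrices in self.matrices_by_level.items():
            total = _level_matrix_sum(matrices)
            for basis in CostBasis:
                total.grid(basis).to_csv(
                    outdir / f"routine_matrix_{level.value}_{basis.value}.csv"
                )


def run_routine_analysis(
    inputs: StudyInputs, config: AnalysisConfig | None = None
) -> RoutineResult:
    """Routine TCV delivery cost per dose via activity-based allocation."""
    config = config or AnalysisConfig()
    if inputs.context is not Context.ROUTINE:
        raise CostingError("routine analysis requires routine-context inputs")
    tcv = config.tcv  # fails fast when no TCV presentation is configured
    matrices_by_level = build_unit_matrices(inputs, config)

    level_estimates: dict[CostBasis, dict[Level, LevelEstimate]] = {}
    combined: dict[CostBasis, LevelEstimate] = {}
    for basis in CostBasis:
        per_level = {}
        for level in _ROUTINE_LEVELS:
            if level not in matrices_by_level:
                logger.warning("no %s-level records; partial report", level.value)
                continue
            matrices = matrices_by_level[level]
            for cost_type, mode in config.allocation_rules.items():
                logger.info(
                    "allocation rule: %s -> %s", cost_type.value, mode
                )
            per_level[level] = routine_tcv_level_estimate(
                matrices,
                inputs.ledger.subset(matrices.keys()),
                inputs.design,
                level,
                basis,
                tcv,
                config.allocation_rules,
                config.volumes,
                config.ci_confidence,
            )
        level_estimates[basis] = per_level
        combined[basis] = combine_levels(
            list(per_level.values()), method=config.combine_ci_method
        )

    result = RoutineResult(
        matrices_by_level=matrices_by_level,
        level_estimates=level_estimates,
        combined=combined,
        shares=_shares_frame(matrices_by_level),
    )
    result.summary = _estimates_frame(level_estimates, combined)
    return result


def run_scenarios(
    inputs: StudyInputs,
    config: AnalysisConfig | None = None,
    specs: Sequence[ScenarioSpec] | None = None,
) -> pd.DataFrame:
    """Standalone-TCV scenario estimates from campaign inputs.

    Returns one row per (scenario, basis) with the combined per-dose cost
    and interval, computed by rescaling each sampled unit's matrix and
    re-running the weighted estimator with TCV doses as the denominator.
    """
    config = config or AnalysisConfig()
    if inputs.context is not Context.CAMPAIGN:
        raise CostingError("scenario analysis requires campaign-context inputs")
    if specs is None:
        specs = list(named_scenarios().values())
    matrices_by_level = build_unit_matrices(inputs, config)
    national_ledger = DoseLedger(
        inputs.ledger.records[
            inputs.ledger.records["unit_id"].isin(
                matrices_by_level.get(Level.NATIONAL, {}).keys()
            )
        ]
    ) if Level.NATIONAL in matrices_by_level else inputs.ledger
    shares = compute_shares(national_ledger, config.volumes, config.tcv_code)
    logger.info(
        "TCV shares: %.4f of doses, %.4f of packed volume",
        shares.dose_share, shares.volume_share,
    )

    rows = []
    for spec in specs:
        for basis in CostBasis:
            for activity, rule in spec.rules.items():
                logger.info(
                    "scenario %s: %s -> %s(%.4f)",
                    spec.name, activity.value, rule.kind, rule.factor(shares),
                )
            _, combined_estimate = scenario_cost_per_dose(
                matrices_by_level,
                inputs.ledger,
                inputs.design,
                spec,
                shares,
                basis,
                config.tcv_code,
                config.ci_confidence,
                config.combine_ci_method,
            )
            rows.append({
                "scenario": spec.name,
                "basis": basis.value,
                "cost_per_dose_usd": cio.round_usd(combined_estimate.cost_per_dose),
                "ci_low_usd": None
                if combined_estimate.ci_low is None
                else cio.round_usd(combined_estimate.ci_low),
                "ci_high_usd": None
                if combined_estimate.ci_high is None
                else cio.round_usd(combined_estimate.ci_high),
                "dose_share": shares.dose_share,
                "volume_share": shares.volume_share,
            })
    return pd.DataFrame(rows)
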