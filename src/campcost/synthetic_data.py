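"""Synthetic campaign and routine datasets with the study's structure.

No unit-level data from the Malawi costing study are deposited, so this
module generates coherent stand-in bundles: 50 sampled facilities in 10
districts in 3 zones plus a national unit, four campaign interventions
(TCV, MRV, bOPV, vitamin A) at published dose magnitudes, line items with
activity/cost-type composition mirroring the published cost structure,
capital registers, size-proxy survey designs, and workforce records.

Generator defaults are calibrated to the published means (facility
financial $301 / economic $7,601; district $219,417 / $224,898; national
$2,155,830 / $2,180,366; dose means 13,347/5,428/5,749/5,153 per facility,
etc.). Dispersion is not published; costs are log-normal (right-skewed,
strictly positive) and doses negative-binomial, with dispersion set once
on realism grounds (see docs/methods.md). Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import SurveyDesign
from .costing_core import (
    DEFAULT_EXCHANGE_RATE,
    Activity,
    Context,
    CostBasis,
    CostingError,
    CostType,
    Level,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticStudy",
    "generate_campaign",
    "generate_routine",
    "sample_design",
    "expected_facility_cost_per_dose",
]

logger = logging.getLogger(__name__)

CAMPAIGN_INTERVENTIONS = ("TCV", "MRV", "bOPV", "vitA")

# Activity / cost-type mixtures per (context, level). Each pool (financial,
# opportunity) is spread over the activity mix, then within each activity
# over the cost-type mix. Facility campaign composition mirrors the
# published pattern: service delivery dominant, human resources ~94% of
# economic cost, vaccinator per diem recorded at district level (hence the
# per-diem-heavy district financial mix — a deliberate replication of the
# study's data-collection quirk).
_MIX: dict[tuple[str, str], dict[str, dict[str, float]]] = {
    ("campaign", "facility"): {
        "activity": {
            "service_delivery": 0.40, "social_mobilization": 0.18,
            "record_keeping": 0.17, "training": 0.08, "management": 0.05,
            "supervision": 0.05, "distribution_storage": 0.04,
            "waste_management": 0.02, "aefi_management": 0.01,
        },
        "financial": {
            "supplies": 0.30, "printing_stationery_comms": 0.25,
            "fuel_maintenance_energy": 0.20, "meetings_events": 0.15,
            "human_resources": 0.10,
        },
        "opportunity": {"human_resources": 0.97, "supplies": 0.03},
    },
    ("campaign", "district"): {
        "activity": {
            "service_delivery": 0.72, "training": 0.18,
            "social_mobilization": 0.04, "management": 0.03,
            "supervision": 0.02, "distribution_storage": 0.01,
        },
        "financial": {
            "per_diem": 0.69, "meetings_events": 0.08,
            "fuel_maintenance_energy": 0.06, "vehicle_rental_transport": 0.06,
            "printing_stationery_comms": 0.05, "supplies": 0.04,
            "human_resources": 0.02,
        },
        "opportunity": {"human_resources": 1.0},
    },
    ("campaign", "national"): {
        "activity": {
            "management": 0.32, "training": 0.20, "social_mobilization": 0.15,
            "distribution_storage": 0.12, "supervision": 0.08,
            "service_delivery": 0.05, "record_keeping": 0.04,
            "waste_management": 0.02, "aefi_management": 0.02,
        },
        "financial": {
            "per_diem": 0.35, "printing_stationery_comms": 0.25,
            "meetings_events": 0.22, "vehicle_rental_transport": 0.08,
            "fuel_maintenance_energy": 0.05, "supplies": 0.03,
            "human_resources": 0.02,
        },
        "opportunity": {"human_resources": 1.0},
    },
    ("routine", "facility"): {
        "activity": {
            "service_delivery": 0.30, "waste_management": 0.15,
            "distribution_storage": 0.15, "record_keeping": 0.10,
            "management": 0.10, "estimating_demand": 0.05, "training": 0.05,
            "supervision": 0.05, "social_mobilization": 0.05,
        },
        "financial": {
            "human_resources": 0.35, "fuel_maintenance_energy": 0.20,
            "supplies": 0.15, "vehicle_rental_transport": 0.10,
            "printing_stationery_comms": 0.08, "meetings_events": 0.07,
            "per_diem": 0.05,
        },
        "opportunity": {"human_resources": 1.0},
    },
    ("routine", "higher"): {
        "activity": {
            "distribution_storage": 0.40, "management": 0.15,
            "supervision": 0.10, "training": 0.10, "service_delivery": 0.05,
            "estimating_demand": 0.05, "record_keeping": 0.05,
            "social_mobilization": 0.05, "waste_management": 0.05,
        },
        "financial": {
            "human_resources": 0.30, "fuel_maintenance_energy": 0.25,
            "vehicle_rental_transport": 0.15, "supplies": 0.10,
            "printing_stationery_comms": 0.08, "meetings_events": 0.07,
            "per_diem": 0.05,
        },
        "opportunity": {"human_resources": 1.0},
    },
}


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic study.

    Dose and cost means are the published magnitudes; dispersion
    parameters (``cost_sigma`` — SD of log cost; ``dose_dispersion`` —
    negative-binomial size k) are assumptions. Setting ``cost_sigma=0``
    and ``dose_dispersion=None`` makes every unit sit exactly at its mean.
    """

    n_facilities: int = 50
    n_districts: int = 10
    n_zones: int = 3
    population_facilities: int = 800

    # campaign doses per unit (means; national totals are administrative and fixed)
    facility_dose_means: dict[str, float] = field(default_factory=lambda: {
        "TCV": 13347.0, "MRV": 5428.0, "bOPV": 5749.0, "vitA": 5153.0})
    district_dose_means: dict[str, float] = field(default_factory=lambda: {
        "TCV": 326439.0, "MRV": 123885.0, "bOPV": 134219.0, "vitA": 127513.0})
    national_dose_totals: dict[str, float] = field(default_factory=lambda: {
        "TCV": 7043335.0, "MRV": 2646095.0, "bOPV": 2925288.0, "vitA": 2620670.0})

    # campaign cost means, 2020 US$
    campaign_cost_means: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "facility": {"financial": 301.0, "economic": 7601.0},
        "district": {"financial": 219417.0, "economic": 224898.0},
        "national": {"financial": 2155830.0, "economic": 2180366.0},
    })
    # routine cost means, 2020 US$ (annual, 2022-style)
    routine_cost_means: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "facility": {"financial": 7384.0, "economic": 26290.0},
        "district": {"financial": 24962.0, "economic": 53197.0},
        "zone": {"financial": 16796.0, "economic": 49248.0},
        "national": {"financial": 186793.0, "economic": 408502.0},
    })
    # routine annual doses per facility by antigen; higher levels scale by
    # throughput (800 facilities / 29 districts / 5 zones nationally)
    routine_facility_dose_means: dict[str, float] = field(default_factory=lambda: {
        "BCG": 750.0, "bOPV": 3000.0, "PENTA": 2250.0, "PCV": 2250.0,
        "ROTA": 1500.0, "MRV": 1500.0, "TCV": 750.0})
    routine_level_scale: dict[str, float] = field(default_factory=lambda: {
        "facility": 1.0, "district": 27.6, "zone": 160.0, "national": 800.0})
    routine_volumes_cm3: dict[str, float] = field(default_factory=lambda: {
        "BCG": 1.2, "bOPV": 1.0, "PENTA": 2.6, "PCV": 4.8,
        "ROTA": 17.1, "MRV": 3.5, "TCV": 3.0})

    cost_sigma: float = 0.5
    dose_dispersion: float | None = 8.0
    size_proxy_median: float = 400.0
    size_proxy_sigma: float = 0.8

    # workforce burden (facility level)
    persons_mean: float = 77.0
    persons_sigma: float = 0.9
    hired_mean: float = 17.0
    hired_dispersion: float = 0.6
    share_longer_days: float = 0.52
    overtime_mean_hours: float = 1.8

    exchange_rate_mwk_per_usd: float = DEFAULT_EXCHANGE_RATE
    mixtures: dict = field(default_factory=lambda: {k: v for k, v in _MIX.items()})

    def __post_init__(self) -> None:
        if self.n_facilities < 0 or self.n_districts < 1 or self.n_zones < 1:
            raise CostingError("facility/district/zone counts must be positive")
        for pool in (self.facility_dose_means, self.district_dose_means,
                     self.national_dose_totals, self.routine_facility_dose_means):
            if any(v <= 0 for v in pool.values()):
                raise CostingError("dose means must be positive")
        for levels in (self.campaign_cost_means, self.routine_cost_means):
            for level, means in levels.items():
                if means["financial"] <= 0 or means["economic"] < means["financial"]:
                    raise CostingError(
                        f"{level}: need 0 < financial <= economic cost mean"
                    )
        for key, mix in self.mixtures.items():
            for name, weights in mix.items():
                total = sum(weights.values())
                if abs(total - 1.0) > 1e-9:
                    raise CostingError(
                        f"mixture {key}/{name} weights sum to {total}, not 1"
                    )


@dataclass
class SyntheticStudy:
    """One coherent generated bundle for a single program context."""

    context: Context
    line_items: pd.DataFrame
    capital: pd.DataFrame
    doses: pd.DataFrame
    design: pd.DataFrame
    hr: pd.DataFrame | None
    manifest: dict

    def survey_design(self) -> SurveyDesign:
        return SurveyDesign(self.design)

    def to_csv(self, outdir: str | Path) -> None:
        """Write the bundle as the package's CSV schemas plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.line_items.to_csv(outdir / "line_items.csv", index=False)
        self.capital.to_csv(outdir / "capital.csv", index=False)
        self.doses.to_csv(outdir / "doses.csv", index=False)
        self.design.to_csv(outdir / "design.csv", index=False)
        if self.hr is not None:
            self.hr.to_csv(outdir / "hr.csv", index=False)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


def _lognormal_around_mean(
    rng: np.random.Generator, mean: float, sigma: float, size: int
) -> np.ndarray:
    """Log-normal draws with arithmetic mean ``mean``; degenerate at sigma 0."""
    if mean < 0:
        raise CostingError("lognormal mean must be >= 0")
    if sigma <= 0 or mean == 0:
        return np.full(size, float(mean))
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size)


def _negbin_around_mean(
    rng: np.random.Generator, mean: float, k: float | None, size: int
) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and size ``k``.

    ``k=None`` (or <= 0) collapses to the rounded mean exactly — the
    zero-dispersion stated world.
    """
    if k is None or k <= 0:
        return np.full(size, round(mean), dtype=np.int64)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size).astype(np.int64)


def _unit_line_rows(
    unit_id: str,
    level: str,
    context: str,
    fin_total_usd: float,
    opp_total_usd: float,
    mix: Mapping[str, Mapping[str, float]],
    rate: float,
) -> list[dict]:
    rows = []
    for pool_total, pool_mix, flag in (
        (fin_total_usd, mix["financial"], False),
        (opp_total_usd, mix["opportunity"], True),
    ):
        for activity, wa in mix["activity"].items():
            for cost_type, wc in pool_mix.items():
                amount = pool_total * wa * wc
                if amount <= 0:
                    continue
                rows.append({
                    "unit_id": unit_id,
                    "level": level,
                    "context": context,
                    "activity": activity,
                    "cost_type": cost_type,
                    "quantity": 1.0,
                    "unit_cost_mwk": amount * rate,
                    "opportunity_flag": flag,
                })
    return rows


_LINE_COLUMNS = ["unit_id", "level", "context", "activity", "cost_type",
                 "quantity", "unit_cost_mwk", "opportunity_flag"]
_CAPITAL_COLUMNS = ["unit_id", "description", "price_mwk", "useful_life_years"]


def _population_frame(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sampling frame: all facilities with district, zone and size proxy."""
    n = config.population_facilities
    ids = [f"F{i:04d}" for i in range(1, n + 1)]
    district_idx = np.arange(n) % config.n_districts
    districts = [f"D{d + 1:02d}" for d in district_idx]
    zones = [f"Z{(d % config.n_zones) + 1}" for d in district_idx]
    sizes = rng.lognormal(np.log(config.size_proxy_median), config.size_proxy_sigma, n)
    return pd.DataFrame(
        {"unit_id": ids, "district": districts, "zone": zones, "size_proxy": sizes}
    )


def _capped_pps_probabilities(sizes: np.ndarray, n_sample: int) -> np.ndarray:
    """Inclusion probabilities proportional to size, capped at 1.

    pi_i = c * s_i with c chosen so the probabilities sum to n; units
    pushed past 1 are taken with certainty and the remainder rescaled.
    """
    pi = np.zeros(len(sizes))
    free = np.ones(len(sizes), dtype=bool)
    remaining = n_sample
    while True:
        total = sizes[free].sum()
        if remaining <= 0 or total <= 0:
            break
        scale = remaining / total
        capped = free & (sizes * scale >= 1.0)
        if not capped.any():
            pi[free] = sizes[free] * scale
            break
        pi[capped] = 1.0
        free &= ~capped
        remaining = n_sample - int((~free).sum())
    return pi


def sample_design(
    sizes: pd.Series,
    n_sample: int,
    strata: pd.Series | None = None,
    seed: int | None = None,
    level: Level = Level.FACILITY,
) -> SurveyDesign:
    """Stratified size-proportional sample with inverse-probability weights.

    ``sizes`` is the size proxy per population unit (index = unit ids);
    ``strata`` assigns each unit to a stratum (one stratum when omitted).
    The sample size is allocated across strata proportional to stratum
    counts, and within each stratum units are drawn by systematic
    probability-proportional-to-size sampling; the design weight is the
    reciprocal inclusion probability. Units with a zero or missing size
    proxy are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    sizes = pd.Series(sizes, dtype=float)
    bad = sizes.index[(sizes <= 0) | sizes.isna()]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} unit(s) with zero/missing size proxy",
            stacklevel=2,
        )
        sizes = sizes.drop(bad)
    if strata is None:
        strata = pd.Series("all", index=sizes.index)
    strata = pd.Series(strata).reindex(sizes.index)
    if n_sample > len(sizes):
        raise CostingError(f"cannot sample {n_sample} from {len(sizes)} units")

    counts = strata.value_counts().sort_index()
    raw = counts / counts.sum() * n_sample
    alloc = raw.astype(int)
    remainder = (raw - alloc).sort_values(ascending=False)
    for stratum in remainder.index:
        if alloc.sum() >= n_sample:
            break
        if alloc[stratum] < counts[stratum]:
            alloc[stratum] += 1

    rows = []
    for stratum in counts.index:
        n_h = int(alloc[stratum])
        if n_h == 0:
            continue
        members = sizes.index[strata == stratum]
        s = sizes.loc[members].to_numpy()
        pi = _capped_pps_probabilities(s, n_h)
        order = rng.permutation(len(members))
        cum = np.cumsum(pi[order])
        start = rng.uniform(0.0, 1.0)
        points = start + np.arange(n_h)
        picks = np.searchsorted(cum, points, side="right")
        picks = np.clip(picks, 0, len(members) - 1)
        for j in np.unique(picks):
            idx = order[j]
            rows.append({
                "unit_id": members[idx],
                "level": Level(level).value,
                "stratum": str(stratum),
                "weight": 1.0 / pi[idx],
            })
    return SurveyDesign(pd.DataFrame(rows, columns=["unit_id", "level", "stratum", "weight"]))


def _draw_unit_costs(
    rng: np.random.Generator,
    means: Mapping[str, float],
    sigma: float,
    size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit (financial, opportunity) cost totals in US$."""
    fin = _lognormal_around_mean(rng, means["financial"], sigma, size)
    opp = _lognormal_around_mean(
        rng, means["economic"] - means["financial"], sigma, size
    )
    return fin, opp


def generate_campaign(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate one integrated-campaign dataset.

    Produces line items for 50 sampled facilities, 10 districts and the
    national unit; capital registers for districts and the national unit;
    campaign dose ledgers; a size-proxy PPS survey design; and facility
    workforce records. Zones carry no campaign records.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    rate = config.exchange_rate_mwk_per_usd

    frame = _population_frame(config, rng)
    design = sample_design(
        frame.set_index("unit_id")["size_proxy"],
        config.n_facilities,
        frame.set_index("unit_id")["zone"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    facility_ids = design.units["unit_id"].tolist()
    district_ids = [f"D{i + 1:02d}" for i in range(config.n_districts)]

    line_rows: list[dict] = []
    dose_rows: list[dict] = []
    hr_rows: list[dict] = []
    capital_rows: list[dict] = []

    n_fac = len(facility_ids)
    fac_fin, fac_opp = _draw_unit_costs(
        rng, config.campaign_cost_means["facility"], config.cost_sigma, n_fac
    )
    for name, mean in config.facility_dose_means.items():
        draws = _negbin_around_mean(rng, mean, config.dose_dispersion, n_fac)
        for uid, d in zip(facility_ids, draws):
            dose_rows.append({"unit_id": uid, "intervention": name, "doses": int(d)})
    for i, uid in enumerate(facility_ids):
        line_rows += _unit_line_rows(
            uid, "facility", "campaign", fac_fin[i], fac_opp[i],
            config.mixtures[("campaign", "facility")], rate,
        )

    # workforce burden at facilities
    persons = np.maximum(
        1, np.round(_lognormal_around_mean(rng, config.persons_mean, config.persons_sigma, n_fac))
    ).astype(int)
    hired = _negbin_around_mean(rng, config.hired_mean, config.hired_dispersion, n_fac)
    longer = rng.uniform(size=n_fac) < config.share_longer_days
    overtime = np.where(
        longer, rng.gamma(2.0, config.overtime_mean_hours / 2.0, n_fac), 0.0
    )
    for i, uid in enumerate(facility_ids):
        hr_rows.append({
            "unit_id": uid, "persons": int(persons[i]), "hired": int(hired[i]),
            "overtime_hours": float(np.round(overtime[i], 2)),
        })

    dist_fin, dist_opp = _draw_unit_costs(
        rng, config.campaign_cost_means["district"], config.cost_sigma,
        config.n_districts,
    )
    for name, mean in config.district_dose_means.items():
        draws = _negbin_around_mean(rng, mean, config.dose_dispersion, config.n_districts)
        for uid, d in zip(district_ids, draws):
            dose_rows.append({"unit_id": uid, "intervention": name, "doses": int(d)})
    for i, uid in enumerate(district_ids):
        line_rows += _unit_line_rows(
            uid, "district", "campaign", dist_fin[i], dist_opp[i],
            config.mixtures[("campaign", "district")], rate,
        )
        capital_rows.append({
            "unit_id": uid, "description": "supervision vehicle",
            "price_mwk": 15_000_000.0, "useful_life_years": 10,
        })
        capital_rows.append({
            "unit_id": uid, "description": "cold chain equipment",
            "price_mwk": 4_000_000.0, "useful_life_years": 8,
        })

    nat_fin, nat_opp = _draw_unit_costs(
        rng, config.campaign_cost_means["national"], config.cost_sigma, 1
    )
    for name, total in config.national_dose_totals.items():
        dose_rows.append({"unit_id": "NAT", "intervention": name, "doses": int(total)})
    line_rows += _unit_line_rows(
        "NAT", "national", "campaign", nat_fin[0], nat_opp[0],
        config.mixtures[("campaign", "national")], rate,
    )
    capital_rows.append({
        "unit_id": "NAT", "description": "distribution truck",
        "price_mwk": 45_000_000.0, "useful_life_years": 10,
    })
    capital_rows.append({
        "unit_id": "NAT", "description": "central cold room",
        "price_mwk": 30_000_000.0, "useful_life_years": 15,
    })

    design_df = pd.concat(
        [
            design.units,
            pd.DataFrame({
                "unit_id": district_ids + ["NAT"],
                "level": ["district"] * len(district_ids) + ["national"],
                "stratum": "all",
                "weight": 1.0,
            }),
        ],
        ignore_index=True,
    )

    manifest = {"context": "campaign", "seed": seed, "config": asdict(config)}
    manifest["config"]["mixtures"] = {
        f"{k[0]}/{k[1]}": v for k, v in config.mixtures.items()
    }
    return SyntheticStudy(
        context=Context.CAMPAIGN,
        line_items=pd.DataFrame(line_rows, columns=_LINE_COLUMNS),
        capital=pd.DataFrame(capital_rows, columns=_CAPITAL_COLUMNS),
        doses=pd.DataFrame(dose_rows, columns=["unit_id", "intervention", "doses"]),
        design=design_df,
        hr=pd.DataFrame(hr_rows, columns=["unit_id", "persons", "hired", "overtime_hours"]),
        manifest=manifest,
    )


def generate_routine(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate one routine-immunization (annual) dataset across all four levels."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    rate = config.exchange_rate_mwk_per_usd

    frame = _population_frame(config, rng)
    if config.n_facilities > 0:
        design = sample_design(
            frame.set_index("unit_id")["size_proxy"],
            config.n_facilities,
            frame.set_index("unit_id")["zone"],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        facility_ids = design.units["unit_id"].tolist()
        fac_design = design.units
    else:
        facility_ids = []
        fac_design = None

    district_ids = [f"D{i + 1:02d}" for i in range(config.n_districts)]
    zone_ids = [f"Z{i + 1}" for i in range(config.n_zones)]
    units_by_level = {
        "facility": facility_ids,
        "district": district_ids,
        "zone": zone_ids,
        "national": ["NAT"],
    }

    line_rows: list[dict] = []
    dose_rows: list[dict] = []
    capital_rows: list[dict] = []

    capital_catalog = {
        "facility": [("vaccine refrigerator", 2_500_000.0, 10)],
        "district": [("cold chain equipment", 4_000_000.0, 8),
                     ("supervision vehicle", 15_000_000.0, 10)],
        "zone": [("regional cold room", 20_000_000.0, 15),
                 ("distribution vehicle", 18_000_000.0, 10)],
        "national": [("central cold room", 30_000_000.0, 15),
                     ("distribution truck", 45_000_000.0, 10)],
    }

    for level, ids in units_by_level.items():
        if not ids:
            continue
        mix_key = ("routine", "facility" if level == "facility" else "higher")
        fin, opp = _draw_unit_costs(
            rng, config.routine_cost_means[level], config.cost_sigma, len(ids)
        )
        scale = config.routine_level_scale[level]
        for antigen, mean in config.routine_facility_dose_means.items():
            draws = _negbin_around_mean(
                rng, mean * scale, config.dose_dispersion, len(ids)
            )
            for uid, d in zip(ids, draws):
                dose_rows.append({
                    "unit_id": uid, "intervention": antigen, "doses": int(d),
                    "packed_volume_cm3_per_dose": config.routine_volumes_cm3[antigen],
                })
        for i, uid in enumerate(ids):
            line_rows += _unit_line_rows(
                uid, level, "routine", fin[i], opp[i], config.mixtures[mix_key], rate
            )
            for desc, price, life in capital_catalog[level]:
                capital_rows.append({
                    "unit_id": uid, "description": desc,
                    "price_mwk": price, "useful_life_years": life,
                })

    higher_design = pd.DataFrame({
        "unit_id": district_ids + zone_ids + ["NAT"],
        "level": (["district"] * len(district_ids)
                  + ["zone"] * len(zone_ids) + ["national"]),
        "stratum": "all",
        "weight": 1.0,
    })
    design_df = (
        higher_design
        if fac_design is None
        else pd.concat([fac_design, higher_design], ignore_index=True)
    )

    manifest = {"context": "routine", "seed": seed, "config": asdict(config)}
    manifest["config"]["mixtures"] = {
        f"{k[0]}/{k[1]}": v for k, v in config.mixtures.items()
    }
    return SyntheticStudy(
        context=Context.ROUTINE,
        line_items=pd.DataFrame(line_rows, columns=_LINE_COLUMNS),
        capital=pd.DataFrame(capital_rows, columns=_CAPITAL_COLUMNS),
        doses=pd.DataFrame(
            dose_rows,
            columns=["unit_id", "intervention", "doses", "packed_volume_cm3_per_dose"],
        ),
        design=design_df,
        hr=None,
        manifest=manifest,
    )


def expected_facility_cost_per_dose(
    config: GeneratorConfig,
    basis: CostBasis,
    n_mc: int = 200_000,
    seed: int = 12345,
) -> float:
    """Generative target for the facility-level campaign cost per dose.

    The estimand of the facility estimator is E[cost / doses] under the
    generator's marginals (facilities carry no campaign capital, so line
    items determine the totals exactly). Computed by plain Monte-Carlo at
    large n, independent of the pipeline.
    """
    rng = np.random.default_rng(seed)
    means = config.campaign_cost_means["facility"]
    fin = _lognormal_around_mean(rng, means["financial"], config.cost_sigma, n_mc)
    opp = _lognormal_around_mean(
        rng, means["economic"] - means["financial"], config.cost_sigma, n_mc
    )
    doses = np.zeros(n_mc)
    for mean in config.facility_dose_means.values():
        doses += _negbin_around_mean(rng, mean, config.dose_dispersion, n_mc)
    cost = fin if CostBasis(basis) is CostBasis.FINANCIAL else fin + opp
    keep = doses > 0
    return float(np.mean(cost[keep] / doses[keep]))
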