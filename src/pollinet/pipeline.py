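"""End-to-end run: simulate (or load) -> build networks -> specialization ->
partner profiles -> trait comparisons -> recovery report.

Every stage is a pure function of its inputs plus the run config and seed;
all output tables are CSV with a ``# config_hash:`` provenance comment line,
so two runs with the same config produce identical artifact directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pollinet import compare as _compare
from pollinet import networks as _networks
from pollinet import specialization as _spec
from pollinet import traits as _traits
from pollinet.simulate import (
    SimConfig,
    planted_truth_report,
    recovery_by_archetype as _recovery_by_archetype,
    simulate as _simulate_fn,
)
from .datamodel import (
    CensusRecord,
    FlowerSurvey,
    InteractionNetwork,
    SpeciesInfo,
    taxonomy_map,
    write_census,
    write_network,
    write_surveys,
    write_taxonomy,
)

logger = logging.getLogger("pollinet")


@dataclass
class RunConfig:
    """Thresholds and modes for a full pipeline run.

    Defaults follow the reference census design: plants need >= 30 census
    minutes, visitors >= 5 observed individuals, species must appear in >= 2
    monthly networks, and 5 species per guild are selected per category.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    fvr_mode: str = "multiply"
    availability: str = "marginal"  # or "external"
    min_plant_minutes: float = 30.0
    min_visitor_individuals: int = 5
    min_months: int = 2
    category_size: int = 5
    stats_method: str = "mixed_model"
    n_perm: int = 999

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    config: RunConfig
    census: list[CensusRecord]
    surveys: list[FlowerSurvey]
    taxonomy: list[SpeciesInfo]
    truth: dict[str, str]
    season_nets: dict[str, InteractionNetwork]
    monthly_nets: list[InteractionNetwork]
    abundances: dict[tuple[str, int], object]
    specialization: pd.DataFrame
    eligible: pd.DataFrame
    assignments: pd.DataFrame
    profiles: pd.DataFrame
    comparisons: pd.DataFrame
    recovery_table: pd.DataFrame
    recovery_fraction: float
    recovery_by_archetype: dict[str, float]


TRAITS = ("evenness", "mean_rank", "functional_richness")
FACTORS = {"linkage": ("generalized", "specialized"), "selectiveness": ("opportunistic", "selective")}


def build_all_networks(census, surveys, communities, n_months, fvr_mode="multiply"):
    """All monthly snapshots plus the season network per community."""
    season: dict[str, InteractionNetwork] = {}
    monthly: list[InteractionNetwork] = []
    for comm in communities:
        season[comm] = _networks.build_network(
            census, surveys, comm, "season", fvr_mode=fvr_mode
        )
        for m in range(1, n_months + 1):
            try:
                net = _networks.build_network(census, surveys, comm, m, fvr_mode=fvr_mode)
            except ValueError:
                continue
            if net.plants:
                monthly.append(net)
    return season, monthly


def compute_profiles(
    selected: pd.DataFrame,
    monthly_nets: Sequence[InteractionNetwork],
    abundances,
    rankings,
    taxonomy,
) -> pd.DataFrame:
    """Month-resolved partner profiles for every selected species-category.

    A species holding two category labels contributes one profile row per
    label (the comparison designs treat category memberships independently).
    """
    tax = taxonomy_map(taxonomy)
    rows = []
    for sel in selected.drop_duplicates(["species", "community"]).itertuples(index=False):
        cats = selected[
            (selected["species"] == sel.species)
            & (selected["community"] == sel.community)
        ]["category"].tolist()
        for net in monthly_nets:
            if net.community != sel.community:
                continue
            if sel.species not in net.plants and sel.species not in net.visitors:
                continue
            m = net.period_month()
            prof = _traits.partner_profile(
                net, rankings[(net.community, m)][_partner_guild(sel.guild)],
                abundances[(net.community, m)], tax, sel.species,
            )
            for cat in cats:
                rows.append(
                    {
                        "species": prof.species,
                        "guild": prof.guild,
                        "community": prof.community,
                        "month": prof.month_index,
                        "category": cat,
                        "evenness": prof.evenness,
                        "mean_rank": prof.mean_rank,
                        "functional_richness": prof.functional_richness,
                        "n_partners": prof.n_partners,
                    }
                )
    return pd.DataFrame(rows)


def _partner_guild(guild: str) -> str:
    return "plant" if guild == "visitor" else "visitor"


def run_comparisons(profiles: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """The comparison battery: each trait x guild x specialization axis,
    plus month comparisons within each category (the seasonal analysis).

    Visitor functional richness is log transformed in the linkage-axis
    models for a better residual fit, as in the reference analysis.
    """
    frames = []
    for axis, cats in FACTORS.items():
        for guild in ("plant", "visitor"):
            sub = profiles[
                (profiles["guild"] == guild) & (profiles["category"].isin(cats))
            ]
            for trait in TRAITS:
                if sub.empty or sub["category"].nunique() < 2:
                    continue
                transform = (
                    "log"
                    if (trait == "functional_richness" and guild == "visitor" and axis == "linkage")
                    else "none"
                )
                spec = _compare.ComparisonSpec(
                    trait=trait, guild=guild, factor="category", transform=transform
                )
                try:
                    if config.stats_method == "permutation":
                        res = _compare.permutation_compare(
                            sub, spec, n_perm=config.n_perm, seed=config.sim.seed
                        )
                    else:
                        res = _compare.compare_categories(sub, spec)
                except ValueError as exc:
                    logger.warning("comparison %s/%s/%s skipped: %s", axis, guild, trait, exc)
                    continue
                frames.append(
                    _compare.results_frame(
                        res, analysis="categories", axis=axis, guild=guild, trait=trait
                    )
                )
    # seasonal: months within one category
    for cat in ("generalized", "specialized", "opportunistic", "selective"):
        for guild in ("plant", "visitor"):
            sub = profiles[
                (profiles["guild"] == guild) & (profiles["category"] == cat)
            ]
            for trait in TRAITS:
                if sub.empty or sub["month"].nunique() < 2:
                    continue
                spec = _compare.ComparisonSpec(trait=trait, guild=guild, factor="month")
                try:
                    res, letters = _compare.compare_months(sub, spec)
                except ValueError as exc:
                    logger.warning("month comparison %s/%s/%s skipped: %s", cat, guild, trait, exc)
                    continue
                frame = _compare.results_frame(
                    res, analysis="months", axis=cat, guild=guild, trait=trait
                )
                frame["letters"] = json.dumps({str(k): v for k, v in letters.items()})
                frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_all(config: RunConfig | None = None, out_dir: str | Path | None = None) -> RunResult:
    """Execute the whole pipeline; optionally write artifacts to ``out_dir``."""
    config = config or RunConfig()

    logger.info("stage simulate: seed=%d", config.sim.seed)
    sim = _simulate_fn(config.sim)
    logger.info(
        "stage simulate: %d census rows, %d surveys, %d taxa",
        len(sim.census),
        len(sim.surveys),
        len(sim.taxonomy),
    )

    communities = [c.name for c in config.sim.communities]
    season_nets, monthly_nets = build_all_networks(
        sim.census, sim.surveys, communities, config.sim.n_months, config.fvr_mode
    )
    logger.info(
        "stage networks: %d season + %d monthly networks",
        len(season_nets),
        len(monthly_nets),
    )
    for net in season_nets.values():
        _networks.check_connected(net)

    abundances = {}
    rankings = {}
    for comm in communities:
        for m in range(1, config.sim.n_months + 1):
            tab = _networks.abundance_table(sim.census, sim.surveys, comm, m)
            abundances[(comm, m)] = tab
            rankings[(comm, m)] = {
                "plant": _traits.rank_abundances(tab.plants) if tab.plants else {},
                "visitor": _traits.rank_abundances(tab.visitors) if tab.visitors else {},
            }

    spec_frames = []
    elig_frames = []
    assign_frames = []
    for comm in communities:
        net = season_nets[comm]
        table = _spec.species_specialization(net)
        spec_frames.append(table)
        eligible = _spec.apply_filters(
            table,
            sim.census,
            [n for n in monthly_nets if n.community == comm],
            min_plant_minutes=config.min_plant_minutes,
            min_visitor_individuals=config.min_visitor_individuals,
            min_months=config.min_months,
        )
        elig_frames.append(eligible)
        assign_frames.append(
            _spec.select_extremes(eligible, net, k=config.category_size)
        )
    specialization = pd.concat(spec_frames, ignore_index=True)
    eligible = pd.concat(elig_frames, ignore_index=True)
    assignments = pd.concat(assign_frames, ignore_index=True)
    logger.info(
        "stage specialization: %d species scored, %d eligible, %d category memberships",
        len(specialization),
        len(eligible),
        len(assignments),
    )

    profiles = compute_profiles(
        assignments, monthly_nets, abundances, rankings, sim.taxonomy
    )
    logger.info("stage profiles: %d species-month rows", len(profiles))

    comparisons = run_comparisons(profiles, config)
    logger.info("stage comparisons: %d contrasts", len(comparisons))

    visitor_assign = assignments[assignments["guild"] == "visitor"]
    recovery_table, recovery_fraction = planted_truth_report(
        sim.truth, visitor_assign
    )
    rec_by = _recovery_by_archetype(sim.truth, visitor_assign)
    logger.info("stage recovery: fraction=%.3f by archetype=%s", recovery_fraction, rec_by)

    result = RunResult(
        config=config,
        census=sim.census,
        surveys=sim.surveys,
        taxonomy=sim.taxonomy,
        truth=sim.truth,
        season_nets=season_nets,
        monthly_nets=monthly_nets,
        abundances=abundances,
        specialization=specialization,
        eligible=eligible,
        assignments=assignments,
        profiles=profiles,
        comparisons=comparisons,
        recovery_table=recovery_table,
        recovery_fraction=recovery_fraction,
        recovery_by_archetype=rec_by,
    )
    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def write_artifacts(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    h = result.config.config_hash()
    cfg_blob = json.dumps(
        dataclasses.asdict(result.config), sort_keys=True, indent=2, default=str
    )
    (out_dir / "run_config.json").write_text(cfg_blob + "\n")
    write_census(result.census, out_dir / "census.csv")
    write_surveys(result.surveys, out_dir / "surveys.csv")
    write_taxonomy(result.taxonomy, out_dir / "taxonomy.csv")
    _write_csv(
        pd.DataFrame(
            {"species": list(result.truth), "archetype": list(result.truth.values())}
        ),
        out_dir / "truth.csv",
        h,
    )
    nets_dir = out_dir / "networks"
    nets_dir.mkdir(exist_ok=True)
    for comm, net in result.season_nets.items():
        write_network(net, nets_dir / f"{comm}_season.csv")
    for net in result.monthly_nets:
        write_network(
            net, nets_dir / f"{net.community}_month{net.period_month()}.csv"
        )
    _write_csv(result.specialization, out_dir / "specialization.csv", h)
    _write_csv(result.assignments, out_dir / "assignments.csv", h)
    _write_csv(result.profiles, out_dir / "profiles.csv", h)
    _write_csv(result.comparisons, out_dir / "comparisons.csv", h)
    _write_csv(
        result.recovery_table.reset_index(names="archetype"),
        out_dir / "recovery.csv",
        h,
    )
    summary = {
        "config_hash": h,
        "recovery_fraction": result.recovery_fraction,
        "recovery_by_archetype": result.recovery_by_archetype,
        "n_monthly_networks": len(result.monthly_nets),
        "n_season_networks": len(result.season_nets),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
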