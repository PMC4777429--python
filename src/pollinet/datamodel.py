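"""Domain types and plain-text table I/O for flower-visitation census data.

All tables are comma-separated UTF-8 with a header row.  Lines starting with
``#`` are treated as comments (pipeline outputs carry a ``# config_hash:``
provenance line).  Validation is total: every malformed row is reported with
its (1-based, header-exclusive) row number; nothing is silently dropped.

Schemas
-------
census   : community,date,plant,duration_min,flowers_observed,visitor,individuals,flowers_contacted
surveys  : community,date,plant,open_flowers,area_m2
taxonomy : name,guild,group

A census with no visits is retained as a row with visitor = ``NONE`` so that
observation effort (duration, flowers observed) is never lost.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pollinet")

#: Sentinel visitor label for censuses during which no insect visited.
NO_VISITOR = "NONE"

#: The controlled vocabulary of flower-visitor functional groups, defined by
#: insect size and foraging behaviour.  Extensible via the ``groups`` argument
#: of :func:`read_taxonomy`.
DEFAULT_FUNCTIONAL_GROUPS = (
    "large bees",
    "small bees",
    "flies",
    "hoverflies",
    "beetles",
    "wasps",
    "butterflies",
    "true bugs",
    "ants",
    "others",
)

GUILDS = ("plant", "visitor")


class SchemaError(ValueError):
    """A required column is missing or a table is structurally malformed."""


class ValidationError(ValueError):
    """One or more rows violate a domain invariant; message lists the rows."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesInfo:
    """A species label with its guild and taxonomic/functional group.

    ``group`` is a plant family for guild ``plant`` and a functional group
    (from the controlled vocabulary) for guild ``visitor``.
    """

    name: str
    guild: str
    group: str


@dataclass(frozen=True)
class CensusRecord:
    """One timed focal observation of one visitor species on one plant.

    ``month_index`` counts months within the community's season (1-based) and
    is derived from ``date`` and the community's season-start date at read or
    generation time; it is not a stored CSV column.
    """

    community: str
    date: _dt.date
    month_index: int
    plant: str
    duration_min: float
    flowers_observed: int
    visitor: str
    individuals: int
    flowers_contacted: int


@dataclass(frozen=True)
class FlowerSurvey:
    """An open-flower count over a known area on a date.

    ``density`` (flowers per square metre) is ``open_flowers / area_m2``.
    A tightly clustered inflorescence (e.g. an Asteraceae capitulum) counts
    as a single flower; that convention is the data producer's responsibility.
    """

    community: str
    date: _dt.date
    month_index: int
    plant: str
    open_flowers: int
    area_m2: float

    @property
    def density(self) -> float:
        return self.open_flowers / self.area_m2


@dataclass
class InteractionNetwork:
    """Weighted bipartite plant x visitor matrix scoped to a community/period.

    ``weights`` holds flower-visitation rates (or whatever weighting the
    builder used); ``raw`` holds the parallel integer contact-count matrix on
    which the specialization index d' is computed.  Plants are always rows,
    visitors always columns.  ``period`` is ``"season"`` or ``"month:k"``.
    """

    community: str
    period: str
    plants: list[str]
    visitors: list[str]
    weights: np.ndarray
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.plants), len(self.visitors)):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"{len(self.plants)} plants x {len(self.visitors)} visitors"
            )
        if (self.weights < 0).any():
            raise ValueError("interaction weights must be non-negative")
        if self.raw is not None:
            self.raw = np.asarray(self.raw, dtype=float)
            if self.raw.shape != self.weights.shape:
                raise ValueError("raw count matrix shape differs from weights")
            if (self.raw < 0).any():
                raise ValueError("raw contact counts must be non-negative")

    # -- derived marginals --------------------------------------------------
    @property
    def row_totals(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.weights.sum())

    @property
    def basis(self) -> np.ndarray:
        """Matrix used for structural questions (presence, pruning, d')."""
        return self.raw if self.raw is not None else self.weights

    def period_month(self) -> int:
        """Month index of a monthly snapshot (0 for a season network)."""
        if self.period.startswith("month:"):
            return int(self.period.split(":", 1)[1])
        return 0

    def prune(self) -> "InteractionNetwork":
        """Drop rows/columns with no interaction at all.

        A species is kept as soon as it has any positive entry in either the
        raw-count or the weight matrix, so pruning can never remove a species
        with a positive weight.
        """
        present = self.weights > 0
        if self.raw is not None:
            present = present | (self.raw > 0)
        keep_r = present.any(axis=1)
        keep_c = present.any(axis=0)
        if keep_r.all() and keep_c.all():
            return self
        return InteractionNetwork(
            community=self.community,
            period=self.period,
            plants=[p for p, k in zip(self.plants, keep_r) if k],
            visitors=[v for v, k in zip(self.visitors, keep_c) if k],
            weights=self.weights[np.ix_(keep_r, keep_c)],
            raw=None if self.raw is None else self.raw[np.ix_(keep_r, keep_c)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        same_raw = (self.raw is None) == (other.raw is None) and (
            self.raw is None or np.array_equal(self.raw, other.raw)
        )
        return (
            self.community == other.community
            and self.period == other.period
            and self.plants == other.plants
            and self.visitors == other.visitors
            and np.array_equal(self.weights, other.weights)
            and same_raw
        )


@dataclass
class AbundanceTable:
    """Per community-month abundances for both guilds.

    Plants: mean flower density over the month's surveys (flowers / m^2).
    Visitors: total individuals observed visiting flowers in the month's
    censuses — the best visitor-abundance estimate a census design yields.
    """

    community: str
    month_index: int
    plants: dict[str, float] = field(default_factory=dict)
    visitors: dict[str, float] = field(default_factory=dict)

    def for_guild(self, guild: str) -> dict[str, float]:
        if guild == "plant":
            return self.plants
        if guild == "visitor":
            return self.visitors
        raise ValueError(f"unknown guild {guild!r}")


# ---------------------------------------------------------------------------
# month-index assignment
# ---------------------------------------------------------------------------


def month_index_for(
    date: _dt.date, community: str, season_starts: Mapping[str, _dt.date]
) -> int:
    """1-based month within the community's season calendar."""
    start = season_starts[community]
    return (date.year - start.year) * 12 + (date.month - start.month) + 1


def infer_season_starts(df: pd.DataFrame) -> dict[str, _dt.date]:
    """Default season calendar: each community's earliest observed month."""
    starts: dict[str, _dt.date] = {}
    for community, sub in df.groupby("community"):
        d = min(sub["date"])
        starts[str(community)] = _dt.date(d.year, d.month, 1)
    return starts


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_CENSUS_COLUMNS = [
    "community",
    "date",
    "plant",
    "duration_min",
    "flowers_observed",
    "visitor",
    "individuals",
    "flowers_contacted",
]
_SURVEY_COLUMNS = ["community", "date", "plant", "open_flowers", "area_m2"]
_TAXONOMY_COLUMNS = ["name", "guild", "group"]


def _load_table(path, required: Sequence[str], schema: Mapping[str, str] | None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (no header)") from None
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: header only, no data rows", path)
    return df


def _parse_date(value: str) -> _dt.date:
    return _dt.date.fromisoformat(str(value).strip())


def read_census(
    path,
    schema: Mapping[str, str] | None = None,
    season_starts: Mapping[str, _dt.date] | None = None,
) -> list[CensusRecord]:
    """Read and validate a census table.

    ``schema`` optionally maps file column names onto the canonical ones.
    ``season_starts`` maps community -> season start date for month indexing;
    when omitted, each community's earliest census month is used.
    """
    df = _load_table(path, _CENSUS_COLUMNS, schema)
    problems: list[str] = []
    rows: list[dict] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = {
                "community": str(row.community),
                "date": _parse_date(row.date),
                "plant": str(row.plant),
                "duration_min": float(row.duration_min),
                "flowers_observed": int(float(row.flowers_observed)),
                "visitor": str(row.visitor),
                "individuals": int(float(row.individuals)),
                "flowers_contacted": int(float(row.flowers_contacted)),
            }
        except (TypeError, ValueError) as exc:
            problems.append(f"row {idx}: unparseable field ({exc})")
            continue
        if rec["duration_min"] <= 0:
            problems.append(f"row {idx}: duration_min must be > 0")
        if rec["flowers_observed"] < 1:
            problems.append(f"row {idx}: flowers_observed must be >= 1")
        if rec["individuals"] < 0 or rec["flowers_contacted"] < 0:
            problems.append(f"row {idx}: negative count")
        if rec["visitor"] == NO_VISITOR:
            if rec["flowers_contacted"] != 0 or rec["individuals"] != 0:
                problems.append(
                    f"row {idx}: {NO_VISITOR} census must have 0 individuals "
                    "and 0 flowers_contacted"
                )
        elif rec["individuals"] < 1:
            problems.append(f"row {idx}: individuals must be >= 1 for a real visitor")
        rows.append(rec)
    if problems:
        raise ValidationError("census validation failed:\n" + "\n".join(problems))
    if season_starts is None:
        tmp = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["community", "date"])
        season_starts = infer_season_starts(tmp) if rows else {}
    return [
        CensusRecord(month_index=month_index_for(r["date"], r["community"], season_starts), **r)
        for r in rows
    ]


def read_surveys(
    path,
    schema: Mapping[str, str] | None = None,
    season_starts: Mapping[str, _dt.date] | None = None,
) -> list[FlowerSurvey]:
    """Read and validate a flower-density survey table."""
    df = _load_table(path, _SURVEY_COLUMNS, schema)
    problems: list[str] = []
    rows: list[dict] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = {
                "community": str(row.community),
                "date": _parse_date(row.date),
                "plant": str(row.plant),
                "open_flowers": int(float(row.open_flowers)),
                "area_m2": float(row.area_m2),
            }
        except (TypeError, ValueError) as exc:
            problems.append(f"row {idx}: unparseable field ({exc})")
            continue
        if rec["open_flowers"] < 0:
            problems.append(f"row {idx}: open_flowers must be >= 0")
        if not np.isfinite(rec["area_m2"]) or rec["area_m2"] <= 0:
            problems.append(f"row {idx}: area_m2 must be a positive finite area")
        rows.append(rec)
    if problems:
        raise ValidationError("survey validation failed:\n" + "\n".join(problems))
    if season_starts is None:
        tmp = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["community", "date"])
        season_starts = infer_season_starts(tmp) if rows else {}
    return [
        FlowerSurvey(month_index=month_index_for(r["date"], r["community"], season_starts), **r)
        for r in rows
    ]


def read_taxonomy(
    path,
    schema: Mapping[str, str] | None = None,
    groups: Sequence[str] = DEFAULT_FUNCTIONAL_GROUPS,
    strict_groups: bool = True,
) -> list[SpeciesInfo]:
    """Read species -> guild/group assignments.

    With ``strict_groups`` (default) visitor groups must come from the
    controlled functional-group vocabulary; plant families are free-form.
    Species names must be unique within a guild.
    """
    df = _load_table(path, _TAXONOMY_COLUMNS, schema)
    problems: list[str] = []
    seen: set[tuple[str, str]] = set()
    out: list[SpeciesInfo] = []
    vocab = set(groups)
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        name, guild, group = str(row.name), str(row.guild), str(row.group)
        if guild not in GUILDS:
            problems.append(f"row {idx}: unknown guild {guild!r}")
            continue
        if guild == "visitor" and strict_groups and group not in vocab:
            problems.append(
                f"row {idx}: functional group {group!r} not in controlled vocabulary"
            )
        key = (guild, name)
        if key in seen:
            problems.append(f"row {idx}: duplicate species {name!r} within guild {guild!r}")
        seen.add(key)
        out.append(SpeciesInfo(name=name, guild=guild, group=group))
    if problems:
        raise ValidationError("taxonomy validation failed:\n" + "\n".join(problems))
    return out


def taxonomy_map(taxonomy: Iterable[SpeciesInfo]) -> dict[tuple[str, str], str]:
    """(guild, name) -> group lookup."""
    return {(t.guild, t.name): t.group for t in taxonomy}


# ---------------------------------------------------------------------------
# writers (lossless round-trips)
# ---------------------------------------------------------------------------


def _records_frame(records: Iterable, columns: Sequence[str]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=list(columns)) if rows else pd.DataFrame(columns=list(columns))


def write_census(records: Iterable[CensusRecord], path) -> None:
    _records_frame(records, _CENSUS_COLUMNS).to_csv(path, index=False)


def write_surveys(records: Iterable[FlowerSurvey], path) -> None:
    _records_frame(records, _SURVEY_COLUMNS).to_csv(path, index=False)


def write_taxonomy(records: Iterable[SpeciesInfo], path) -> None:
    _records_frame(records, _TAXONOMY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network files
# ---------------------------------------------------------------------------

_NET_MAGIC = "# pollinet-network v1"


def _matrix_block(labels_r, labels_c, mat) -> list[str]:
    lines = ["," + ",".join(labels_c)]
    for name, row in zip(labels_r, mat):
        lines.append(name + "," + ",".join(repr(float(x)) for x in row))
    return lines


def write_network(net: InteractionNetwork, path) -> None:
    """Serialize a network (weights + raw counts) to a commented CSV file."""
    lines = [
        _NET_MAGIC,
        f"# community: {net.community}",
        f"# period: {net.period}",
        "# section: weights",
    ]
    lines += _matrix_block(net.plants, net.visitors, net.weights)
    if net.raw is not None:
        lines.append("# section: raw")
        lines += _matrix_block(net.plants, net.visitors, net.raw)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_matrix(lines: list[str]) -> tuple[list[str], list[str], np.ndarray]:
    header = lines[0].split(",")
    cols = header[1:]
    rows, data = [], []
    for ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != len(cols) + 1:
            raise SchemaError(f"malformed matrix row: {ln!r}")
        rows.append(parts[0])
        try:
            data.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise SchemaError(f"non-numeric weight in row {parts[0]!r}: {exc}") from None
    mat = np.array(data, dtype=float) if data else np.zeros((0, len(cols)))
    return rows, cols, mat


def read_network(path) -> InteractionNetwork:
    """Read a network file; zero rows/columns are pruned with a warning.

    A mismatch between the header community and the ``<community>_`` filename
    convention is reported as a warning only.
    """
    import os

    with open(path, encoding="utf-8") as fh:
        raw_lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not raw_lines or raw_lines[0] != _NET_MAGIC:
        raise SchemaError(f"{path}: not a pollinet network file")
    meta: dict[str, str] = {}
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for ln in raw_lines[1:]:
        if ln.startswith("# section:"):
            current = []
            sections[ln.split(":", 1)[1].strip()] = current
        elif ln.startswith("#"):
            key, _, value = ln[1:].partition(":")
            meta[key.strip()] = value.strip()
        else:
            if current is None:
                raise SchemaError(f"{path}: data outside any section")
            current.append(ln)
    if "weights" not in sections:
        raise SchemaError(f"{path}: missing weights section")
    plants, visitors, weights = _parse_matrix(sections["weights"])
    raw = None
    if "raw" in sections:
        p2, v2, raw = _parse_matrix(sections["raw"])
        if p2 != plants or v2 != visitors:
            raise SchemaError(f"{path}: raw and weight sections disagree on labels")
    community = meta.get("community", "")
    base = os.path.basename(str(path))
    if community and not base.startswith(community):
        logger.warning(
            "%s: header community %r does not match filename convention", path, community
        )
    net = InteractionNetwork(
        community=community,
        period=meta.get("period", "season"),
        plants=plants,
        visitors=visitors,
        weights=weights,
        raw=raw,
    )
    pruned = net.prune()
    if len(pruned.plants) < len(net.plants) or len(pruned.visitors) < len(net.visitors):
        logger.warning("%s: pruned all-zero rows/columns on read", path)
    return pruned
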