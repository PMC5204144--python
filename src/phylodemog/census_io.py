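"""Input/output and selection filters for forest-census data.

Four inputs drive the pipeline:

* a stem-level census table (CSV, one row per stem per census),
* a plot metadata table (CSV),
* a wood-density lookup (CSV, taxon -> g cm^-3),
* a rooted phylogeny with branch lengths (Newick, tips = genera or species).

Dates are carried internally as decimal years; ISO dates in the CSV are
converted on read (interval arithmetic is then a plain difference — the
sub-day error is far below measurement noise). Selection mirrors standard
lowland-moist-forest plot criteria: a minimum annual precipitation, a
maximum elevation, and — for demographic rates only — a minimum total
monitoring period; stems not identified to genus are dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CensusObservation",
    "StemRecord",
    "PlotInfo",
    "FilterConfig",
    "FilterResult",
    "read_inputs",
    "read_census",
    "read_plots",
    "read_wood_density",
    "read_tree",
    "apply_selection_filters",
    "write_census",
    "write_trait_table",
    "write_exclusion_log",
]

CENSUS_COLUMNS = [
    "stem_id", "plot_id", "genus", "species", "growth_form", "census_date",
    "diameter", "pom_height", "alive", "method_tape", "new_pom_diameter",
]
PLOT_COLUMNS = [
    "plot_id", "latitude", "longitude", "elevation", "annual_precip", "E", "area",
]
WD_COLUMNS = ["taxon", "wd"]


@dataclass(frozen=True)
class CensusObservation:
    """One measurement of one stem at one census."""

    date: float  # decimal years
    diameter: float | None  # cm at the current POM; None for a death record
    pom_height: float  # m
    alive: bool
    method_tape: bool = True
    new_pom_diameter: float | None = None  # cm at the new POM, POM-change census only


@dataclass
class StemRecord:
    """One tree or palm with its ordered census observations."""

    stem_id: str
    plot_id: str
    genus: str
    species: str | None
    growth_form: str  # "tree" | "palm"
    observations: list[CensusObservation] = field(default_factory=list)

    def validate(self) -> None:
        if not self.observations:
            raise ValueError(f"stem {self.stem_id}: no observations")
        if self.growth_form not in ("tree", "palm"):
            raise ValueError(f"stem {self.stem_id}: growth_form must be tree|palm")
        dates = [o.date for o in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"stem {self.stem_id}: census dates not strictly increasing")
        dead = False
        for o in self.observations:
            if dead and o.alive:
                raise ValueError(f"stem {self.stem_id}: recorded alive after a dead record")
            if o.alive and (o.diameter is None or o.diameter <= 0):
                raise ValueError(f"stem {self.stem_id}: alive record needs diameter > 0")
            dead = dead or (not o.alive)

    @property
    def alive_observations(self) -> list[CensusObservation]:
        return [o for o in self.observations if o.alive]


@dataclass(frozen=True)
class PlotInfo:
    plot_id: str
    latitude: float
    longitude: float
    elevation: float  # m
    annual_precip: float  # mm yr^-1
    E: float  # dimensionless environmental stress
    area: float  # ha

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"plot {self.plot_id}: area must be > 0")
        if not np.isfinite(self.E):
            raise ValueError(f"plot {self.plot_id}: E must be finite")


def _decimal_year(raw: str, where: str) -> float:
    """Parse a decimal year or ISO date to decimal years."""
    try:
        return float(raw)
    except ValueError:
        pass
    try:
        ts = pd.Timestamp(raw)
    except ValueError as err:
        raise ValueError(f"{where}: unparseable date {raw!r}") from err
    start = pd.Timestamp(year=ts.year, month=1, day=1)
    end = pd.Timestamp(year=ts.year + 1, month=1, day=1)
    return ts.year + (ts - start) / (end - start)


def _parse_bool(raw: str, where: str) -> bool:
    v = raw.strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"{where}: expected a boolean, got {raw!r}")


def _check_header(header, expected, path) -> None:
    if header != expected:
        raise ValueError(f"{path}: header must be {','.join(expected)}")


def read_census(path) -> list[StemRecord]:
    """Read the stem-level census CSV into validated StemRecords."""
    path = Path(path)
    stems: dict[str, StemRecord] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, CENSUS_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:line {lineno}"
            if len(row) != len(CENSUS_COLUMNS):
                raise ValueError(f"{where}: expected {len(CENSUS_COLUMNS)} fields, got {len(row)}")
            rec = dict(zip(CENSUS_COLUMNS, row))
            try:
                alive = _parse_bool(rec["alive"], where)
                obs = CensusObservation(
                    date=_decimal_year(rec["census_date"], where),
                    diameter=float(rec["diameter"]) if rec["diameter"] != "" else None,
                    pom_height=float(rec["pom_height"]) if rec["pom_height"] != "" else 1.3,
                    alive=alive,
                    method_tape=_parse_bool(rec["method_tape"], where) if rec["method_tape"] != "" else True,
                    new_pom_diameter=float(rec["new_pom_diameter"]) if rec["new_pom_diameter"] != "" else None,
                )
            except ValueError as err:
                raise ValueError(f"{where}: malformed row ({err})") from err
            sid = rec["stem_id"]
            if sid == "":
                raise ValueError(f"{where}: empty stem_id")
            if sid not in stems:
                stems[sid] = StemRecord(
                    stem_id=sid,
                    plot_id=rec["plot_id"],
                    genus=rec["genus"].strip(),
                    species=rec["species"].strip() or None,
                    growth_form=rec["growth_form"].strip() or "tree",
                )
            else:
                s = stems[sid]
                if (s.plot_id, s.genus) != (rec["plot_id"], rec["genus"].strip()):
                    raise ValueError(
                        f"{where}: stem {sid} duplicated with conflicting plot/genus identity"
                    )
                if any(abs(o.date - obs.date) < 1e-9 for o in s.observations):
                    raise ValueError(f"{where}: duplicate census date for stem {sid}")
            stems[sid].observations.append(obs)

    for s in stems.values():
        s.observations.sort(key=lambda o: o.date)
        s.validate()
    return list(stems.values())


def read_plots(path) -> dict[str, PlotInfo]:
    path = Path(path)
    plots: dict[str, PlotInfo] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, PLOT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:line {lineno}"
            if len(row) != len(PLOT_COLUMNS):
                raise ValueError(f"{where}: expected {len(PLOT_COLUMNS)} fields")
            rec = dict(zip(PLOT_COLUMNS, row))
            if rec["plot_id"] in plots:
                raise ValueError(f"{where}: duplicate plot_id {rec['plot_id']!r}")
            try:
                plots[rec["plot_id"]] = PlotInfo(
                    plot_id=rec["plot_id"],
                    latitude=float(rec["latitude"]),
                    longitude=float(rec["longitude"]),
                    elevation=float(rec["elevation"]),
                    annual_precip=float(rec["annual_precip"]),
                    E=float(rec["E"]),
                    area=float(rec["area"]),
                )
            except ValueError as err:
                raise ValueError(f"{where}: malformed row ({err})") from err
    return plots


def read_wood_density(path) -> dict[str, float]:
    """Read the taxon -> wood density (g cm^-3) lookup.

    Keys are either binomials ("Genus species") or bare genus names.
    """
    path = Path(path)
    out: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, WD_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:line {lineno}"
            if len(row) != 2:
                raise ValueError(f"{where}: expected 2 fields")
            taxon = row[0].strip()
            try:
                wd = float(row[1])
            except ValueError as err:
                raise ValueError(f"{where}: malformed density ({err})") from err
            if taxon == "" or wd <= 0:
                raise ValueError(f"{where}: taxon must be non-empty and density > 0")
            out[taxon] = wd
    return out


def read_tree(path) -> dendropy.Tree:
    """Parse a Newick phylogeny; requires branch lengths and unique tips."""
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted",
            preserve_underscores=True,
        )
    except NewickReader.NewickReaderDuplicateTaxonError as err:
        raise ValueError(f"duplicate tip label in tree: {err.message}") from err
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip label(s) in tree: {dup}")
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        if nd.edge.length is None or nd.edge.length <= 0:
            raise ValueError("tree has a missing or non-positive branch length")
    return tree


def read_inputs(census_path, plot_path, wd_path, newick_path):
    """Read and cross-validate all four inputs.

    Returns (stems, plots, wood-density map, tree). Every stem must
    reference a known plot.
    """
    stems = read_census(census_path)
    plots = read_plots(plot_path)
    wd = read_wood_density(wd_path)
    tree = read_tree(newick_path)
    unknown = sorted({s.plot_id for s in stems} - set(plots))
    if unknown:
        raise ValueError(f"stems reference unknown plot(s): {unknown}")
    return stems, plots, wd, tree


# ---------------------------------------------------------------------------
# selection filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    precip_min: float = 1300.0  # mm yr^-1
    elev_max: float = 500.0  # m
    min_monitoring_years: float = 2.0  # demographic-rate subset only


@dataclass
class FilterResult:
    stems: list[StemRecord]
    plots: dict[str, PlotInfo]
    demography_plot_ids: set[str]  # plots usable for growth/mortality
    log: pd.DataFrame  # columns: kind, id, reason


def apply_selection_filters(
    stems: list[StemRecord],
    plots: dict[str, PlotInfo],
    config: FilterConfig = FilterConfig(),
) -> FilterResult:
    """Apply plot- and stem-level selection rules.

    Plots outside the precipitation/elevation envelope are removed (with
    their stems); stems with no genus are removed. Plots passing the static
    criteria but monitored for less than ``min_monitoring_years`` stay in
    the size/wood-density set but are excluded from the demographic-rate
    subset (logged with kind ``plot_demography``). The log plus the kept
    sets exactly partition the input.
    """
    log_rows: list[dict] = []
    kept_plots: dict[str, PlotInfo] = {}
    for pid, p in plots.items():
        if p.annual_precip < config.precip_min:
            log_rows.append({"kind": "plot", "id": pid, "reason": "precip"})
        elif p.elevation >= config.elev_max:
            log_rows.append({"kind": "plot", "id": pid, "reason": "elevation"})
        else:
            kept_plots[pid] = p
    if plots and not kept_plots:
        raise ValueError(
            "all plots excluded by the precipitation/elevation filters; "
            "review FilterConfig"
        )

    kept_stems: list[StemRecord] = []
    span: dict[str, list[float]] = {}
    for s in stems:
        if s.plot_id not in kept_plots:
            log_rows.append({"kind": "stem", "id": s.stem_id, "reason": "plot_excluded"})
            continue
        if not s.genus:
            log_rows.append({"kind": "stem", "id": s.stem_id, "reason": "unidentified"})
            continue
        kept_stems.append(s)
        lo, hi = s.observations[0].date, s.observations[-1].date
        if s.plot_id in span:
            span[s.plot_id][0] = min(span[s.plot_id][0], lo)
            span[s.plot_id][1] = max(span[s.plot_id][1], hi)
        else:
            span[s.plot_id] = [lo, hi]

    demog = set()
    for pid in kept_plots:
        lo, hi = span.get(pid, [0.0, 0.0])
        if hi - lo >= config.min_monitoring_years:
            demog.add(pid)
        else:
            log_rows.append({"kind": "plot_demography", "id": pid, "reason": "monitoring"})

    log = pd.DataFrame(log_rows, columns=["kind", "id", "reason"])
    return FilterResult(stems=kept_stems, plots=kept_plots, demography_plot_ids=demog, log=log)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return repr(v)  # shortest round-trippable form
    return str(v)


def write_census(stems: list[StemRecord], path) -> None:
    """Write StemRecords back to the documented census dialect (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CENSUS_COLUMNS)
        for s in stems:
            for o in s.observations:
                w.writerow([
                    s.stem_id, s.plot_id, s.genus, s.species or "", s.growth_form,
                    _fmt(o.date), _fmt(o.diameter), _fmt(o.pom_height),
                    _fmt(o.alive), _fmt(o.method_tape), _fmt(o.new_pom_diameter),
                ])


def write_trait_table(table: pd.DataFrame, path) -> None:
    """Write a genus x trait long table (genus, trait_name, value, se, n_stems, n_species)."""
    cols = ["genus", "trait_name", "value", "se", "n_stems", "n_species"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    table[cols].to_csv(path, index=False)


def write_exclusion_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)
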