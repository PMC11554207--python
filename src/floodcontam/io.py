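"""Survey tables, species registry, and validation.

The data model mirrors a long-term fish-monitoring design: a *sampling unit*
is one gillnetting or seining event at one locality and campaign; catches are
stored one row per (unit, species) with the summed weight of all individuals;
a registry maps each species to its origin (native, non-native, or
unclassified).  Three plain CSV files carry the whole survey:

``units.csv``     ``unit_id,locality,habitat,gear,campaign_date,area_m2``
``catches.csv``   ``unit_id,species_id,n_individuals,total_weight_g``
``registry.csv``  ``species_id,species_name,origin``

Dates are ISO-8601, decimals use a dot, the delimiter is a comma and headers
are mandatory.  ``write_survey`` emits a canonical form (stable row order,
ISO dates, shortest float repr) so that read -> write round-trips are
byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ORIGINS = ("native", "non_native", "unclassified")
LOCALITIES = ("lfec", "lgar", "lgua", "lpat", "lpve", "lven", "rbai", "rivi", "rpar")
HABITATS = ("lake", "river")
GEARS = ("gillnet", "seine")

UNITS_COLUMNS = ["unit_id", "locality", "habitat", "gear", "campaign_date", "area_m2"]
CATCHES_COLUMNS = ["unit_id", "species_id", "n_individuals", "total_weight_g"]
REGISTRY_COLUMNS = ["species_id", "species_name", "origin"]


@dataclass
class ValidationReport:
    """Outcome of structural validation of a survey.

    ``errors`` holds (row, rule, message) triples; a survey with any error is
    rejected by the metric and trend layers.  ``warnings`` are advisory.
    """

    errors: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[tuple[int, str, str]] = field(default_factory=list)
    n_units: int = 0
    n_species: int = 0
    n_records: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        return (
            f"{self.n_units} units, {self.n_species} species, "
            f"{self.n_records} records; {len(self.errors)} errors, "
            f"{len(self.warnings)} warnings"
        )


@dataclass
class SurveyTable:
    """A fully linked survey: sampling units, catches, species registry.

    All three members are pandas DataFrames with the canonical column sets
    above; ``units`` additionally carries a derived ``season`` column
    (meteorological quarter, "Q1".."Q4").
    """

    units: pd.DataFrame
    catches: pd.DataFrame
    registry: pd.DataFrame
    report: ValidationReport = field(default_factory=ValidationReport)


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read a species registry CSV.

    Unknown origin strings are coerced to ``unclassified`` with a
    ``UserWarning``.  Duplicate ``species_id`` values or an empty file are
    hard errors.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry {path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"registry {path}: empty")
    dup = df["species_id"][df["species_id"].duplicated()]
    if len(dup):
        raise ValueError(f"registry {path}: duplicate species_id {sorted(set(dup))}")
    df = df[REGISTRY_COLUMNS].copy()
    bad = ~df["origin"].isin(ORIGINS)
    if bad.any():
        n = int(bad.sum())
        warnings.warn(
            f"registry {path}: {n} row(s) with unrecognised origin coerced to "
            "'unclassified'",
            UserWarning,
            stacklevel=2,
        )
        df.loc[bad, "origin"] = "unclassified"
    return df.reset_index(drop=True)


def _derive_season(dates: pd.Series) -> pd.Series:
    return "Q" + pd.to_datetime(dates).dt.quarter.astype(str)


def read_survey(
    units_path: str | Path,
    catches_path: str | Path,
    registry: pd.DataFrame,
) -> SurveyTable:
    """Read and link a survey; structural problems land in ``report``.

    Dates are parsed to calendar dates and the season (quarter) is derived.
    Referential errors (catch rows naming unknown units or species) are
    collected, not raised, so a single pass reports every problem.
    """
    units = pd.read_csv(units_path)
    catches = pd.read_csv(catches_path)
    for cols, df, name in (
        (UNITS_COLUMNS, units, "units"),
        (CATCHES_COLUMNS, catches, "catches"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} file: missing columns {missing}")
    units = units[UNITS_COLUMNS].copy()
    units["campaign_date"] = pd.to_datetime(units["campaign_date"]).dt.date
    units["area_m2"] = units["area_m2"].astype(float)
    units["season"] = _derive_season(units["campaign_date"])
    catches = catches[CATCHES_COLUMNS].copy()
    catches["n_individuals"] = catches["n_individuals"].astype(int)
    catches["total_weight_g"] = catches["total_weight_g"].astype(float)
    survey = SurveyTable(units=units, catches=catches, registry=registry)
    survey.report = validate(survey)
    return survey


def validate(survey: SurveyTable) -> ValidationReport:
    """Apply every structural invariant; never raises on parsable input.

    Rules: positive sampled area; locality codes drawn from the nine known
    sites with the "l"/"r" prefix agreeing with the habitat; seining occurs
    in lakes only; catches reference existing units and species; at most one
    record per (unit, species); counts and weights non-negative, with weight
    strictly positive whenever individuals were caught.
    """
    rep = ValidationReport()
    units, catches, registry = survey.units, survey.catches, survey.registry
    rep.n_units = len(units)
    rep.n_species = len(registry)
    rep.n_records = len(catches)

    def collect(sink, mask, rule, fmt):
        for row in mask.index[mask]:
            sink.append((int(row), rule, fmt(row)))

    uid = units["unit_id"]
    loc = units["locality"].astype(str)
    hab = units["habitat"]
    gear = units["gear"]
    known_locality = loc.isin(LOCALITIES)
    expected_hab = loc.str[:1].map({"l": "lake", "r": "river"})
    collect(rep.errors, uid.duplicated(), "unique_unit",
            lambda r: f"duplicate unit_id {uid[r]}")
    collect(rep.errors, ~known_locality, "locality_code",
            lambda r: f"{uid[r]}: unknown locality {loc[r]!r}")
    collect(rep.errors, known_locality & (hab != expected_hab), "habitat_prefix",
            lambda r: f"{uid[r]}: locality {loc[r]} implies habitat {expected_hab[r]}, got {hab[r]!r}")
    collect(rep.errors, ~gear.isin(GEARS), "gear_code",
            lambda r: f"{uid[r]}: unknown gear {gear[r]!r}")
    collect(rep.errors, (gear == "seine") & (hab != "lake"), "seine_in_lakes",
            lambda r: f"{uid[r]}: seining occurs in lakes only")
    collect(rep.errors, ~(units["area_m2"] > 0), "positive_area",
            lambda r: f"{uid[r]}: area_m2 must be > 0, got {units['area_m2'][r]}")

    cuid = catches["unit_id"]
    sid = catches["species_id"]
    n = catches["n_individuals"]
    w = catches["total_weight_g"]
    collect(rep.errors, ~cuid.isin(set(uid)), "catch_unit_ref",
            lambda r: f"catch references unknown unit {cuid[r]!r}")
    collect(rep.errors, ~sid.isin(set(registry["species_id"])), "catch_species_ref",
            lambda r: f"catch references unknown species {sid[r]!r}")
    collect(rep.errors, catches.duplicated(subset=["unit_id", "species_id"]), "one_record_per_pair",
            lambda r: f"duplicate record for ({cuid[r]}, {sid[r]})")
    collect(rep.errors, n < 0, "count_nonnegative",
            lambda r: f"({cuid[r]}, {sid[r]}): n_individuals < 0")
    collect(rep.errors, w < 0, "weight_nonnegative",
            lambda r: f"({cuid[r]}, {sid[r]}): total_weight_g < 0")
    collect(rep.errors, (n > 0) & ~(w > 0), "weight_positive_when_caught",
            lambda r: f"({cuid[r]}, {sid[r]}): {n[r]} individuals but zero weight")
    collect(rep.warnings, (n == 0) & (w > 0), "weight_without_count",
            lambda r: f"({cuid[r]}, {sid[r]}): weight with zero individuals")
    return rep


def require_valid(survey: SurveyTable) -> None:
    """Raise ``ValueError`` if the survey's report carries errors."""
    if not survey.report.ok:
        lines = "; ".join(f"[{rule}] {msg}" for _, rule, msg in survey.report.errors[:10])
        raise ValueError(f"survey failed validation ({len(survey.report.errors)} errors): {lines}")


def write_survey(
    survey: SurveyTable,
    units_path: str | Path,
    catches_path: str | Path,
    registry_path: str | Path,
) -> None:
    """Write the three CSVs in canonical form (stable sort, ISO dates)."""
    units = survey.units.sort_values("unit_id", kind="mergesort")[UNITS_COLUMNS].copy()
    units["campaign_date"] = units["campaign_date"].astype(str)
    catches = survey.catches.sort_values(["unit_id", "species_id"], kind="mergesort")[CATCHES_COLUMNS]
    registry = survey.registry.sort_values("species_id", kind="mergesort")[REGISTRY_COLUMNS]
    units.to_csv(units_path, index=False, lineterminator="\n")
    catches.to_csv(catches_path, index=False, lineterminator="\n")
    registry.to_csv(registry_path, index=False, lineterminator="\n")
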