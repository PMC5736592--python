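"""Table schemas, validated I/O and eligibility filters.

The analysis consumes six comma-separated tables (UTF-8, one record per
row) describing an observational study of group-living primates:

``individuals.csv``
    id, sex (F/M), birth_year, mother_id (optional), natal_group (optional)
``membership.csv``
    id, group, year, full_year (true/false) — one group per individual-year
``grooming.csv``
    actor, recipient, group, year, seconds — directed grooming durations
``effort.csv``
    id, group, year, hours_observed — focal observation effort
``agonistic.csv``
    winner, loser, group, year, count — aggregated win–loss records
``pedigree.csv``
    id, mother_id, father_id — parentage links (either parent may be blank)

Analysis-ready subsets are produced by :func:`filter_eligible` (mature
adults, i.e. age >= 6 in the observation year, present for the full year)
and :func:`assemble_group_year`, which bundles everything needed to build
one group-year grooming network.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ADULT_AGE",
    "SCHEMAS",
    "SchemaError",
    "ReferentialIntegrityError",
    "DegenerateGroupError",
    "DemographyTables",
    "GroupYearDataset",
    "load_tables",
    "validate_tables",
    "write_tables",
    "filter_eligible",
    "assemble_group_year",
]

#: Minimum age (in whole years) at which an individual is a mature adult.
ADULT_AGE = 6

#: Canonical column names per table.
SCHEMAS: dict[str, list[str]] = {
    "individuals": ["id", "sex", "birth_year", "mother_id", "natal_group"],
    "membership": ["id", "group", "year", "full_year"],
    "grooming": ["actor", "recipient", "group", "year", "seconds"],
    "effort": ["id", "group", "year", "hours_observed"],
    "agonistic": ["winner", "loser", "group", "year", "count"],
    "pedigree": ["id", "mother_id", "father_id"],
}

_INT_COLS = {"birth_year", "year", "count"}
_FLOAT_COLS = {"seconds", "hours_observed"}


class SchemaError(ValueError):
    """A table violates its declared schema or a record-level invariant."""


class ReferentialIntegrityError(ValueError):
    """A record references an identifier absent from the individuals table."""


class DegenerateGroupError(ValueError):
    """A group-year has fewer than two eligible individuals."""


@dataclass
class DemographyTables:
    """Validated bundle of the six input tables (pandas DataFrames)."""

    individuals: pd.DataFrame
    membership: pd.DataFrame
    grooming: pd.DataFrame
    effort: pd.DataFrame
    agonistic: pd.DataFrame
    pedigree: pd.DataFrame

    def copy(self) -> "DemographyTables":
        return DemographyTables(
            **{name: getattr(self, name).copy() for name in SCHEMAS}
        )

    def observed_group_years(self) -> list[tuple[str, int]]:
        """(group, year) pairs with recorded observation effort."""
        pairs = self.effort[["group", "year"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))


@dataclass
class GroupYearDataset:
    """Everything needed to build one group-year grooming network."""

    group: str
    year: int
    ids: list[str]
    grooming: pd.DataFrame  # actor, recipient, seconds among eligible ids
    hours: dict[str, float]  # id -> hours observed
    agonistic: pd.DataFrame  # winner, loser, count among eligible ids


def _coerce(name: str, df: pd.DataFrame) -> pd.DataFrame:
    cols = SCHEMAS[name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    df = df[cols].copy()
    for c in cols:
        if c in _INT_COLS:
            try:
                df[c] = df[c].astype(int)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{name}.{c}: non-integer value ({exc})")
        elif c in _FLOAT_COLS:
            df[c] = df[c].astype(float)
        elif c == "full_year":
            df[c] = df[c].map(
                lambda v: str(v).strip().lower() in {"true", "1", "t", "yes"}
                if not isinstance(v, (bool, np.bool_))
                else bool(v)
            )
        else:  # identifier-like columns; blanks become <NA>
            df[c] = df[c].astype("string")
            df[c] = df[c].replace({"": pd.NA})
    return df


def _check_invariants(t: DemographyTables) -> None:
    ind = t.individuals
    if ind["id"].duplicated().any():
        dup = ind.loc[ind["id"].duplicated(), "id"].iloc[0]
        raise SchemaError(f"individuals.id: duplicate identifier {dup!r}")
    bad_sex = ~ind["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise SchemaError(
            f"individuals.sex: values must be F or M, got "
            f"{ind.loc[bad_sex, 'sex'].unique().tolist()}"
        )
    if t.membership.duplicated(["id", "year"]).any():
        row = t.membership[t.membership.duplicated(["id", "year"])].iloc[0]
        raise SchemaError(
            f"membership: ({row['id']}, {row['year']}) appears in more than "
            "one group — an individual is analysed in one group per year"
        )
    if (t.grooming["actor"] == t.grooming["recipient"]).any():
        raise SchemaError("grooming: actor == recipient (self-grooming row)")
    if (t.grooming["seconds"] < 0).any():
        raise SchemaError("grooming.seconds: negative value")
    if (t.effort["hours_observed"] <= 0).any():
        raise SchemaError("effort.hours_observed: must be > 0")
    if (t.agonistic["winner"] == t.agonistic["loser"]).any():
        raise SchemaError("agonistic: winner == loser")
    if (t.agonistic["count"] <= 0).any():
        raise SchemaError("agonistic.count: must be a positive integer")

    known = set(ind["id"])
    refs = {
        "membership.id": t.membership["id"],
        "grooming.actor": t.grooming["actor"],
        "grooming.recipient": t.grooming["recipient"],
        "effort.id": t.effort["id"],
        "agonistic.winner": t.agonistic["winner"],
        "agonistic.loser": t.agonistic["loser"],
        "pedigree.id": t.pedigree["id"],
    }
    for where, col in refs.items():
        dangling = set(col.dropna()) - known
        if dangling:
            raise ReferentialIntegrityError(
                f"{where}: unknown identifier(s) {sorted(dangling)[:5]}"
            )

    # birth_year must not postdate any observation of the individual
    merged = t.membership.merge(ind[["id", "birth_year"]], on="id")
    early = merged["year"] < merged["birth_year"]
    if early.any():
        row = merged[early].iloc[0]
        raise SchemaError(
            f"membership: {row['id']} observed in {row['year']} before "
            f"birth year {row['birth_year']}"
        )


def validate_tables(tables: DemographyTables) -> DemographyTables:
    """Coerce column types and enforce all record-level invariants."""
    coerced = DemographyTables(
        **{name: _coerce(name, getattr(tables, name)) for name in SCHEMAS}
    )
    _check_invariants(coerced)
    return coerced


def load_tables(
    source: str | os.PathLike | Mapping[str, str | os.PathLike],
    column_map: Mapping[str, Mapping[str, str]] | None = None,
) -> DemographyTables:
    """Read and validate the six CSV tables.

    Parameters
    ----------
    source
        Either a directory containing ``<table>.csv`` for each table, or a
        mapping of table name to file path.
    column_map
        Optional per-table mapping ``{table: {source_column: schema_column}}``
        so externally produced files with different headers can be adapted
        without rewriting them.
    """
    if isinstance(source, (str, os.PathLike)):
        base = Path(source)
        paths = {name: base / f"{name}.csv" for name in SCHEMAS}
    else:
        paths = {name: Path(p) for name, p in source.items()}
    missing = [name for name in SCHEMAS if name not in paths]
    if missing:
        raise SchemaError(f"no path given for table(s) {missing}")

    frames = {}
    for name in SCHEMAS:
        p = paths[name]
        if not p.exists():
            raise FileNotFoundError(p)
        df = pd.read_csv(p)
        if column_map and name in column_map:
            df = df.rename(columns=dict(column_map[name]))
        frames[name] = df
    return validate_tables(DemographyTables(**frames))


def write_tables(tables: DemographyTables, outdir: str | os.PathLike) -> None:
    """Write all six tables as CSV into *outdir* (created if needed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in SCHEMAS:
        getattr(tables, name).to_csv(out / f"{name}.csv", index=False)


def age_in_year(tables: DemographyTables, ids: Iterable[str], year: int) -> pd.Series:
    """Age (whole years, observation year minus birth year) per id."""
    birth = tables.individuals.set_index("id")["birth_year"]
    ids = list(ids)
    return pd.Series([year - int(birth[i]) for i in ids], index=ids)


def filter_eligible(tables: DemographyTables, year: int) -> dict[str, set[str]]:
    """Eligible (mature adult, full-year) individuals per group in *year*.

    An individual qualifies if its age (``year - birth_year``) is at least
    :data:`ADULT_AGE` and its membership record for the year is flagged
    ``full_year`` — animals that entered or left a group part way through
    the year are excluded. Returns ``{group: set_of_ids}``; groups with no
    eligible member are omitted, and an empty dict is allowed.
    """
    mem = tables.membership[tables.membership["year"] == year]
    if mem.empty:
        return {}
    birth = tables.individuals.set_index("id")["birth_year"]
    out: dict[str, set[str]] = {}
    for row in mem.itertuples(index=False):
        if not row.full_year:
            continue
        if year - int(birth[row.id]) < ADULT_AGE:
            continue
        out.setdefault(row.group, set()).add(row.id)
    return out


def assemble_group_year(
    tables: DemographyTables, group: str, year: int
) -> GroupYearDataset:
    """Bundle the eligible-adult data for one group-year.

    Grooming, effort and agonistic rows involving ineligible animals
    (juveniles, partial-year residents, non-members) are dropped. Raises
    :class:`DegenerateGroupError` when fewer than two individuals qualify.
    """
    eligible = filter_eligible(tables, year).get(group, set())
    if len(eligible) < 2:
        raise DegenerateGroupError(
            f"group {group!r} year {year}: {len(eligible)} eligible "
            "individual(s); need at least 2"
        )
    ids = sorted(eligible)

    g = tables.grooming
    g = g[
        (g["group"] == group)
        & (g["year"] == year)
        & g["actor"].isin(eligible)
        & g["recipient"].isin(eligible)
    ][["actor", "recipient", "seconds"]].reset_index(drop=True)

    e = tables.effort
    e = e[(e["group"] == group) & (e["year"] == year) & e["id"].isin(eligible)]
    hours = dict(zip(e["id"], e["hours_observed"]))

    a = tables.agonistic
    a = a[
        (a["group"] == group)
        & (a["year"] == year)
        & a["winner"].isin(eligible)
        & a["loser"].isin(eligible)
    ][["winner", "loser", "count"]].reset_index(drop=True)

    return GroupYearDataset(
        group=group, year=year, ids=ids, grooming=g, hours=hours, agonistic=a
    )
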