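"""Individual-level social attributes: dominance rank, kinship, tenure.

Dominance hierarchies are inferred separately per group, year and sex from
aggregated win–loss records using David's score; ordinal rank is converted
to the percentage of same-sex groupmates outranked, and individuals
outranking more than 80% are classed as high ranking. Relatedness comes
from the standard recursive kinship computation on the pedigree (founders
unrelated, non-inbred baseline; r = 2 * kinship for distinct individuals).
Male tenure counts consecutive prior years of membership in the current
group, with zero in the year of entry.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataio import ADULT_AGE, DemographyTables

__all__ = [
    "RankError",
    "davids_score",
    "infer_hierarchy",
    "percent_outranked",
    "Pedigree",
    "count_close_adult_female_kin",
    "tenure",
    "covariate_table",
]

#: Threshold (percent of same-sex groupmates outranked) for the high class.
HIGH_RANK_PERCENT = 80.0

#: Tolerance used when testing relatedness against 1/2.
_R_TOL = 1e-9


class RankError(ValueError):
    """A hierarchy cannot be inferred (no agonistic data)."""


def davids_score(wins: np.ndarray) -> np.ndarray:
    """David's scores from a win-count matrix (``wins[i, j]`` = i beats j).

    Uses dyadic win proportions ``P_ij = wins_ij / (wins_ij + wins_ji)``;
    dyads that never interacted contribute nothing. Returns
    ``DS = w + w2 - l - l2`` where ``w``/``l`` are summed win/loss
    proportions and ``w2``/``l2`` their partner-weighted second-order sums.
    """
    wins = np.asarray(wins, dtype=float)
    total = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(total > 0, wins / total, 0.0)
    np.fill_diagonal(P, 0.0)
    w = P.sum(axis=1)
    l = P.sum(axis=0)
    w2 = P @ w
    l2 = P.T @ l
    return w + w2 - l - l2


def infer_hierarchy(
    agonistic: pd.DataFrame, ids: Sequence[str]
) -> dict[str, int]:
    """Ordinal ranks (1 = top) for *ids* from win–loss records.

    *agonistic* needs columns winner, loser, count; rows involving
    individuals outside *ids* are ignored. Ordering is by David's score,
    ties broken by total wins then id order. Raises :class:`RankError`
    when no usable agonistic data exist for these individuals.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise RankError("need at least 2 same-sex individuals to rank")
    idx = {i: k for k, i in enumerate(ids)}
    wins = np.zeros((len(ids), len(ids)))
    for row in agonistic.itertuples(index=False):
        if row.winner in idx and row.loser in idx:
            wins[idx[row.winner], idx[row.loser]] += row.count
    if not wins.any():
        raise RankError("no agonistic data for these individuals")
    ds = davids_score(wins)
    total_wins = wins.sum(axis=1)
    order = sorted(range(len(ids)), key=lambda k: (-ds[k], -total_wins[k], ids[k]))
    return {ids[k]: rank + 1 for rank, k in enumerate(order)}


def percent_outranked(ranks: dict[str, int]) -> pd.DataFrame:
    """Percent of same-sex groupmates outranked, plus high/low class.

    ``percent = 100 * (n - rank) / (n - 1)`` for *n* ranked individuals;
    class is high iff percent > 80. A single-individual ranking is
    undefined: the row is returned flagged with NaN percent and no class.
    """
    rows = []
    n = len(ranks)
    for i, r in ranks.items():
        if n < 2:
            warnings.warn(f"{i}: only individual of its sex; rank undefined")
            rows.append({"id": i, "ordinal_rank": r, "percent_outranked": np.nan,
                         "rank_class": pd.NA})
            continue
        pct = 100.0 * (n - r) / (n - 1)
        rows.append({
            "id": i,
            "ordinal_rank": r,
            "percent_outranked": pct,
            "rank_class": "high" if pct > HIGH_RANK_PERCENT else "low",
        })
    return pd.DataFrame(rows)


class Pedigree:
    """Parentage map supporting kinship / relatedness queries.

    Built from a table with columns id, mother_id, father_id (parents may
    be missing). The pedigree must be acyclic; referenced parents that
    have no row of their own are treated as founders.
    """

    def __init__(self, table: pd.DataFrame):
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        for row in table.itertuples(index=False):
            m = None if pd.isna(row.mother_id) else str(row.mother_id)
            f = None if pd.isna(row.father_id) else str(row.father_id)
            self.parents[str(row.id)] = (m, f)
        # implicit founders for parents without their own row
        for m, f in list(self.parents.values()):
            for p in (m, f):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self._generation: dict[str, int] = {}
        for i in self.parents:
            self._gen(i, ())

    def _gen(self, i: str, stack: tuple) -> int:
        if i in self._generation:
            return self._generation[i]
        if i in stack:
            raise ValueError(f"pedigree cycle involving {i!r}")
        m, f = self.parents[i]
        g = 1 + max(
            (self._gen(p, stack + (i,)) for p in (m, f) if p is not None),
            default=-1,
        )
        self._generation[i] = g
        return g

    def __contains__(self, i: str) -> bool:
        return i in self.parents

    @lru_cache(maxsize=None)
    def kinship(self, i: str, j: str) -> float:
        """Malecot kinship coefficient phi(i, j) on the pedigree."""
        if i not in self.parents or j not in self.parents:
            raise KeyError(f"unknown individual {i!r} or {j!r}")
        if i == j:
            m, f = self.parents[i]
            inb = self.kinship(m, f) if (m is not None and f is not None) else 0.0
            return 0.5 * (1.0 + inb)
        # recurse through the parents of the later-generation individual
        if self._generation[i] < self._generation[j]:
            i, j = j, i
        m, f = self.parents[i]
        phi = 0.0
        if m is not None:
            phi += 0.5 * self.kinship(*sorted((m, j)))
        if f is not None:
            phi += 0.5 * self.kinship(*sorted((f, j)))
        return phi

    def relatedness(self, i: str, j: str) -> float:
        """Coefficient of relatedness r = 2 * kinship (r(i,i) = 1 non-inbred)."""
        if i == j:
            m, f = self.parents[i]
            inb = self.kinship(*sorted((m, f))) if (m and f) else 0.0
            return 1.0 + inb
        return 2.0 * self.kinship(*sorted((i, j)))


def count_close_adult_female_kin(
    tables: DemographyTables,
    pedigree: Pedigree,
    id: str,
    group: str,
    year: int,
) -> int:
    """Number of close adult female relatives co-resident in a group-year.

    Counts other females with coefficient of relatedness exactly 0.5
    (within 1e-9), aged at least 6 in *year*, who are members of the same
    group that year. Individuals absent from the pedigree are treated as
    unrelated.
    """
    mem = tables.membership
    present = set(
        mem[(mem["group"] == group) & (mem["year"] == year)]["id"]
    ) - {id}
    if not present:
        return 0
    ind = tables.individuals.set_index("id")
    n = 0
    for other in present:
        if ind.loc[other, "sex"] != "F":
            continue
        if year - int(ind.loc[other, "birth_year"]) < ADULT_AGE:
            continue
        if other not in pedigree or id not in pedigree:
            continue
        if abs(pedigree.relatedness(id, other) - 0.5) <= _R_TOL:
            n += 1
    return n


def tenure(
    membership: pd.DataFrame, id: str, group: str, year: int
) -> int:
    """Consecutive prior years of membership in *group* (0 in entry year)."""
    years = set(
        membership[(membership["id"] == id) & (membership["group"] == group)]["year"]
    )
    t = 0
    y = year - 1
    while y in years:
        t += 1
        y -= 1
    return t


def covariate_table(
    tables: DemographyTables,
    pedigree: Pedigree,
    group_years: Iterable[tuple[str, int]] | None = None,
    eligible: dict[tuple[str, int], Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per individual-year covariates for the mixed models.

    For every eligible individual in every observed group-year: age, sex,
    ordinal rank / percent outranked / rank class (within group-sex-year),
    number of close adult female kin (females), group tenure (males),
    mother id and natal group. Individuals whose rank is undefined (only
    member of their sex) get NaN rank fields.
    """
    from .dataio import filter_eligible  # local import to avoid cycle noise

    if group_years is None:
        group_years = tables.observed_group_years()
    ind = tables.individuals.set_index("id")
    ag = tables.agonistic
    records = []
    for group, year in group_years:
        if eligible is not None:
            ids = list(eligible[(group, year)])
        else:
            ids = sorted(filter_eligible(tables, year).get(group, set()))
        sexes = {i: ind.loc[i, "sex"] for i in ids}
        ag_gy = ag[(ag["group"] == group) & (ag["year"] == year)]
        rank_rows: dict[str, dict] = {}
        for sex in ("F", "M"):
            same = [i for i in ids if sexes[i] == sex]
            if len(same) < 2:
                for i in same:
                    rank_rows[i] = {
                        "ordinal_rank": np.nan,
                        "percent_outranked": np.nan,
                        "rank_class": pd.NA,
                    }
                continue
            ranks = infer_hierarchy(ag_gy, same)
            for row in percent_outranked(ranks).itertuples(index=False):
                rank_rows[row.id] = {
                    "ordinal_rank": row.ordinal_rank,
                    "percent_outranked": row.percent_outranked,
                    "rank_class": row.rank_class,
                }
        for i in ids:
            sex = sexes[i]
            rec = {
                "id": i,
                "group": group,
                "year": year,
                "sex": sex,
                "age": year - int(ind.loc[i, "birth_year"]),
                "mother": ind.loc[i, "mother_id"],
                "natal_group": ind.loc[i, "natal_group"],
                **rank_rows[i],
            }
            rec["n_kin"] = (
                count_close_adult_female_kin(tables, pedigree, i, group, year)
                if sex == "F"
                else np.nan
            )
            rec["tenure"] = (
                tenure(tables.membership, i, group, year) if sex == "M" else np.nan
            )
            records.append(rec)
    return pd.DataFrame(records)
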