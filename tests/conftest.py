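from __future__ import annotations

import pandas as pd
import pytest

from socisol.dataio import DemographyTables, validate_tables
from socisol.simulate import (
    SimulationConfig,
    default_config,
    generate_dataset,
)


def make_tables(
    individuals=None, membership=None, grooming=None, effort=None,
    agonistic=None, pedigree=None, validate=True,
) -> DemographyTables:
    """Build a DemographyTables bundle from plain row dicts (with defaults)."""
    empty = {
        "individuals": ["id", "sex", "birth_year", "mother_id", "natal_group"],
        "membership": ["id", "group", "year", "full_year"],
        "grooming": ["actor", "recipient", "group", "year", "seconds"],
        "effort": ["id", "group", "year", "hours_observed"],
        "agonistic": ["winner", "loser", "group", "year", "count"],
        "pedigree": ["id", "mother_id", "father_id"],
    }
    frames = {}
    given = {
        "individuals": individuals, "membership": membership,
        "grooming": grooming, "effort": effort, "agonistic": agonistic,
        "pedigree": pedigree,
    }
    for name, cols in empty.items():
        rows = given[name]
        frames[name] = (
            pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
        )
    tables = DemographyTables(**frames)
    return validate_tables(tables) if validate else tables


@pytest.fixture
def trio_tables():
    """Three adults + one juvenile in one group-year, with simple grooming."""
    return make_tables(
        individuals=[
            ("A", "F", 2000, None, "G"),
            ("B", "F", 1998, None, "G"),
            ("C", "M", 1995, None, "G"),
            ("J", "F", 2009, "A", "G"),  # age 4 in 2013
        ],
        membership=[
            ("A", "G", 2013, True),
            ("B", "G", 2013, True),
            ("C", "G", 2013, True),
            ("J", "G", 2013, True),
        ],
        grooming=[
            ("A", "B", "G", 2013, 120.0),
            ("B", "A", "G", 2013, 30.0),
            ("A", "C", "G", 2013, 60.0),
            ("J", "A", "G", 2013, 45.0),
        ],
        effort=[
            ("A", "G", 2013, 4.0),
            ("B", "G", 2013, 6.0),
            ("C", "G", 2013, 5.0),
            ("J", "G", 2013, 5.0),
        ],
        agonistic=[
            ("A", "B", "G", 2013, 5),
            ("B", "C", "G", 2013, 2),
        ],
        pedigree=[
            ("A", None, None),
            ("B", None, None),
            ("C", None, None),
            ("J", "A", None),
        ],
    )


def small_sim_config(seed: int = 11) -> SimulationConfig:
    """Two small groups, one followed two years: fast end-to-end fixture."""
    return SimulationConfig(
        group_year_sizes={"A": {2010: 14, 2011: 14}, "B": {2010: 12}},
        new_entrants={("A", 2011): 3},
        n_cross_group_males=0,
        partial_year_fraction=0.0,
        juvenile_fraction=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_sim():
    """One full study-condition synthetic dataset (session-cached)."""
    return generate_dataset(default_config(seed=20260921))


@pytest.fixture(scope="session")
def study_table(study_sim):
    """Analysis table built from the study-condition dataset."""
    from socisol.pipeline import build_analysis_table

    df, mt = build_analysis_table(study_sim.tables)
    return df
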