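"""Synthetic focal-sampling data with known ground truth.

The generator emulates the structure of a multi-year observational study
of free-ranging rhesus macaques: six social groups, one of which is
followed for six consecutive years while the others contribute a single
year each; female philopatry and male dispersal; focal-sample observation
effort of about 5.7 h per monkey (SD 1.98, truncated at 1 h); grooming
rates structured by stable individual propensities, maternal identity,
group, year, dominance rank, kinship and male tenure; and win–loss
agonistic records generated from a latent hierarchy with a configurable
upset probability.

The generative model for the latent (log-scale) grooming propensities is,
separately for giving and receiving,

    eta_{i, year} = beta' x_{i, year} + a_i + m_{mother(i)} + g_group + y_year + e_{i, year}

with each random component Normal with standard deviation
``sqrt(fraction) * total_latent_sd``; the variance fractions are part of
the configuration and sum to one. Expected grooming of recipient *j* by
actor *i* is

    mu_ij = baseline_rate * exp(eta_give_i + eta_recv_j
                                + kin_bonus * [r_ij = 0.5]
                                + rank_bonus * [j high-ranking])

in seconds per combined observation hour, and observed seconds are Poisson
(or negative-binomial when overdispersed) with mean ``mu_ij * (h_i + h_j)``.

Because the default configuration reproduces the study's group-year sizes
exactly, the generated analysis panel always contains 836 individual-years
of 429 unique adults, with roughly 143 individuals observed in two or more
years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .dataio import ADULT_AGE, DemographyTables, validate_tables, write_tables

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedData",
    "default_config",
    "recovery_config",
    "study_group_year_sizes",
    "simulate_population",
    "simulate_latents",
    "simulate_grooming",
    "simulate_agonistic",
    "generate_dataset",
    "expected_rate_matrix",
]

#: Age used to centre the true age effect on the latent scale.
AGE_CENTER = 12


def study_group_year_sizes() -> dict[str, dict[int, int]]:
    """Adults analysed per group and year in the emulated study design."""
    return {
        "F": {2010: 85, 2011: 100, 2012: 82, 2013: 94, 2014: 104, 2015: 96},
        "HH": {2013: 43},
        "KK": {2013: 52},
        "R": {2013: 85},
        "S": {2013: 27},
        "V": {2013: 68},
    }


def _study_new_entrants() -> dict[tuple[str, int], int]:
    # Calibrated so the longitudinal group holds 170 unique adults and the
    # whole design 429 (836 individual-years).
    return {
        ("F", 2011): 28,
        ("F", 2012): 0,
        ("F", 2013): 23,
        ("F", 2014): 24,
        ("F", 2015): 10,
    }


@dataclass
class SimulationConfig:
    """All knobs of the generative model; defaults are the study conditions."""

    group_year_sizes: dict[str, dict[int, int]] = field(
        default_factory=study_group_year_sizes
    )
    new_entrants: dict[tuple[str, int], int] | None = field(
        default_factory=_study_new_entrants
    )
    turnover: float = 0.15  # fallback yearly churn when new_entrants is None
    n_cross_group_males: int = 16
    sex_ratio_female: float = 0.646
    max_entry_age: int = 28
    n_natal_groups_male: int = 8
    variance_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "animal": 0.25,
            "maternal": 0.10,
            "group": 0.05,
            "year": 0.05,
            "residual": 0.55,
        }
    )
    total_latent_sd: float = 0.6
    fixed_effects_true: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.02,
            "sex_male": -0.2,
            "rank_high": 0.4,
            "n_kin": 0.15,
            "tenure": 0.05,
        }
    )
    baseline_rate: float = 0.3  # seconds per combined observation hour
    kin_dyad_bonus: float = 0.8
    rank_dyad_bonus: float = 0.3
    focal_hours_mean: float = 5.70
    focal_hours_sd: float = 1.98
    focal_hours_min: float = 1.0
    bouts_dispersion: float | None = 0.1  # NB dispersion; None = pure Poisson
    mean_bouts_agonistic: float = 3.0
    upset_probability: float = 0.05
    male_dispersal_rate: float = 0.25  # yearly prob.; sets tenure at entry
    max_tenure: int = 15
    partial_year_fraction: float = 0.03
    juvenile_fraction: float = 0.02
    p_sibling_reuse: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.variance_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"variance fractions sum to {tot}, not 1")
        if any(v < 0 for v in self.variance_fractions.values()):
            raise ValueError("variance fractions must be non-negative")
        if self.total_latent_sd < 0 or self.focal_hours_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.upset_probability < 1):
            raise ValueError("upset_probability must be in [0, 1)")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["new_entrants"] is not None:
            d["new_entrants"] = {f"{g}:{y}": v for (g, y), v in d["new_entrants"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("group_year_sizes"):
            d["group_year_sizes"] = {
                str(g): {int(y): int(s) for y, s in ys.items()}
                for g, ys in d["group_year_sizes"].items()
            }
        if d.get("new_entrants") is not None:
            d["new_entrants"] = {
                (k.split(":")[0], int(k.split(":")[1])): int(v)
                for k, v in d["new_entrants"].items()
            }
        return cls(**d)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-condition configuration (optionally overridden)."""
    return SimulationConfig(seed=seed, **overrides)


def recovery_config(
    seed: int = 0,
    n_individuals: int = 300,
    n_years: int = 6,
    n_groups: int = 10,
    total_latent_sd: float = 1.0,
) -> SimulationConfig:
    """Balanced closed-panel configuration for variance-recovery checks.

    *n_individuals* adults split over *n_groups* groups, each observed
    every year with no turnover, no true fixed effects, and stronger
    sibling sharing so the maternal component is well identified.
    """
    per = n_individuals // n_groups
    years = list(range(2010, 2010 + n_years))
    sizes = {f"G{k:02d}": {y: per for y in years} for k in range(n_groups)}
    return SimulationConfig(
        group_year_sizes=sizes,
        new_entrants={},
        turnover=0.0,
        n_cross_group_males=0,
        fixed_effects_true={k: 0.0 for k in
                            ("age", "sex_male", "rank_high", "n_kin", "tenure")},
        total_latent_sd=total_latent_sd,
        partial_year_fraction=0.0,
        juvenile_fraction=0.0,
        p_sibling_reuse=0.6,
        seed=seed,
    )


@dataclass
class TruthRecord:
    """Ground truth: latent propensities, their components, true covariates."""

    latents: pd.DataFrame  # id, group, year, eta_give, eta_receive + parts
    components: dict  # trait -> {"animal": {...}, "maternal": {...}, ...}
    covariates: pd.DataFrame  # id, group, year, age, sex, rank_class, n_kin, tenure

    def to_csv(self, path) -> None:
        self.latents.merge(
            self.covariates, on=["id", "group", "year"]
        ).to_csv(path, index=False)


@dataclass
class SimulatedData:
    """A complete synthetic dataset plus its generating truth."""

    config: SimulationConfig
    tables: DemographyTables
    truth: TruthRecord

    def write(self, outdir) -> None:
        out = Path(outdir)
        write_tables(self.tables, out)
        self.truth.to_csv(out / "truth.csv")
        self.config.to_yaml(out / "config.yaml")


# ---------------------------------------------------------------------------
# population structure


class _Population:
    """Intermediate state shared by the generator stages."""

    def __init__(self) -> None:
        self.individuals: list[dict] = []
        self.membership: list[dict] = []
        self.pedigree: list[dict] = []
        self.rosters: dict[tuple[str, int], list[str]] = {}
        self.extras: dict[tuple[str, int], list[str]] = {}  # partial/juvenile
        self.dominance: dict[str, float] = {}
        self.mother_of: dict[str, str | None] = {}
        self._serial = 0

    def new_id(self, prefix: str = "A") -> str:
        self._serial += 1
        return f"{prefix}{self._serial:04d}"


def _draw_entry_age(rng: np.random.Generator, max_age: int) -> int:
    return ADULT_AGE + min(int(rng.geometric(0.12)) - 1, max_age - ADULT_AGE)


def _make_individual(
    pop: _Population,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    entry_year: int,
    group: str,
    natal_labels: list[str],
    sex: str | None = None,
    age: int | None = None,
) -> str:
    i = pop.new_id()
    if sex is None:
        sex = "F" if rng.random() < cfg.sex_ratio_female else "M"
    if age is None:
        age = _draw_entry_age(rng, cfg.max_entry_age)
    natal = group if sex == "F" else natal_labels[rng.integers(len(natal_labels))]
    pop.individuals.append({
        "id": i, "sex": sex, "birth_year": entry_year - age,
        "mother_id": None, "natal_group": natal,
    })
    pop.dominance[i] = float(rng.standard_normal())
    return i


def _build_rosters(pop: _Population, rng, cfg: SimulationConfig, natal_labels):
    sizes = cfg.group_year_sizes
    single_year_groups = [g for g, ys in sizes.items() if len(ys) == 1]
    dropped_males: list[tuple[str, int]] = []  # (id, last_year_in_group)

    for group, ys in sizes.items():
        years = sorted(ys)
        if len(years) == 1:
            continue  # filled later (may receive cross-group males)
        roster = [
            _make_individual(pop, rng, cfg, years[0], group, natal_labels)
            for _ in range(ys[years[0]])
        ]
        pop.rosters[(group, years[0])] = list(roster)
        info = {r["id"]: r for r in pop.individuals}
        for prev, year in zip(years, years[1:]):
            size = ys[year]
            if cfg.new_entrants is not None and (group, year) in cfg.new_entrants:
                n_new = min(cfg.new_entrants[(group, year)], size)
            elif cfg.new_entrants is not None:
                n_new = max(0, size - len(roster))
            else:
                churn = round(cfg.turnover * len(roster))
                n_new = max(0, size - max(0, len(roster) - churn))
            n_retain = size - n_new
            if n_retain > len(roster):
                raise ValueError(
                    f"group {group} year {year}: cannot retain {n_retain} "
                    f"of {len(roster)} members"
                )
            # dispersal / mortality: males and the elderly leave preferentially
            w = np.array([
                (2.5 if info[i]["sex"] == "M" else 1.0)
                * (2.5 if year - info[i]["birth_year"] >= 25 else 1.0)
                for i in roster
            ])
            drop_idx = rng.choice(
                len(roster), size=len(roster) - n_retain, replace=False,
                p=w / w.sum(),
            )
            for k in drop_idx:
                if info[roster[k]]["sex"] == "M":
                    dropped_males.append((roster[k], prev))
            keep = [roster[k] for k in range(len(roster)) if k not in set(drop_idx)]
            newcomers = [
                _make_individual(pop, rng, cfg, year, group, natal_labels)
                for _ in range(n_new)
            ]
            roster = keep + newcomers
            pop.rosters[(group, year)] = list(roster)
            info = {r["id"]: r for r in pop.individuals}

    # single-year groups: some slots taken by males who left the focal group
    cross: dict[str, list[str]] = {g: [] for g in single_year_groups}
    if single_year_groups and cfg.n_cross_group_males > 0:
        candidates = [
            (i, last) for i, last in dropped_males
            if last < min(min(sizes[g]) for g in single_year_groups)
        ]
        rng.shuffle(candidates)
        for i, _last in candidates[: cfg.n_cross_group_males]:
            cross[single_year_groups[int(rng.integers(len(single_year_groups)))]].append(i)

    for group in single_year_groups:
        year = next(iter(sizes[group]))
        assigned = cross[group]
        fresh = [
            _make_individual(pop, rng, cfg, year, group, natal_labels)
            for _ in range(sizes[group][year] - len(assigned))
        ]
        pop.rosters[(group, year)] = assigned + fresh


def _assign_mothers(pop: _Population, rng, cfg: SimulationConfig):
    """Give every subject a mother; shared mothers create sibships."""
    info = {r["id"]: r for r in pop.individuals}
    current_group = {}
    for (group, _y), roster in sorted(pop.rosters.items()):
        for i in roster:
            current_group.setdefault(i, group)
    used: dict[str, list[str]] = {}  # natal group -> mothers already used
    order = sorted(info, key=lambda i: (info[i]["birth_year"], i))
    for i in order:
        rec = info[i]
        natal = rec["natal_group"]
        pool = used.setdefault(natal, [])
        compatible = [
            m for m in pool
            if info[m]["birth_year"] <= rec["birth_year"] - ADULT_AGE and m != i
        ]
        mother = None
        if compatible and rng.random() < cfg.p_sibling_reuse:
            mother = compatible[int(rng.integers(len(compatible)))]
        if mother is None:
            # prefer a co-resident subject female as the mother of philopatric
            # females, otherwise create an off-panel (phantom) mother
            cands = [
                j for j in order
                if info[j]["sex"] == "F"
                and current_group.get(j) == natal
                and info[j]["birth_year"] <= rec["birth_year"] - ADULT_AGE
                and j != i
            ] if rec["sex"] == "F" and natal in {g for g, _ in pop.rosters} else []
            if cands and rng.random() < 0.7:
                mother = cands[int(rng.integers(len(cands)))]
            else:
                mother = pop.new_id("P")
                pop.individuals.append({
                    "id": mother, "sex": "F",
                    "birth_year": rec["birth_year"] - int(rng.integers(8, 20)),
                    "mother_id": None, "natal_group": natal,
                })
                info[mother] = pop.individuals[-1]
                pop.dominance[mother] = float(rng.standard_normal())
        rec["mother_id"] = mother
        pop.mother_of[i] = mother
        if mother not in pool:
            pool.append(mother)


def _build_membership(pop: _Population, rng, cfg: SimulationConfig):
    info = {r["id"]: r for r in pop.individuals}
    first_year: dict[tuple[str, str], int] = {}
    rows = set()
    for (group, year), roster in sorted(pop.rosters.items()):
        for i in roster:
            rows.add((i, group, year))
            key = (i, group)
            if key not in first_year or year < first_year[key]:
                first_year[key] = year
    # back-fill male residence before first observation to seed tenure;
    # a male entering in the observation year has tenure zero
    observed_first = {}
    for (i, group), y0 in first_year.items():
        observed_first.setdefault(i, (y0, group))
        if y0 < observed_first[i][0]:
            observed_first[i] = (y0, group)
    group_start = {g: min(ys) for g, ys in cfg.group_year_sizes.items()}
    for i, (y0, group) in observed_first.items():
        rec = info[i]
        if rec["sex"] != "M":
            continue
        if y0 != group_start.get(group):
            continue  # entered mid-study: tenure starts at zero
        max_prior = min(y0 - (rec["birth_year"] + ADULT_AGE), cfg.max_tenure)
        if max_prior <= 0:
            continue
        if cfg.male_dispersal_rate <= 0:
            prior = max_prior
        else:
            prior = min(int(rng.geometric(cfg.male_dispersal_rate)) - 1, max_prior)
        for y in range(y0 - prior, y0):
            rows.add((i, group, y))
    # cross-group males entered their second group recently: no back-fill
    for i, group, year in sorted(rows):
        pop.membership.append(
            {"id": i, "group": group, "year": year, "full_year": True}
        )


def _add_extras(pop: _Population, rng, cfg: SimulationConfig, natal_labels):
    """Partial-year residents and juveniles, excluded by the filters."""
    for (group, year), roster in sorted(pop.rosters.items()):
        extras = []
        for _ in range(round(len(roster) * cfg.partial_year_fraction)):
            i = _make_individual(pop, rng, cfg, year, group, natal_labels)
            pop.membership.append(
                {"id": i, "group": group, "year": year, "full_year": False}
            )
            extras.append(i)
        for _ in range(round(len(roster) * cfg.juvenile_fraction)):
            age = int(rng.integers(2, ADULT_AGE))
            i = _make_individual(
                pop, rng, cfg, year, group, natal_labels, age=age
            )
            pop.membership.append(
                {"id": i, "group": group, "year": year, "full_year": True}
            )
            extras.append(i)
        pop.extras[(group, year)] = extras


def simulate_population(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[_Population, pd.DataFrame]:
    """Demography, pedigree, membership and true per-year covariates.

    Females are philopatric (natal group equals the observed group); males
    carry a natal group drawn from a wider set of labels and acquire
    tenure through (possibly back-filled) consecutive membership years.
    Returns the population state and a covariate frame with the *true*
    rank class, kin count and tenure per individual-year.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pop = _Population()
    study_groups = list(cfg.group_year_sizes)
    extra_natal = [
        f"X{k}" for k in range(1, max(0, cfg.n_natal_groups_male - len(study_groups)) + 1)
    ]
    natal_labels = study_groups + extra_natal

    _build_rosters(pop, rng, cfg, natal_labels)
    _assign_mothers(pop, rng, cfg)
    _build_membership(pop, rng, cfg)
    _add_extras(pop, rng, cfg, natal_labels)

    info = {r["id"]: r for r in pop.individuals}
    mother_of = pop.mother_of

    # true covariates per roster individual-year
    records = []
    for (group, year), roster in sorted(pop.rosters.items()):
        present = set(roster)
        kids_of = {}
        for i in roster:
            m = mother_of.get(i)
            if m is not None:
                kids_of.setdefault(m, []).append(i)
        for sex in ("F", "M"):
            same = [i for i in roster if info[i]["sex"] == sex]
            same.sort(key=lambda i: -pop.dominance[i])
            n = len(same)
            for rank0, i in enumerate(same):
                pct = 100.0 * (n - rank0 - 1) / (n - 1) if n > 1 else np.nan
                rec = {
                    "id": i, "group": group, "year": year, "sex": sex,
                    "age": year - info[i]["birth_year"],
                    "rank_class": ("high" if pct > 80 else "low") if n > 1 else None,
                    "percent_outranked": pct,
                }
                if sex == "F":
                    n_kin = 0
                    m = mother_of.get(i)
                    if m in present and info[m]["sex"] == "F" and \
                            year - info[m]["birth_year"] >= ADULT_AGE:
                        n_kin += 1
                    for c in kids_of.get(i, []):
                        if c in present and info[c]["sex"] == "F" and \
                                year - info[c]["birth_year"] >= ADULT_AGE:
                            n_kin += 1
                    rec["n_kin"] = n_kin
                    rec["tenure"] = np.nan
                else:
                    rec["n_kin"] = np.nan
                    years_in = {
                        m["year"] for m in pop.membership
                        if m["id"] == i and m["group"] == group
                    }
                    t, y = 0, year - 1
                    while y in years_in:
                        t, y = t + 1, y - 1
                    rec["tenure"] = t
                records.append(rec)
    covariates = pd.DataFrame(records).sort_values(
        ["group", "year", "id"]
    ).reset_index(drop=True)
    return pop, covariates


# ---------------------------------------------------------------------------
# latent propensities


def simulate_latents(
    covariates: pd.DataFrame,
    mother_of: dict[str, str | None],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> TruthRecord:
    """Latent giving / receiving propensities with known components.

    For each trait the per-row latent is the fixed-effect contribution
    plus animal, maternal, group and year random draws plus a residual,
    each Normal with SD ``sqrt(fraction) * total_latent_sd``.
    """
    df = covariates.copy()
    ids = sorted(df["id"].unique())
    groups = sorted(df["group"].unique())
    years = sorted(df["year"].unique())
    mothers = sorted({str(mother_of.get(i)) for i in ids})

    fe = cfg.fixed_effects_true
    beta_x = (
        fe.get("age", 0.0) * (df["age"] - AGE_CENTER)
        + fe.get("sex_male", 0.0) * (df["sex"] == "M").astype(float)
        + fe.get("rank_high", 0.0) * (df["rank_class"] == "high").astype(float)
        + fe.get("n_kin", 0.0) * df["n_kin"].fillna(0.0)
        + fe.get("tenure", 0.0) * df["tenure"].fillna(0.0)
    ).to_numpy()

    sd = {
        k: np.sqrt(f) * cfg.total_latent_sd
        for k, f in cfg.variance_fractions.items()
    }
    components: dict[str, dict] = {}
    out = df[["id", "group", "year"]].copy()
    for trait in ("give", "receive"):
        a = dict(zip(ids, sd["animal"] * rng.standard_normal(len(ids))))
        m = dict(zip(mothers, sd["maternal"] * rng.standard_normal(len(mothers))))
        g = dict(zip(groups, sd["group"] * rng.standard_normal(len(groups))))
        y = dict(zip(years, sd["year"] * rng.standard_normal(len(years))))
        e = sd["residual"] * rng.standard_normal(len(df))
        av = df["id"].map(a).to_numpy()
        mv = df["id"].map(lambda i: m[str(mother_of.get(i))]).to_numpy()
        gv = df["group"].map(g).to_numpy()
        yv = df["year"].map(y).to_numpy()
        eta = beta_x + av + mv + gv + yv + e
        out[f"eta_{trait}"] = eta
        out[f"a_{trait}"] = av
        out[f"m_{trait}"] = mv
        out[f"g_{trait}"] = gv
        out[f"y_{trait}"] = yv
        out[f"e_{trait}"] = e
        components[trait] = {
            "animal": a, "maternal": m, "group": g, "year": y,
        }
    out["beta_x"] = beta_x
    return TruthRecord(latents=out, components=components, covariates=covariates)


# ---------------------------------------------------------------------------
# observation process


def _dyad_log_modifiers(
    ids: list[str],
    mother_of: dict[str, str | None],
    high: np.ndarray,
    cfg: SimulationConfig,
) -> np.ndarray:
    n = len(ids)
    idx = {i: k for k, i in enumerate(ids)}
    mod = np.zeros((n, n))
    for k, i in enumerate(ids):
        m = mother_of.get(i)
        if m is not None and m in idx:  # parent-offspring dyad: r = 0.5
            mod[k, idx[m]] += cfg.kin_dyad_bonus
            mod[idx[m], k] += cfg.kin_dyad_bonus
    mod += cfg.rank_dyad_bonus * high[None, :]
    return mod


def expected_rate_matrix(
    truth: TruthRecord,
    mother_of: dict[str, str | None],
    cfg: SimulationConfig,
    group: str,
    year: int,
) -> tuple[list[str], np.ndarray]:
    """Noise-free expected grooming-rate matrix (s per combined hour).

    Because the realised rate divides observed seconds by the dyad's
    combined hours, its expectation equals ``mu_ij`` independent of the
    effort draws; this is the oracle input for attenuation analyses.
    """
    lat = truth.latents
    cov = truth.covariates
    sel = (lat["group"] == group) & (lat["year"] == year)
    sub = lat[sel].set_index("id")
    csub = cov[(cov["group"] == group) & (cov["year"] == year)].set_index("id")
    ids = sorted(sub.index)
    eg = sub.loc[ids, "eta_give"].to_numpy()
    er = sub.loc[ids, "eta_receive"].to_numpy()
    high = (csub.loc[ids, "rank_class"] == "high").to_numpy().astype(float)
    mod = _dyad_log_modifiers(ids, mother_of, high, cfg)
    mu = cfg.baseline_rate * np.exp(eg[:, None] + er[None, :] + mod)
    np.fill_diagonal(mu, 0.0)
    return ids, mu


def simulate_grooming(
    truth: TruthRecord,
    pop: _Population,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Focal-sampled grooming seconds and observation effort.

    Per-monkey yearly effort is Normal(5.70, 1.98) hours truncated below
    at 1 h. Observed seconds per ordered dyad are negative-binomial
    (Poisson when ``bouts_dispersion`` is None) with mean
    ``mu_ij * (h_i + h_j)``.
    """
    grooming_rows = []
    effort_rows = []
    lo = (cfg.focal_hours_min - cfg.focal_hours_mean) / cfg.focal_hours_sd
    for (group, year) in sorted(pop.rosters):
        ids, mu = expected_rate_matrix(truth, pop.mother_of, cfg, group, year)
        n = len(ids)
        h = truncnorm.rvs(
            lo, np.inf, loc=cfg.focal_hours_mean, scale=cfg.focal_hours_sd,
            size=n, random_state=rng,
        )
        mean_sec = mu * (h[:, None] + h[None, :])
        if cfg.bouts_dispersion:
            k = cfg.bouts_dispersion
            p = k / (k + mean_sec)
            sec = rng.negative_binomial(k, np.where(mean_sec > 0, p, 1.0))
        else:
            sec = rng.poisson(mean_sec)
        np.fill_diagonal(sec, 0)
        nz = np.nonzero(sec)
        for a, b in zip(*nz):
            grooming_rows.append({
                "actor": ids[a], "recipient": ids[b], "group": group,
                "year": year, "seconds": float(sec[a, b]),
            })
        for i, hi in zip(ids, h):
            effort_rows.append({
                "id": i, "group": group, "year": year,
                "hours_observed": float(hi),
            })
        # ineligible extras are observed too; their rows are later dropped
        # by the eligibility filters
        for i in pop.extras.get((group, year), []):
            effort_rows.append({
                "id": i, "group": group, "year": year,
                "hours_observed": float(
                    truncnorm.rvs(lo, np.inf, loc=cfg.focal_hours_mean,
                                  scale=cfg.focal_hours_sd, random_state=rng)
                ),
            })
            if n and cfg.baseline_rate > 0:
                partner = ids[int(rng.integers(n))]
                secs = int(rng.poisson(60))
                if secs > 0:
                    grooming_rows.append({
                        "actor": i, "recipient": partner, "group": group,
                        "year": year, "seconds": float(secs),
                    })
    return pd.DataFrame(
        grooming_rows, columns=["actor", "recipient", "group", "year", "seconds"]
    ), pd.DataFrame(
        effort_rows, columns=["id", "group", "year", "hours_observed"]
    )


def simulate_agonistic(
    pop: _Population, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Win–loss records from the latent hierarchy.

    For every same-sex dyad in a group-year the number of bouts is Poisson
    and the higher-ranked individual wins each bout with probability
    ``1 - upset_probability``.
    """
    info = {r["id"]: r for r in pop.individuals}
    rows = []
    for (group, year), roster in sorted(pop.rosters.items()):
        for sex in ("F", "M"):
            same = sorted(
                (i for i in roster if info[i]["sex"] == sex),
                key=lambda i: -pop.dominance[i],
            )
            for ki in range(len(same)):
                for kj in range(ki + 1, len(same)):
                    bouts = int(rng.poisson(cfg.mean_bouts_agonistic))
                    if bouts == 0:
                        continue
                    wins_hi = int(rng.binomial(bouts, 1 - cfg.upset_probability))
                    hi, lo_ = same[ki], same[kj]
                    if wins_hi > 0:
                        rows.append({"winner": hi, "loser": lo_, "group": group,
                                     "year": year, "count": wins_hi})
                    if bouts - wins_hi > 0:
                        rows.append({"winner": lo_, "loser": hi, "group": group,
                                     "year": year, "count": bouts - wins_hi})
    return pd.DataFrame(rows, columns=["winner", "loser", "group", "year", "count"])


def generate_dataset(cfg: SimulationConfig | None = None) -> SimulatedData:
    """Run the whole generator: demography, latents, grooming, agonism.

    Bit-exactly reproducible for a fixed ``cfg.seed``.
    """
    cfg = cfg or default_config()
    rng = np.random.default_rng(cfg.seed)
    pop, covariates = simulate_population(cfg, rng)
    truth = simulate_latents(covariates, pop.mother_of, cfg, rng)
    grooming, effort = simulate_grooming(truth, pop, cfg, rng)
    agonistic = simulate_agonistic(pop, cfg, rng)

    individuals = pd.DataFrame(pop.individuals)[
        ["id", "sex", "birth_year", "mother_id", "natal_group"]
    ]
    membership = pd.DataFrame(pop.membership)
    pedigree = individuals[["id", "mother_id"]].copy()
    pedigree["father_id"] = pd.NA
    tables = validate_tables(DemographyTables(
        individuals=individuals,
        membership=membership,
        grooming=grooming,
        effort=effort,
        agonistic=agonistic,
        pedigree=pedigree,
    ))
    return SimulatedData(config=cfg, tables=tables, truth=truth)
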