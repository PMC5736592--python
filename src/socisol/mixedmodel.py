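"""Bayesian Gaussian mixed models with multiple random intercepts.

The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k I),  e ~ N(0, sigma2_e I)

fit by a conjugate Gibbs sampler: multivariate-normal full conditionals
for ``beta`` and each level vector ``u_k``, inverse-gamma full
conditionals for every variance. Priors are weakly informative by
default — inverse-gamma(0.001, 0.001) on each variance and N(0, 1e8) on
fixed effects — in the style of the MCMC mixed-model software commonly
used for repeatability studies.

Reported quantities per fit:

- fixed effects: posterior mean, equal-tailed 95% credible interval and
  an MCMC p-value (twice the smaller posterior tail probability of zero,
  floored at 1 / n_draws);
- variance components: posterior mean and 95% CI of each sigma2 and of
  its *proportion* of total variance (component variance over the sum of
  all component variances plus residual). The proportion for the animal
  (individual identity) component is the repeatability R.

Components whose posterior-mean proportion exceeds 10% but whose lower
credible limit falls below 0.01 are flagged "non-robust": the data cannot
rule out a negligibly small contribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "MixedModelSpec",
    "MCMCConfig",
    "MixedModelFit",
    "gibbs_fit",
    "variance_proportions",
    "pmcmc",
    "interaction_screen",
    "potential_scale_reduction",
    "anova_repeatability",
]

#: Mean proportion above which a component is considered noteworthy.
NONROBUST_MEAN = 0.10
#: Lower-CI limit below which a noteworthy component is flagged non-robust.
NONROBUST_LOWER = 0.01

_CODINGS = {"sex": {"F": 0.0, "M": 1.0}, "rank_class": {"low": 0.0, "high": 1.0}}


@dataclass
class MixedModelSpec:
    """What to fit: response, fixed effects, random intercepts, subset."""

    response: str
    fixed_effects: list[str] = field(default_factory=list)
    random_effects: list[str] = field(default_factory=list)
    subset: str = "all"  # all | females_only | males_only

    def __post_init__(self) -> None:
        if self.subset not in {"all", "females_only", "males_only"}:
            raise ValueError(f"unknown subset {self.subset!r}")


@dataclass
class MCMCConfig:
    """Chain settings; defaults give 1,000 retained draws."""

    n_iterations: int = 13_000
    burn_in: int = 3_000
    thin: int = 10
    seed: int = 0
    variance_prior: tuple[float, float] = (0.001, 0.001)  # IG(shape, scale)
    fixed_prior_variance: float = 1e8

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class MixedModelFit:
    """Posterior draws plus tidy summaries for one model."""

    spec: MixedModelSpec
    config: MCMCConfig
    n_obs: int
    n_dropped: int
    beta_names: list[str]
    beta_draws: np.ndarray  # (draws, p)
    sigma2_draws: dict[str, np.ndarray]  # component -> (draws,), incl. "residual"
    dropped_components: list[str] = field(default_factory=list)

    @property
    def fixed_effects(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.beta_names):
            d = self.beta_draws[:, j]
            rows.append({
                "term": name,
                "mean": d.mean(),
                "lower": np.percentile(d, 2.5),
                "upper": np.percentile(d, 97.5),
                "pmcmc": pmcmc(d),
            })
        return pd.DataFrame(rows)

    @property
    def proportions(self) -> pd.DataFrame:
        return variance_proportions(self.sigma2_draws)

    @property
    def variance_components(self) -> pd.DataFrame:
        rows = []
        for name, d in self.sigma2_draws.items():
            rows.append({
                "component": name,
                "mean": d.mean(),
                "lower": np.percentile(d, 2.5),
                "upper": np.percentile(d, 97.5),
            })
        return pd.DataFrame(rows)

    @property
    def repeatability(self) -> float:
        """Posterior-mean proportion of variance due to individual identity."""
        props = self.proportions.set_index("component")
        if "animal" not in props.index:
            raise KeyError("no 'animal' random effect in this model")
        return float(props.loc["animal", "mean"])

    def to_dict(self) -> dict:
        return {
            "spec": {
                "response": self.spec.response,
                "fixed_effects": list(self.spec.fixed_effects),
                "random_effects": list(self.spec.random_effects),
                "subset": self.spec.subset,
            },
            "n_obs": int(self.n_obs),
            "n_dropped": int(self.n_dropped),
            "dropped_components": list(self.dropped_components),
            "fixed_effects": self.fixed_effects.round(6).to_dict("records"),
            "variance_components": self.variance_components.round(6).to_dict("records"),
            "proportions": self.proportions.round(6).to_dict("records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def pmcmc(draws: np.ndarray) -> float:
    """MCMC p-value: twice the smaller tail beyond zero, floored at 1/n."""
    draws = np.asarray(draws, dtype=float)
    n = draws.size
    frac_pos = np.mean(draws > 0)
    frac_neg = np.mean(draws < 0)
    return float(max(2.0 * min(frac_pos, frac_neg), 1.0 / n))


def variance_proportions(
    sigma2_draws: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Draw-wise variance proportions with mean, 95% CI and robustness flag.

    Each component's proportion is its variance divided by the sum over
    all components including the residual, computed per draw and then
    summarised. A component is flagged non-robust when its posterior-mean
    proportion exceeds 0.10 but the lower credible limit is below 0.01.
    """
    names = list(sigma2_draws)
    mat = np.column_stack([np.asarray(sigma2_draws[k], float) for k in names])
    if mat.shape[0] < 500:
        warnings.warn(
            f"only {mat.shape[0]} retained draws; summaries may be unstable"
        )
    total = mat.sum(axis=1)
    props = mat / total[:, None]
    rows = []
    for j, name in enumerate(names):
        p = props[:, j]
        mean, lo, hi = p.mean(), np.percentile(p, 2.5), np.percentile(p, 97.5)
        rows.append({
            "component": name,
            "mean": mean,
            "lower": lo,
            "upper": hi,
            "non_robust": bool(mean > NONROBUST_MEAN and lo < NONROBUST_LOWER),
        })
    return pd.DataFrame(rows)


def _code_column(data: pd.DataFrame, term: str) -> np.ndarray:
    """Numeric design column for a fixed-effect term ('a:b' = interaction)."""
    if ":" in term:
        a, b = term.split(":", 1)
        return _code_column(data, a) * _code_column(data, b)
    col = data[term]
    if term in _CODINGS:
        coded = col.map(_CODINGS[term])
        if coded.isna().any() and not col.isna().all():
            bad = col[coded.isna()].dropna().unique()
            if len(bad):
                raise ValueError(f"{term}: cannot code value(s) {bad.tolist()}")
        return coded.to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def _build_design(
    data: pd.DataFrame, spec: MixedModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, tuple[np.ndarray, int]], int, list[str]]:
    df = data
    if spec.subset == "females_only":
        df = df[df["sex"] == "F"]
    elif spec.subset == "males_only":
        df = df[df["sex"] == "M"]

    cols_needed = [spec.response]
    for t in spec.fixed_effects:
        cols_needed.extend(t.split(":"))
    keep = df.index
    n_before = len(df)
    # drop rows with missing response or missing covariates
    mask = df[spec.response].notna()
    for c in set(cols_needed[1:]):
        mask &= df[c].notna()
    df = df[mask]
    n_dropped = n_before - len(df)
    if len(df) == 0:
        raise ValueError("no usable rows after dropping missing values")

    y = df[spec.response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError(f"non-finite response values in {spec.response!r}")

    X_cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for t in spec.fixed_effects:
        X_cols.append(_code_column(df, t))
        names.append(t)
    X = np.column_stack(X_cols)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in the fixed-effect design")

    z: dict[str, tuple[np.ndarray, int]] = {}
    dropped_components = []
    for comp in spec.random_effects:
        codes, levels = pd.factorize(df[comp].astype(str), sort=True)
        if len(levels) < 2:
            warnings.warn(
                f"random effect {comp!r} has a single level; dropped"
            )
            dropped_components.append(comp)
            continue
        z[comp] = (codes.astype(np.intp), len(levels))
    return y, X, names, z, n_dropped, dropped_components


def _run_gibbs(
    y: np.ndarray,
    X: np.ndarray,
    z: dict[str, tuple[np.ndarray, int]],
    cfg: MCMCConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    n, p = X.shape
    a0, b0 = cfg.variance_prior
    XtX = X.T @ X
    comps = list(z)
    counts = {k: np.bincount(z[k][0], minlength=z[k][1]).astype(float) for k in comps}

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    u = {k: np.zeros(q) for k, (_, q) in z.items()}
    sig2 = {k: max(np.var(y) / (len(z) + 1), 1e-6) for k in comps}
    sig2_e = max(np.var(y) / (len(z) + 1), 1e-6)

    zu = np.zeros(n)
    for k in comps:
        zu += u[k][z[k][0]]

    n_keep = cfg.n_retained
    beta_out = np.empty((n_keep, p))
    sig_out = {k: np.empty(n_keep) for k in comps}
    sig_out["residual"] = np.empty(n_keep)
    kept = 0

    for it in range(cfg.n_iterations):
        # beta | rest
        A = XtX / sig2_e + np.eye(p) / cfg.fixed_prior_variance
        rhs = X.T @ (y - zu) / sig2_e
        cf = cho_factor(A, lower=True)
        mean = cho_solve(cf, rhs)
        L = np.linalg.cholesky(np.linalg.inv(A))
        beta = mean + L @ rng.standard_normal(p)
        xb = X @ beta

        # each u_k | rest
        for k in comps:
            codes, q = z[k]
            zu -= u[k][codes]
            r = y - xb - zu
            sums = np.bincount(codes, weights=r, minlength=q)
            denom = counts[k] + sig2_e / sig2[k]
            mu = sums / denom
            sd = np.sqrt(sig2_e / denom)
            u[k] = mu + sd * rng.standard_normal(q)
            zu += u[k][codes]
            # sigma2_k | u_k
            a_post = a0 + q / 2.0
            b_post = b0 + 0.5 * np.dot(u[k], u[k])
            sig2[k] = b_post / rng.gamma(a_post)

        # residual variance
        e = y - xb - zu
        a_post = a0 + n / 2.0
        b_post = b0 + 0.5 * np.dot(e, e)
        sig2_e = b_post / rng.gamma(a_post)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            beta_out[kept] = beta
            for k in comps:
                sig_out[k][kept] = sig2[k]
            sig_out["residual"][kept] = sig2_e
            kept += 1

    return beta_out[:kept], {k: v[:kept] for k, v in sig_out.items()}


def gibbs_fit(
    data: pd.DataFrame, spec: MixedModelSpec, cfg: MCMCConfig | None = None
) -> MixedModelFit:
    """Fit one Gaussian mixed model by Gibbs sampling.

    *data* is an individual-year table; rows with missing response or
    covariates are dropped (counted in the fit). Categorical covariates
    are coded sex F=0/M=1 and rank_class low=0/high=1; interaction terms
    are written ``"a:b"``. Random-effect columns are treated as grouping
    factors; a factor with a single level is dropped with a warning.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or MCMCConfig()
    y, X, names, z, n_dropped, dropped = _build_design(data, spec)
    rng = np.random.default_rng(cfg.seed)
    beta_draws, sig_draws = _run_gibbs(y, X, z, cfg, rng)
    return MixedModelFit(
        spec=spec,
        config=cfg,
        n_obs=len(y),
        n_dropped=n_dropped,
        beta_names=names,
        beta_draws=beta_draws,
        sigma2_draws=sig_draws,
        dropped_components=dropped,
    )


def interaction_screen(
    data: pd.DataFrame,
    spec: MixedModelSpec,
    cfg: MCMCConfig | None = None,
    alpha: float = 0.05,
) -> MixedModelSpec:
    """Add pairwise fixed-effect interactions that reach pMCMC < alpha.

    Each pairwise interaction among the spec's fixed effects is added to
    the base model one at a time; it is retained in the returned spec only
    when its MCMC p-value falls below *alpha*.
    """
    cfg = cfg or MCMCConfig()
    base_terms = list(spec.fixed_effects)
    kept = []
    for i in range(len(base_terms)):
        for j in range(i + 1, len(base_terms)):
            term = f"{base_terms[i]}:{base_terms[j]}"
            trial = replace(spec, fixed_effects=base_terms + [term])
            fit = gibbs_fit(data, trial, cfg)
            row = fit.fixed_effects.set_index("term")
            if float(row.loc[term, "pmcmc"]) < alpha:
                kept.append(term)
    if not kept:
        return replace(spec, fixed_effects=base_terms)
    return replace(spec, fixed_effects=base_terms + kept)


def potential_scale_reduction(chains: Sequence[np.ndarray]) -> float:
    """Gelman–Rubin potential scale reduction across chains of equal length."""
    chains = [np.asarray(c, float) for c in chains]
    m = len(chains)
    if m < 2:
        raise ValueError("need at least two chains")
    n = min(len(c) for c in chains)
    arr = np.stack([c[:n] for c in chains])
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def anova_repeatability(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA (intraclass correlation) repeatability estimate.

    Moment estimator for possibly unbalanced designs: among-group variance
    ``(MS_A - MS_W) / n0`` with ``n0 = (N - sum n_i^2 / N) / (a - 1)``,
    repeatability = among / (among + within). Negative among-group
    estimates are truncated at zero.
    """
    values = np.asarray(values, float)
    codes, levels = pd.factorize(pd.Series(groups).astype(str), sort=True)
    a = len(levels)
    N = len(values)
    if a < 2 or N <= a:
        raise ValueError("need >= 2 groups and replicate observations")
    counts = np.bincount(codes).astype(float)
    sums = np.bincount(codes, weights=values)
    means = sums / counts
    grand = values.mean()
    ss_a = np.sum(counts * (means - grand) ** 2)
    ss_w = np.sum((values - means[codes]) ** 2)
    ms_a = ss_a / (a - 1)
    ms_w = ss_w / (N - a)
    n0 = (N - np.sum(counts**2) / N) / (a - 1)
    s2_a = max((ms_a - ms_w) / n0, 0.0)
    return float(s2_a / (s2_a + ms_w)) if (s2_a + ms_w) > 0 else 0.0
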