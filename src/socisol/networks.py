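"""Directed weighted grooming networks and social-isolation metrics.

A group-year network has edge weight ``w[i][j]`` equal to the rate (seconds
per hour) at which individual *i* grooms individual *j*; the rate divides
the dyad's total grooming seconds by the dyad's combined observation hours.
Five per-individual metrics quantify social isolation:

- **instrength / outstrength** — column / row sums of ``W``: the rate at
  which grooming is received / given.
- **betweenness** — fractional count of weighted shortest paths through an
  individual (edge length ``1/w``; endpoints excluded; equal-length ties
  split fractionally, Brandes-style).
- **clustering coefficient** — fraction of an individual's partner pairs
  that are themselves connected (partnership = any grooming in either
  direction); undefined (None) below two partners.
- **eigenvector centrality** — principal eigenvector of the symmetrised
  weight matrix ``W + W.T``, unit Euclidean norm, non-negative entries.

Metrics are standardised *within* each group-year (:func:`zscore_within`)
so that isolation is measured relative to an individual's current social
environment rather than on an absolute scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .dataio import GroupYearDataset

__all__ = [
    "GroupYearNetwork",
    "build_rate_matrix",
    "instrength",
    "outstrength",
    "betweenness",
    "clustering_coefficient",
    "eigenvector_centrality",
    "zscore_within",
    "metric_table",
    "METRICS",
]

#: Metric column names, in canonical order.
METRICS = ["instrength", "outstrength", "betweenness", "clustering", "eigenvector"]

#: Relative tolerance used when deciding that two path lengths tie.
_TIE_RTOL = 1e-12


@dataclass
class GroupYearNetwork:
    """Directed grooming-rate network for one group in one year."""

    ids: list[str]
    W: np.ndarray  # n x n, w[i][j] = rate i grooms j (s/h), zero diagonal
    group: str
    year: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise ValueError("weight matrix shape does not match id list")
        if n < 2:
            raise ValueError("a network needs at least 2 individuals")
        if (self.W < 0).any():
            raise ValueError("negative grooming rate")
        if np.diag(self.W).any():
            raise ValueError("nonzero diagonal (self-grooming)")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def index(self, i: str) -> int:
        try:
            return self._index[i]
        except KeyError:
            raise KeyError(f"unknown individual {i!r}") from None


def build_rate_matrix(dataset: GroupYearDataset) -> GroupYearNetwork:
    """Grooming-rate matrix: seconds divided by the dyad's combined hours.

    ``w[i][j] = total_seconds(i grooms j) / (hours_i + hours_j)``. Dyads
    never observed grooming get 0; direction is preserved. Raises if any
    individual lacks an observation-effort record.
    """
    ids = dataset.ids
    missing = [i for i in ids if i not in dataset.hours]
    if missing:
        raise ValueError(f"missing observation effort for {missing[:5]}")
    h = np.array([dataset.hours[i] for i in ids], dtype=float)
    if (h <= 0).any():
        raise ValueError("observation effort must be positive")
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    seconds = np.zeros((n, n))
    for row in dataset.grooming.itertuples(index=False):
        seconds[idx[row.actor], idx[row.recipient]] += row.seconds
    W = seconds / (h[:, None] + h[None, :])
    np.fill_diagonal(W, 0.0)
    return GroupYearNetwork(ids=list(ids), W=W, group=dataset.group, year=dataset.year)


def instrength(net: GroupYearNetwork, i: str | None = None):
    """Rate of grooming received (column sum). Dict over ids when *i* is None."""
    col = net.W.sum(axis=0)
    if i is None:
        return dict(zip(net.ids, col))
    return float(col[net.index(i)])


def outstrength(net: GroupYearNetwork, i: str | None = None):
    """Rate of grooming given (row sum). Dict over ids when *i* is None."""
    row = net.W.sum(axis=1)
    if i is None:
        return dict(zip(net.ids, row))
    return float(row[net.index(i)])


def _shortest_path_dag(L: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Boolean matrix: edge (u, v) lies on some shortest path from the source."""
    with np.errstate(invalid="ignore"):
        target = d[:, None] + L
        finite = np.isfinite(target) & np.isfinite(d[None, :])
        tol = _TIE_RTOL * np.maximum(1.0, np.abs(d[None, :]))
        gap = np.where(finite, np.abs(np.where(finite, target, 0.0) - d[None, :]), np.inf)
    return finite & (gap <= tol)


def betweenness(net: GroupYearNetwork) -> dict[str, float]:
    """Weighted directed betweenness with fractional tie handling.

    Edges with rate ``w > 0`` get length ``1/w`` (absent edges are absent;
    no connection). For every ordered source–target pair the shortest paths
    by total length are found and each interior individual receives the
    fraction of those paths passing through it (Brandes accumulation);
    endpoints are excluded and disconnected pairs contribute nothing. Path
    lengths within a relative tolerance of 1e-12 count as tied.
    """
    W = net.W
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, np.inf)
    rows, cols = np.nonzero(np.isfinite(L))
    graph = csr_matrix((L[rows, cols], (rows, cols)), shape=(n, n))
    dist = _sp_dijkstra(graph, directed=True, indices=np.arange(n))

    bc = np.zeros(n)
    for s in range(n):
        d = dist[s]
        reach = np.isfinite(d)
        if reach.sum() <= 1:
            continue
        dag = _shortest_path_dag(L, d)
        order = np.argsort(d[reach], kind="stable")
        nodes = np.nonzero(reach)[0][order]  # increasing distance from s

        sigma = np.zeros(n)
        sigma[s] = 1.0
        for v in nodes:
            if v == s:
                continue
            preds = np.nonzero(dag[:, v])[0]
            sigma[v] = sigma[preds].sum()

        delta = np.zeros(n)
        for v in nodes[::-1]:
            succs = np.nonzero(dag[v])[0]
            if succs.size:
                delta[v] = np.sum(sigma[v] / sigma[succs] * (1.0 + delta[succs]))
            if v != s:
                bc[v] += delta[v]
    return dict(zip(net.ids, bc))


def _partner_matrix(W: np.ndarray) -> np.ndarray:
    A = (W > 0) | (W.T > 0)
    np.fill_diagonal(A, False)
    return A


def clustering_coefficient(net: GroupYearNetwork, i: str | None = None):
    """Fraction of an individual's partner pairs that are partners themselves.

    Partnership is any grooming in either direction. With fewer than two
    distinct partners the coefficient is undefined and ``None`` is returned
    (such individuals are excluded from standardisation downstream).
    """
    A = _partner_matrix(net.W)

    def one(k: int):
        nbrs = np.nonzero(A[k])[0]
        m = len(nbrs)
        if m < 2:
            return None
        sub = A[np.ix_(nbrs, nbrs)]
        links = np.triu(sub, 1).sum()
        return float(links) / (m * (m - 1) / 2)

    if i is None:
        return {idv: one(k) for k, idv in enumerate(net.ids)}
    return one(net.index(i))


def eigenvector_centrality(
    net: GroupYearNetwork, tol: float = 1e-10, max_iter: int = 100_000
) -> dict[str, float]:
    """Principal eigenvector of the symmetrised weight matrix.

    Power iteration on ``S = W + W.T`` (shifted by its max row sum to
    guarantee convergence on the dominant eigenpair), run to relative
    tolerance *tol*, entries non-negative, scaled to unit Euclidean norm.
    An empty network (no grooming at all) yields all-zero centralities
    with a warning.
    """
    S = net.W + net.W.T
    n = S.shape[0]
    if not S.any():
        warnings.warn("empty network: eigenvector centralities are all zero")
        return dict(zip(net.ids, np.zeros(n)))
    shift = S.sum(axis=1).max()  # makes S + shift*I PSD; eigenvectors unchanged
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nv = S @ v + shift * v
        nv /= np.linalg.norm(nv)
        if np.linalg.norm(nv - v) <= tol * np.linalg.norm(nv):
            v = nv
            break
        v = nv
    v = np.abs(v)
    v /= np.linalg.norm(v)
    return dict(zip(net.ids, v))


def zscore_within(values: Mapping[str, float | None]) -> dict[str, float | None]:
    """Standardise one metric within a single group-year.

    ``z = (x - mean) / SD`` over the non-null entries, with the sample SD
    (n-1 denominator). Null entries stay null. When fewer than two non-null
    values exist or the spread is zero, all non-null z-scores are set to 0
    and a warning is issued (the individuals stay in the panel).
    """
    keys = list(values)
    x = np.array(
        [np.nan if values[k] is None else float(values[k]) for k in keys]
    )
    ok = ~np.isnan(x)
    if ok.sum() < 2 or np.nanstd(x[ok], ddof=1) == 0:
        warnings.warn("degenerate spread in group-year metric; z-scores set to 0")
        z = np.where(ok, 0.0, np.nan)
    else:
        mu = x[ok].mean()
        sd = x[ok].std(ddof=1)
        z = (x - mu) / sd
    return {k: (None if np.isnan(z[j]) else float(z[j])) for j, k in enumerate(keys)}


def metric_table(networks: Iterable[GroupYearNetwork]) -> pd.DataFrame:
    """Tidy per-individual-year table of the five metrics and their z-scores.

    One row per (id, group, year); ``clustering`` is NaN for individuals
    with fewer than two partners and its z-score stays NaN for them.
    """
    rows = []
    for net in networks:
        raw = {
            "instrength": instrength(net),
            "outstrength": outstrength(net),
            "betweenness": betweenness(net),
            "clustering": clustering_coefficient(net),
            "eigenvector": eigenvector_centrality(net),
        }
        zs = {m: zscore_within(raw[m]) for m in METRICS}
        for i in net.ids:
            rec = {"id": i, "group": net.group, "year": net.year}
            for m in METRICS:
                v = raw[m][i]
                rec[m] = np.nan if v is None else v
                zv = zs[m][i]
                rec[f"z_{m}"] = np.nan if zv is None else zv
            rows.append(rec)
    return pd.DataFrame(rows)
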