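"""Rank-correlation comparison of indices and the Erdős–Rényi null model.

Observed networks are compared against G(N, p) random graphs matched to
their size: p = L / ((N² − N)/2), the density of the observed network.  For
each replicate every structural index is recomputed and all pairwise
Spearman rank correlations are taken; the ensemble yields a mean and a 95%
percentile confidence interval per index pair.  In structured (e.g.
biological) networks the observed correlations fall below the null means —
different centralities capture genuinely different aspects of topology,
whereas in density-matched random graphs they largely agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .indices import compute_all, index_columns

logger = logging.getLogger("medianet")

__all__ = [
    "NullModelSpec",
    "NullSummary",
    "spearman",
    "correlation_matrix",
    "er_probability",
    "sample_er",
    "randomization_test",
    "index_distributions",
]


def spearman(x, y) -> float:
    """Tie-corrected Spearman rank correlation of two node→value maps.

    Accepts mappings (matched by key) or aligned sequences.  Undefined when
    either input is constant; returned as NaN (missing), never coerced to 0.
    """
    if hasattr(x, "keys") and hasattr(y, "keys"):
        if set(x.keys()) != set(y.keys()):
            raise ValueError("spearman: node sets differ")
        keys = sorted(x.keys())
        xv = np.array([x[k] for k in keys], dtype=float)
        yv = np.array([y[k] for k in keys], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise ValueError("spearman: length mismatch")
    if xv.size < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return float("nan")
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho for every unordered pair of index columns.

    Returns a square symmetric DataFrame (diagonal 1; NaN marks undefined
    pairs).  The layout is independent of node order.
    """
    if len(table) < 3:
        raise ValueError("correlation matrix requires at least 3 nodes")
    cols = list(table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        rho = spearman(table[a].to_numpy(), table[b].to_numpy())
        out.loc[a, b] = out.loc[b, a] = rho
    return out


def upper_triangle(matrix: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangular view (first index column vs the rest) for reporting."""
    cols = list(matrix.columns)
    out = matrix.copy().astype(object)
    for i in range(len(cols)):
        for j in range(i + 1):
            out.iloc[i, j] = ""
    return out.iloc[:-1]


def er_probability(N: int, L: int) -> float:
    """Link probability p = L / ((N² − N)/2) of the matched G(N, p) model."""
    if N < 2:
        raise ValueError("N must be >= 2")
    max_links = N * (N - 1) // 2
    if not 0 <= L <= max_links:
        raise ValueError(f"L={L} outside [0, {max_links}] for a simple graph on N={N}")
    return L / ((N * N - N) / 2)


def sample_er(N: int, p: float, seed: int | None = None) -> nx.Graph:
    """One G(N, p) draw; every node is retained, including isolated ones."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return nx.fast_gnp_random_graph(N, p, seed=seed)


@dataclass
class NullModelSpec:
    """Ensemble specification matched to an observed network's N and L."""

    N: int
    L: int
    reps: int = 1000
    seed: int = 0

    @property
    def p(self) -> float:
        return er_probability(self.N, self.L)

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        er_probability(self.N, self.L)  # validates N, L


@dataclass
class NullSummary:
    """Per index pair: mean and 95% percentile CI over the ensemble."""

    spec: NullModelSpec
    table: pd.DataFrame  # columns: index_a, index_b, mean, ci_low, ci_high, n_used
    replicates: pd.DataFrame | None = None

    def mean(self, index_a: str, index_b: str) -> float:
        t = self.table
        m = t[
            ((t.index_a == index_a) & (t.index_b == index_b))
            | ((t.index_a == index_b) & (t.index_b == index_a))
        ]
        if m.empty:
            raise KeyError(f"no pair ({index_a}, {index_b}) in summary")
        return float(m["mean"].iloc[0])


def _replicate_seeds(seed: int, reps: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(reps, dtype=np.uint32)]


def randomization_test(
    spec: NullModelSpec,
    n: int = 3,
    thresholds=(0.01, 0.005),
    keep_replicates: bool = False,
) -> NullSummary:
    """Erdős–Rényi randomization test on index rank correlations.

    Per replicate: draw G(N, p), compute all indices, take Spearman rho for
    each index pair.  The summary reports the ensemble mean and the 2.5th /
    97.5th percentiles per pair.  Replicates where a pair's correlation is
    undefined (constant index, possible at very small N·p) are excluded
    pair-wise with a logged count; a pair undefined in every replicate is
    flagged missing (NaN mean and CI).
    """
    cols = index_columns(n, thresholds)
    pairs = list(combinations(cols, 2))
    seeds = _replicate_seeds(spec.seed, spec.reps)
    values = np.full((spec.reps, len(pairs)), np.nan)
    for r, s in enumerate(seeds):
        G = sample_er(spec.N, spec.p, seed=s)
        table = compute_all(G, n=n, thresholds=thresholds)
        for c, (a, b) in enumerate(pairs):
            values[r, c] = spearman(table[a].to_numpy(), table[b].to_numpy())
    rows = []
    for c, (a, b) in enumerate(pairs):
        col = values[:, c]
        ok = col[~np.isnan(col)]
        n_missing = spec.reps - ok.size
        if n_missing:
            logger.info(
                "randomization_test: pair (%s, %s): %d replicate(s) undefined, "
                "excluded pair-wise", a, b, n_missing,
            )
        if ok.size == 0:
            rows.append(
                dict(index_a=a, index_b=b, mean=np.nan, ci_low=np.nan,
                     ci_high=np.nan, n_used=0)
            )
            continue
        lo, hi = (
            np.percentile(ok, [2.5, 97.5]) if ok.size >= 2 else (ok[0], ok[0])
        )
        rows.append(
            dict(
                index_a=a,
                index_b=b,
                mean=float(ok.mean()),
                ci_low=float(lo),
                ci_high=float(hi),
                n_used=int(ok.size),
            )
        )
    summary = NullSummary(spec=spec, table=pd.DataFrame(rows))
    if keep_replicates:
        summary.replicates = pd.DataFrame(
            values, columns=[f"{a}|{b}" for a, b in pairs]
        )
    return summary


def index_distributions(table: pd.DataFrame, bins: int = 20) -> dict:
    """Histogram (counts, bin edges) per index column; counts sum to N."""
    if table.empty:
        raise ValueError("index table is empty")
    out = {}
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        counts, edges = np.histogram(vals, bins=bins)
        out[col] = (counts, edges)
    return out
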