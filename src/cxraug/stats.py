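"""Non-parametric comparison of model configurations.

The comparison protocol: per evaluation metric, a tie-corrected
Kruskal–Wallis test across the k model configurations (each contributing
one value per pathology class row, the aggregate ``all`` row included);
where the omnibus test is significant, a Nemenyi post hoc locates the
differing pairs.

Two Nemenyi flavors are provided. The default ``block`` variant ranks the
k models within each row (the Friedman-aligned Nemenyi): mean rank
differences are referred to the studentized-range distribution via
q = |R̄_i − R̄_j| / sqrt(k(k+1)/(6n)), p = P(Q_{k,∞} > q·√2). The
``ranksum`` variant pools all observations, ranks them globally, and
compares tie-corrected mean-rank differences the same way. Only the block
variant reproduces published pairwise tables for this protocol; the
rank-sum variant is what a literal reading of "post hoc after
Kruskal–Wallis" would give, and is kept for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Metrics with packaged reference tables (four model configurations × the
#: aggregate row plus eight pathology classes).
REFERENCE_METRICS = ("precision", "recall", "f1", "map50", "map50_95")


@dataclass(frozen=True)
class KruskalResult:
    """Tie-corrected Kruskal–Wallis H statistic and chi-square p-value."""

    H: float
    p: float
    df: int


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis test over k groups.

    All N values are pooled and average-ranked; with R_i the rank sum of
    group i of size n_i,

        H = [ 12/(N(N+1)) · Σ R_i²/n_i − 3(N+1) ] / C,
        C = 1 − Σ(t³ − t)/(N³ − N)  over tie groups of size t,

    and p is the chi-square survival probability at H with k−1 degrees of
    freedom. When every value is identical (C = 0) H is defined as 0 with
    p = 1 and a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    n = np.array([len(g) for g in groups])
    N = int(pooled.size)
    ranks = sps.rankdata(pooled)
    # tie correction over pooled tie-group sizes
    _, counts = np.unique(pooled, return_counts=True)
    C = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    if C == 0.0:
        warnings.warn("all observations identical: H defined as 0, p = 1")
        return KruskalResult(0.0, 1.0, k - 1)
    bounds = np.cumsum(n)[:-1]
    rank_sums = np.array([g.sum() for g in np.split(ranks, bounds)])
    H = (12.0 / (N * (N + 1)) * np.sum(rank_sums**2 / n) - 3.0 * (N + 1)) / C
    p = float(sps.chi2.sf(H, df=k - 1))
    return KruskalResult(float(H), p, k - 1)


def studentized_range_sf(q: float, k: int) -> float:
    """Upper tail of the studentized range with k groups, infinite df."""
    return float(sps.studentized_range.sf(q, k, np.inf))


def nemenyi_posthoc(table: pd.DataFrame, method: str = "block") -> pd.DataFrame:
    """Pairwise Nemenyi p-values for the models in ``table``'s columns.

    ``table`` is a rows × models grid of one metric (rows are blocks —
    pathology classes plus the aggregate row). Returns a symmetric k×k
    p-value matrix with unit diagonal. ``method`` selects the ``block``
    (within-row ranking, studentized range) or ``ranksum`` (pooled global
    ranking) variant; see the module docstring.
    """
    values = table.to_numpy(dtype=float)
    n, k = values.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 models (columns) and 2 rows")
    if method == "block":
        ranks = np.apply_along_axis(sps.rankdata, 1, values)
        mean_ranks = ranks.mean(axis=0)
        se = np.sqrt(k * (k + 1) / (6.0 * n))
    elif method == "ranksum":
        pooled_ranks = sps.rankdata(values.ravel()).reshape(values.shape)
        mean_ranks = pooled_ranks.mean(axis=0)
        N = n * k
        _, counts = np.unique(values.ravel(), return_counts=True)
        tie = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
        se = np.sqrt(tie * (N * (N + 1) / 12.0) * (2.0 / n))
    else:
        raise ValueError("method must be 'block' or 'ranksum'")
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if se == 0:
                p = 1.0
            else:
                q = abs(mean_ranks[i] - mean_ranks[j]) / se
                p = studentized_range_sf(q * np.sqrt(2.0), k)
            pvals[i, j] = pvals[j, i] = min(1.0, p)
    labels = list(table.columns)
    return pd.DataFrame(pvals, index=labels, columns=labels)


@dataclass
class ComparisonReport:
    """Omnibus and post hoc results across metrics."""

    kruskal: dict[str, KruskalResult]
    nemenyi: dict[str, pd.DataFrame]
    significant_pairs: dict[str, list[tuple[str, str, float]]]
    alpha: float


def compare_models(
    tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    posthoc: str = "block",
) -> ComparisonReport:
    """Run the full comparison protocol over named metric tables.

    Each table is rows × models of one metric; all tables must share row
    and column labels. Each model's column is one Kruskal–Wallis group.
    The Nemenyi post hoc runs for every metric whose omnibus p < alpha, and
    pairs with post hoc p < alpha are flagged.
    """
    tables = dict(tables)
    ref = next(iter(tables.values()))
    for name, tab in tables.items():
        if list(tab.index) != list(ref.index) or list(tab.columns) != list(ref.columns):
            raise ValueError(f"table {name!r} has mismatched row/column labels")
    kw: dict[str, KruskalResult] = {}
    nem: dict[str, pd.DataFrame] = {}
    pairs: dict[str, list[tuple[str, str, float]]] = {}
    for name, tab in tables.items():
        kw[name] = kruskal_wallis([tab[c].to_numpy() for c in tab.columns])
        if kw[name].p < alpha:
            grid = nemenyi_posthoc(tab, method=posthoc)
            nem[name] = grid
            cols = list(grid.columns)
            pairs[name] = [
                (cols[i], cols[j], float(grid.iloc[i, j]))
                for i in range(len(cols))
                for j in range(i + 1, len(cols))
                if grid.iloc[i, j] < alpha
            ]
    return ComparisonReport(kw, nem, pairs, alpha)


def load_reference_table(metric: str) -> pd.DataFrame:
    """Load a packaged reference metric table (rows × four models).

    These are published benchmark results of the four augmentation
    scenarios on expert-annotated chest radiographs, shipped verbatim as
    the inputs to the statistical comparison. Rows: the aggregate ``all``
    plus eight abnormality classes; columns: model1..model4.
    """
    if metric not in REFERENCE_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {REFERENCE_METRICS}")
    path = resources.files("cxraug").joinpath(f"data/reference_metrics/{metric}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, index_col=0)


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """All packaged reference metric tables keyed by metric name."""
    return {m: load_reference_table(m) for m in REFERENCE_METRICS}
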