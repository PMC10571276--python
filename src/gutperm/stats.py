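"""Nonparametric statistics for comparing compound sets.

Four tools are provided:

* :func:`cles` — the common-language effect size, the probability that a
  random observation from the first sample exceeds one from the second,
  ties counted half.
* :func:`kruskal_conover` — Kruskal–Wallis omnibus test with, for more than
  two groups, the Conover–Iman all-pairs post-hoc on tie-corrected pooled
  ranks, plus a CLES matrix for the direction of each contrast.
* :func:`mannwhitney_bh` — a grid of two-group Mann–Whitney tests (e.g. one
  cell per chemical class × property) corrected jointly with
  Benjamini–Hochberg, direction from CLES against 0.5.
* :func:`contingency_posthoc` — adjusted (standardized) residuals of a
  contingency table with a cell-wise exact post-hoc: each cell is collapsed
  to a 2×2 table (cell vs rest of row / rest of column) and tested with the
  two-sided Fisher exact test; significance after Bonferroni (default) or
  Benjamini–Hochberg correction across all cells, direction from the
  residual sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------


def cles(x: Sequence[float], y: Sequence[float]) -> float:
    """Common-language effect size P(X > Y) + 0.5 P(X = Y).

    Values above 0.5 mean the first sample is shifted to larger values.
    Satisfies cles(x, y) + cles(y, x) == 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cles requires two non-empty samples")
    diff = x[:, None] - y[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / diff.size)


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Conover post-hoc
# ---------------------------------------------------------------------------


@dataclass
class GroupComparisonResult:
    omnibus_p: float
    omnibus_stat: float
    pairwise_p: Optional[np.ndarray]  # raw two-sided Conover p, k x k
    cles: np.ndarray  # cles(group_i, group_j), k x k
    adjusted_p: Optional[np.ndarray]  # BH-adjusted pairwise p
    method: str = "kruskal-conover"


def _conover_pairwise(groups: list[np.ndarray], h_stat: float) -> np.ndarray:
    """Conover–Iman all-pairs t statistics on tie-corrected pooled ranks.

    Uses the pooled-rank variance S^2 and the chi-square-adjusted scale
    (N - 1 - H)/(N - k); two-sided p from Student's t with N - k df.
    """
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    splits = np.cumsum(sizes)[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = np.array([r.mean() for r in group_ranks])
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    scale = s2 * (n - 1 - h_stat) / (n - k)
    df = n - k
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                pij = 1.0
            else:
                t = (mean_ranks[i] - mean_ranks[j]) / se
                pij = 2.0 * sps.t.sf(abs(t), df)
            p[i, j] = p[j, i] = min(1.0, pij)
    return p


def kruskal_conover(groups: Sequence[Sequence[float]]) -> GroupComparisonResult:
    """Kruskal–Wallis omnibus + (for >2 groups) Conover all-pairs post-hoc."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    h, p = sps.kruskal(*arrays)
    k = len(arrays)
    cles_mat = np.full((k, k), 0.5)
    for i in range(k):
        for j in range(k):
            if i != j:
                cles_mat[i, j] = cles(arrays[i], arrays[j])
    if k > 2:
        pw = _conover_pairwise(arrays, h)
        iu = np.triu_indices(k, 1)
        adj = np.ones((k, k))
        adj_flat = multipletests(pw[iu], method="fdr_bh")[1]
        adj[iu] = adj_flat
        adj.T[iu] = adj_flat
    else:
        pw = None
        adj = None
    return GroupComparisonResult(
        omnibus_p=float(p), omnibus_stat=float(h), pairwise_p=pw, cles=cles_mat, adjusted_p=adj
    )


# ---------------------------------------------------------------------------
# Mann–Whitney grid with BH correction
# ---------------------------------------------------------------------------


def mannwhitney_bh(
    cells: dict[tuple[str, str], tuple[Sequence[float], Sequence[float]]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Grid of two-group Mann–Whitney tests with joint BH correction.

    ``cells`` maps (row label, column label) — e.g. (chemical class,
    property) — to the two samples compared in that cell. Cells where either
    sample is empty are marked ``not_tested`` and excluded from the
    correction family. Direction: ``higher`` when CLES(first, second) > 0.5
    and significant, ``lower`` when < 0.5 and significant, else ``ns``.

    Returns a tidy frame with columns row, col, p, adjusted_p, cles, call.
    """
    rows = []
    for (r, c), (a, b) in cells.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            rows.append((r, c, np.nan, np.nan, np.nan, "not_tested"))
            continue
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append((r, c, p, np.nan, cles(a, b), "ns"))
    df = pd.DataFrame(rows, columns=["row", "col", "p", "adjusted_p", "cles", "call"])
    tested = df["p"].notna()
    if tested.any():
        df.loc[tested, "adjusted_p"] = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
        sig = tested & (df["adjusted_p"] < alpha)
        df.loc[sig & (df["cles"] > 0.5), "call"] = "higher"
        df.loc[sig & (df["cles"] < 0.5), "call"] = "lower"
    return df


# ---------------------------------------------------------------------------
# Contingency-table post-hoc
# ---------------------------------------------------------------------------


class Direction(str, Enum):
    OVER = "over"
    UNDER = "under"
    NONE = "none"


@dataclass
class ContingencyPosthocResult:
    observed: np.ndarray
    expected: np.ndarray
    adjusted_residuals: np.ndarray
    cell_pvalues: np.ndarray
    significant: np.ndarray  # bool, after correction
    direction: np.ndarray  # object array of Direction
    testable: np.ndarray  # bool; False where a margin is zero
    alpha: float
    correction: str

    def to_frame(
        self, row_labels: Sequence[str] | None = None, col_labels: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Tidy per-cell table suitable for heatmap plotting."""
        nr, nc = self.observed.shape
        row_labels = list(row_labels) if row_labels is not None else [str(i) for i in range(nr)]
        col_labels = list(col_labels) if col_labels is not None else [str(j) for j in range(nc)]
        rows = []
        for i in range(nr):
            for j in range(nc):
                rows.append(
                    (
                        row_labels[i],
                        col_labels[j],
                        int(self.observed[i, j]),
                        self.expected[i, j],
                        self.adjusted_residuals[i, j],
                        self.cell_pvalues[i, j],
                        bool(self.significant[i, j]),
                        self.direction[i, j].value,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["row", "col", "observed", "expected", "residual", "p", "significant", "direction"],
        )


def adjusted_residuals(observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected counts and adjusted standardized residuals of a table.

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - rowsum_i/N)(1 - colsum_j/N)).
    Cells in a zero margin get residual 0 (and are flagged untestable by the
    caller).
    """
    obs = np.asarray(observed, dtype=float)
    n = obs.sum()
    rowsum = obs.sum(axis=1, keepdims=True)
    colsum = obs.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(expected * (1 - rowsum / n) * (1 - colsum / n))
        resid = np.where(denom > 0, (obs - expected) / np.where(denom > 0, denom, 1.0), 0.0)
    return expected, resid


def _fisher_cell_p(obs: np.ndarray, i: int, j: int) -> float:
    """Two-sided Fisher exact p of the 2x2 collapse of cell (i, j) vs rest."""
    a = obs[i, j]
    b = obs[i, :].sum() - a
    c = obs[:, j].sum() - a
    d = obs.sum() - a - b - c
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def contingency_posthoc(
    observed,
    alpha: float = DEFAULT_ALPHA,
    correction: str = "bonferroni",
) -> ContingencyPosthocResult:
    """Cell-wise post-hoc of an R×C contingency table.

    See the module docstring; the correction family is all R·C cells of the
    analyzed table. Cells lying in a zero row or column margin are flagged
    untestable (p = NaN, never significant).
    """
    obs = np.asarray(observed)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(obs < 0) or obs.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    obs = obs.astype(np.int64)
    nr, nc = obs.shape
    expected, resid = adjusted_residuals(obs)
    testable = (obs.sum(axis=1, keepdims=True) > 0) & (obs.sum(axis=0, keepdims=True) > 0)
    pvals = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            if testable[i, j]:
                pvals[i, j] = _fisher_cell_p(obs, i, j)
    flat = pvals[testable]
    method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
    # family size = all cells of the table, untestable ones counted as p=1
    full = np.ones(nr * nc)
    full[testable.ravel()] = flat
    rejected = multipletests(full, alpha=alpha, method=method)[0]
    significant = rejected.reshape(nr, nc) & testable
    direction = np.empty((nr, nc), dtype=object)
    direction[:] = Direction.NONE
    direction[significant & (resid > 0)] = Direction.OVER
    direction[significant & (resid < 0)] = Direction.UNDER
    return ContingencyPosthocResult(
        observed=obs,
        expected=expected,
        adjusted_residuals=resid,
        cell_pvalues=pvals,
        significant=significant,
        direction=direction,
        testable=testable,
        alpha=alpha,
        correction=correction,
    )
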