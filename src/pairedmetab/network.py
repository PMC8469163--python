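"""Paired univariate tests and differential correlation networks.

Three complementary views of the same paired table:

* a classical paired t-test per metabolite (one-sample t on the
  within-animal differences, two-sided, no multiple-testing correction by
  default to match raw-p reporting conventions in small-n metabolomics);
* per-condition Pearson correlation networks, keeping edges whose
  correlation is significant at ``alpha`` under the t-transform
  t = r sqrt((n-2)/(1-r^2)), df = n-2;
* the correlation-shift criterion: a metabolite pair whose correlation
  changes by more than a threshold (default 1, e.g. +0.78 before vs -0.82
  after) is flagged as rewired, and every metabolite in at least one
  flagged pair is a "discrepant" metabolite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConcentrationTable, Condition, paired_differences

__all__ = [
    "PairedTestResult",
    "CorrelationNetwork",
    "CorrelationShift",
    "paired_t_tests",
    "pairwise_correlations",
    "correlation_network",
    "correlation_shifts",
]


@dataclass
class PairedTestResult:
    table: pd.DataFrame  # per metabolite: t, p, mean_diff, direction

    def significant(self, alpha: float = 0.05, strict: bool = True) -> list[str]:
        p = self.table["p"]
        mask = (p < alpha) if strict else (p <= alpha)
        return list(self.table.index[mask.fillna(False)])


def paired_t_tests(
    table: ConcentrationTable, adjust: str | None = None
) -> PairedTestResult:
    """Paired t-test per metabolite on (AFTER - BEFORE) differences.

    Degenerate cases never crash: all-zero differences give t = 0, p = 1;
    constant non-zero differences (sd = 0) give p = NA with a warning.
    ``adjust='fdr_bh'`` adds a Benjamini-Hochberg column (off by default).
    """
    diffs = paired_differences(table)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 animals")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.full(len(mean), np.nan)
    p = np.full(len(mean), np.nan)
    degenerate = []
    for j, m in enumerate(diffs.columns):
        if sd.iloc[j] == 0:
            if mean.iloc[j] == 0:
                t[j], p[j] = 0.0, 1.0
            else:
                degenerate.append(m)
        else:
            res = stats.ttest_1samp(diffs[m], 0.0)
            t[j], p[j] = float(res.statistic), float(res.pvalue)
    if degenerate:
        warnings.warn(
            f"zero-variance non-zero differences for {degenerate}; p set to NA",
            stacklevel=2,
        )
    direction = np.where(mean > 0, "up", np.where(mean < 0, "down", "flat"))
    out = pd.DataFrame(
        {"t": t, "p": p, "mean_diff": mean.to_numpy(), "direction": direction},
        index=diffs.columns,
    )
    if adjust == "fdr_bh":
        ok = ~np.isnan(p)
        adj = np.full(len(p), np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(p[ok], method="bh")
        out["p_adj"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return PairedTestResult(out)


@dataclass
class CorrelationNetwork:
    condition: Condition
    edges: pd.DataFrame      # metabolite_i, metabolite_j, r, p (p < alpha only)
    all_pairs: pd.DataFrame  # every i < j pair with r, p (NaN r for constants)
    alpha: float
    n_samples: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_positive(self) -> int:
        return int((self.edges["r"] > 0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.edges["r"] < 0).sum())

    def to_graph(self):
        """Edges as a networkx Graph (for GraphML export etc.)."""
        import networkx as nx

        g = nx.Graph(condition=self.condition.value, alpha=self.alpha)
        for row in self.edges.itertuples():
            g.add_edge(row.metabolite_i, row.metabolite_j, r=row.r, p=row.p)
        return g


def _correlation_pairs(data: pd.DataFrame) -> pd.DataFrame:
    """All unordered metabolite pairs with Pearson r and two-sided p."""
    X = data.to_numpy(dtype=float)
    n = X.shape[0]
    sds = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    rows = []
    for i, j in itertools.combinations(range(X.shape[1]), 2):
        if sds[i] == 0 or sds[j] == 0:
            r, p = np.nan, np.nan
        else:
            r = float(np.clip(R[i, j], -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            p = float(p)
        rows.append((data.columns[i], data.columns[j], r, p))
    return pd.DataFrame(rows, columns=["metabolite_i", "metabolite_j", "r", "p"])


def pairwise_correlations(
    table: ConcentrationTable, condition: Condition
) -> pd.DataFrame:
    """Pearson r and p for every metabolite pair within one condition."""
    data = table.condition_slice(condition)
    if len(data) < 3:
        raise ValueError("correlation needs at least 3 samples per condition")
    return _correlation_pairs(data)


def correlation_network(
    table: ConcentrationTable, condition: Condition, alpha: float = 0.05
) -> CorrelationNetwork:
    """Significant-edge network for one condition (keep p < alpha)."""
    pairs = pairwise_correlations(table, condition)
    keep = pairs["p"] < alpha
    return CorrelationNetwork(
        condition=condition,
        edges=pairs.loc[keep.fillna(False)].reset_index(drop=True),
        all_pairs=pairs,
        alpha=alpha,
        n_samples=len(table.condition_slice(condition)),
    )


@dataclass
class CorrelationShift:
    pairs: pd.DataFrame       # pair, r_before, r_after, delta, flagged
    discrepant: list[str]     # metabolites in >= 1 flagged pair
    threshold: float
    skipped: pd.DataFrame     # pairs dropped for NA correlations

    @property
    def flagged_pairs(self) -> pd.DataFrame:
        return self.pairs.loc[self.pairs["flagged"]]


def correlation_shifts(
    table: ConcentrationTable, threshold: float = 1.0, alpha: float = 0.05
) -> CorrelationShift:
    """Between-condition correlation differences for every metabolite pair.

    delta = |r_before - r_after| is computed on raw correlations for all
    pairs (no significance gate, so a shift cannot hide behind a
    just-insignificant edge); pairs with delta > threshold are flagged.
    Pairs with an undefined correlation in either condition are skipped and
    reported in ``skipped``.
    """
    if not 0 < threshold <= 2:
        raise ValueError(f"shift threshold must lie in (0, 2], got {threshold}")
    before = pairwise_correlations(table, Condition.BEFORE)
    after = pairwise_correlations(table, Condition.AFTER)
    merged = before.merge(
        after,
        on=["metabolite_i", "metabolite_j"],
        suffixes=("_before", "_after"),
    )
    na = merged["r_before"].isna() | merged["r_after"].isna()
    skipped = merged.loc[na, ["metabolite_i", "metabolite_j"]].reset_index(drop=True)
    ok = merged.loc[~na].copy()
    ok["delta"] = (ok["r_before"] - ok["r_after"]).abs()
    ok["flagged"] = ok["delta"] > threshold
    ok = ok[
        ["metabolite_i", "metabolite_j", "r_before", "r_after",
         "p_before", "p_after", "delta", "flagged"]
    ].reset_index(drop=True)
    flagged = ok.loc[ok["flagged"]]
    discrepant = sorted(
        set(flagged["metabolite_i"]).union(flagged["metabolite_j"]),
        key=table.metabolites.index,
    )
    return CorrelationShift(
        pairs=ok, discrepant=discrepant, threshold=threshold, skipped=skipped
    )
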