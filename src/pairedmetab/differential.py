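"""Union-based differential-metabolite calling and over-representation.

A metabolite is called differential when it passes ANY of three criteria:

* multivariate influence: VIP > 1 in the fitted PLS-DA model;
* univariate significance: paired t-test p below 0.05;
* network rewiring: membership in at least one metabolite pair whose
  between-condition correlation difference exceeds 1.

The three criteria capture complementary signal (mean shift, class
discrimination, association rewiring), so the union — not the intersection
— defines the call set; ``criteria_hit`` records the audit trail.  A
missing value in one criterion (e.g. an undefined t-test p) never counts as
a pass, but cannot veto a pass by another criterion either.

Pathway context is added by a generic hypergeometric over-representation
test of the called set against named metabolite sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PathwaySet, ValidationError

__all__ = [
    "CallThresholds",
    "DifferentialCallSet",
    "call_differential",
    "apply_union_rule",
    "load_reference_calls",
    "enrich",
]


@dataclass(frozen=True)
class CallThresholds:
    """The three call criteria and how the p-value is compared.

    ``p_comparison='lt'`` (strict, the default) is the right choice on raw
    p-values; ``'le'`` is for published tables whose p-values are rounded
    to a fixed number of decimals, where a printed 0.050 means "at the
    threshold" rather than above it.
    """

    vip: float = 1.0
    p: float = 0.05
    shift: float = 1.0
    p_comparison: str = "lt"

    def __post_init__(self) -> None:
        if self.vip <= 0 or self.p <= 0 or self.shift <= 0:
            raise ValueError("thresholds must be positive")
        if self.p_comparison not in {"lt", "le"}:
            raise ValueError("p_comparison must be 'lt' or 'le'")


@dataclass
class DifferentialCallSet:
    table: pd.DataFrame  # vip, p_paired, shift_flag, regulation, criteria, selected
    thresholds: CallThresholds

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def hits(self, criterion: str) -> list[str]:
        mask = self.table["criteria"].map(lambda c: criterion in c)
        return list(self.table.index[mask])


def apply_union_rule(
    frame: pd.DataFrame, thresholds: CallThresholds = CallThresholds()
) -> DifferentialCallSet:
    """Apply the three-criterion union to a per-metabolite summary frame.

    ``frame`` must carry columns ``vip``, ``p_paired`` (NaN allowed),
    ``shift_flag`` (boolean, NaN allowed) and ``regulation``; NaN in any
    criterion means that criterion cannot fire for that metabolite.
    """
    vip = pd.to_numeric(frame["vip"], errors="coerce")
    p = pd.to_numeric(frame["p_paired"], errors="coerce")
    shift = frame["shift_flag"]
    vip_hit = (vip > thresholds.vip).fillna(False)
    if thresholds.p_comparison == "lt":
        p_hit = (p < thresholds.p).fillna(False)
    else:
        p_hit = (p <= thresholds.p).fillna(False)
    shift_hit = shift.map(lambda v: bool(v) if pd.notna(v) else False)
    criteria = [
        tuple(
            name
            for name, hit in (("VIP", v), ("TTEST", t), ("SHIFT", s))
            if hit
        )
        for v, t, s in zip(vip_hit, p_hit, shift_hit)
    ]
    out = frame.copy()
    out["criteria"] = criteria
    out["selected"] = [len(c) > 0 for c in criteria]
    return DifferentialCallSet(out, thresholds)


def call_differential(
    vip: pd.Series,
    tests: pd.DataFrame,
    discrepant: Iterable[str],
    thresholds: CallThresholds = CallThresholds(),
) -> DifferentialCallSet:
    """Assemble pipeline outputs and apply the union rule.

    Parameters
    ----------
    vip:
        Per-metabolite VIP from :func:`pairedmetab.multivariate.vip_scores`.
    tests:
        The :class:`~pairedmetab.network.PairedTestResult` table (columns
        ``p``, ``mean_diff``, ``direction``).
    discrepant:
        Metabolites appearing in at least one flagged correlation-shift
        pair.
    All inputs must cover the same metabolite set; a metabolite absent from
    one input gets NA for that criterion.
    """
    metabolites = list(vip.index)
    if set(tests.index) != set(metabolites):
        extra = sorted(set(tests.index) ^ set(metabolites))
        warnings.warn(
            f"criterion inputs cover different metabolites ({extra}); "
            "missing entries treated as NA",
            stacklevel=2,
        )
        metabolites = sorted(
            set(metabolites) | set(tests.index), key=str
        )
    discrepant = set(discrepant)
    frame = pd.DataFrame(index=pd.Index(metabolites, name="metabolite"))
    frame["vip"] = vip.reindex(metabolites)
    frame["p_paired"] = tests["p"].reindex(metabolites)
    frame["shift_flag"] = [m in discrepant for m in metabolites]
    frame["regulation"] = tests["direction"].reindex(metabolites)
    return apply_union_rule(frame, thresholds)


def load_reference_calls(path: str | Path | None = None) -> pd.DataFrame:
    """Load the published cattle cold-stress serum call summary.

    The shipped reference lists, for each of 19 serum metabolites reported
    as cold-responsive in Sanhe cattle, its PLS-DA VIP, paired t-test p
    (3 decimals, NA where undefined), whether it sat in a correlation pair
    shifted by more than 1, and its regulation direction.  Values are as
    printed in the source publication's summary table and serve as a
    fixture for the union rule.
    """
    if path is None:
        ref = resources.files("pairedmetab").joinpath(
            "data/cold_stress_serum_calls.csv"
        )
        with resources.as_file(ref) as p:
            raw = pd.read_csv(p, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str)
    frame = pd.DataFrame(index=pd.Index(raw["metabolite"], name="metabolite"))
    frame["vip"] = pd.to_numeric(raw["vip"].to_numpy(), errors="coerce")
    frame["p_paired"] = pd.to_numeric(
        raw["p_paired"].replace("NA", np.nan).to_numpy(), errors="raise"
    )
    shift = raw["correlation_shift"].to_numpy()
    frame["shift_flag"] = [
        np.nan if v == "NA" else v == ">1" for v in shift
    ]
    frame["regulation"] = raw["regulation"].to_numpy()
    return frame


# -- over-representation ---------------------------------------------------


def enrich(
    selected: Sequence[str],
    background: Sequence[str],
    sets: Sequence[PathwaySet],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each set.

    Each pathway is first intersected with ``background``; p is the
    upper-tail probability of drawing at least the observed number of set
    members when |selected| metabolites are drawn from the background
    without replacement.  Fold enrichment is (hits/|selected|) /
    (set_size/|background|).  Results are sorted by p.
    """
    background_set = set(background)
    selected_set = set(selected)
    if not selected_set <= background_set:
        raise ValidationError(
            f"selected metabolites outside background: "
            f"{sorted(selected_set - background_set)}"
        )
    M, N = len(background_set), len(selected_set)
    if N == 0:
        warnings.warn("empty selected list; no enrichment computed", stacklevel=2)
        return pd.DataFrame(
            columns=["set_size", "hits", "expected", "fold", "p"]
        )
    rows = {}
    for ps in sets:
        members = ps.members & background_set
        if not members:
            continue  # disjoint from background: untestable, skip
        n = len(members)
        hits = len(members & selected_set)
        expected = N * n / M
        fold = (hits / N) / (n / M)
        p = float(stats.hypergeom.sf(hits - 1, M, n, N))
        rows[ps.name] = (n, hits, expected, fold, min(p, 1.0))
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["set_size", "hits", "expected", "fold", "p"],
    )
    out.index.name = "pathway"
    out["background_size"] = M
    out["n_selected"] = N
    return out.sort_values("p", kind="stable")
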