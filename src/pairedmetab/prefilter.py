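"""Sign-consistency pre-filter for paired designs.

In a before/after design every metabolite yields one within-animal
difference per animal.  A metabolite whose difference has the same sign in
at least a threshold fraction of animals (default 70%) is treated as a
population-level response to the exposure; the rest — metabolites that rise
in some animals and fall in others — are treated as individual variation or
baseline noise and removed before multivariate modelling.  Exact-zero
differences count toward neither direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PrefilterResult", "sign_consistency_filter", "required_count"]

_EPS = 1e-9  # guards ceil/floor against float noise in threshold * n


@dataclass
class PrefilterResult:
    retained: list[str]
    dropped: list[str]
    tallies: pd.DataFrame  # per metabolite: n_up, n_down, n_tie, consistent
    threshold: float
    mode: str

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def required_count(n_animals: int, threshold: float, mode: str = "ge") -> int:
    """Smallest directional count that passes the consistency rule.

    ``mode='ge'`` keeps a metabolite when at least ``threshold`` of animals
    agree (count >= ceil(threshold * n)); ``mode='gt'`` requires strictly
    more than the threshold fraction.
    """
    if mode == "ge":
        return math.ceil(threshold * n_animals - _EPS)
    if mode == "gt":
        return math.floor(threshold * n_animals + _EPS) + 1
    raise ValueError(f"mode must be 'ge' or 'gt', got {mode!r}")


def sign_consistency_filter(
    diffs: pd.DataFrame, threshold: float = 0.70, mode: str = "ge"
) -> PrefilterResult:
    """Retain metabolites whose change direction agrees across animals.

    Parameters
    ----------
    diffs:
        (animals x metabolites) within-animal difference matrix from
        :func:`pairedmetab.io.paired_differences`.
    threshold:
        Agreement fraction in (0.5, 1]; below 0.5 the rule would retain
        everything and discriminate nothing.
    mode:
        ``'ge'`` (default) or ``'gt'``; see :func:`required_count`.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(
            f"threshold must lie in (0.5, 1], got {threshold}"
        )
    values = diffs.to_numpy(dtype=float)
    n_animals = values.shape[0]
    n_up = (values > 0).sum(axis=0)
    n_down = (values < 0).sum(axis=0)
    n_tie = n_animals - n_up - n_down
    needed = required_count(n_animals, threshold, mode)
    consistent = np.maximum(n_up, n_down) >= needed
    tallies = pd.DataFrame(
        {
            "n_up": n_up,
            "n_down": n_down,
            "n_tie": n_tie,
            "consistent": consistent,
        },
        index=diffs.columns,
    )
    retained = [m for m, ok in zip(diffs.columns, consistent) if ok]
    dropped = [m for m, ok in zip(diffs.columns, consistent) if not ok]
    return PrefilterResult(
        retained=retained,
        dropped=dropped,
        tallies=tallies,
        threshold=threshold,
        mode=mode,
    )
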