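"""Synthetic paired serum-metabolome cohorts with known ground truth.

The generator emulates the statistical structure of a small paired NMR
study: a handful of animals sampled before and after an exposure, ~40
quantified metabolites spanning three orders of magnitude in concentration,
a subset of truly responsive metabolites with a consistent directional
shift, a few "idiosyncratic" metabolites that shift in animal-specific
random directions (so they fool unpaired analyses but not the
sign-consistency prefilter), and optional correlated blocks whose
within-block correlation differs between conditions (planting detectable
correlation rewiring).

Concentrations are generated multiplicatively on the log scale — they span
orders of magnitude and must stay positive:

    log C[animal, metabolite, cond] = log baseline_j + animal effect_ij
                                      + effect_ij * [cond == after]
                                      + noise_sd * eps_ijc

The animal effect is shared between the two conditions of a pair; it is
exactly this shared term that makes the paired design more informative than
a two-group comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Condition, ConcentrationTable, SampleKey

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "make_paper_shaped_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level parameters of the generator.

    ``effect_size`` is the standardised shift of responsive metabolites:
    the log-scale mean change equals ``effect_size`` times the standard
    deviation of the within-animal difference noise (``sqrt(2) *
    noise_sd``), so it is directly the expected paired effect size d.
    ``direction_mix`` is the fraction of responsive metabolites shifted up.
    ``idiosyncratic_fraction`` applies to the non-responsive metabolites;
    an idiosyncratic metabolite receives the same magnitude of shift but
    with an independent random sign per animal.
    ``correlation_blocks`` is a list of (size, r_before, r_after) tuples;
    each block of inert metabolites shares a latent factor per condition
    whose loadings produce the requested within-block correlation (negative
    r alternates loading signs, exact for blocks of two).
    """

    n_animals: int = 10
    n_metabolites: int = 41
    n_responsive: int = 19
    effect_size: float = 1.5
    direction_mix: float = 17 / 19
    idiosyncratic_fraction: float = 0.10
    baseline_range_mmol: tuple[float, float] = (0.005, 3.4)
    animal_effect_sd: float = 0.3
    noise_sd: float = 0.2
    correlation_blocks: tuple[tuple[int, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_responsive <= self.n_metabolites:
            raise ValueError("n_responsive must lie in [0, n_metabolites]")
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals")
        if min(self.animal_effect_sd, self.noise_sd) < 0 or self.effect_size < 0:
            raise ValueError("effect size and sds must be non-negative")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must lie in [0, 1]")
        if not 0 <= self.idiosyncratic_fraction <= 1:
            raise ValueError("idiosyncratic_fraction must lie in [0, 1]")
        lo, hi = self.baseline_range_mmol
        if not 0 < lo <= hi:
            raise ValueError("baseline range must be positive and ordered")
        n_inert_needed = sum(b[0] for b in self.correlation_blocks)
        for size, rb, ra in self.correlation_blocks:
            if size < 2:
                raise ValueError("correlation block needs at least 2 metabolites")
            if not (abs(rb) <= 1 and abs(ra) <= 1):
                raise ValueError("block correlations must lie in [-1, 1]")
        n_inert = self.n_metabolites - self.n_responsive
        n_idio = round(self.idiosyncratic_fraction * n_inert)
        if n_inert_needed > n_inert - n_idio:
            raise ValueError(
                "correlation blocks need more inert metabolites than available"
            )


@dataclass
class GroundTruth:
    """What was planted: per-metabolite roles and within-block correlations."""

    labels: pd.DataFrame  # role, direction, block
    planted_pairs: pd.DataFrame  # metabolite_i, metabolite_j, r_before, r_after
    config: SyntheticConfig

    @property
    def responsive(self) -> list[str]:
        return list(self.labels.index[self.labels["role"] == "responsive"])

    @property
    def idiosyncratic(self) -> list[str]:
        return list(self.labels.index[self.labels["role"] == "idiosyncratic"])

    @property
    def inert(self) -> list[str]:
        return list(self.labels.index[self.labels["role"] == "inert"])


def _block_noise(
    rng: np.random.Generator, n: int, members: np.ndarray, r: float, eps: np.ndarray
) -> None:
    """Overwrite eps columns of a block with factor-structured noise."""
    lam = math.sqrt(abs(r))
    signs = np.ones(len(members))
    if r < 0:
        signs[1::2] = -1.0
    g = rng.standard_normal(n)
    resid = rng.standard_normal((n, len(members)))
    eps[:, members] = np.outer(g, signs * lam) + math.sqrt(1 - lam**2) * resid


def generate(config: SyntheticConfig) -> tuple[ConcentrationTable, GroundTruth]:
    """Draw one paired cohort; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    nA, J = config.n_animals, config.n_metabolites
    metabolites = [f"M{j + 1:02d}" for j in range(J)]
    animals = [f"A{i + 1:02d}" for i in range(nA)]

    roles = np.array(["inert"] * J, dtype=object)
    order = rng.permutation(J)
    responsive_idx = np.sort(order[: config.n_responsive])
    roles[responsive_idx] = "responsive"
    inert_pool = np.sort(order[config.n_responsive:])
    n_idio = round(config.idiosyncratic_fraction * len(inert_pool))
    idio_idx = np.sort(rng.permutation(inert_pool)[:n_idio])
    roles[idio_idx] = "idiosyncratic"

    # consistent shift directions: first fraction up, rest down (shuffled)
    n_up = round(config.direction_mix * config.n_responsive)
    dir_vec = np.zeros(J)
    signs = np.array([1.0] * n_up + [-1.0] * (config.n_responsive - n_up))
    dir_vec[responsive_idx] = rng.permutation(signs)

    # correlation blocks consume inert, non-idiosyncratic metabolites
    free_inert = [j for j in inert_pool if j not in set(idio_idx)]
    block_of = np.full(J, -1)
    block_members: list[np.ndarray] = []
    cursor = 0
    for b, (size, _, _) in enumerate(config.correlation_blocks):
        members = np.array(free_inert[cursor:cursor + size])
        cursor += size
        block_of[members] = b
        block_members.append(members)

    lo, hi = config.baseline_range_mmol
    log_baseline = rng.uniform(math.log(lo), math.log(hi), size=J)
    animal_effect = rng.normal(0.0, config.animal_effect_sd, size=(nA, J))
    # block members carry their planted correlation in the condition-specific
    # factor, so their animal effect is folded into that factor's scale:
    # otherwise the independent animal effect would dilute the planted r
    noise_scale = np.full(J, config.noise_sd)
    in_block = block_of >= 0
    animal_effect[:, in_block] = 0.0
    noise_scale[in_block] = math.hypot(config.animal_effect_sd, config.noise_sd)

    delta = config.effect_size * math.sqrt(2.0) * config.noise_sd
    effect = np.zeros((nA, J))
    effect[:, responsive_idx] = delta * dir_vec[responsive_idx]
    if len(idio_idx):
        effect[:, idio_idx] = delta * rng.choice([-1.0, 1.0], size=(nA, len(idio_idx)))

    logc = {}
    for cond, r_index in ((Condition.BEFORE, 1), (Condition.AFTER, 2)):
        eps = rng.standard_normal((nA, J))
        for (size, rb, ra), members in zip(config.correlation_blocks, block_members):
            r = rb if cond is Condition.BEFORE else ra
            _block_noise(rng, nA, members, r, eps)
        shift = effect if cond is Condition.AFTER else 0.0
        logc[cond] = log_baseline + animal_effect + shift + noise_scale * eps

    rows, keys = [], []
    for i, animal in enumerate(animals):
        for cond in (Condition.BEFORE, Condition.AFTER):
            rows.append(np.exp(logc[cond][i]))
            keys.append(SampleKey(animal, cond))
    table = ConcentrationTable(pd.DataFrame(rows, columns=metabolites), keys)

    labels = pd.DataFrame(
        {
            "role": roles,
            "direction": np.where(dir_vec > 0, "up", np.where(dir_vec < 0, "down", "none")),
            "block": block_of,
        },
        index=pd.Index(metabolites, name="metabolite"),
    )
    pair_rows = []
    for (size, rb, ra), members in zip(config.correlation_blocks, block_members):
        for a in range(size):
            for b in range(a + 1, size):
                def planted(r: float) -> float:
                    s = -1.0 if (r < 0 and (a + b) % 2 == 1) else 1.0
                    return s * abs(r)
                pair_rows.append(
                    (metabolites[members[a]], metabolites[members[b]],
                     planted(rb), planted(ra))
                )
    planted_pairs = pd.DataFrame(
        pair_rows, columns=["metabolite_i", "metabolite_j", "r_before", "r_after"]
    )
    return table, GroundTruth(labels=labels, planted_pairs=planted_pairs, config=config)


def make_paper_shaped_cohort(seed: int = 0) -> tuple[ConcentrationTable, GroundTruth]:
    """Preset cohort shaped like the cattle cold-stress study.

    10 animals x 41 metabolites, 19 responsive (17 up, 2 down), ~2
    idiosyncratic metabolites, and one two-metabolite block whose
    correlation flips from +0.9 before to -0.9 after — a planted
    correlation shift of 1.8.
    """
    config = SyntheticConfig(
        correlation_blocks=((2, 0.9, -0.9),),
        seed=seed,
    )
    return generate(config)
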