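"""End-to-end orchestration: prefilter -> PLS-DA -> tests -> networks -> calls.

`run_pipeline` executes the full paired-analysis workflow in a fixed order,
writes one artifact file per stage, and produces a machine-readable summary
whose content is a pure function of (input table, config, seed).  Stage
failures raise :class:`PipelineError` naming the stage; artifacts written
before the failure are preserved for debugging.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import differential, multivariate, network, prefilter
from .differential import CallThresholds
from .io import ConcentrationTable, Condition, paired_differences

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "compare_prefilter"]

log = logging.getLogger("pairedmetab")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    prefilter_threshold: float = 0.70
    prefilter_mode: str = "ge"
    n_components: int = 5
    folds: int = 10
    permutations: int = 1000
    alpha: float = 0.05
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    shift_threshold: float = 1.0
    scaling: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.prefilter_threshold <= 1.0:
            raise ValueError("prefilter_threshold must lie in (0.5, 1]")
        if self.prefilter_mode not in {"ge", "gt"}:
            raise ValueError("prefilter_mode must be 'ge' or 'gt'")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.vip_threshold, self.p_threshold, self.shift_threshold) <= 0:
            raise ValueError("call thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _write(df, out_dir: Path | None, name: str) -> None:
    if out_dir is not None:
        df.to_csv(out_dir / name)


def run_pipeline(
    table: ConcentrationTable,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage in order and return the result bundle.

    Returns a dict with the stage objects (``prefilter``, ``model``,
    ``vip``, ``tests``, ``networks``, ``shifts``, ``calls``) and a
    ``summary`` sub-dict of scalar metrics.  With ``out_dir`` set, per-stage
    CSV artifacts and ``summary.json`` are written there.
    """
    out_path: Path | None = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_path / "config.yaml")
    results: dict = {"config": config}

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                log.info("stage %-12s done in %.2fs", name, time.perf_counter() - self.t0)

        return _Stage()

    with stage("prefilter"):
        diffs = paired_differences(table)
        pf = prefilter.sign_consistency_filter(
            diffs, threshold=config.prefilter_threshold, mode=config.prefilter_mode
        )
        if pf.n_retained < 2:
            raise ValueError(
                f"prefilter retained only {pf.n_retained} metabolite(s)"
            )
        retained = table.subset(pf.retained)
        results["prefilter"] = pf
        _write(pf.tallies, out_path, "prefilter_tallies.csv")

    with stage("multivariate"):
        scaled = multivariate.autoscale(retained, scaling=config.scaling)
        y = retained.class_labels()
        model = multivariate.fit_plsda(scaled, y, n_components=config.n_components)
        vip = multivariate.vip_scores(model)
        q2 = multivariate.cross_validate_q2(
            retained.data.to_numpy(), y, n_components=config.n_components,
            folds=config.folds, seed=config.seed, scaling=config.scaling,
            columns=retained.metabolites,
        )
        perm_p, _ = multivariate.permutation_test(
            retained.data.to_numpy(), y, n_components=config.n_components,
            B=config.permutations, seed=config.seed, scaling=config.scaling,
            columns=retained.metabolites,
        )
        results.update(model=model, vip=vip, q2y=q2, perm_p=perm_p)
        _write(vip.to_frame(), out_path, "vip.csv")

    with stage("univariate"):
        tests = network.paired_t_tests(retained)
        results["tests"] = tests
        _write(tests.table, out_path, "paired_tests.csv")

    with stage("network"):
        nets = {
            cond: network.correlation_network(retained, cond, alpha=config.alpha)
            for cond in (Condition.BEFORE, Condition.AFTER)
        }
        shifts = network.correlation_shifts(
            retained, threshold=config.shift_threshold, alpha=config.alpha
        )
        results.update(networks=nets, shifts=shifts)
        for cond, net in nets.items():
            _write(net.edges, out_path, f"edges_{cond.value}.csv")
        _write(shifts.pairs, out_path, "correlation_shifts.csv")

    with stage("call"):
        calls = differential.call_differential(
            vip, tests.table, shifts.discrepant,
            CallThresholds(
                vip=config.vip_threshold, p=config.p_threshold,
                shift=config.shift_threshold,
            ),
        )
        results["calls"] = calls
        _write(
            calls.table.assign(
                criteria=calls.table["criteria"].map(lambda c: "+".join(c))
            ),
            out_path, "differential_calls.csv",
        )

    summary = {
        "n_input": len(table.metabolites),
        "n_retained": pf.n_retained,
        "r2x": round(float(model.r2x[-1]), 10),
        "r2y": round(float(model.r2y[-1]), 10),
        "q2y": round(float(q2), 10),
        "perm_p": round(float(perm_p), 10),
        "n_vip_hits": len(calls.hits("VIP")),
        "n_ttest_hits": len(calls.hits("TTEST")),
        "n_edges_before": nets[Condition.BEFORE].n_edges,
        "n_edges_after": nets[Condition.AFTER].n_edges,
        "n_shift_pairs": int(shifts.pairs["flagged"].sum()),
        "n_discrepant": len(shifts.discrepant),
        "n_selected": calls.n_selected,
        "seed": config.seed,
    }
    results["summary"] = summary
    if out_path is not None:
        (out_path / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return results


def compare_prefilter(
    table: ConcentrationTable, config: PipelineConfig = PipelineConfig()
) -> dict:
    """Fit PLS-DA on all metabolites and on the prefiltered subset.

    Returns ``{'unfiltered': {...}, 'filtered': {...}}`` where each entry
    carries (r2y, q2y, perm_p) — the side-by-side diagnostic of whether the
    sign-consistency prefilter improves multivariate model quality.
    """
    diffs = paired_differences(table)
    pf = prefilter.sign_consistency_filter(
        diffs, threshold=config.prefilter_threshold, mode=config.prefilter_mode
    )
    if pf.n_retained < 2:
        raise ValueError(f"prefilter retained only {pf.n_retained} metabolite(s)")
    out = {}
    for label, sub in (("unfiltered", table), ("filtered", table.subset(pf.retained))):
        y = sub.class_labels()
        scaled = multivariate.autoscale(sub, scaling=config.scaling)
        model = multivariate.fit_plsda(scaled, y, n_components=config.n_components)
        q2 = multivariate.cross_validate_q2(
            sub.data.to_numpy(), y, n_components=config.n_components,
            folds=config.folds, seed=config.seed, scaling=config.scaling,
            columns=sub.metabolites,
        )
        perm_p, _ = multivariate.permutation_test(
            sub.data.to_numpy(), y, n_components=config.n_components,
            B=config.permutations, seed=config.seed, scaling=config.scaling,
            columns=sub.metabolites,
        )
        out[label] = {
            "n_metabolites": len(sub.metabolites),
            "r2y": float(model.r2y[-1]),
            "q2y": float(q2),
            "perm_p": float(perm_p),
        }
    return out
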