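"""Replicated simulation benchmark of the selection methods.

For each replication a fresh training set (and, for the e-value methods, an
independent test set of the same size for tuning s by prediction error) is
generated, the method is run, and the selection is scored against the
design's ground truth (TP/TN/RTP/RTN).  Replications use independent child
seeds spawned from one master seed, so a report is reproducible from
``(config, method_spec, reps, seed)`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .baselines import bh_select, mbic2_backward, single_snp_scan
from .evalues import DEFAULT_Q_SET
from .gbs import GbsConfig
from .pipeline import SIM_S_GRID, run_selection
from .simulate import MetricsReport, SimConfig, average_metrics, compute_metrics, simulate_dataset

__all__ = ["MethodSpec", "benchmark"]

_METHODS = ("evalue-E1", "evalue-E2", "singlesnp-BH", "mbic2")


@dataclass(frozen=True)
class MethodSpec:
    """A selection method plus its settings, as run inside the benchmark.

    ``t`` may be a single threshold or a sequence; with a sequence, every
    threshold shares the simulated datasets, fits and bootstrap ensembles,
    and :func:`benchmark` returns one report per threshold.
    """

    method: str = "evalue-E2"
    t: float | tuple[float, ...] = 0.8
    s_grid: tuple[float, ...] = SIM_S_GRID
    q_set: tuple[float, ...] = DEFAULT_Q_SET
    B_ref: int = 500
    B_eval: int = 500
    weight_law: str = "gamma"
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")

    @property
    def map_kind(self) -> str:
        return "E1" if self.method == "evalue-E1" else "E2"

    @property
    def t_values(self) -> tuple[float, ...]:
        return tuple(self.t) if isinstance(self.t, (tuple, list)) else (float(self.t),)


def _evalue_rep(
    config: SimConfig, spec: MethodSpec, rng: np.random.Generator
) -> dict[float, MetricsReport]:
    train, _ = simulate_dataset(config, rng)
    test, _ = simulate_dataset(config, rng)
    gbs_cfg = GbsConfig(
        s=spec.s_grid[0],
        B_ref=spec.B_ref,
        B_eval=spec.B_eval,
        weight_law=spec.weight_law,
        seed=int(rng.integers(2**31 - 1)),
    )
    result = run_selection(
        train,
        test,
        map_kind=spec.map_kind,
        s_grid=spec.s_grid,
        t_grid=spec.t_values,
        gbs_config=gbs_cfg,
        q_set=spec.q_set,
    )
    out = {}
    for t in spec.t_values:
        s_best = result.best_s_for_t(t)
        out[t] = compute_metrics(result.selection_at(s_best, t), config)
    return out


def _baseline_rep(
    config: SimConfig, spec: MethodSpec, rng: np.random.Generator
) -> MetricsReport:
    train, _ = simulate_dataset(config, rng)
    if spec.method == "singlesnp-BH":
        scan = single_snp_scan(train)
        selected = bh_select(scan.pvalue, spec.fdr_level)
    else:
        selected = mbic2_backward(train)
    return compute_metrics(selected, config)


def benchmark(
    config: SimConfig,
    method_spec: MethodSpec,
    reps: int,
    seed: int,
) -> "MetricsReport | dict[float, MetricsReport]":
    """Average TP/TN/RTP/RTN of one method over ``reps`` simulated datasets.

    Returns a single :class:`MetricsReport` (with the per-replication table
    attached) for baseline methods or a single-threshold e-value spec, and a
    ``{t: MetricsReport}`` dict when ``method_spec.t`` is a sequence.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    is_evalue = method_spec.method.startswith("evalue")
    per_t: dict[float, list[MetricsReport]] = {t: [] for t in method_spec.t_values}
    plain: list[MetricsReport] = []
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        if is_evalue:
            rep = _evalue_rep(config, method_spec, rng)
            for t, report in rep.items():
                per_t[t].append(report)
        else:
            plain.append(_baseline_rep(config, method_spec, rng))
    if not is_evalue:
        return average_metrics(plain)
    averaged = {t: average_metrics(reports) for t, reports in per_t.items()}
    if not isinstance(method_spec.t, (tuple, list)):
        return averaged[method_spec.t_values[0]]
    return averaged
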