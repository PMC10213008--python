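"""End-to-end selection with (s, t) tuning by holdout prediction error.

The bootstrap noise scale s and the detection threshold t are nuisance
settings of the quantile e-value rule.  They are tuned by the fixed-effect
prediction error of the selected model on held-out families,

    PE_t(s) = sum over test individuals of (y - x' beta_hat_{S_t(s)})^2,

where beta_hat is the restricted GLS refit of the selected SNPs (plus
intercept and covariates) on the training families.  Only the full model is
ever fitted; every (s, t) cell reuses the cached cross-products, so the grid
costs bootstrap ensembles (one pair per s) and small linear solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .evalues import (
    DEFAULT_Q_SET,
    EvalueSummary,
    evalue_distributions,
    select_snps_quantile,
)
from .gbs import GbsConfig, gbs_ensemble
from .lmm import AceModelFit, FitConfig, fit_ace_lmm
from .pedigree import Dataset

__all__ = [
    "SIM_S_GRID",
    "DATA_S_GRID",
    "DATA_T_GRID",
    "TuningResult",
    "prediction_error",
    "run_selection",
]

#: s grid used in the simulation-style experiments (endpoints 0.1 ... 0.95, 2).
SIM_S_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.05), 2)) + (2.0,)

#: (s, t) grids used for real-data style selection: s = 0.2(0.2)3, t = 0.1(0.05)0.8.
DATA_S_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.2, 3.01, 0.2), 1))
DATA_T_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.801, 0.05), 2))


def prediction_error(
    selected,
    fit: AceModelFit,
    train: Dataset,
    test: Dataset,
    include_covariates: bool = True,
) -> float:
    """Holdout squared prediction error of the selected fixed-effect model.

    Refits the restricted GLS coefficients (intercept, active SNPs,
    covariates) on ``train`` with variance components frozen at ``fit`` and
    sums squared residuals of the fixed-effect prediction over every test
    individual.
    """
    if tuple(test.snp_ids) != tuple(train.snp_ids) or tuple(test.snp_ids) != fit.snp_ids:
        raise ValueError("train/test SNP panels must match the fitted model")
    coef = fit.restricted_coef(selected)
    alpha = coef[0]
    beta_g = coef[1 : 1 + fit.p_g]
    beta_c = coef[1 + fit.p_g :]
    pe = 0.0
    for fam in test.families:
        yhat = alpha + fam.G @ beta_g
        if include_covariates and fam.C.size:
            yhat = yhat + fam.C @ beta_c
        pe += float(np.sum((fam.y - yhat) ** 2))
    return pe


@dataclass
class TuningResult:
    """Full (s, t) tuning grid and the PE-optimal selection."""

    grid: pd.DataFrame  # columns: s, t, pe, n_selected
    best_s: float
    best_t: float
    final_selected: set[int]
    final_beta: np.ndarray
    selections: dict[tuple[float, float], frozenset[int]] = field(repr=False)
    summaries: dict[float, EvalueSummary] = field(default_factory=dict, repr=False)
    fit: AceModelFit | None = field(default=None, repr=False)
    n_fits: int = 1

    def selection_at(self, s: float, t: float) -> set[int]:
        return set(self.selections[(s, t)])

    def best_s_for_t(self, t: float) -> float:
        """The PE-minimising s for a fixed threshold t."""
        sub = self.grid[self.grid["t"] == t]
        return float(sub.loc[sub["pe"].idxmin(), "s"])


def run_selection(
    train: Dataset,
    test: Dataset,
    map_kind: str = "E2",
    s_grid: Sequence[float] = DATA_S_GRID,
    t_grid: Sequence[float] = DATA_T_GRID,
    gbs_config: GbsConfig | None = None,
    q_set: Sequence[float] = DEFAULT_Q_SET,
    fit_config: FitConfig | None = None,
    fit: AceModelFit | None = None,
    include_covariates_in_pe: bool = True,
    keep_summaries: bool = False,
) -> TuningResult:
    """Quantile e-value selection with (s, t) tuned by holdout prediction error.

    Fits the full multi-SNP model once on ``train``; for each s draws one
    reference/evaluation ensemble pair and scores all thresholds t; returns
    the whole grid and the selection minimising PE (ties: first in grid
    order).  Deterministic given ``gbs_config.seed``.
    """
    if not len(s_grid) or not len(t_grid):
        raise ValueError("s_grid and t_grid must be non-empty")
    base_cfg = gbs_config or GbsConfig()
    if fit is None:
        fit = fit_ace_lmm(train, fit_config)
    seed_seq = np.random.SeedSequence(base_cfg.seed)
    child_rngs = [np.random.default_rng(s) for s in seed_seq.spawn(len(s_grid))]

    rows = []
    selections: dict[tuple[float, float], frozenset[int]] = {}
    summaries: dict[float, EvalueSummary] = {}
    pe_cache: dict[frozenset[int], float] = {}
    for s, rng in zip(s_grid, child_rngs):
        cfg_s = replace(base_cfg, s=float(s))
        ref, ev = gbs_ensemble(fit, train, cfg_s, rng=rng)
        summary = evalue_distributions(ref, ev, map_kind, q_set, s=float(s))
        if keep_summaries:
            summaries[float(s)] = summary
        for t in t_grid:
            sel = frozenset(select_snps_quantile(summary, float(t)))
            if sel not in pe_cache:
                pe_cache[sel] = prediction_error(
                    sel, fit, train, test, include_covariates_in_pe
                )
            selections[(float(s), float(t))] = sel
            rows.append(
                {
                    "s": float(s),
                    "t": float(t),
                    "pe": pe_cache[sel],
                    "n_selected": len(sel),
                }
            )
    grid = pd.DataFrame(rows)
    best = grid.loc[grid["pe"].idxmin()]
    best_s, best_t = float(best["s"]), float(best["t"])
    final_selected = set(selections[(best_s, best_t)])
    final_coef = fit.restricted_coef(final_selected)
    return TuningResult(
        grid=grid,
        best_s=best_s,
        best_t=best_t,
        final_selected=final_selected,
        final_beta=final_coef[1 : 1 + fit.p_g],
        selections=selections,
        summaries=summaries,
        fit=fit,
        n_fits=1,
    )
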