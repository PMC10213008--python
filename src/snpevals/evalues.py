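"""Evaluation maps, e-value distributions and the quantile selection rule.

A candidate parameter point x is scored against the full model's bootstrap
sampling distribution through an *evaluation map*: with z the coordinate-wise
standardisation of x by the reference ensemble's mean and standard deviation,

    E1(x) = 1 / (1 + ||z||^2),        E2(x) = exp(-||z||),

both in (0, 1] and equal to 1 exactly at the reference mean.  The *e-value*
of a model is a functional (mean, or a tail quantile c_q) of the evaluation
map's distribution when x ranges over a bootstrap ensemble.  Dropping SNP j
means zeroing coordinate j of every draw; if SNP j matters, the zeroed draws
sit far from the reference distribution and the e-values of the
leave-j-out model fall below those of the full model.  The quantile rule
selects SNP j when

    c_q(E_minus_j) < t * c_q(E_star)   for every q in q_set,

with q_set = {0.5, ..., 0.9} by default and 0 < t < 1 the detection
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gbs import BootstrapEnsemble

__all__ = [
    "DEFAULT_Q_SET",
    "EvalMapSpec",
    "EvalueSummary",
    "evaluate_map",
    "reduced_model_point",
    "evalue_distributions",
    "select_snps_quantile",
    "select_snps_mean",
]

DEFAULT_Q_SET: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)

_KINDS = ("E1", "E2")


@dataclass(frozen=True)
class EvalMapSpec:
    """Which evaluation map to use: inverse-quadratic E1 or exponential E2."""

    kind: str = "E2"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")


def _map_from_sqnorm(sqnorm: np.ndarray, kind: str) -> np.ndarray:
    if kind == "E1":
        return 1.0 / (1.0 + sqnorm)
    return np.exp(-np.sqrt(sqnorm))


def evaluate_map(
    x: np.ndarray, ref_mean: np.ndarray, ref_sd: np.ndarray, kind: str = "E2"
) -> float:
    """Score one parameter point against reference moments.

    ``E1 = 1/(1 + ||z||^2)`` and ``E2 = exp(-||z||)`` with
    ``z = (x - ref_mean) / ref_sd`` coordinate-wise.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    x = np.asarray(x, dtype=float)
    ref_mean = np.asarray(ref_mean, dtype=float)
    ref_sd = np.asarray(ref_sd, dtype=float)
    if x.shape != ref_mean.shape or x.shape != ref_sd.shape:
        raise ValueError("x, ref_mean and ref_sd must have equal length")
    if np.any(ref_sd <= 0):
        raise ValueError("ref_sd must be strictly positive in every coordinate")
    z = (x - ref_mean) / ref_sd
    return float(_map_from_sqnorm(np.array(z @ z), kind))


def reduced_model_point(theta_draw: np.ndarray, j: int) -> np.ndarray:
    """Copy of ``theta_draw`` with coordinate ``j`` set to 0 (drop-one model)."""
    theta_draw = np.asarray(theta_draw, dtype=float)
    out = theta_draw.copy()
    out[j] = 0.0
    return out


@dataclass
class EvalueSummary:
    """E-value samples and quantiles for the full and leave-one-SNP-out models."""

    e_star_samples: np.ndarray  # (B_eval,)
    e_minus_samples: np.ndarray  # (p_g, B_eval)
    q_set: tuple[float, ...]
    quantiles_star: np.ndarray = field(init=False)  # (|q_set|,)
    quantiles_minus: np.ndarray = field(init=False)  # (p_g, |q_set|)
    mean_star: float = field(init=False)
    mean_minus: np.ndarray = field(init=False)
    map_kind: str = "E2"
    s: float | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q_set, dtype=float)
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("q_set must lie strictly inside (0, 1)")
        self.q_set = tuple(q)
        self.quantiles_star = np.quantile(self.e_star_samples, q)
        self.quantiles_minus = np.quantile(self.e_minus_samples, q, axis=1).T
        self.mean_star = float(np.mean(self.e_star_samples))
        self.mean_minus = self.e_minus_samples.mean(axis=1)

    @property
    def p_g(self) -> int:
        return self.e_minus_samples.shape[0]

    def quantile_ratios(self, q: float) -> np.ndarray:
        """c_q(E_minus_j) / c_q(E_star) for every SNP j."""
        qi = self.q_set.index(q)
        return self.quantiles_minus[:, qi] / self.quantiles_star[qi]

    def to_frame(self, snp_ids: Sequence[str] | None = None, t: float | None = None) -> pd.DataFrame:
        """Selection report: per-SNP quantile e-values and flags."""
        ids = list(snp_ids) if snp_ids is not None else [
            f"snp{j + 1}" for j in range(self.p_g)
        ]
        df = pd.DataFrame({"snp_id": ids})
        for qi, q in enumerate(self.q_set):
            df[f"c{q:g}_reduced"] = self.quantiles_minus[:, qi]
            df[f"c{q:g}_full"] = self.quantiles_star[qi]
        df["mean_evalue_reduced"] = self.mean_minus
        df["mean_evalue_full"] = self.mean_star
        df["map"] = self.map_kind
        if self.s is not None:
            df["s"] = self.s
        if t is not None:
            sel = select_snps_quantile(self, t)
            df["t"] = t
            df["selected"] = [j in sel for j in range(self.p_g)]
        return df


def evalue_distributions(
    reference: BootstrapEnsemble,
    evaluation: BootstrapEnsemble,
    map_spec: EvalMapSpec | str = "E2",
    q_set: Sequence[float] = DEFAULT_Q_SET,
    s: float | None = None,
) -> EvalueSummary:
    """E-value samples for the full model and every leave-one-SNP-out model.

    For each evaluation draw theta_b the full-model sample is
    ``E(theta_b)``; the drop-j sample re-scores the draw with coordinate j
    zeroed.  Zeroing only changes one coordinate of the standardised vector,
    so all p_g reduced models are scored with one rank-1 update of the
    squared norms rather than p_g full passes.
    """
    kind = map_spec.kind if isinstance(map_spec, EvalMapSpec) else str(map_spec)
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    mean = reference.ref_mean
    sd = reference.ref_sd
    if np.any(sd <= 0):
        raise ValueError("degenerate reference ensemble (zero spread coordinate)")
    Z = (evaluation.draws - mean) / sd  # (B, p_g)
    sq = np.einsum("bj,bj->b", Z, Z)  # ||z_b||^2
    e_star = _map_from_sqnorm(sq, kind)
    # dropping j replaces z_bj by (0 - mean_j)/sd_j
    zero_z = (-mean / sd) ** 2  # (p_g,)
    sq_minus = sq[None, :] - (Z.T**2) + zero_z[:, None]  # (p_g, B)
    np.maximum(sq_minus, 0.0, out=sq_minus)
    e_minus = _map_from_sqnorm(sq_minus, kind)
    return EvalueSummary(
        e_star_samples=e_star,
        e_minus_samples=e_minus,
        q_set=tuple(q_set),
        map_kind=kind,
        s=s,
    )


def select_snps_quantile(summary: EvalueSummary, t: float) -> set[int]:
    """SNPs with c_q(E_minus_j) < t c_q(E_star) for *every* q in the q-set.

    Strict inequality at every quantile level; ties are not selected.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("t must lie strictly inside (0, 1)")
    thresh = t * summary.quantiles_star  # (|q_set|,)
    passes = summary.quantiles_minus < thresh[None, :]
    return set(np.flatnonzero(passes.all(axis=1)).tolist())


def select_snps_mean(summary: EvalueSummary) -> set[int]:
    """SNPs whose mean e-value falls below the full model's (the mean rule)."""
    return set(np.flatnonzero(summary.mean_minus < summary.mean_star).tolist())
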