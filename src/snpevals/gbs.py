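"""Generalized bootstrap for the SNP coefficient vector.

Instead of refitting the mixed model on resampled data, the generalized
bootstrap perturbs the fitted model's estimating equations with positive
i.i.d. random weights of mean 1 and standard deviation s, one weight per
family (families are the independent sampling units):

    beta_b = ( sum_i w_bi X_i' V_i^-1 X_i )^-1  sum_i w_bi X_i' V_i^-1 y_i.

The per-family cross-products are cached in the fitted model and the
variance components are never re-estimated, so a draw costs one small linear
solve and the whole ensemble is a couple of batched matrix products.  To
first order the coordinate-wise spread of the draws is s times the GLS
standard error, so s directly scales the synthetic bootstrap noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lmm import AceModelFit
from .pedigree import Dataset

__all__ = ["GbsConfig", "BootstrapEnsemble", "draw_weights", "gbs_ensemble"]


@dataclass(frozen=True)
class GbsConfig:
    """Settings of the generalized bootstrap.

    ``s`` is the standard deviation of the resampling weights (the synthetic
    noise scale s_n = tau_n / sqrt(n)); ``B_ref`` and ``B_eval`` are the
    sizes of the reference and evaluation ensembles; ``weight_law`` is
    ``"gamma"`` (Gamma(1/s^2, s^2): positive, mean 1, sd s) or
    ``"multinomial"`` (classical m-out-of-m resampling counts, s ignored).
    """

    s: float = 0.6
    B_ref: int = 500
    B_eval: int = 500
    weight_law: str = "gamma"
    weight_scale: str = "individual"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.B_ref < 100 or self.B_eval < 100:
            raise ValueError("B_ref and B_eval must be at least 100")
        if self.weight_law not in ("gamma", "multinomial"):
            raise ValueError("weight_law must be 'gamma' or 'multinomial'")
        if self.weight_scale not in ("individual", "family"):
            raise ValueError("weight_scale must be 'individual' or 'family'")

    def family_weight_sd(self, n: int, m: int) -> float:
        """Standard deviation of the per-family weights implied by s.

        Under the default ``individual`` convention s is the synthetic-noise
        scale per individual (s = tau_n / sqrt(n) with tau_n the total noise
        aggregated over the m independent family weights), so the family
        weight sd is s * sqrt(n / m).  Under ``family`` the weights have sd s
        directly.
        """
        if self.weight_scale == "family":
            return self.s
        return self.s * float(np.sqrt(n / m))


@dataclass
class BootstrapEnsemble:
    """B bootstrap draws of beta_g plus the ensemble's reference moments."""

    draws: np.ndarray  # (B, p_g)
    ref_mean: np.ndarray = field(init=False)
    ref_sd: np.ndarray = field(init=False)
    source_fit: AceModelFit | None = None
    n_rejected: int = 0
    require_spread: bool = True

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2:
            raise ValueError("draws must be a (B, p_g) matrix")
        self.ref_mean = self.draws.mean(axis=0)
        self.ref_sd = self.draws.std(axis=0, ddof=1)
        if self.require_spread and np.any(self.ref_sd <= 0):
            raise ValueError(
                "degenerate bootstrap ensemble: a coordinate has zero spread"
            )

    @property
    def B(self) -> int:
        return self.draws.shape[0]

    def to_frame(self, snp_ids=None):
        """Flat long-format table of the draws: draw_index, snp_id, value."""
        import pandas as pd

        p = self.draws.shape[1]
        ids = list(snp_ids) if snp_ids is not None else [f"snp{j + 1}" for j in range(p)]
        if len(ids) != p:
            raise ValueError("snp_ids length does not match the draws")
        return pd.DataFrame(
            {
                "draw_index": np.repeat(np.arange(self.B), p),
                "snp_id": np.tile(ids, self.B),
                "value": self.draws.ravel(),
            }
        )


def draw_weights(
    m: int, s: float, B: int, rng: np.random.Generator, weight_law: str = "gamma"
) -> np.ndarray:
    """(B, m) matrix of i.i.d. positive resampling weights, mean 1, sd s."""
    if s <= 0:
        raise ValueError("s must be positive")
    if weight_law == "gamma":
        shape = 1.0 / (s * s)
        return rng.gamma(shape, scale=s * s, size=(B, m))
    if weight_law == "multinomial":
        counts = rng.multinomial(m, np.full(m, 1.0 / m), size=B)
        return counts.astype(float)
    raise ValueError(f"unknown weight law {weight_law!r}")


def _weighted_beta(
    fit: AceModelFit,
    weights: np.ndarray,
    rng: np.random.Generator,
    config: GbsConfig,
    s_w: float | None = None,
) -> tuple[np.ndarray, int]:
    """Solve the reweighted normal equations for every row of ``weights``."""
    A = fit.A_fam  # (m, k, k)
    b = fit.b_fam  # (m, k)
    sl = fit.snp_slice()
    B = weights.shape[0]
    out = np.empty((B, fit.p_g))
    pending = np.arange(B)
    w = weights
    rejected = 0
    for _ in range(50):
        Aw = np.tensordot(w, A, axes=(1, 0))  # (B', k, k)
        bw = w @ b  # (B', k)
        bad = []
        try:
            sol = np.linalg.solve(Aw, bw[..., None])[..., 0]
            out[pending] = sol[:, sl]
            bad = []
        except np.linalg.LinAlgError:
            # isolate singular draws, redraw their weights
            for r in range(w.shape[0]):
                try:
                    out[pending[r]] = np.linalg.solve(Aw[r], bw[r])[sl]
                except np.linalg.LinAlgError:
                    bad.append(r)
        if not bad:
            break
        rejected += len(bad)
        pending = pending[bad]
        redraw_sd = config.s if s_w is None else s_w
        w = draw_weights(A.shape[0], redraw_sd, len(bad), rng, config.weight_law)
    else:  # pragma: no cover - pathological
        raise RuntimeError("could not obtain non-singular bootstrap draws")
    return out, rejected


def gbs_ensemble(
    fit: AceModelFit,
    dataset: Dataset | None,
    config: GbsConfig,
    rng: np.random.Generator | None = None,
) -> tuple[BootstrapEnsemble, BootstrapEnsemble]:
    """Reference and evaluation bootstrap ensembles of beta_g.

    Two independent ensembles are drawn from the same fitted model: the
    *reference* ensemble supplies the moments the evaluation maps normalise
    by, and the *evaluation* ensemble supplies the points being scored.
    ``dataset`` is accepted for interface symmetry (the cached cross-products
    already encode the data) and, when given, is checked for consistency.
    """
    if dataset is not None and tuple(dataset.snp_ids) != fit.snp_ids:
        raise ValueError("dataset SNP panel differs from the fitted model")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = fit.m
    s_w = config.family_weight_sd(fit.n, fit.m)
    ensembles = []
    total_rejected = 0
    for B in (config.B_ref, config.B_eval):
        w = draw_weights(m, s_w, B, rng, config.weight_law)
        draws, rejected = _weighted_beta(fit, w, rng, config, s_w=s_w)
        total_rejected += rejected
        # spread may underflow to exactly 0 in the s -> 0 limit; allow it there
        ensembles.append(
            BootstrapEnsemble(
                draws=draws, source_fit=fit, require_spread=s_w > 1e-6
            )
        )
        ensembles[-1].n_rejected = rejected
    if total_rejected > 0.01 * (config.B_ref + config.B_eval):
        warnings.warn(
            f"{total_rejected} singular bootstrap draws were rejected and redrawn",
            RuntimeWarning,
            stacklevel=2,
        )
    return ensembles[0], ensembles[1]
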