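"""Baseline SNP-selection methods: single-SNP GLS scan + BH, and mBIC2.

The single-SNP scan fits the one-SNP-at-a-time version of the ACE mixed
model: variance components are estimated once on the null (no-SNP) model and
reused for every SNP, after which each SNP's coefficient is an exact GLS
solve with a Wald t-test.  The resulting marginal p-values feed the
Benjamini-Hochberg step-up rule.

mBIC2 ignores the family structure on purpose (ordinary least squares) and
performs backward deletion of SNPs under the modified BIC

    n log(RSS/n) + k log n + 2 k log(p_g / c) - 2 log k!,   c = 4,

whose extra penalty terms control FDR-like error in many-predictor
regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .lmm import AceModelFit, FitConfig, VarianceComponents, fit_ace_lmm
from .pedigree import Dataset

__all__ = ["ScanResult", "single_snp_scan", "bh_select", "mbic2_backward"]


@dataclass
class ScanResult:
    """Per-SNP single-marker GLS estimates, tests and BH decisions."""

    snp_ids: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    df: int
    varcomp: VarianceComponents | None = None
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def bh_selected(self, level: float = 0.05) -> set[int]:
        return bh_select(self.pvalue, level)

    def to_frame(self, level: float = 0.05) -> pd.DataFrame:
        sel = self.bh_selected(level)
        return pd.DataFrame(
            {
                "snp_id": list(self.snp_ids),
                "beta": self.beta,
                "se": self.se,
                "t": self.tstat,
                "p": self.pvalue,
                "bh_selected": [j in sel for j in range(len(self.snp_ids))],
            }
        )


def _null_varcomp(dataset: Dataset, fit_config: FitConfig | None) -> VarianceComponents:
    """ACE variance components from the covariates-only (no SNP) model."""
    null_fams = [
        type(f)(
            family_id=f.family_id,
            y=f.y,
            G=np.zeros((f.n_members, 0)),
            C=f.C,
            phi=f.phi,
            member_roles=f.member_roles,
        )
        for f in dataset.families
    ]
    null_ds = Dataset(null_fams, (), dataset.covariate_names)
    return fit_ace_lmm(null_ds, fit_config).varcomp


def single_snp_scan(
    dataset: Dataset,
    varcomp: VarianceComponents | None = None,
    per_snp_varcomp: bool = False,
    fit_config: FitConfig | None = None,
) -> ScanResult:
    """Exact one-SNP-at-a-time GLS scan of the ACE mixed model.

    By default the variance components are estimated once on the null model
    and plugged into every per-SNP GLS solve (fast, mirrors the intent of
    rapid single-marker mixed-model scans); ``per_snp_varcomp=True`` instead
    re-estimates them for every SNP.  Monomorphic SNPs get p = 1 with a
    warning.
    """
    if per_snp_varcomp:
        return _scan_refit_each(dataset, fit_config)
    if varcomp is None:
        varcomp = _null_varcomp(dataset, fit_config)

    from .lmm import assemble_covariance

    p_g = dataset.p_g
    k0 = 1 + dataset.p  # intercept + covariates
    A00 = np.zeros((k0, k0))
    A0g = np.zeros((k0, p_g))
    agg = np.zeros(p_g)
    b0 = np.zeros(k0)
    bg = np.zeros(p_g)
    n = 0
    vinv_cache: dict[bytes, np.ndarray] = {}
    for fam in dataset.families:
        key = fam.phi.tobytes()
        Vinv = vinv_cache.get(key)
        if Vinv is None:
            V = assemble_covariance(varcomp, fam.phi)
            Vinv = linalg.inv(V)
            vinv_cache[key] = Vinv
        W = np.hstack([np.ones((fam.n_members, 1)), fam.C])  # (n_i, k0)
        G = fam.G  # (n_i, p_g)
        VW = Vinv @ W
        VG = Vinv @ G
        A00 += W.T @ VW
        A0g += W.T @ VG
        agg += np.einsum("ij,ij->j", G, VG)
        b0 += VW.T @ fam.y
        bg += VG.T @ fam.y
        n += fam.n_members

    A00_inv = linalg.inv(A00)
    M = A00_inv @ A0g  # (k0, p_g)
    schur = agg - np.einsum("kj,kj->j", A0g, M)  # per-SNP information
    mono = schur <= 1e-10 * np.maximum(agg, 1.0)
    num = bg - M.T @ b0
    beta = np.zeros(p_g)
    se = np.full(p_g, np.inf)
    ok = ~mono
    beta[ok] = num[ok] / schur[ok]
    se[ok] = 1.0 / np.sqrt(schur[ok])
    tstat = np.where(ok, beta / se, 0.0)
    df = n - k0 - 1
    pval = np.ones(p_g)
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df=df)
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNP(s); p-value set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
    return ScanResult(
        snp_ids=tuple(dataset.snp_ids),
        beta=beta,
        se=se,
        tstat=tstat,
        pvalue=pval,
        df=df,
        varcomp=varcomp,
        monomorphic=mono,
    )


def _scan_refit_each(dataset: Dataset, fit_config: FitConfig | None) -> ScanResult:
    """Per-SNP scan re-estimating the variance components for every SNP."""
    betas, ses, ts, ps = [], [], [], []
    vc_last = None
    n = dataset.n
    k = 2 + dataset.p
    for j in range(dataset.p_g):
        fams = [
            type(f)(
                family_id=f.family_id,
                y=f.y,
                G=f.G[:, [j]],
                C=f.C,
                phi=f.phi,
                member_roles=f.member_roles,
            )
            for f in dataset.families
        ]
        sub = Dataset(fams, (dataset.snp_ids[j],), dataset.covariate_names)
        if np.ptp(np.concatenate([f.G.ravel() for f in fams])) == 0:
            warnings.warn("monomorphic SNP; p-value set to 1", RuntimeWarning)
            betas.append(0.0)
            ses.append(np.inf)
            ts.append(0.0)
            ps.append(1.0)
            continue
        fit = fit_ace_lmm(sub, fit_config)
        beta = float(fit.beta_g[0])
        se = float(fit.beta_g_se[0])
        betas.append(beta)
        ses.append(se)
        ts.append(beta / se)
        ps.append(2.0 * stats.t.sf(abs(beta / se), df=n - k))
        vc_last = fit.varcomp
    return ScanResult(
        snp_ids=tuple(dataset.snp_ids),
        beta=np.array(betas),
        se=np.array(ses),
        tstat=np.array(ts),
        pvalue=np.array(ps),
        df=n - k,
        varcomp=vc_last,
        monomorphic=np.array([se == np.inf for se in ses]),
    )


def bh_select(pvalues, level: float = 0.05) -> set[int]:
    """Benjamini-Hochberg step-up rejection set at the given FDR level."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return set()
    reject = multipletests(p, alpha=level, method="fdr_bh")[0]
    return set(np.flatnonzero(reject).tolist())


def mbic2_backward(dataset: Dataset, c: float = 4.0, return_trace: bool = False):
    """Backward deletion of SNPs in an OLS model under the mBIC2 criterion.

    Starts from the model with all SNPs (plus intercept and covariates,
    which are never deleted), removes at each step the SNP whose removal
    lowers the criterion the most, and stops when no removal improves it.
    Family structure is deliberately ignored (plain linear model).
    """
    X_parts, y_parts = [], []
    for fam in dataset.families:
        X_parts.append(np.hstack([np.ones((fam.n_members, 1)), fam.G, fam.C]))
        y_parts.append(fam.y)
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    n, k_tot = X.shape
    p_g = dataset.p_g
    if n <= k_tot:
        raise ValueError("mBIC2 requires n > number of predictors")
    gram = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    fixed_cols = [0] + list(range(1 + p_g, k_tot))  # intercept + covariates

    def rss(active_snps: list[int]) -> float:
        cols = fixed_cols + [1 + j for j in active_snps]
        A = gram[np.ix_(cols, cols)]
        b = xty[cols]
        try:
            coef = linalg.solve(A, b, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("rank-deficient design in mBIC2") from exc
        return max(yty - float(coef @ b), 1e-300)

    def criterion(active_snps: list[int]) -> float:
        k = len(active_snps)
        val = n * math.log(rss(active_snps) / n) + k * math.log(n)
        if k:
            val += 2.0 * k * math.log(p_g / c) - 2.0 * math.lgamma(k + 1)
        return val

    active = list(range(p_g))
    current = criterion(active)
    trace = [current]
    while active:
        best_j, best_val = None, current
        for j in active:
            trial = [x for x in active if x != j]
            val = criterion(trial)
            if val < best_val - 1e-12:
                best_j, best_val = j, val
        if best_j is None:
            break
        active.remove(best_j)
        current = best_val
        trace.append(current)
    if return_trace:
        return set(active), trace
    return set(active)
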