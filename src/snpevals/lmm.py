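"""Multi-SNP ACE linear mixed model: likelihood, fitting, restricted GLS.

The model for family i is

    y_i = alpha + G_i beta_g + C_i beta_c + eps_i,
    eps_i ~ N(0, V_i),   V_i = sigma_a^2 Phi_i + sigma_c^2 11' + sigma_e^2 I,

with Phi_i the family's expected-relatedness matrix.  The three variance
components capture additive polygenic effects (A), the environment shared by
a whole family (C) and individual-specific noise (E).  Because families are
independent, the likelihood factorises over pedigree blocks and every solve
is a small per-family one; no n x n matrix is ever formed.

Fixed effects are profiled out by generalized least squares at each variance
component value, and the three components are maximised on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .pedigree import Dataset

__all__ = [
    "VarianceComponents",
    "FitConfig",
    "AceModelFit",
    "ConvergenceError",
    "assemble_covariance",
    "profile_loglik",
    "fit_ace_lmm",
    "fit_call_count",
    "gls_refit",
]


class ConvergenceError(RuntimeError):
    """Raised when the variance-component optimiser fails; carries the best iterate."""

    def __init__(self, message: str, best_fit: "AceModelFit | None" = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class VarianceComponents:
    """ACE variance components (sigma_a^2, sigma_c^2, sigma_e^2)."""

    sigma_a2: float
    sigma_c2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("variance components must be finite")
        if self.sigma_a2 < 0 or self.sigma_c2 < 0:
            raise ValueError("sigma_a2 and sigma_c2 must be non-negative")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_a2, self.sigma_c2, self.sigma_e2], dtype=float)

    @property
    def total(self) -> float:
        return float(self.sigma_a2 + self.sigma_c2 + self.sigma_e2)


def assemble_covariance(varcomp: VarianceComponents, phi: np.ndarray) -> np.ndarray:
    """Family covariance V = sigma_a^2 Phi + sigma_c^2 11' + sigma_e^2 I."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise ValueError("phi must be a square matrix")
    if not np.allclose(phi, phi.T):
        raise ValueError("phi must be symmetric")
    n = phi.shape[0]
    return (
        varcomp.sigma_a2 * phi
        + varcomp.sigma_c2 * np.ones((n, n))
        + varcomp.sigma_e2 * np.eye(n)
    )


@dataclass
class FitConfig:
    """Optimiser settings for :func:`fit_ace_lmm`.

    ``method`` is ``"ML"`` (default) or ``"REML"``; the restricted likelihood
    adds the usual log-determinant correction for the fixed-effect projection.
    ``sigma_e2_floor_frac`` floors sigma_e^2 at this fraction of the total
    phenotypic variance so every V_i stays invertible.
    """

    method: str = "ML"
    max_iter: int = 200
    tol: float = 1e-8
    sigma_e2_floor_frac: float = 1e-6
    boundary_frac: float = 1e-4  # components below this fraction of total are flagged


# ---------------------------------------------------------------------------
# stacked representation: families grouped by identical (n_i, phi)


class _StackedDesign:
    """Families grouped by relatedness pattern, with stacked [1 | G | C] designs."""

    def __init__(self, dataset: Dataset):
        if dataset.m == 0:
            raise ValueError("dataset is empty")
        self.p_g = dataset.p_g
        self.p = dataset.p
        self.k = 1 + self.p_g + self.p
        self.n = dataset.n
        self.m = dataset.m
        groups: dict[bytes, list[int]] = {}
        for i, fam in enumerate(dataset.families):
            key = np.round(fam.phi, 12).tobytes() + fam.phi.shape[0].to_bytes(2, "little")
            groups.setdefault(key, []).append(i)
        # canonical order (sorted keys, families sorted by id within a group) so
        # accumulated sums — hence the whole fit — do not depend on input order
        self.groups: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for key in sorted(groups):
            idx = sorted(groups[key], key=lambda i: str(dataset.families[i].family_id))
            fams = [dataset.families[i] for i in idx]
            phi = fams[0].phi
            X = np.stack(
                [
                    np.hstack([np.ones((f.n_members, 1)), f.G, f.C])
                    for f in fams
                ]
            )  # (g, n_i, k)
            y = np.stack([f.y for f in fams])  # (g, n_i)
            self.groups.append((np.asarray(idx), phi, X, y))

    def normal_equations(self, varcomp: VarianceComponents):
        """Accumulate Sum X'V^-1 X, Sum X'V^-1 y, Sum y'V^-1 y, Sum logdet V."""
        k = self.k
        A_sum = np.zeros((k, k))
        b_sum = np.zeros(k)
        yVy = 0.0
        logdet = 0.0
        for _, phi, X, y in self.groups:
            V = assemble_covariance(varcomp, phi)
            c, low = linalg.cho_factor(V, lower=True)
            Vinv = linalg.cho_solve((c, low), np.eye(V.shape[0]))
            ld = 2.0 * np.sum(np.log(np.diag(c)))
            g = X.shape[0]
            VinvX = np.matmul(Vinv[None, :, :], X)  # (g, n_i, k)
            A_sum += np.einsum("gij,gik->jk", X, VinvX)
            Vinvy = y @ Vinv  # (g, n_i)
            b_sum += np.einsum("gij,gi->j", X, Vinvy)
            yVy += float(np.einsum("gi,gi->", y, Vinvy))
            logdet += g * ld
        return A_sum, b_sum, yVy, logdet

    def per_family_equations(self, varcomp: VarianceComponents):
        """Per-family cross-products A_i = X_i'V_i^-1 X_i and b_i = X_i'V_i^-1 y_i."""
        A = np.zeros((self.m, self.k, self.k))
        b = np.zeros((self.m, self.k))
        for idx, phi, X, y in self.groups:
            V = assemble_covariance(varcomp, phi)
            c, low = linalg.cho_factor(V, lower=True)
            Vinv = linalg.cho_solve((c, low), np.eye(V.shape[0]))
            VinvX = np.matmul(Vinv[None, :, :], X)
            A[idx] = np.einsum("gij,gik->gjk", X, VinvX)
            b[idx] = np.einsum("gij,gi->gj", X, y @ Vinv)
        return A, b


def _loglik_from_equations(A_sum, b_sum, yVy, logdet, n, method: str):
    try:
        cA = linalg.cho_factor(A_sum)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular normal equations: collinear predictors in [1 | G | C]"
        ) from exc
    coef = linalg.cho_solve(cA, b_sum)
    quad = yVy - float(coef @ b_sum)
    ll = -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    if method.upper() == "REML":
        ll -= 0.5 * 2.0 * np.sum(np.log(np.diag(cA[0])))
    return ll, coef


def profile_loglik(
    dataset: Dataset, varcomp: VarianceComponents, method: str = "ML"
) -> tuple[float, np.ndarray]:
    """Gaussian log-likelihood with fixed effects profiled out by GLS.

    Returns ``(loglik, coef)`` where ``coef`` stacks the profiled GLS fixed
    effects in the order [intercept, beta_g, beta_c].  The computation uses
    the per-family block structure; complexity is linear in the number of
    families.

    Raises
    ------
    numpy.linalg.LinAlgError
        If the stacked design is rank deficient (collinear predictors).
    """
    stacked = _StackedDesign(dataset)
    A_sum, b_sum, yVy, logdet = stacked.normal_equations(varcomp)
    ll, coef = _loglik_from_equations(A_sum, b_sum, yVy, logdet, stacked.n, method)
    return float(ll), coef


@dataclass
class AceModelFit:
    """Fitted multi-SNP ACE mixed model with cached per-family cross-products.

    The caches (``A_fam[i] = X_i' V_i^-1 X_i``, ``b_fam[i] = X_i' V_i^-1 y_i``)
    are what the generalized bootstrap reweights; they are frozen at the
    fitted variance components.
    """

    alpha: float
    beta_g: np.ndarray
    beta_c: np.ndarray
    varcomp: VarianceComponents
    loglik: float
    method: str
    converged: bool
    boundary_flags: dict[str, bool]
    snp_ids: tuple[str, ...]
    covariate_names: tuple[str, ...]
    n: int
    m: int
    A_fam: np.ndarray = field(repr=False)  # (m, k, k)
    b_fam: np.ndarray = field(repr=False)  # (m, k)
    A_sum: np.ndarray = field(repr=False)
    b_sum: np.ndarray = field(repr=False)
    fixed_effect_cov: np.ndarray = field(repr=False)

    @property
    def p_g(self) -> int:
        return len(self.snp_ids)

    @property
    def p(self) -> int:
        return len(self.covariate_names)

    @property
    def k(self) -> int:
        return 1 + self.p_g + self.p

    @property
    def coef(self) -> np.ndarray:
        """Full fixed-effect vector [intercept, beta_g, beta_c]."""
        return np.concatenate([[self.alpha], self.beta_g, self.beta_c])

    @property
    def beta_g_se(self) -> np.ndarray:
        """GLS standard errors of the SNP coefficients."""
        return np.sqrt(np.diag(self.fixed_effect_cov)[1 : 1 + self.p_g])

    def snp_slice(self) -> slice:
        """Columns of the stacked design holding the SNP coefficients."""
        return slice(1, 1 + self.p_g)

    def restricted_coef(self, active_snps) -> np.ndarray:
        """GLS coefficients using only [1 | G_active | C]; zeros elsewhere.

        Variance components stay frozen at the fitted values.  Returns the
        full-length coefficient vector [intercept, beta_g, beta_c] with the
        inactive SNP entries set to 0.
        """
        active = np.asarray(sorted(set(int(j) for j in active_snps)), dtype=int)
        if active.size and (active.min() < 0 or active.max() >= self.p_g):
            raise IndexError("active SNP index out of range")
        idx = np.concatenate(
            [
                [0],
                1 + active,
                np.arange(1 + self.p_g, self.k),
            ]
        ).astype(int)
        A_r = self.A_sum[np.ix_(idx, idx)]
        b_r = self.b_sum[idx]
        coef_r = linalg.cho_solve(linalg.cho_factor(A_r), b_r)
        full = np.zeros(self.k)
        full[idx] = coef_r
        return full


_fit_calls = 0


def fit_call_count() -> int:
    """Number of full-model fits performed so far (efficiency instrumentation)."""
    return _fit_calls


def _moment_start(stacked: _StackedDesign) -> np.ndarray:
    """Equal-thirds split of the OLS residual variance as a starting point."""
    X = np.concatenate([g[2].reshape(-1, stacked.k) for g in stacked.groups])
    y = np.concatenate([g[3].ravel() for g in stacked.groups])
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    v = float(np.var(resid))
    v = max(v, 1e-8)
    return np.full(3, v / 3.0)


def fit_ace_lmm(dataset: Dataset, config: FitConfig | None = None) -> AceModelFit:
    """Maximum-likelihood fit of the multi-SNP ACE mixed model.

    Variance components are optimised on the log scale with L-BFGS-B
    (Nelder-Mead fallback) starting from an equal-thirds moment split of the
    OLS residual variance.  Components that land on the lower boundary are
    flagged in ``boundary_flags``, not treated as errors.
    """
    global _fit_calls
    _fit_calls += 1
    cfg = config or FitConfig()
    stacked = _StackedDesign(dataset)
    if stacked.n <= stacked.k:
        raise ValueError(
            f"model not estimable: n={stacked.n} <= number of fixed effects {stacked.k}"
        )
    start = _moment_start(stacked)
    vtot = float(start.sum())
    floor_e = cfg.sigma_e2_floor_frac * vtot

    def unpack(x: np.ndarray) -> VarianceComponents:
        v = np.exp(x)
        return VarianceComponents(v[0], v[1], max(v[2], floor_e))

    def neg_ll(x: np.ndarray) -> float:
        try:
            A_sum, b_sum, yVy, logdet = stacked.normal_equations(unpack(x))
            ll, _ = _loglik_from_equations(
                A_sum, b_sum, yVy, logdet, stacked.n, cfg.method
            )
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    x0 = np.log(start)
    lo = np.log(vtot * 1e-10)
    hi = np.log(vtot * 1e4)
    res = optimize.minimize(
        neg_ll,
        x0,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * 3,
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-10},
    )
    converged = bool(res.success)
    if not converged or not np.isfinite(res.fun):
        res_nm = optimize.minimize(
            neg_ll,
            res.x if np.isfinite(res.fun) else x0,
            method="Nelder-Mead",
            options={"maxiter": 4 * cfg.max_iter, "fatol": cfg.tol, "xatol": 1e-8},
        )
        if res_nm.fun <= res.fun:
            res = res_nm
        converged = bool(res.success or res_nm.success)

    vc = unpack(res.x)
    A_sum, b_sum, yVy, logdet = stacked.normal_equations(vc)
    ll, coef = _loglik_from_equations(A_sum, b_sum, yVy, logdet, stacked.n, cfg.method)
    A_fam, b_fam = stacked.per_family_equations(vc)
    fixed_cov = linalg.cho_solve(linalg.cho_factor(A_sum), np.eye(stacked.k))
    fixed_cov = 0.5 * (fixed_cov + fixed_cov.T)
    boundary = {
        "sigma_a2": bool(vc.sigma_a2 < cfg.boundary_frac * vc.total),
        "sigma_c2": bool(vc.sigma_c2 < cfg.boundary_frac * vc.total),
        "sigma_e2": bool(vc.sigma_e2 <= floor_e * (1 + 1e-9)),
    }
    fit = AceModelFit(
        alpha=float(coef[0]),
        beta_g=coef[1 : 1 + stacked.p_g].copy(),
        beta_c=coef[1 + stacked.p_g :].copy(),
        varcomp=vc,
        loglik=float(ll),
        method=cfg.method.upper(),
        converged=converged,
        boundary_flags=boundary,
        snp_ids=tuple(dataset.snp_ids),
        covariate_names=tuple(dataset.covariate_names),
        n=stacked.n,
        m=stacked.m,
        A_fam=A_fam,
        b_fam=b_fam,
        A_sum=A_sum,
        b_sum=b_sum,
        fixed_effect_cov=fixed_cov,
    )
    if not converged:
        raise ConvergenceError(
            "variance-component optimiser did not converge", best_fit=fit
        )
    return fit


def gls_refit(dataset: Dataset, fit: AceModelFit, active_snps) -> np.ndarray:
    """Restricted GLS SNP coefficients using only the active SNP columns.

    Refits [1 | G_active | C] by GLS with the variance components frozen at
    ``fit.varcomp`` and returns the full-length ``beta_g`` with zeros off the
    active set.  ``dataset`` must carry the same SNP panel as ``fit``.
    """
    if tuple(dataset.snp_ids) != fit.snp_ids:
        raise ValueError("dataset SNP panel differs from the fitted model")
    full = fit.restricted_coef(active_snps)
    return full[1 : 1 + fit.p_g]
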