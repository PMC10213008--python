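"""Synthetic family-GWAS generator and selection metrics.

The generator emulates a twin-study design: m nuclear families of four
(father, mother, two children), genotyped at p_g SNPs arranged in
independent blocks.  Within a block the 0/1 parental allele vectors are
correlated through a Gaussian copula (equicorrelated latent normals
thresholded at the MAF quantile; the correlation can be imposed on the
latent scale, the default, or calibrated so the binary-scale correlation
hits the target exactly), across blocks they are independent, and each
entry is Bernoulli(MAF) marginally.  A parent's genotype is the sum of two
independent allele vectors; a child inherits one randomly chosen allele
vector from each parent.  MZ twins share both transmitted vectors, DZ twins
and full siblings draw transmissions independently, adoptees come from
fresh, unrelated allele vectors.

Phenotypes follow the ACE mixed model: a causal subset of SNPs acts through
fixed effects whose sizes are set by a per-SNP heritability parameter h, and
the error stacks an additive polygenic term (covariance sigma_a^2 Phi), a
family-shared environment (sigma_c^2) and individual noise (sigma_e^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .lmm import VarianceComponents, assemble_covariance
from .pedigree import Dataset, FamilyBlock, build_kinship_matrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "causal_effect_size",
    "calibrate_latent_correlation",
    "simulate_parent_alleles",
    "simulate_family_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "compute_metrics",
    "MetricsReport",
]


@dataclass(frozen=True)
class SimConfig:
    """Study design of the synthetic family GWAS.

    Defaults reproduce the reference design: 250 MZ-twin families, 50 SNPs in
    five independent blocks of sizes [6, 4, 6, 4, 30] with block MAFs
    [0.2, 0.4, 0.4, 0.25, 0.25] and within-block binary correlation 0.7; the
    first SNP of each of blocks 1-4 is causal with per-SNP heritability
    parameter ``h``; error variance components (4, 1, 1).

    ``effect_size_convention`` picks how ``h`` maps to a coefficient, see
    :func:`causal_effect_size`.
    """

    m: int = 250
    block_sizes: tuple[int, ...] = (6, 4, 6, 4, 30)
    block_mafs: tuple[float, ...] = (0.2, 0.4, 0.4, 0.25, 0.25)
    within_block_corr: float = 0.7
    h: float = 10.0
    n_causal_blocks: int = 4
    varcomp: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(4.0, 1.0, 1.0)
    )
    family_type_mix: tuple[tuple[str, float], ...] = (("MZ", 1.0),)
    include_covariates: bool = False
    effect_size_convention: str = "variance_fraction"
    corr_scale: str = "latent"

    def __post_init__(self) -> None:
        if len(self.block_sizes) != len(self.block_mafs):
            raise ValueError("block_sizes and block_mafs must have equal length")
        if any(not 0.0 < f <= 0.5 for f in self.block_mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.h < 0:
            raise ValueError("h must be non-negative")
        if self.n_causal_blocks > len(self.block_sizes):
            raise ValueError("more causal blocks than blocks")
        if self.corr_scale not in ("latent", "binary"):
            raise ValueError("corr_scale must be 'latent' or 'binary'")

    @property
    def p_g(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def block_starts(self) -> tuple[int, ...]:
        return tuple(
            int(x) for x in np.concatenate([[0], np.cumsum(self.block_sizes)[:-1]])
        )

    @property
    def causal_indices(self) -> tuple[int, ...]:
        """First SNP of each causal block (0-based)."""
        return self.block_starts[: self.n_causal_blocks]

    def block_of(self, j: int) -> int:
        """Block index (0-based) containing SNP j."""
        return int(np.searchsorted(np.cumsum(self.block_sizes), j, side="right"))

    def causal_betas(self) -> np.ndarray:
        """Full-length coefficient vector beta_g implied by h."""
        beta = np.zeros(self.p_g)
        for k, j in enumerate(self.causal_indices):
            beta[j] = causal_effect_size(
                self.h,
                self.block_mafs[k],
                self.varcomp,
                convention=self.effect_size_convention,
            )
        return beta


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated dataset, for scoring selections."""

    causal_indices: tuple[int, ...]
    beta_g: np.ndarray
    varcomp: VarianceComponents
    h: float


def causal_effect_size(
    h: float,
    maf: float,
    varcomp: VarianceComponents,
    convention: str = "variance_fraction",
) -> float:
    """Coefficient of a causal SNP with per-SNP heritability parameter h.

    With genotype variance 2 MAF (1 - MAF) under Hardy-Weinberg, the
    ``variance_fraction`` convention makes the SNP explain h / (100 S) of the
    total error variance S = sigma_a^2 + sigma_c^2 + sigma_e^2 (i.e. the SNP
    contributes absolute variance h/100):

        beta = sqrt( h / (100 * 2 MAF (1 - MAF)) ).

    The ``scaled`` convention divides additionally by S,

        beta = sqrt( h / (100 * S * 2 MAF (1 - MAF)) ),

    so the explained fraction becomes h / (100 S^2).  The default is
    ``variance_fraction``; see docs/methods.md for why.
    """
    if h < 0:
        raise ValueError("h must be non-negative")
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie strictly in (0, 1)")
    denom = 100.0 * 2.0 * maf * (1.0 - maf)
    if convention == "variance_fraction":
        return float(np.sqrt(h / denom))
    if convention == "scaled":
        return float(np.sqrt(h / (denom * varcomp.total)))
    raise ValueError(f"unknown effect-size convention {convention!r}")


# ---------------------------------------------------------------------------
# correlated Bernoulli haplotypes (Gaussian copula)

_LATENT_CACHE: dict[tuple[float, float], float] = {}


def calibrate_latent_correlation(maf: float, target_corr: float) -> float:
    """Latent normal correlation giving binary-scale correlation ``target_corr``.

    Two standard normals with correlation rho, each thresholded at the MAF
    quantile, yield Bernoulli(maf) variables whose correlation is found by a
    bivariate-normal orthant probability; rho is solved by bisection.
    """
    if target_corr == 0.0:
        return 0.0
    key = (round(maf, 10), round(target_corr, 10))
    if key in _LATENT_CACHE:
        return _LATENT_CACHE[key]
    z = stats.norm.ppf(maf)

    def binary_corr(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [z, z], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - maf * maf) / (maf * (1.0 - maf))

    lo, hi = 0.0, 0.999999
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if binary_corr(mid) < target_corr:
            lo = mid
        else:
            hi = mid
    rho = 0.5 * (lo + hi)
    _LATENT_CACHE[key] = rho
    return rho


def _simulate_haplotypes(config: SimConfig, n_hap: int, rng: np.random.Generator) -> np.ndarray:
    """n_hap independent 0/1 allele vectors of length p_g with the block structure."""
    out = np.empty((n_hap, config.p_g), dtype=np.int8)
    col = 0
    for size, maf in zip(config.block_sizes, config.block_mafs):
        if config.corr_scale == "binary":
            rho = calibrate_latent_correlation(maf, config.within_block_corr)
        else:
            rho = config.within_block_corr
        common = rng.standard_normal((n_hap, 1))
        indiv = rng.standard_normal((n_hap, size))
        latent = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * indiv
        out[:, col : col + size] = latent < stats.norm.ppf(maf)
        col += size
    return out


def simulate_parent_alleles(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One haplotype-like 0/1 vector of length p_g (block-correlated Bernoulli)."""
    return _simulate_haplotypes(config, 1, rng)[0]


def simulate_family_genotypes(
    config: SimConfig, rng: np.random.Generator, family_type: str = "MZ"
) -> np.ndarray:
    """Genotypes of one family, rows [father, mother, child1, child2].

    Each parent is the sum of two independent allele vectors.  Biological
    children receive one randomly chosen allele vector from each parent; MZ
    twins share the transmitted vectors, DZ twins / full siblings draw
    transmissions independently.  Adopted children are built from fresh
    unrelated allele vectors.
    """
    hap = _simulate_haplotypes(config, 4, rng)
    father = hap[0] + hap[1]
    mother = hap[2] + hap[3]

    def biological_child(transmit=None):
        if transmit is None:
            transmit = (rng.integers(2), rng.integers(2))
        return hap[transmit[0]] + hap[2 + transmit[1]], transmit

    def adopted_child():
        extra = _simulate_haplotypes(config, 2, rng)
        return extra[0] + extra[1]

    if family_type == "MZ":
        child, _ = biological_child()
        children = [child, child.copy()]
    elif family_type in ("DZ", "non_twin_sibs"):
        children = [biological_child()[0], biological_child()[0]]
    elif family_type == "adopted":
        children = [adopted_child(), adopted_child()]
    elif family_type == "mixed_adopted_bio":
        children = [biological_child()[0], adopted_child()]
    else:
        raise ValueError(f"unknown family type {family_type!r}")
    return np.vstack([father, mother, children[0], children[1]])


def simulate_phenotypes(
    genotypes: np.ndarray,
    beta_g: np.ndarray,
    phi: np.ndarray,
    varcomp: VarianceComponents,
    rng: np.random.Generator,
    covariates: np.ndarray | None = None,
    beta_c: np.ndarray | None = None,
    alpha: float = 0.0,
) -> np.ndarray:
    """Trait vector of one family under the ACE error structure.

    y = alpha + G beta_g + C beta_c + a + c 1 + e with a ~ N(0, sigma_a^2 Phi),
    c ~ N(0, sigma_c^2) shared by the family, e ~ N(0, sigma_e^2 I).
    """
    G = np.asarray(genotypes, dtype=float)
    beta_g = np.asarray(beta_g, dtype=float)
    if G.shape[1] != beta_g.shape[0]:
        raise ValueError("beta_g length does not match the number of SNPs")
    n = G.shape[0]
    mean = alpha + G @ beta_g
    if covariates is not None and beta_c is not None and covariates.size:
        mean = mean + covariates @ beta_c
    if varcomp.sigma_a2 > 0:
        # Phi can be singular (MZ twins share genotype rows), so jitter before Cholesky
        L = np.linalg.cholesky(varcomp.sigma_a2 * phi + 1e-12 * np.eye(n))
        a = L @ rng.standard_normal(n)
    else:
        a = np.zeros(n)
    c = rng.normal(0.0, np.sqrt(varcomp.sigma_c2)) if varcomp.sigma_c2 > 0 else 0.0
    e = rng.normal(0.0, np.sqrt(varcomp.sigma_e2), size=n)
    return mean + a + c + e


def _draw_family_types(config: SimConfig, rng: np.random.Generator) -> list[str]:
    types = [t for t, _ in config.family_type_mix]
    probs = np.array([w for _, w in config.family_type_mix], dtype=float)
    probs = probs / probs.sum()
    if len(types) == 1:
        return [types[0]] * config.m
    return list(rng.choice(types, size=config.m, p=probs))


def simulate_dataset(
    config: SimConfig, seed_or_rng
) -> tuple[Dataset, SimTruth]:
    """Generate one complete dataset (with ground truth) under ``config``."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    beta_g = config.causal_betas()
    family_types = _draw_family_types(config, rng)
    phis = {t: build_kinship_matrix(t, 4) for t in set(family_types)}
    # Cholesky factors of sigma_a^2 Phi, reused across families of a type
    chol_a = {
        t: np.linalg.cholesky(config.varcomp.sigma_a2 * phi + 1e-12 * np.eye(4))
        if config.varcomp.sigma_a2 > 0
        else None
        for t, phi in phis.items()
    }
    covar_names: tuple[str, ...] = ()
    beta_c = None
    if config.include_covariates:
        covar_names = ("sex", "age_std")
        beta_c = np.array([0.5, 0.3])

    families = []
    sd_c = np.sqrt(config.varcomp.sigma_c2)
    sd_e = np.sqrt(config.varcomp.sigma_e2)
    for i, ftype in enumerate(family_types):
        G = simulate_family_genotypes(config, rng, ftype)
        phi = phis[ftype]
        if config.include_covariates:
            sex = rng.integers(0, 2, size=4).astype(float)
            age = np.concatenate([rng.normal(1.0, 0.3, 2), rng.normal(-1.0, 0.3, 2)])
            C = np.column_stack([sex, age])
        else:
            C = np.zeros((4, 0))
        mean = G @ beta_g
        if beta_c is not None and C.size:
            mean = mean + C @ beta_c
        L = chol_a[ftype]
        a = L @ rng.standard_normal(4) if L is not None else np.zeros(4)
        y = mean + a + rng.normal(0.0, sd_c) + rng.normal(0.0, sd_e, size=4)
        families.append(
            FamilyBlock(
                family_id=f"fam{i + 1}",
                y=y,
                G=G,
                C=C,
                phi=phi,
                member_roles=("father", "mother", "child", "child"),
                family_type=ftype,
            )
        )
    snp_ids = tuple(f"snp{j + 1}" for j in range(config.p_g))
    dataset = Dataset(families, snp_ids, covar_names)
    truth = SimTruth(
        causal_indices=config.causal_indices,
        beta_g=beta_g,
        varcomp=config.varcomp,
        h=config.h,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# selection metrics


@dataclass
class MetricsReport:
    """Strict and block-relaxed selection rates, per replication and averaged.

    TP: proportion of causal SNPs selected.  TN: proportion of non-causal
    SNPs not selected.  RTP: proportion of causal blocks with at least one
    selected SNP.  RTN: proportion of SNPs in the null block (no causal SNP)
    not selected.  At h = 0 there are no causal SNPs and TP/RTP are NaN.
    """

    tp: float
    tn: float
    rtp: float
    rtn: float
    per_rep: "np.ndarray | None" = None  # (reps, 4) columns tp, tn, rtp, rtn
    reps: int = 1

    def as_dict(self) -> dict[str, float]:
        return {"tp": self.tp, "tn": self.tn, "rtp": self.rtp, "rtn": self.rtn}


def compute_metrics(selected, config: SimConfig) -> MetricsReport:
    """Score one selected index set against the design's ground truth."""
    selected = set(int(j) for j in selected)
    if selected and (min(selected) < 0 or max(selected) >= config.p_g):
        raise IndexError("selected SNP index out of range")
    # at h = 0 no SNP is causal: TP/RTP are undefined, TN covers every SNP
    n_causal_blocks = config.n_causal_blocks if config.h > 0 else 0
    causal = set(config.causal_indices) if config.h > 0 else set()
    noncausal = set(range(config.p_g)) - causal
    n_blocks = len(config.block_sizes)
    causal_blocks = range(n_causal_blocks)
    null_blocks = set(range(config.n_causal_blocks, n_blocks))

    tp = len(selected & causal) / len(causal) if causal else float("nan")
    tn = len(noncausal - selected) / len(noncausal) if noncausal else float("nan")
    if n_causal_blocks:
        hits = sum(
            1
            for b in causal_blocks
            if any(config.block_of(j) == b for j in selected)
        )
        rtp = hits / n_causal_blocks
    else:
        rtp = float("nan")
    null_snps = {j for j in range(config.p_g) if config.block_of(j) in null_blocks}
    rtn = len(null_snps - selected) / len(null_snps) if null_snps else float("nan")
    return MetricsReport(tp=tp, tn=tn, rtp=rtp, rtn=rtn)


def average_metrics(reports: list[MetricsReport]) -> MetricsReport:
    """Average per-replication metrics (NaN-aware, e.g. TP at h = 0)."""
    arr = np.array([[r.tp, r.tn, r.rtp, r.rtn] for r in reports], dtype=float)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(arr, axis=0)
    return MetricsReport(
        tp=float(means[0]),
        tn=float(means[1]),
        rtp=float(means[2]),
        rtn=float(means[3]),
        per_rep=arr,
        reps=len(reports),
    )


def null_config(config: SimConfig) -> SimConfig:
    """Same design with h = 0 (no causal effects)."""
    return replace(config, h=0.0)
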