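"""Shared fixtures: small hand-built pedigrees and cached simulated fits."""

from __future__ import annotations

import numpy as np
import pytest

from snpevals import (
    Dataset,
    FamilyBlock,
    SimConfig,
    VarianceComponents,
    build_kinship_matrix,
    fit_ace_lmm,
    simulate_dataset,
)

#: reduced SNP panel (p_g = 15) for cheap end-to-end runs
SMALL_BLOCKS = dict(
    block_sizes=(3, 2, 3, 2, 5), block_mafs=(0.2, 0.4, 0.4, 0.25, 0.25)
)


@pytest.fixture(scope="session")
def toy_dataset() -> Dataset:
    """Three hand-built families (MZ, DZ, adopted), 2 SNPs, 1 covariate."""
    rng = np.random.default_rng(42)
    fams = []
    for i, ftype in enumerate(("MZ", "DZ", "adopted")):
        phi = build_kinship_matrix(ftype, 4)
        G = rng.integers(0, 3, size=(4, 2)).astype(float)
        if ftype == "MZ":
            G[3] = G[2]
        C = rng.standard_normal((4, 1))
        y = G @ np.array([0.5, -0.3]) + C[:, 0] * 0.2 + rng.standard_normal(4)
        fams.append(
            FamilyBlock(
                family_id=f"f{i}",
                y=y,
                G=G,
                C=C,
                phi=phi,
                member_roles=("father", "mother", "child", "child"),
                family_type=ftype,
            )
        )
    return Dataset(fams, ("rs1", "rs2"), ("age",))


@pytest.fixture(scope="session")
def sim_small():
    """m=120 MZ families, 15 SNPs, h=10: dataset + truth (cheap, reused)."""
    cfg = SimConfig(m=120, h=10.0, **SMALL_BLOCKS)
    ds, truth = simulate_dataset(cfg, 2024)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def sim_small_fit(sim_small):
    cfg, ds, truth = sim_small
    return cfg, ds, truth, fit_ace_lmm(ds)


@pytest.fixture(scope="session")
def sim_full_fit():
    """One full-scale dataset (m=250, 50 SNPs, h=10) and its fitted model."""
    cfg = SimConfig(h=10.0)
    ds, truth = simulate_dataset(cfg, 7)
    return cfg, ds, truth, fit_ace_lmm(ds)


@pytest.fixture()
def vc_default() -> VarianceComponents:
    return VarianceComponents(4.0, 1.0, 1.0)
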