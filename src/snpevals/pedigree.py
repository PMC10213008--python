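"""Pedigree data containers, expected-relatedness matrices, and file readers.

The unit of observation is a *nuclear family*: two parents plus one or two
children (biological twins, full siblings, or adoptees).  Families are
mutually unrelated, so the phenotype covariance of the whole sample is block
diagonal with one block per family.  Each family carries its own relatedness
matrix ``phi`` whose (s, t) entry is twice the kinship coefficient of
individuals s and t — 1 on the diagonal, 1 for monozygotic (MZ) twins, 1/2
for parent–(biological) child pairs, dizygotic twins and full siblings, and
0 for all pairs involving an adoptee or the two (unrelated) parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FamilyBlock",
    "Dataset",
    "build_kinship_matrix",
    "read_wide_csv",
    "read_plink_raw",
    "write_wide_csv",
    "FAMILY_TYPES",
]

#: Recognised nuclear-family types for :func:`build_kinship_matrix`.
FAMILY_TYPES = ("MZ", "DZ", "adopted", "non_twin_sibs", "mixed_adopted_bio")

_PARENT_ROLES = ("father", "mother")


def build_kinship_matrix(family_type: str, n_members: int = 4) -> np.ndarray:
    """Expected-relatedness matrix (twice the kinship coefficients) for one family.

    Members are ordered father, mother, child 1, child 2.  ``n_members`` may be
    4 (the standard pedigree), 3 (parents + one child) or 2 (parents only).
    For ``mixed_adopted_bio`` the biological child is member 3 and the adoptee
    member 4.

    Parameters
    ----------
    family_type
        One of ``MZ``, ``DZ``, ``adopted``, ``non_twin_sibs``,
        ``mixed_adopted_bio``.
    n_members
        Number of individuals in the family (2–4).

    Returns
    -------
    numpy.ndarray
        Symmetric ``(n_members, n_members)`` matrix with unit diagonal.
    """
    if family_type not in FAMILY_TYPES:
        raise ValueError(
            f"unknown family type {family_type!r}; expected one of {FAMILY_TYPES}"
        )
    if n_members not in (2, 3, 4):
        raise ValueError("n_members must be 2, 3 or 4 for a nuclear pedigree")
    if family_type == "mixed_adopted_bio" and n_members != 4:
        raise ValueError("mixed_adopted_bio requires both children (n_members=4)")

    phi = np.eye(n_members)
    if n_members == 2:  # parents only: unrelated pair
        return phi

    # parent-child sharing: 2 * (1/4) = 1/2 for biological children, 0 for adoptees
    child_parent = {
        "MZ": (0.5, 0.5),
        "DZ": (0.5, 0.5),
        "non_twin_sibs": (0.5, 0.5),
        "adopted": (0.0, 0.0),
        "mixed_adopted_bio": (0.5, 0.0),  # (biological, adopted)
    }[family_type]
    for c, share in zip(range(2, n_members), child_parent):
        phi[0, c] = phi[1, c] = phi[c, 0] = phi[c, 1] = share

    if n_members == 4:
        child_child = {
            "MZ": 1.0,
            "DZ": 0.5,
            "non_twin_sibs": 0.5,
            "adopted": 0.0,
            "mixed_adopted_bio": 0.0,
        }[family_type]
        phi[2, 3] = phi[3, 2] = child_child
    return phi


@dataclass
class FamilyBlock:
    """One pedigree: trait vector, genotypes, covariates and relatedness.

    Attributes
    ----------
    family_id
        Identifier of the pedigree.
    y
        Trait values, shape ``(n_i,)``.
    G
        Genotype dosages in {0, 1, 2}, shape ``(n_i, p_g)``.
    C
        Covariates, shape ``(n_i, p)`` (``p`` may be 0).
    phi
        Relatedness matrix (twice the kinship coefficients), ``(n_i, n_i)``.
    member_roles
        Per-individual role labels in {"father", "mother", "child"}.
    """

    family_id: str
    y: np.ndarray
    G: np.ndarray
    C: np.ndarray
    phi: np.ndarray
    member_roles: Sequence[str] = field(default_factory=tuple)
    family_type: str | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.C.size == 0:
            self.C = np.zeros((self.n_members, 0))
        self.phi = np.asarray(self.phi, dtype=float)
        self.validate()

    @property
    def n_members(self) -> int:
        return self.y.shape[0]

    def validate(self) -> None:
        n = self.n_members
        if n < 1:
            raise ValueError("family must contain at least one individual")
        if self.G.shape[0] != n or self.C.shape[0] != n:
            raise ValueError(
                f"family {self.family_id}: row counts of y/G/C disagree "
                f"({n}, {self.G.shape[0]}, {self.C.shape[0]})"
            )
        if self.phi.shape != (n, n):
            raise ValueError(f"family {self.family_id}: phi must be {n}x{n}")
        if not np.allclose(self.phi, self.phi.T):
            raise ValueError(f"family {self.family_id}: phi is not symmetric")
        if not np.allclose(np.diag(self.phi), 1.0):
            raise ValueError(f"family {self.family_id}: phi diagonal must be 1")
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError(f"family {self.family_id}: phi entries must lie in [0, 1]")
        if np.isnan(self.G).any():
            raise ValueError(f"family {self.family_id}: missing genotypes not allowed")
        if not np.isin(self.G, (0.0, 1.0, 2.0)).all():
            raise ValueError(f"family {self.family_id}: genotypes must be 0, 1 or 2")
        if self.member_roles and len(self.member_roles) != n:
            raise ValueError(f"family {self.family_id}: member_roles length mismatch")


@dataclass
class Dataset:
    """Ordered collection of :class:`FamilyBlock` sharing SNP and covariate panels."""

    families: list[FamilyBlock]
    snp_ids: Sequence[str]
    covariate_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.snp_ids = tuple(self.snp_ids)
        self.covariate_names = tuple(self.covariate_names)
        for fam in self.families:
            if fam.G.shape[1] != self.p_g:
                raise ValueError(f"family {fam.family_id}: expected {self.p_g} SNPs")
            if fam.C.shape[1] != self.p:
                raise ValueError(
                    f"family {fam.family_id}: expected {self.p} covariates"
                )

    @property
    def m(self) -> int:
        """Number of families."""
        return len(self.families)

    @property
    def n(self) -> int:
        """Total number of individuals."""
        return sum(f.n_members for f in self.families)

    @property
    def p_g(self) -> int:
        return len(self.snp_ids)

    @property
    def p(self) -> int:
        return len(self.covariate_names)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        """New dataset containing the families at ``indices`` (in that order)."""
        fams = [self.families[i] for i in indices]
        return Dataset(fams, self.snp_ids, self.covariate_names)

    def split_families(
        self, train_fraction: float, rng: np.random.Generator
    ) -> tuple["Dataset", "Dataset"]:
        """Family-level random split into (train, test)."""
        if not 0.0 < train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        perm = rng.permutation(self.m)
        n_train = int(round(train_fraction * self.m))
        n_train = min(max(n_train, 1), self.m - 1)
        return self.subset(np.sort(perm[:n_train])), self.subset(
            np.sort(perm[n_train:])
        )


# ---------------------------------------------------------------------------
# readers / writers


def _phi_for_family(
    family_id: str,
    roles: Sequence[str],
    family_types: Mapping[str, str] | None,
    zygosity: str | None,
) -> np.ndarray:
    ftype = None
    if family_types is not None:
        ftype = family_types.get(str(family_id))
    if ftype is None:
        ftype = zygosity
    if ftype is None:
        raise ValueError(
            f"family {family_id}: no family type given (provide family_types "
            "mapping or a zygosity column)"
        )
    phi4 = build_kinship_matrix(ftype, 4)
    # map observed members onto the canonical father/mother/child1/child2 order
    idx: list[int] = []
    next_child = 2
    for role in roles:
        if role == "father":
            idx.append(0)
        elif role == "mother":
            idx.append(1)
        elif role == "child":
            if next_child > 3:
                raise ValueError(f"family {family_id}: more than two children")
            idx.append(next_child)
            next_child += 1
        else:
            raise ValueError(f"family {family_id}: unknown role {role!r}")
    if len(set(idx)) != len(idx):
        raise ValueError(f"family {family_id}: duplicated parental role")
    return phi4[np.ix_(idx, idx)]


def read_wide_csv(
    path,
    snp_columns: Sequence[str] | None = None,
    covariate_columns: Sequence[str] = (),
    trait_column: str = "y",
    family_types: Mapping[str, str] | None = None,
) -> Dataset:
    """Read the wide per-individual CSV layout.

    Expected columns: ``family_id``, ``individual_id``, ``role`` (father /
    mother / child), optionally ``zygosity`` (a family type label), the trait
    column, covariate columns, and the SNP dosage columns.  When
    ``snp_columns`` is not given, every column not otherwise accounted for is
    treated as a SNP.
    """
    df = pd.read_csv(path)
    required = {"family_id", "individual_id", "role", trait_column}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wide CSV is missing columns: {sorted(missing)}")
    reserved = {"family_id", "individual_id", "role", "zygosity", trait_column}
    reserved |= set(covariate_columns)
    if snp_columns is None:
        snp_columns = [c for c in df.columns if c not in reserved]
    snp_df = df[list(snp_columns)]
    if snp_df.isna().any().any():
        raise ValueError("missing genotypes are not allowed")

    families: list[FamilyBlock] = []
    for fam_id, grp in df.groupby("family_id", sort=False):
        roles = list(grp["role"])
        zyg = str(grp["zygosity"].iloc[0]) if "zygosity" in grp.columns else None
        phi = _phi_for_family(str(fam_id), roles, family_types, zyg)
        ftype = (family_types or {}).get(str(fam_id), zyg)
        families.append(
            FamilyBlock(
                family_id=str(fam_id),
                y=grp[trait_column].to_numpy(float),
                G=grp[list(snp_columns)].to_numpy(float),
                C=grp[list(covariate_columns)].to_numpy(float)
                if covariate_columns
                else np.zeros((len(grp), 0)),
                phi=phi,
                member_roles=roles,
                family_type=ftype,
            )
        )
    return Dataset(families, snp_columns, covariate_columns)


def write_wide_csv(dataset: Dataset, path, family_types: Mapping[str, str] | None = None) -> None:
    """Write a :class:`Dataset` in the wide CSV layout read by :func:`read_wide_csv`."""
    rows = []
    for fam in dataset.families:
        roles = list(fam.member_roles) or ["child"] * fam.n_members
        for k in range(fam.n_members):
            row: dict[str, object] = {
                "family_id": fam.family_id,
                "individual_id": f"{fam.family_id}_{k + 1}",
                "role": roles[k],
                "y": fam.y[k],
            }
            ftype = (
                family_types.get(str(fam.family_id), fam.family_type)
                if family_types is not None
                else fam.family_type
            )
            if ftype is not None:
                row["zygosity"] = ftype
            for name, val in zip(dataset.covariate_names, fam.C[k]):
                row[name] = val
            for name, val in zip(dataset.snp_ids, fam.G[k]):
                row[name] = int(val)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plink_raw(
    path,
    trait_column: str = "PHENOTYPE",
    family_types: Mapping[str, str] | None = None,
    zygosity_default: str | None = None,
) -> Dataset:
    """Read a PLINK ``--recode A`` (``.raw``) additive-dosage table.

    Whitespace separated with header ``FID IID PAT MAT SEX PHENOTYPE`` followed
    by one column per SNP allele (``rs123_A`` style).  Individuals with both
    ``PAT`` and ``MAT`` equal to 0 are parents; others are children.  Only
    nuclear pedigrees (one generation of children) are supported; the family
    type comes from ``family_types`` keyed by FID (or ``zygosity_default``).
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", trait_column]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f".raw file is missing columns: {missing}")
    snp_cols = [c for c in df.columns if c not in meta]
    if df[snp_cols].isna().any().any():
        raise ValueError("missing genotypes are not allowed")

    families: list[FamilyBlock] = []
    for fid, grp in df.groupby("FID", sort=False):
        is_parent = (grp["PAT"].astype(str) == "0") & (grp["MAT"].astype(str) == "0")
        roles = []
        seen_father = False
        for parent, sex in zip(is_parent, grp["SEX"]):
            if parent:
                if int(sex) == 1 and not seen_father:
                    roles.append("father")
                    seen_father = True
                else:
                    roles.append("mother" if int(sex) == 2 else "father")
            else:
                roles.append("child")
        zyg = None
        if family_types is not None:
            zyg = family_types.get(str(fid))
        if zyg is None:
            zyg = zygosity_default
        phi = _phi_for_family(str(fid), roles, None, zyg)
        families.append(
            FamilyBlock(
                family_id=str(fid),
                y=grp[trait_column].to_numpy(float),
                G=grp[snp_cols].to_numpy(float),
                C=np.zeros((len(grp), 0)),
                phi=phi,
                member_roles=roles,
            )
        )
    return Dataset(families, snp_cols, ())
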