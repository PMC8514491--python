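"""Relationship matrices and pairwise kinship.

Three complementary views of relatedness drive the mixed models:

* the realized genomic relationship matrix G (VanRaden method 1,
  ``G = ZZ' / 2 sum p(1-p)`` with dosages centered at twice the sample
  allele frequency), which captures Mendelian-sampling deviations;
* the pedigree numerator relationship matrix A (tabular recursion),
  which carries only expected relationships; and
* the KING-robust pairwise kinship estimator with its degree
  classification bands, used to type relationships among broodstock
  without any pedigree.

A permutation Mantel test compares two relationship matrices over the
same individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .core import MISSING, GenotypeMatrix, Pedigree, UNKNOWN_PARENT

__all__ = [
    "RelationshipMatrix",
    "KinshipEstimate",
    "MantelResult",
    "compute_grm",
    "compute_amatrix",
    "king_kinship",
    "classify_degree",
    "mantel_test",
]

#: KING-robust kinship bands (closed below, open above), highest first.
DEGREE_BANDS: tuple[tuple[float, str], ...] = (
    (0.354, "duplicate"),
    (0.177, "1st-degree"),
    (0.0884, "2nd-degree"),
    (0.0442, "3rd-degree"),
)


@dataclass
class RelationshipMatrix:
    """Symmetric individuals x individuals relationship matrix."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "genomic" | "pedigree"
    c: float | None = None  # VanRaden normalisation constant (genomic only)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return RelationshipMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            c=self.c,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def from_tsv(cls, path, kind: str = "genomic") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(), kind=kind)


@dataclass
class KinshipEstimate:
    """KING-robust kinship for one pair, with the underlying counts."""

    id_i: str
    id_j: str
    n_sites: int  # co-observed sites
    n_het_i: int
    n_het_j: int
    n_het_het: int
    n_opp_hom: int
    phi: float  # NaN when undefined (no heterozygous sites)
    degree: str


@dataclass
class MantelResult:
    statistic: float
    n_permutations: int
    p_value: float


# ---------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------

def compute_grm(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 GRM from complete dosages.

    ``G = ZZ' / c`` with ``Z`` the dosage matrix centered column-wise at
    twice the sample allele frequency and ``c = 2 sum_k p_k (1 - p_k)``.
    Monomorphic columns contribute zero to both the numerator and c.
    """
    if (g.dosages == MISSING).any():
        raise ValueError("GRM requires complete genotypes; impute first")
    if g.n_samples < 2:
        raise ValueError("GRM needs at least two samples")
    M = g.dosages.astype(float)
    p = M.mean(axis=0) / 2.0
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c == 0.0:
        raise ValueError("all SNPs monomorphic: GRM undefined (c = 0)")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / c
    G = (G + G.T) / 2.0
    return RelationshipMatrix(ids=list(g.samples), values=G, kind="genomic", c=c)


# ---------------------------------------------------------------------
# pedigree numerator relationship matrix
# ---------------------------------------------------------------------

def compute_amatrix(
    ped: Pedigree,
    founder_relationships: Iterable[tuple[str, str, float]] | None = None,
) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular recursion.

    ``a_ii = 1 + 0.5 a(sire, dam)`` and ``a_ij = 0.5 (a_j,sire +
    a_j,dam)`` in parents-first order; an unknown parent contributes 0.
    Founders are unrelated and non-inbred unless prior pairwise values
    are supplied via ``founder_relationships``.
    """
    order = ped.topological_order()
    pos = {s: i for i, s in enumerate(order)}
    parents = ped.parents_of()
    n = len(order)
    A = np.zeros((n, n))
    if founder_relationships:
        for a, b, val in founder_relationships:
            A[pos[a], pos[b]] = A[pos[b], pos[a]] = val
    for i, ind in enumerate(order):
        sire, dam = parents[ind]
        si = pos[sire] if sire != UNKNOWN_PARENT else None
        di = pos[dam] if dam != UNKNOWN_PARENT else None
        if si is None and di is None:
            # founder: keep any pre-seeded prior relationships
            A[i, i] = max(A[i, i], 1.0)
            continue
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        inb = 0.5 * A[si, di] if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + inb
    # put back into pedigree order
    idx = np.array([pos[s] for s in ped.ids])
    return RelationshipMatrix(
        ids=ped.ids, values=A[np.ix_(idx, idx)], kind="pedigree"
    )


# ---------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------

def classify_degree(phi: float) -> str:
    """Relationship-degree label from the kinship coefficient bands."""
    if np.isnan(phi):
        return "undefined"
    for lo, label in DEGREE_BANDS:
        if phi >= lo:
            return label
    return "unrelated"


def king_kinship(
    g: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[KinshipEstimate]:
    """KING-robust (between-family) kinship for the given or all pairs.

    Over co-observed sites, with het counts ``N_i``, ``N_j``, both-het
    count ``N_hh`` and opposite-homozygote count ``N_oo``::

        phi = (N_hh - 2 N_oo) / (2 min(N_i, N_j))
              + 1/2 - (N_i + N_j) / (4 min(N_i, N_j))

    A pair with ``min(N_i, N_j) = 0`` gets ``phi = NaN`` and the
    ``"undefined"`` degree label rather than an exception.
    """
    if g.n_samples < 2:
        raise ValueError("kinship needs at least two samples")
    d = g.dosages
    obs = (d != MISSING).astype(np.float64)
    het = (d == 1).astype(np.float64)
    aa = (d == 0).astype(np.float64)
    bb = (d == 2).astype(np.float64)

    # all-pairs count matrices via matmuls (co-observation handled by
    # the indicator encodings: het/aa/bb are zero where missing)
    n_co = obs @ obs.T
    n_hh = het @ het.T
    n_oo = aa @ bb.T + bb @ aa.T
    n_het_i = het @ obs.T  # hets of i over sites co-observed with j

    idx = {s: i for i, s in enumerate(g.samples)}
    if pairs is None:
        pairs = [
            (g.samples[i], g.samples[j])
            for i in range(g.n_samples)
            for j in range(i + 1, g.n_samples)
        ]
    out = []
    for a, b in pairs:
        i, j = idx[a], idx[b]
        ni, nj = n_het_i[i, j], n_het_i[j, i]
        nmin = min(ni, nj)
        if nmin == 0:
            phi = float("nan")
        else:
            phi = (
                (n_hh[i, j] - 2.0 * n_oo[i, j]) / (2.0 * nmin)
                + 0.5
                - (ni + nj) / (4.0 * nmin)
            )
        out.append(
            KinshipEstimate(
                id_i=a,
                id_j=b,
                n_sites=int(n_co[i, j]),
                n_het_i=int(ni),
                n_het_j=int(nj),
                n_het_het=int(n_hh[i, j]),
                n_opp_hom=int(n_oo[i, j]),
                phi=phi,
                degree=classify_degree(phi),
            )
        )
    return out


def kinship_table(estimates: Iterable[KinshipEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.id_i, e.id_j, e.n_sites, e.phi, e.degree)
            for e in estimates
        ],
        columns=["id1", "id2", "n_sites", "phi", "degree"],
    )


# ---------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------

def mantel_test(
    m1: RelationshipMatrix,
    m2: RelationshipMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation of two relationship matrices.

    Pearson correlation of strictly-lower-triangle entries (similarity
    values, diagonal excluded); the p-value counts simultaneous
    row/column permutations of ``m2`` with r >= observed, with the
    add-one convention.
    """
    if m1.ids != m2.ids:
        raise ValueError("matrices must cover the same individuals in order")
    n = m1.n
    if n < 3:
        raise ValueError("Mantel test needs at least three individuals")
    il = np.tril_indices(n, k=-1)
    x = m1.values[il]
    if x.std() == 0.0:
        raise ValueError("constant lower triangle in first matrix")
    if m2.values[il].std() == 0.0:
        raise ValueError("constant lower triangle in second matrix")
    xc = (x - x.mean()) / x.std()

    def corr_with(B: np.ndarray) -> float:
        y = B[il]
        return float(np.mean(xc * (y - y.mean()) / y.std()))

    r_obs = corr_with(m2.values)
    rng = substream(seed, "mantel")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(m2.values[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    return MantelResult(
        statistic=r_obs,
        n_permutations=n_perm,
        p_value=(1 + hits) / (n_perm + 1),
    )
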