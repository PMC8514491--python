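"""Pedigree reconstruction from genotypes alone.

Individuals (parents and offspring together) are clustered under the
admixture model: genotype ``g_is`` is Binomial(2, sum_k q_ik f_ks) with
per-individual ancestry proportions Q and per-cluster allele
frequencies F.  The likelihood is maximised by EM; with enough clusters
each parental genome attracts its own cluster, an offspring's ancestry
vector sits at the midpoint of its parents', and parent pairs can be
assigned by nearest midpoint.  K is chosen by entry-wise masked
cross-validation; kinship typing among the parents (KING) supplies the
founder sib-structure, and everything is assembled into a pedigree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import cdist

from ._rng import substream
from .core import (
    MISSING,
    UNKNOWN_PARENT,
    ConfigurationError,
    GenotypeMatrix,
    Pedigree,
)
from .relatedness import KinshipEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "AdmixtureFit",
    "ParentAssignment",
    "admixture_em",
    "select_K",
    "assign_parent_pairs",
    "reconstruct_pedigree",
    "founder_sib_groups",
]

_F_EPS = 1e-6
_P_EPS = 1e-9


@dataclass
class AdmixtureFit:
    """Converged (or stopped) admixture model."""

    K: int
    ids: list[str]
    Q: np.ndarray  # (n, K) ancestry proportions, rows sum to 1
    F: np.ndarray  # (K, m) cluster allele frequencies in [0, 1]
    loglik_trace: list[float]
    converged: bool
    cv_error: float | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def q_of(self, sample_id: str) -> np.ndarray:
        return self.Q[self.ids.index(sample_id)]


@dataclass
class ParentAssignment:
    offspring: str
    dam: str
    sire: str
    score: float
    second_best: float
    ambiguous: bool


# ---------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------

def _em(
    G: np.ndarray,
    W: np.ndarray | None,
    Q: np.ndarray,
    F: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """EM iterations on the binomial admixture likelihood.

    ``W`` is an optional 0/1 observation-weight matrix (masked-entry CV
    treats held-out entries as unobserved); None means all observed.
    """
    n, m = G.shape
    G2 = 2.0 - G
    if W is None:
        row_tot = np.full(n, 2.0 * m)
        WG, WG2 = G, G2
    else:
        row_tot = 2.0 * W.sum(axis=1)
        WG, WG2 = W * G, W * G2
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        P = np.clip(Q @ F, _P_EPS, 1.0 - _P_EPS)
        if W is None:
            ll = float(np.sum(G * np.log(P) + G2 * np.log1p(-P)))
        else:
            ll = float(np.sum(WG * np.log(P) + WG2 * np.log1p(-P)))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        R1 = WG / P
        R0 = WG2 / (1.0 - P)
        # both updates use the same E-step (pre-update Q and F)
        T1 = Q * (R1 @ F.T)
        T0 = Q * (R0 @ (1.0 - F).T)
        N1 = F * (Q.T @ R1)
        N0 = (1.0 - F) * (Q.T @ R0)
        Q = (T1 + T0) / row_tot[:, None]
        Q = np.clip(Q, 0.0, None)
        Q /= Q.sum(axis=1, keepdims=True)
        F = np.clip(N1 / np.clip(N1 + N0, _P_EPS, None), _F_EPS, 1.0 - _F_EPS)
    return Q, F, trace, converged


def _init(
    G: np.ndarray,
    K: int,
    rng: np.random.Generator,
    how: str,
    anchor_rows: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    n, m = G.shape
    if how == "anchored":
        # one cluster seeded per anchor individual (e.g. the genotyped
        # broodstock, whose identity — but not pedigree — is known);
        # spare clusters start at perturbed population frequencies
        if not anchor_rows:
            raise ConfigurationError("anchored init needs anchor rows")
        if len(anchor_rows) > K:
            raise ConfigurationError(
                f"{len(anchor_rows)} anchors exceed K={K} clusters"
            )
        pbar = G.mean(axis=0) / 2.0
        F = np.empty((K, m))
        for k, row in enumerate(anchor_rows):
            F[k] = G[row] / 2.0
        for k in range(len(anchor_rows), K):
            F[k] = pbar + rng.normal(0.0, 0.05, m)
        F = np.clip(F, 0.02, 0.98)
        Q = np.full((n, K), 1.0 / K)
        for k, row in enumerate(anchor_rows):
            Q[row] = 0.1 / (K - 1) if K > 1 else 1.0
            Q[row, k] = 0.9
        Q /= Q.sum(axis=1, keepdims=True)
    elif how == "random":
        Q = rng.dirichlet(np.ones(K), size=n)
        F = rng.uniform(0.05, 0.95, size=(K, m))
    elif how == "kmeans":
        # cluster individuals in a low-rank genotype space; each cluster's
        # allele frequencies seed one ancestral population
        Gc = G - G.mean(axis=0)
        n_comp = int(min(n - 1, max(2 * K, 10), 60))
        _, _, Vt = np.linalg.svd(Gc, full_matrices=False)
        coords = Gc @ Vt[:n_comp].T
        _, labels = kmeans2(coords, K, minit="++", seed=rng, missing="warn")
        F = np.empty((K, m))
        for k in range(K):
            members = labels == k
            if members.any():
                F[k] = G[members].mean(axis=0) / 2.0
            else:
                F[k] = G[rng.integers(n)] / 2.0
        F = np.clip(F, 0.05, 0.95)
        Q = np.full((n, K), 0.1 / max(K - 1, 1))
        Q[np.arange(n), labels] = 0.9
        Q /= Q.sum(axis=1, keepdims=True)
    else:
        raise ConfigurationError(f"unknown init {how!r}")
    return Q, F


def admixture_em(
    g: GenotypeMatrix,
    K: int,
    max_iter: int = 300,
    tol: float = 1e-3,
    seed: int = 0,
    n_restarts: int = 1,
    init: str = "kmeans",
    anchor_ids: Sequence[str] | None = None,
) -> AdmixtureFit:
    """Fit the admixture model at fixed K, keeping the best restart.

    ``init="kmeans"`` seeds cluster frequencies from a k-means
    partition of the individuals in a low-rank genotype space (fast and
    stable at large K); ``init="random"`` draws Dirichlet ancestry rows
    and uniform frequencies; ``init="anchored"`` seeds one cluster per
    individual in ``anchor_ids`` (e.g. the genotyped broodstock, whose
    sample identity is observable even though the pedigree is not).
    Restarts after the first always use random initialisation.
    """
    if not (2 <= K <= g.n_samples):
        raise ConfigurationError(f"K={K} must lie in [2, n={g.n_samples}]")
    if (g.dosages == MISSING).any():
        raise ConfigurationError("admixture_em requires complete genotypes")
    G = g.dosages.astype(np.float64)
    anchor_rows = (
        [g.samples.index(s) for s in anchor_ids] if anchor_ids else None
    )
    best: AdmixtureFit | None = None
    for r in range(n_restarts):
        rng = substream(seed, "admixture", r)
        Q0, F0 = _init(G, K, rng, init if r == 0 else "random", anchor_rows)
        Q, F, trace, converged = _em(G, None, Q0, F0, max_iter, tol)
        fit = AdmixtureFit(
            K=K, ids=list(g.samples), Q=Q, F=F,
            loglik_trace=trace, converged=converged,
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def select_K(
    g: GenotypeMatrix,
    K_range: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 150,
    tol: float = 1e-2,
    init: str = "kmeans",
) -> tuple[int, dict[int, float]]:
    """Choose K by entry-wise masked cross-validation.

    Genotype entries are partitioned into ``folds`` random masks; each
    fold's entries are held out (treated as unobserved by EM) and
    predicted as ``2 Q F``; the CV error for a K is the mean squared
    dosage deviation over held-out entries, averaged over folds.
    """
    if len(K_range) == 0:
        raise ConfigurationError("empty K range")
    if folds < 2:
        raise ConfigurationError("need at least two folds")
    if (g.dosages == MISSING).any():
        raise ConfigurationError("select_K requires complete genotypes")
    G = g.dosages.astype(np.float64)
    n, m = G.shape
    rng = substream(seed, "cv-mask")
    fold_id = rng.permutation(np.arange(n * m) % folds).reshape(n, m)
    errors: dict[int, float] = {}
    for K in K_range:
        if not (2 <= K <= n):
            raise ConfigurationError(f"K={K} out of range [2, {n}]")
        fold_errs = []
        for f in range(folds):
            W = (fold_id != f).astype(np.float64)
            rngf = substream(seed, "cv-fit", K, f)
            Q0, F0 = _init(G, K, rngf, init)
            Q, F, _, _ = _em(G, W, Q0, F0, max_iter, tol)
            pred = 2.0 * (Q @ F)
            mask = fold_id == f
            fold_errs.append(float(np.mean((G[mask] - pred[mask]) ** 2)))
        errors[K] = float(np.mean(fold_errs))
        logger.info("select_K: K=%d cv_error=%.5f", K, errors[K])
    K_star = min(errors, key=errors.get)
    return K_star, errors


# ---------------------------------------------------------------------
# parentage
# ---------------------------------------------------------------------

def assign_parent_pairs(
    fit: AdmixtureFit,
    offspring_ids: Sequence[str],
    parent_ids: Sequence[str],
    parent_sexes: Mapping[str, str],
    gap_threshold: float = 0.05,
) -> list[ParentAssignment]:
    """Assign each offspring to the (dam, sire) pair whose ancestry
    midpoint is nearest its own ancestry vector (Euclidean on Q rows).

    An assignment is flagged ambiguous when the runner-up pair scores
    within ``gap_threshold`` of the best.
    """
    dams = [p for p in parent_ids if parent_sexes.get(p) == "F"]
    sires = [p for p in parent_ids if parent_sexes.get(p) == "M"]
    if not dams or not sires:
        raise ConfigurationError("need at least one dam and one sire")
    pos = {s: i for i, s in enumerate(fit.ids)}
    for sid in list(offspring_ids) + dams + sires:
        if sid not in pos:
            raise KeyError(f"no ancestry vector for {sid!r}")
    Qd = fit.Q[[pos[d] for d in dams]]
    Qs = fit.Q[[pos[s] for s in sires]]
    pairs = [(d, s) for d in dams for s in sires]
    mid = ((Qd[:, None, :] + Qs[None, :, :]) / 2.0).reshape(len(pairs), -1)
    Qo = fit.Q[[pos[o] for o in offspring_ids]]
    dist = cdist(Qo, mid)
    out = []
    for i, o in enumerate(offspring_ids):
        order = np.argsort(dist[i], kind="stable")
        best = order[0]
        score = float(dist[i, best])
        second = float(dist[i, order[1]]) if len(pairs) > 1 else float("inf")
        dam, sire = pairs[best]
        out.append(
            ParentAssignment(
                offspring=o,
                dam=dam,
                sire=sire,
                score=score,
                second_best=second,
                ambiguous=(second - score) < gap_threshold,
            )
        )
    return out


def founder_sib_groups(
    kinships: Iterable[KinshipEstimate],
    degrees: tuple[str, ...] = ("duplicate", "1st-degree"),
) -> list[set[str]]:
    """Single-linkage sib groups among founders from kinship calls."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: set[str] = set()
    for e in kinships:
        members.update((e.id_i, e.id_j))
        if e.degree in degrees:
            parent[find(e.id_i)] = find(e.id_j)
    groups: dict[str, set[str]] = {}
    for s in members:
        groups.setdefault(find(s), set()).add(s)
    return list(groups.values())


def reconstruct_pedigree(
    parent_kinships: Iterable[KinshipEstimate],
    assignments: Iterable[ParentAssignment],
    parent_sexes: Mapping[str, str],
    offspring_sexes: Mapping[str, str] | None = None,
) -> tuple[Pedigree, list[str]]:
    """Assemble founders and unambiguous parent-pair assignments.

    Returns the pedigree (founders with unknown parents, generation
    ``F0``; assigned offspring in ``F1``) and the list of offspring
    excluded for ambiguity.  Founder sib groups from the kinship calls
    are recorded in the pedigree order (grouped founders adjacent) but
    founder parents stay unknown.
    """
    offspring_sexes = offspring_sexes or {}
    groups = founder_sib_groups(parent_kinships)
    grouped: list[str] = []
    for grp in sorted(groups, key=lambda s: sorted(s)[0]):
        grouped.extend(sorted(grp))
    for p in parent_sexes:
        if p not in grouped:
            grouped.append(p)

    records = [
        (p, UNKNOWN_PARENT, UNKNOWN_PARENT, parent_sexes.get(p, "U"), "F0")
        for p in grouped
    ]
    excluded: list[str] = []
    for a in assignments:
        if a.dam not in parent_sexes or a.sire not in parent_sexes:
            raise KeyError(
                f"assignment for {a.offspring!r} references unknown parent"
            )
        if a.ambiguous:
            excluded.append(a.offspring)
            continue
        records.append(
            (a.offspring, a.sire, a.dam,
             offspring_sexes.get(a.offspring, "U"), "F1")
        )
    ped = Pedigree.from_records(records)
    ped.validate()
    if excluded:
        logger.info("excluded %d ambiguous offspring", len(excluded))
    return ped, excluded
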