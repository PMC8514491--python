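"""Genotype I/O, SNP quality control, LD-kNNi imputation, subset sampling.

QC mirrors a two-generation amplicon-panel workflow: biallelic SNPs with
minor allele frequency strictly inside (0.01, 0.4) in each generation,
then a >= 60% call-rate filter applied to the parental generation, the
survivors extracted from the offspring generation, and the call-rate
filter applied there too.  Missing calls on the retained panel are
imputed with LD-kNNi: the k nearest neighbours of an individual, with
distance measured over the sites in highest LD with the target site,
vote for the missing dosage weighted by inverse distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .core import MISSING, ConfigurationError, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "SNPSubset",
    "read_vcf",
    "write_vcf",
    "read_012",
    "write_012",
    "qc_filter",
    "ld_knni_impute",
    "sample_snp_subsets",
]


class EmptyPanelError(ValueError):
    """Every SNP was removed; downstream stages refuse empty input."""


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with one GT-only sample column per individual."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in g.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        v = g.variants
        for j in range(g.n_variants):
            calls = "\t".join(_GT_STRINGS[int(x)] for x in g.dosages[:, j])
            fh.write(
                f"{v['chrom'].iat[j]}\t{v['pos'].iat[j]}\t"
                f"{v['chrom'].iat[j]}_{v['pos'].iat[j]}\t"
                f"{v['ref'].iat[j]}\t{v['alt'].iat[j]}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a dosage matrix.

    Multiallelic records are skipped; their count is stored under
    ``meta["non_biallelic_skipped"]`` and folded into the QC report by
    :func:`qc_filter`.  Non-diploid calls raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dos_cols = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid call at {var.CHROM}:{var.POS} "
                    f"sample {samples[i]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = alleles[0] + alleles[1]
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dos_cols.append(col)
    vcf.close()
    if not rows:
        logger.warning("VCF %s contains no biallelic variants", path)
        dosages = np.empty((len(samples), 0), dtype=np.int8)
        variants = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    else:
        dosages = np.stack(dos_cols, axis=1)
        variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    if skipped:
        logger.warning("skipped %d multiallelic records in %s", skipped, path)
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosages=dosages,
        meta={"non_biallelic_skipped": skipped},
    )


def write_012(g: GenotypeMatrix, path) -> None:
    """012 TSV: header of variant ids, first column the sample id, NA missing."""
    df = pd.DataFrame(
        g.dosages.astype(object), index=pd.Index(g.samples, name="id"),
        columns=g.variant_ids,
    )
    df = df.where(g.dosages != MISSING, other=np.nan)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_012(g_path) -> GenotypeMatrix:
    df = pd.read_csv(g_path, sep="\t", index_col="id")
    dosages = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    chrom, pos = [], []
    for vid in df.columns:
        c, _, p = vid.rpartition("_")
        chrom.append(c)
        pos.append(int(p))
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(
        samples=[str(s) for s in df.index], variants=variants, dosages=dosages
    )


# ---------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-filter removal counts; categories are mutually exclusive."""

    input_variants: int
    removed: dict[str, int]
    retained: int

    CATEGORIES = (
        "non_biallelic",
        "absent_in_generation",
        "maf_low",
        "maf_high",
        "call_rate_f0",
        "call_rate_f1",
    )

    def __post_init__(self) -> None:
        total = self.retained + sum(self.removed.values())
        if total != self.input_variants:
            raise ValueError(
                f"QC counts do not conserve: {total} != {self.input_variants}"
            )

    def to_tsv(self, path) -> None:
        rows = [("input", self.input_variants)]
        rows += [(k, self.removed.get(k, 0)) for k in self.CATEGORIES]
        rows.append(("retained", self.retained))
        pd.DataFrame(rows, columns=["category", "count"]).to_csv(
            path, sep="\t", index=False
        )


def qc_filter(
    g: GenotypeMatrix,
    maf_low: float = 0.01,
    maf_high: float = 0.4,
    min_call_rate: float = 0.6,
    generation_labels: Mapping[str, str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the MAF-window and per-generation call-rate filters.

    ``generation_labels`` maps sample id to ``"F0"``/``"F1"`` (or any
    two labels; the lexicographically first is treated as the parental
    generation).  With no labels the population is a single group and
    the call-rate filter is applied once.

    MAF bounds are strict (MAF must exceed ``maf_low`` and stay below
    ``maf_high`` in every generation, computed on non-missing calls
    before any call-rate filtering); call rate is inclusive
    (>= ``min_call_rate`` retained).
    """
    if g.n_variants == 0:
        raise EmptyPanelError("input panel is empty")
    if generation_labels is None:
        groups = {"all": np.arange(g.n_samples)}
    else:
        labels = [generation_labels[s] for s in g.samples]
        groups = {
            lab: np.flatnonzero(np.array(labels) == lab)
            for lab in sorted(set(labels))
        }
    group_names = list(groups)

    m = g.n_variants
    # category assignment by precedence; -1 = retained so far
    category = np.full(m, "", dtype=object)

    def mark(mask: np.ndarray, name: str) -> None:
        mask = mask & (category == "")
        category[mask] = name

    freqs = {lab: g.allele_freq(idx) for lab, idx in groups.items()}
    absent = np.zeros(m, dtype=bool)
    low = np.zeros(m, dtype=bool)
    high = np.zeros(m, dtype=bool)
    for lab in group_names:
        f = freqs[lab]
        maf = np.minimum(f, 1.0 - f)
        absent |= np.isnan(f)
        low |= ~np.isnan(f) & (maf <= maf_low)
        high |= ~np.isnan(f) & (maf >= maf_high)
    mark(absent, "absent_in_generation")
    mark(low, "maf_low")
    mark(high, "maf_high")

    # call-rate: parental generation first, then offspring among survivors
    cr_names = (
        ["call_rate_f0"]
        if len(group_names) == 1
        else ["call_rate_f0", "call_rate_f1"]
    )
    for lab, cname in zip(group_names, cr_names):
        cr = g.call_rate(groups[lab])
        mark(cr < min_call_rate, cname)

    keep = np.flatnonzero(category == "")
    removed = {
        name: int((category == name).sum())
        for name in set(category)
        if name != ""
    }
    pre_skipped = int(g.meta.get("non_biallelic_skipped", 0))
    if pre_skipped:
        removed["non_biallelic"] = pre_skipped
    report = QCReport(
        input_variants=m + pre_skipped,
        removed=removed,
        retained=len(keep),
    )
    if len(keep) == 0:
        raise EmptyPanelError("all SNPs removed by QC")
    return g.take_variants(keep), report


# ---------------------------------------------------------------------
# LD-kNNi imputation
# ---------------------------------------------------------------------

def _ld_r2_block(
    A: np.ndarray, W: np.ndarray, A2: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Squared dosage correlation between target sites and all sites.

    Pairwise-complete: statistics accumulate only over individuals
    observed at both sites.  A = zero-filled dosages, W = observed mask
    (both float), A2 = A**2.
    """
    At, Wt, A2t = A[:, targets].T, W[:, targets].T, A2[:, targets].T
    n = Wt @ W
    sx = At @ W
    sy = Wt @ A
    sxy = At @ A
    sxx = A2t @ W
    syy = Wt @ A2
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r2 = cov**2 / (vx * vy)
    r2[~np.isfinite(r2)] = -1.0  # monomorphic / too few co-observations
    return r2


def ld_knni_impute(
    g: GenotypeMatrix, n_ld_sites: int = 30, k: int = 5
) -> GenotypeMatrix:
    """LD-kNNi genotype imputation (no pedigree, no phasing).

    For each missing call (individual i, site s): rank the other sites
    by squared dosage correlation with s, keep the top ``n_ld_sites``;
    measure the Manhattan distance (ignoring coordinates missing in
    either individual, +1 pseudo-count) from i to every individual
    observed at s over those sites; among the ``k`` nearest neighbours,
    impute the dosage maximising the sum of inverse distances of its
    carriers.  Observed calls are never altered.
    """
    D = g.dosages.astype(np.float64)
    D[D == MISSING] = np.nan
    obs = ~np.isnan(D)
    to_fill = np.flatnonzero(~obs.all(axis=0))
    if to_fill.size == 0:
        return g.copy()
    dead = np.flatnonzero(~obs.any(axis=0))
    if dead.size:
        raise ValueError(
            f"site {dead[0]} has no non-missing calls; drop it before imputing"
        )
    if g.n_variants - 1 < 1:
        raise ValueError("imputation needs at least two sites")

    A = np.nan_to_num(D)
    W = obs.astype(np.float64)
    A2 = A**2
    out = g.copy()
    out.haplotypes = None
    newdos = out.dosages

    block = 256
    n_top = min(n_ld_sites, g.n_variants - 1)
    for bstart in range(0, to_fill.size, block):
        targets = to_fill[bstart : bstart + block]
        r2 = _ld_r2_block(A, W, A2, targets)
        r2[np.arange(targets.size), targets] = -np.inf  # exclude self
        top = np.argpartition(-r2, n_top - 1, axis=1)[:, :n_top]
        for row, s in enumerate(targets):
            lset = top[row]
            X = D[:, lset]  # (n, L)
            cand = np.flatnonzero(obs[:, s])
            miss = np.flatnonzero(~obs[:, s])
            # pairwise Manhattan over co-observed coordinates, +1
            diff = np.abs(X[miss, None, :] - X[None, cand, :])
            dist = np.nansum(diff, axis=2) + 1.0
            kk = min(k, cand.size)
            if kk < k:
                logger.warning(
                    "site %d: only %d neighbours available (k=%d)",
                    s, cand.size, k,
                )
            nearest = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
            for mi, i in enumerate(miss):
                nb = cand[nearest[mi]]
                w = 1.0 / dist[mi, nearest[mi]]
                scores = np.zeros(3)
                np.add.at(scores, newdos[nb, s].astype(int), w)
                newdos[i, s] = int(np.argmax(scores))
    return out


# ---------------------------------------------------------------------
# subset sampling
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SNPSubset:
    """One random draw of SNP indices from a parent panel."""

    subset_size: int
    replicate_index: int  # 1-based
    indices: np.ndarray  # unique, sorted, < m_total
    seed: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if len(idx) != self.subset_size or len(np.unique(idx)) != len(idx):
            raise ValueError("subset indices must be unique with |idx| = size")
        object.__setattr__(self, "indices", np.sort(idx))


def sample_snp_subsets(
    m_total: int,
    sizes: Sequence[int],
    replicates: int = 10,
    seed: int = 0,
) -> list[SNPSubset]:
    """Uniform without-replacement SNP subsets, independent per (size, rep)."""
    for size in sizes:
        if size > m_total:
            raise ConfigurationError(
                f"subset size {size} exceeds panel size {m_total}"
            )
    subsets = []
    for size in sizes:
        for rep in range(1, replicates + 1):
            rng = substream(seed, "subset", int(size), rep)
            idx = rng.choice(m_total, size=size, replace=False)
            subsets.append(
                SNPSubset(
                    subset_size=int(size),
                    replicate_index=rep,
                    indices=np.sort(idx),
                    seed=seed,
                )
            )
    return subsets
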