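"""Breeding-population simulator.

Emulates a two-generation aquaculture design: a small founder set with
internal full-sib/half-sib structure (made genuine by simulating the
founders' own unobserved parents), a factorial mating of a few dams and
sires into many full-sib families, and polygenic additive traits with a
configurable heritability, optional full-sib common-environment variance
and sex-restricted recording.

Linkage matters here: Mendelian-sampling variance among full sibs — the
quantity that separates genomic from pedigree relationships — vanishes
with fully independent loci.  Meiosis therefore draws Poisson crossover
counts per chromosome (Haldane, no interference) on a genetic map of 22
chromosomes of 100 cM by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .core import (
    MISSING,
    UNKNOWN_PARENT,
    ConfigurationError,
    GenotypeMatrix,
    Pedigree,
    TraitTable,
    TrueGeneticValues,
)

__all__ = [
    "TraitSpec",
    "SimConfig",
    "DEFAULT_FOUNDER_DESIGN",
    "simulate_founders",
    "simulate_offspring",
    "simulate_traits",
    "apply_genotyping_noise",
    "simulate_population",
    "stack_samples",
]


@dataclass(frozen=True)
class TraitSpec:
    """One polygenic additive trait.

    Parameters
    ----------
    name : trait label.
    h2 : narrow-sense heritability in (0, 1), the generative
        var(TBV)/var(phenotype) ratio.
    sex : restrict recording to ``"M"`` or ``"F"`` (None = both sexes).
    record_fraction : fraction of sex-eligible individuals with a
        recorded phenotype (emulates incomplete phenotyping at harvest).
    n_causal : number of causal SNPs (None = all SNPs causal).
    common_env : full-sib common-environment fraction of phenotypic
        variance (c2); 0 disables the term.
    mu : trait mean (intercept of the generative model).
    """

    name: str
    h2: float
    sex: str | None = None
    record_fraction: float = 1.0
    n_causal: int | None = None
    common_env: float = 0.0
    mu: float = 0.0


# Founder layout: group kind + one sex letter per member.  The default
# mirrors a 28-fish broodstock of six full-sib families, two half-sib
# pairs and one lone female, giving 9 dams and 19 sires.
DEFAULT_FOUNDER_DESIGN: tuple[tuple[str, str], ...] = (
    ("fullsib", "FMMM"),
    ("fullsib", "FMMM"),
    ("fullsib", "FMMM"),
    ("fullsib", "FMMM"),
    ("fullsib", "FMMM"),
    ("fullsib", "FMM"),
    ("halfsib", "FM"),
    ("halfsib", "FM"),
    ("singleton", "F"),
)

DEFAULT_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("SL", 0.538, record_fraction=695 / 712),
    TraitSpec("BW", 0.557, record_fraction=695 / 712),
    TraitSpec("TW", 0.686, sex="M", record_fraction=0.69),
)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated breeding population."""

    n_snps: int = 4075
    n_chromosomes: int = 22
    chromosome_length_cM: float = 100.0
    maf_low: float = 0.01
    maf_high: float = 0.4
    founder_design: tuple[tuple[str, str], ...] = DEFAULT_FOUNDER_DESIGN
    n_dams: int = 9
    n_sires: int = 19
    n_families: int = 129
    offspring_total: int = 712
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    # amplicon-panel data quality: dropout and miscall rates applied by
    # the (separate) genotyping-noise stage
    missing_rate: float = 0.05
    genotype_error_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.maf_low < self.maf_high <= 0.5):
            raise ConfigurationError(
                "need 0 < maf_low < maf_high <= 0.5, got "
                f"({self.maf_low}, {self.maf_high})"
            )
        for t in self.traits:
            if not (0.0 < t.h2 < 1.0):
                raise ConfigurationError(
                    f"trait {t.name!r}: h2 must lie in the open interval "
                    f"(0, 1), got {t.h2}"
                )
            if t.common_env < 0 or t.h2 + t.common_env >= 1.0:
                raise ConfigurationError(
                    f"trait {t.name!r}: h2 + common_env must be < 1"
                )
            if t.sex not in (None, "M", "F"):
                raise ConfigurationError(f"trait {t.name!r}: bad sex")
        if self.n_families > self.n_dams * self.n_sires:
            raise ConfigurationError(
                f"{self.n_families} families exceed the "
                f"{self.n_dams} x {self.n_sires} mating grid"
            )
        if self.offspring_total < self.n_families:
            raise ConfigurationError(
                "offspring_total must be >= n_families (every family "
                "contributes at least one offspring)"
            )
        for rate, label in (
            (self.missing_rate, "missing_rate"),
            (self.genotype_error_rate, "genotype_error_rate"),
        ):
            if not (0.0 <= rate < 1.0):
                raise ConfigurationError(f"{label} must lie in [0, 1)")
        kinds = {k for k, _ in self.founder_design}
        bad = kinds - {"fullsib", "halfsib", "singleton"}
        if bad:
            raise ConfigurationError(f"unknown founder group kind {bad}")


# ---------------------------------------------------------------------
# genetic map and meiosis
# ---------------------------------------------------------------------

def _variant_table(config: SimConfig) -> pd.DataFrame:
    """SNPs spread as evenly as possible over the chromosomes.

    ``cm`` holds the genetic-map position used by meiosis; the physical
    ``pos`` is a nominal 1-kb grid per chromosome.
    """
    n, k = config.n_snps, config.n_chromosomes
    per = np.full(k, n // k)
    per[: n % k] += 1
    rows = []
    for c in range(k):
        m_c = per[c]
        length = config.chromosome_length_cM
        for j in range(m_c):
            cm = (j + 1) * length / (m_c + 1)
            rows.append((f"chr{c + 1}", (j + 1) * 1000, "A", "G", cm))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "cm"])


def _chrom_slices(variants: pd.DataFrame) -> list[slice]:
    slices = []
    start = 0
    for _, grp in variants.groupby("chrom", sort=False):
        slices.append(slice(start, start + len(grp)))
        start += len(grp)
    return slices


def _meiosis(
    rng: np.random.Generator,
    haps: np.ndarray,  # (m, 2) parental haplotypes
    slices: Sequence[slice],
    cm: np.ndarray,
    length_cM: float,
) -> np.ndarray:
    """One gamete: Poisson crossovers per chromosome, no interference."""
    out = np.empty(haps.shape[0], dtype=np.int8)
    for sl in slices:
        start = int(rng.integers(2))
        n_x = int(rng.poisson(length_cM / 100.0)) if length_cM > 0 else 0
        if n_x == 0:
            out[sl] = haps[sl, start]
        else:
            xpos = np.sort(rng.uniform(0.0, length_cM, n_x))
            which = (start + np.searchsorted(xpos, cm[sl])) % 2
            out[sl] = haps[sl, :][np.arange(sl.stop - sl.start), which]
    return out


# ---------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------

def simulate_founders(config: SimConfig) -> tuple[GenotypeMatrix, Pedigree]:
    """Founder genotypes with genuine full-sib/half-sib structure.

    Per-SNP ancestral allele frequencies are drawn uniformly on
    (maf_low, maf_high); unobserved grandparents in linkage equilibrium
    are then crossed (with recombination) to produce each founder group.
    The grandparents are not emitted: founders carry unknown parents.
    """
    config.validate()
    rng = substream(config.seed, "founders")
    variants = _variant_table(config)
    slices = _chrom_slices(variants)
    cm = variants["cm"].to_numpy()
    m = config.n_snps
    p = rng.uniform(config.maf_low, config.maf_high, m)

    def fresh_parent() -> np.ndarray:
        # grandparent haplotype pair in linkage equilibrium
        return (rng.random((m, 2)) < p[:, None]).astype(np.int8)

    def child_of(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
        g1 = _meiosis(rng, pa, slices, cm, config.chromosome_length_cM)
        g2 = _meiosis(rng, pb, slices, cm, config.chromosome_length_cM)
        return np.stack([g1, g2], axis=1)  # (m, 2)

    haplotypes: list[np.ndarray] = []
    sexes: list[str] = []
    group_labels: list[int] = []
    for gi, (kind, sex_string) in enumerate(config.founder_design):
        size = len(sex_string)
        if kind == "fullsib":
            pa, pb = fresh_parent(), fresh_parent()
            members = [child_of(pa, pb) for _ in range(size)]
        elif kind == "halfsib":
            if size != 2:
                raise ConfigurationError("halfsib groups must have size 2")
            shared = fresh_parent()
            members = [
                child_of(shared, fresh_parent()),
                child_of(shared, fresh_parent()),
            ]
        else:  # singleton
            if size != 1:
                raise ConfigurationError("singleton groups must have size 1")
            members = [child_of(fresh_parent(), fresh_parent())]
        haplotypes.extend(members)
        sexes.extend(sex_string)
        group_labels.extend([gi] * size)

    n_f = sum(1 for s in sexes if s == "F")
    n_m = sum(1 for s in sexes if s == "M")
    if config.n_dams > n_f or config.n_sires > n_m:
        raise ConfigurationError(
            f"mating design needs {config.n_dams} dams / {config.n_sires} "
            f"sires but the founder design provides {n_f} females / "
            f"{n_m} males"
        )

    n = len(haplotypes)
    width = max(2, len(str(n)))
    ids = [f"F0_{i + 1:0{width}d}" for i in range(n)]
    hap = np.stack(haplotypes, axis=0).transpose(0, 1, 2)  # (n, m, 2)
    geno = GenotypeMatrix(
        samples=ids,
        variants=variants,
        dosages=hap.sum(axis=2).astype(np.int8),
        haplotypes=hap,
        meta={"founder_group": dict(zip(ids, group_labels))},
    )
    ped = Pedigree.from_records(
        [(i, UNKNOWN_PARENT, UNKNOWN_PARENT, s, "F0") for i, s in zip(ids, sexes)]
    )
    return geno, ped


# ---------------------------------------------------------------------
# offspring
# ---------------------------------------------------------------------

def simulate_offspring(
    founders: GenotypeMatrix,
    founder_pedigree: Pedigree,
    config: SimConfig,
) -> tuple[GenotypeMatrix, Pedigree]:
    """F1 generation from a factorial dam x sire mating.

    Distinct (dam, sire) pairs are drawn without replacement from the
    mating grid; every family receives one offspring and the remainder
    is shared multinomially (uniform weights).  Each offspring is one
    meiosis per parent; sex is assigned 1:1.

    Returns the offspring genotype matrix and the combined
    founder + offspring pedigree.
    """
    config.validate()
    if founders.haplotypes is None:
        raise ConfigurationError(
            "founder genotypes must carry phased haplotypes (simulate_founders)"
        )
    sex = founder_pedigree.sex_of()
    dams = [s for s in founders.samples if sex.get(s) == "F"][: config.n_dams]
    sires = [s for s in founders.samples if sex.get(s) == "M"][: config.n_sires]
    if len(dams) < config.n_dams or len(sires) < config.n_sires:
        raise ConfigurationError("not enough founders of each sex for mating")

    rng = substream(config.seed, "meiosis")
    grid = [(d, s) for d in dams for s in sires]
    pair_idx = rng.choice(len(grid), size=config.n_families, replace=False)
    pairs = [grid[i] for i in pair_idx]
    extra = rng.multinomial(
        config.offspring_total - config.n_families,
        np.full(config.n_families, 1.0 / config.n_families),
    )
    fam_sizes = 1 + extra

    slices = _chrom_slices(founders.variants)
    cm = founders.variants["cm"].to_numpy()
    hap_of = {s: founders.haplotypes[i] for i, s in enumerate(founders.samples)}
    length = config.chromosome_length_cM

    n_off = int(fam_sizes.sum())
    width = max(4, len(str(n_off)))
    hap = np.empty((n_off, founders.n_variants, 2), dtype=np.int8)
    records = []
    ids = []
    i = 0
    for (dam, sire), size in zip(pairs, fam_sizes):
        for _ in range(size):
            oid = f"F1_{i + 1:0{width}d}"
            hap[i, :, 0] = _meiosis(rng, hap_of[dam], slices, cm, length)
            hap[i, :, 1] = _meiosis(rng, hap_of[sire], slices, cm, length)
            osex = "M" if rng.random() < 0.5 else "F"
            records.append((oid, sire, dam, osex, "F1"))
            ids.append(oid)
            i += 1

    geno = GenotypeMatrix(
        samples=ids,
        variants=founders.variants.copy(),
        dosages=hap.sum(axis=2).astype(np.int8),
        haplotypes=hap,
    )
    ped = Pedigree(
        pd.concat(
            [founder_pedigree.table, Pedigree.from_records(records).table],
            ignore_index=True,
        )
    )
    ped.validate()
    return geno, ped


def stack_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices over the same variant set (founders + offspring)."""
    if not a.variants[["chrom", "pos"]].equals(b.variants[["chrom", "pos"]]):
        raise ValueError("variant sets differ")
    haps = None
    if a.haplotypes is not None and b.haplotypes is not None:
        haps = np.concatenate([a.haplotypes, b.haplotypes], axis=0)
    return GenotypeMatrix(
        samples=list(a.samples) + list(b.samples),
        variants=a.variants.copy(),
        dosages=np.concatenate([a.dosages, b.dosages], axis=0),
        haplotypes=haps,
        meta={**a.meta, **b.meta},
    )


# ---------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------

def simulate_traits(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: SimConfig,
) -> tuple[TraitTable, TrueGeneticValues]:
    """Polygenic phenotypes: y = mu + TBV (+ family env) + residual.

    SNP effects are i.i.d. normal on the causal subset; TBV is the
    centered-dosage x effect product; the residual (and optional
    full-sib common-environment) variance is set from the realized TBV
    variance so the variance fractions equal the configured h2 (and c2)
    in expectation.  Recording honours the trait's sex restriction and
    ``record_fraction``; the pedigree supplies sexes and families.
    """
    config.validate()
    if (genotypes.dosages == MISSING).any():
        raise ConfigurationError("simulate_traits requires complete genotypes")
    D = genotypes.dosages.astype(float)
    Z = D - D.mean(axis=0)
    sex = pedigree.sex_of()
    fam_of: dict[str, int] = {}
    for fi, members in enumerate(pedigree.families().values()):
        for mid in members:
            fam_of[mid] = fi

    values: dict[str, np.ndarray] = {}
    tbvs: dict[str, np.ndarray] = {}
    effects: dict[str, np.ndarray] = {}
    mus: dict[str, float] = {}
    n, m = D.shape
    for t in config.traits:
        rng = substream(config.seed, "traits", t.name)
        beta = np.zeros(m)
        n_causal = m if t.n_causal is None else t.n_causal
        if n_causal > 0:
            causal = (
                np.arange(m)
                if n_causal >= m
                else np.sort(rng.choice(m, n_causal, replace=False))
            )
            beta[causal] = rng.normal(0.0, 1.0, len(causal))
        tbv = Z @ beta
        var_t = float(tbv.var())
        if var_t > 0:
            sigma_f2 = var_t * t.common_env / t.h2
            sigma_e2 = var_t * (1.0 - t.h2 - t.common_env) / t.h2
        else:  # null architecture: pure-noise phenotype
            sigma_f2, sigma_e2 = 0.0, 1.0
        y = t.mu + tbv + rng.normal(0.0, np.sqrt(sigma_e2), n)
        if sigma_f2 > 0:
            fam_idx = np.array(
                [fam_of.get(s, -1) for s in genotypes.samples]
            )
            n_fam = fam_idx.max() + 1
            fam_eff = rng.normal(0.0, np.sqrt(sigma_f2), max(n_fam, 1))
            y = y + np.where(fam_idx >= 0, fam_eff[fam_idx], 0.0)
        eligible = np.array(
            [t.sex is None or sex.get(s) == t.sex for s in genotypes.samples]
        )
        recorded = eligible & (rng.random(n) < t.record_fraction)
        values[t.name] = np.where(recorded, y, np.nan)
        tbvs[t.name] = tbv
        effects[t.name] = beta
        mus[t.name] = t.mu

    idx = pd.Index(genotypes.samples, name="id")
    return (
        TraitTable(pd.DataFrame(values, index=idx)),
        TrueGeneticValues(pd.DataFrame(tbvs, index=idx), effects, mus),
    )


# ---------------------------------------------------------------------
# genotyping noise
# ---------------------------------------------------------------------

def apply_genotyping_noise(
    genotypes: GenotypeMatrix, config: SimConfig
) -> GenotypeMatrix:
    """Independent per-call dropout and genotyping error (input untouched)."""
    config.validate()
    rng = substream(config.seed, "noise")
    out = genotypes.copy()
    out.haplotypes = None  # noisy calls are unphased
    d = out.dosages
    if config.genotype_error_rate > 0:
        err = rng.random(d.shape) < config.genotype_error_rate
        # replace by a uniform draw from the other two dosage values
        offset = rng.integers(1, 3, size=d.shape).astype(np.int8)
        d[err] = (d[err] + offset[err]) % 3
    if config.missing_rate > 0:
        drop = rng.random(d.shape) < config.missing_rate
        d[drop] = MISSING
    return out


def simulate_population(
    config: SimConfig,
) -> tuple[GenotypeMatrix, Pedigree, TraitTable, TrueGeneticValues]:
    """Founders + offspring + traits in one call (clean genotypes).

    Returns the stacked founder+offspring genotype matrix, the full
    pedigree, the trait table (offspring phenotypes; founders
    unrecorded) and the ground-truth genetic values.
    """
    founders, fped = simulate_founders(config)
    offspring, ped = simulate_offspring(founders, fped, config)
    traits, tgv = simulate_traits(offspring, ped, config)
    return stack_samples(founders, offspring), ped, traits, tgv
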