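"""Shared domain containers: genotype matrices, pedigrees, trait tables.

The allele-dosage matrix (individuals x SNPs, counts of the alternate
allele, ``MISSING`` = -1 for a failed call) is the lingua franca passed
between all modules; the pedigree drives the numerator relationship
matrix and the simulator.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid call in a dosage matrix.
MISSING: int = -1

#: Code for an unknown parent in pedigree files.
UNKNOWN_PARENT: str = "0"

VALID_DOSAGES = frozenset({0, 1, 2, MISSING})


class ConfigurationError(ValueError):
    """An input or configuration violates a documented precondition."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage table with sample/variant metadata.

    Parameters
    ----------
    samples : ordered sample identifiers (length n).
    variants : DataFrame with columns ``chrom``, ``pos``, ``ref``, ``alt``
        (extra columns such as a genetic-map position ``cm`` are carried
        along untouched); positions strictly increase within a chromosome.
    dosages : (n, m) integer array over {0, 1, 2, MISSING}.
    haplotypes : optional (n, m, 2) phased 0/1 array kept by the simulator
        so gametes can be formed; dropped by I/O round trips.
    meta : free-form provenance (e.g. multiallelic records skipped on read).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but {n} dosage rows"
            )
        if m != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variants but {m} dosage columns"
            )
        self.variants = self.variants.reset_index(drop=True)

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        v = self.variants
        return [f"{c}_{p}" for c, p in zip(v["chrom"], v["pos"])]

    def validate(self) -> None:
        """Check dosage domain and per-chromosome position ordering."""
        bad = ~np.isin(self.dosages, list(VALID_DOSAGES))
        if bad.any():
            raise ValueError("dosages contain values outside {0,1,2,MISSING}")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("variant positions not strictly increasing")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (self.n_samples, self.n_variants, 2):
                raise ValueError("haplotype array shape mismatch")

    # -- derived quantities --------------------------------------------
    def observed_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls.

        NaN where a SNP has no observed call in the selected samples.
        """
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)
        return np.where(n_obs > 0, freq, np.nan)

    def call_rate(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        return (d != MISSING).mean(axis=0)

    def missing_fraction(self) -> float:
        return float((self.dosages == MISSING).mean())

    # -- subsetting ----------------------------------------------------
    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx].copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx].copy(),
            meta=dict(self.meta),
        )

    def take_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(ids)
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        idx = np.array([pos[s] for s in ids], dtype=int)
        return GenotypeMatrix(
            samples=ids,
            variants=self.variants.copy(),
            dosages=self.dosages[idx].copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx].copy(),
            meta=dict(self.meta),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.copy(),
            dosages=self.dosages.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
            meta=dict(self.meta),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.variants[["chrom", "pos", "ref", "alt"]].equals(
                other.variants[["chrom", "pos", "ref", "alt"]]
            )
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class Pedigree:
    """Acyclic id/sire/dam/sex/generation table.

    ``table`` columns: ``id``, ``sire``, ``dam`` (``"0"`` = unknown),
    ``sex`` (``"M"``/``"F"``/``"U"``), ``generation`` (free label,
    e.g. ``"F0"``/``"F1"``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["id", "sire", "dam", "sex", "generation"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns {missing}")
        self.table = self.table[required].reset_index(drop=True)
        if self.table["id"].duplicated().any():
            dup = self.table.loc[self.table["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate pedigree id {dup!r}")

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def sex_of(self) -> dict[str, str]:
        return dict(zip(self.table["id"], self.table["sex"]))

    def parents_of(self) -> dict[str, tuple[str, str]]:
        return {
            r.id: (r.sire, r.dam)
            for r in self.table.itertuples(index=False)
        }

    def founders(self) -> list[str]:
        t = self.table
        mask = (t["sire"] == UNKNOWN_PARENT) & (t["dam"] == UNKNOWN_PARENT)
        return t.loc[mask, "id"].tolist()

    def offspring(self) -> list[str]:
        t = self.table
        mask = (t["sire"] != UNKNOWN_PARENT) | (t["dam"] != UNKNOWN_PARENT)
        return t.loc[mask, "id"].tolist()

    def families(self) -> dict[tuple[str, str], list[str]]:
        """Full-sib families: offspring grouped by the exact (dam, sire) pair."""
        fams: dict[tuple[str, str], list[str]] = {}
        for r in self.table.itertuples(index=False):
            if r.sire == UNKNOWN_PARENT and r.dam == UNKNOWN_PARENT:
                continue
            fams.setdefault((r.dam, r.sire), []).append(r.id)
        return fams

    def topological_order(self) -> list[str]:
        """Parents-before-offspring order; raises on a cycle naming an id."""
        known = set(self.ids)
        ts: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
        for r in self.table.itertuples(index=False):
            preds = [p for p in (r.sire, r.dam) if p != UNKNOWN_PARENT]
            unknown = [p for p in preds if p not in known]
            if unknown:
                raise ValueError(
                    f"individual {r.id!r} lists unknown parent {unknown[0]!r}"
                )
            ts.add(r.id, *preds)
        try:
            return list(ts.static_order())
        except graphlib.CycleError as err:
            cycle = err.args[1]
            raise ValueError(f"pedigree cycle involving {cycle[0]!r}") from err

    def validate(self) -> None:
        """Acyclicity and sex consistency (sires male, dams female)."""
        self.topological_order()
        sex = self.sex_of()
        for r in self.table.itertuples(index=False):
            if r.sire != UNKNOWN_PARENT and sex.get(r.sire) == "F":
                raise ValueError(f"sire {r.sire!r} of {r.id!r} is female")
            if r.dam != UNKNOWN_PARENT and sex.get(r.dam) == "M":
                raise ValueError(f"dam {r.dam!r} of {r.id!r} is male")

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype=str))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "Pedigree":
        return cls(
            pd.DataFrame(
                records, columns=["id", "sire", "dam", "sex", "generation"]
            )
        )


@dataclass
class TraitTable:
    """Phenotype values per individual and trait; NaN = unrecorded."""

    values: pd.DataFrame  # index: individual id; one column per trait

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def recorded(self, trait: str) -> pd.Series:
        """Non-missing phenotype values for one trait, indexed by id."""
        return self.values[trait].dropna()

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t", index_col="id"))


@dataclass
class TrueGeneticValues:
    """Ground truth from the simulator: per-trait TBVs and SNP effects."""

    tbv: pd.DataFrame  # index id, one column per trait
    effects: Mapping[str, np.ndarray]  # trait -> per-SNP additive effect
    mu: Mapping[str, float]  # trait -> intercept
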