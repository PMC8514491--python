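"""Shared fixtures: simulated populations reused across the suite."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import aquagp as ag
from aquagp.core import GenotypeMatrix


def clean_config(**kw) -> ag.SimConfig:
    """SimConfig with the genotyping-noise stage disabled."""
    kw.setdefault("missing_rate", 0.0)
    kw.setdefault("genotype_error_rate", 0.0)
    return ag.SimConfig(**kw)


@pytest.fixture(scope="session")
def pop4000():
    """Default-design population (28 founders, 129 families, 712
    offspring) on a clean 4000-SNP panel."""
    cfg = clean_config(seed=3, n_snps=4000)
    geno, ped, traits, tgv = ag.simulate_population(cfg)
    return SimpleNamespace(cfg=cfg, geno=geno, ped=ped, traits=traits, tgv=tgv)


@pytest.fixture(scope="session")
def small_pop():
    """Cheap population for unit tests: 20 families, 80 offspring, 300 SNPs."""
    cfg = clean_config(
        seed=11, n_snps=300, n_chromosomes=4, n_families=20, offspring_total=80,
        traits=(ag.TraitSpec("T", 0.5),),
    )
    geno, ped, traits, tgv = ag.simulate_population(cfg)
    return SimpleNamespace(cfg=cfg, geno=geno, ped=ped, traits=traits, tgv=tgv)


def toy_matrix(dosages, chrom="chr1") -> GenotypeMatrix:
    """GenotypeMatrix around a literal dosage array."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    return GenotypeMatrix(
        samples=[f"s{i + 1}" for i in range(n)],
        variants=pd.DataFrame(
            {
                "chrom": chrom,
                "pos": (np.arange(m) + 1) * 100,
                "ref": "A",
                "alt": "G",
            }
        ),
        dosages=d,
    )
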