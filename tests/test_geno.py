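"""Genotype I/O round trips, QC filtering, LD-kNNi imputation, subsets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aquagp as ag
from aquagp.core import MISSING, ConfigurationError
from aquagp.geno import EmptyPanelError
from aquagp.popsim import stack_samples

from conftest import clean_config, toy_matrix
from _oracles import modal_impute


# ---------------------------------------------------------------- I/O

def test_vcf_round_trip_preserves_missing(tmp_path):
    g = toy_matrix([[0, 1, 2, MISSING], [2, MISSING, 1, 0], [1, 1, 0, 2]])
    path = tmp_path / "x.vcf"
    ag.write_vcf(g, path)
    assert g.equals(ag.read_vcf(path))


def test_012_round_trip(tmp_path):
    g = toy_matrix([[0, 1, 2], [MISSING, 2, 0]])
    path = tmp_path / "x.tsv"
    ag.write_012(g, path)
    g2 = ag.read_012(path)
    assert np.array_equal(g.dosages, g2.dosages)
    assert g.samples == g2.samples


def test_multiallelic_records_skipped_and_counted(tmp_path):
    path = tmp_path / "m.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "chr1\t10\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\n"
        "chr1\t20\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        "chr1\t30\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\n"
    )
    g = ag.read_vcf(path)
    assert g.n_variants == 2
    assert g.meta["non_biallelic_skipped"] == 1
    # skipped count flows into the QC report
    _, report = ag.qc_filter(g, maf_low=0.0001, maf_high=0.49999)
    assert report.removed.get("non_biallelic") == 1


def test_empty_vcf_gives_empty_matrix(tmp_path):
    path = tmp_path / "e.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
    )
    g = ag.read_vcf(path)
    assert g.n_variants == 0 and g.n_samples == 1


# ----------------------------------------------------------------- QC

def _two_generation_matrix():
    """6 F0 + 6 F1 samples with crafted per-SNP properties."""
    # SNP columns:
    # 0: healthy (MAF ~0.25 everywhere)
    # 1: MAF 0.5 in F0 -> removed maf_high (>= 0.4)
    # 2: monomorphic everywhere -> maf_low
    # 3: call rate 0.5 in F0 -> call_rate_f0
    # 4: healthy in F0, call rate 0.5 in F1 -> call_rate_f1
    # 5: no calls at all in F1 -> absent_in_generation
    f0 = np.array([
        [1, 1, 0, MISSING, 1, 0],
        [0, 1, 0, MISSING, 0, 1],
        [1, 1, 0, MISSING, 1, 0],
        [0, 1, 0, 0, 0, 1],
        [1, 1, 0, 1, 1, 0],
        [0, 1, 0, 0, 0, 1],
    ])
    f1 = np.array([
        [1, 1, 0, 0, MISSING, MISSING],
        [0, 0, 0, 1, MISSING, MISSING],
        [1, 1, 0, 0, MISSING, MISSING],
        [0, 0, 0, 1, 1, MISSING],
        [1, 1, 0, 0, 0, MISSING],
        [0, 0, 0, 1, 1, MISSING],
    ])
    g = toy_matrix(np.vstack([f0, f1]))
    labels = {s: ("F0" if i < 6 else "F1") for i, s in enumerate(g.samples)}
    return g, labels


def test_qc_filter_categories_and_conservation():
    g, labels = _two_generation_matrix()
    kept, report = ag.qc_filter(g, generation_labels=labels)
    assert kept.n_variants == 1
    assert report.removed == {
        "maf_high": 1,
        "maf_low": 1,
        "call_rate_f0": 1,
        "call_rate_f1": 1,
        "absent_in_generation": 1,
    }
    assert report.retained + sum(report.removed.values()) == report.input_variants


def test_qc_maf_bounds_are_strict():
    # MAF exactly 0.4 must go (strict upper bound); 0.35 and 0.2 stay
    d = np.array([
        [2, 1, 1],
        [2, 1, 1],
        [2, 1, 1],
        [2, 1, 1],
        [0, 1, 0],
        [0, 1, 0],
        [0, 1, 0],
        [0, 0, 0],
        [0, 0, 0],
        [0, 0, 0],
    ])
    # freqs: 0.4 exactly, 0.35, 0.2
    g = toy_matrix(d)
    f = g.allele_freq()
    assert np.allclose(f, [0.4, 0.35, 0.2])
    kept, report = ag.qc_filter(g, maf_low=0.01, maf_high=0.4)
    assert kept.n_variants == 2
    assert report.removed == {"maf_high": 1}


def test_qc_idempotent_on_simulated_panel(small_pop):
    cfg = clean_config(seed=11, missing_rate=0.08)
    noisy = ag.apply_genotyping_noise(small_pop.geno, cfg)
    labels = {
        r.id: r.generation
        for r in small_pop.ped.table.itertuples(index=False)
    }
    once, _ = ag.qc_filter(noisy, generation_labels=labels)
    twice, rep2 = ag.qc_filter(once, generation_labels=labels)
    assert twice.n_variants == once.n_variants
    assert sum(rep2.removed.values()) == 0


def test_qc_all_removed_raises():
    g = toy_matrix(np.zeros((4, 3), dtype=int))  # all monomorphic
    with pytest.raises(EmptyPanelError):
        ag.qc_filter(g)


# -------------------------------------------------------- imputation

def test_impute_perfect_ld_copies_duplicate_site():
    base = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1])
    d = np.stack([base, base, np.roll(base, 3)], axis=1).astype(np.int8)
    d = np.hstack([d, np.tile(base[:, None], 5)])  # extra correlated sites
    g = toy_matrix(d)
    g.dosages[0, 0] = MISSING  # sample s1, site A; site B duplicates A
    out = ag.ld_knni_impute(g, n_ld_sites=3, k=3)
    assert out.dosages[0, 0] == base[0]
    # observed calls untouched, nothing missing
    assert (out.dosages != MISSING).all()
    mask = g.dosages != MISSING
    assert np.array_equal(out.dosages[mask], g.dosages[mask])


def test_impute_no_missing_is_identity(small_pop):
    out = ag.ld_knni_impute(small_pop.geno)
    assert out.equals(small_pop.geno)


def test_impute_dead_site_raises():
    d = np.array([[0, MISSING], [1, MISSING], [2, MISSING]])
    with pytest.raises(ValueError, match="non-missing"):
        ag.ld_knni_impute(toy_matrix(d))


def test_impute_beats_modal_baseline_on_linked_panel():
    """Masked-recovery: LD-kNNi concordance strictly exceeds the
    per-site modal baseline on every seed."""
    for seed in range(3):
        cfg = clean_config(
            seed=400 + seed, n_snps=400, n_families=30, offspring_total=120,
            traits=(),
        )
        founders, fped = ag.simulate_founders(cfg)
        off, _ = ag.simulate_offspring(founders, fped, cfg)
        g = stack_samples(founders, off)
        rng = np.random.default_rng(seed)
        mask = rng.random(g.dosages.shape) < 0.05
        noisy = g.copy()
        noisy.haplotypes = None
        noisy.dosages[mask] = MISSING
        imp = ag.ld_knni_impute(noisy)
        conc = (imp.dosages[mask] == g.dosages[mask]).mean()
        conc_modal = (
            modal_impute(noisy.dosages, MISSING)[mask] == g.dosages[mask]
        ).mean()
        assert conc > conc_modal


# ----------------------------------------------------------- subsets

def test_subset_collection_matches_design():
    sizes = (200, 400, 800, 1200, 1600, 2000, 2400, 2800, 3200, 3600, 4000)
    subs = ag.sample_snp_subsets(4075, sizes, replicates=10, seed=1)
    assert len(subs) == 110
    for s in subs:
        assert len(s.indices) == s.subset_size
        assert len(np.unique(s.indices)) == s.subset_size
        assert s.indices.max() < 4075


def test_subset_full_panel_and_reproducibility():
    full = ag.sample_snp_subsets(100, [100], replicates=3, seed=2)
    assert all(np.array_equal(s.indices, np.arange(100)) for s in full)

    a = ag.sample_snp_subsets(1000, [50], replicates=2, seed=3)
    b = ag.sample_snp_subsets(1000, [50], replicates=2, seed=3)
    assert all(
        np.array_equal(x.indices, y.indices) for x, y in zip(a, b)
    )
    assert not np.array_equal(a[0].indices, a[1].indices)

    with pytest.raises(ConfigurationError):
        ag.sample_snp_subsets(100, [101])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    m=st.integers(min_value=20, max_value=400),
    size=st.integers(min_value=1, max_value=20),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_subset_indices_always_valid(m, size, seed):
    (sub,) = ag.sample_snp_subsets(m, [size], replicates=1, seed=seed)
    assert len(sub.indices) == size
    assert sub.indices.min() >= 0 and sub.indices.max() < m
    assert np.all(np.diff(sub.indices) > 0)


def test_subset_inclusion_frequency_uniform():
    m, size, reps = 50, 10, 400
    counts = np.zeros(m)
    for sub in ag.sample_snp_subsets(m, [size], replicates=reps, seed=5):
        counts[sub.indices] += 1
    expected = reps * size / m
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    # chi2_49 0.999 quantile ~ 85
    assert chi2 < 85
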