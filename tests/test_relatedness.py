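"""Relationship matrices: hand-computed oracles, KING bands, Mantel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aquagp as ag
from aquagp.core import Pedigree
from aquagp.relatedness import RelationshipMatrix

from conftest import toy_matrix


# ----------------------------------------------------------------- GRM

def test_grm_hand_example():
    """M = [[0,2],[2,0]]: p = (0.5, 0.5), c = 1, Z = [[-1,1],[1,-1]]."""
    g = toy_matrix([[0, 2], [2, 0]])
    grm = ag.compute_grm(g)
    assert grm.c == pytest.approx(1.0)
    assert np.allclose(grm.values, [[2.0, -2.0], [-2.0, 2.0]])


def test_grm_duplicate_samples_and_monomorphic_columns():
    g = toy_matrix([[0, 2, 1, 1], [0, 2, 1, 1], [0, 2, 1, 0]])
    grm = ag.compute_grm(g)  # first two columns monomorphic, ignored
    assert grm.values[0, 0] == pytest.approx(grm.values[1, 1])
    assert grm.values[0, 1] == pytest.approx(grm.values[0, 0])

    with pytest.raises(ValueError, match="monomorphic"):
        ag.compute_grm(toy_matrix([[0, 2], [0, 2]]))


def test_grm_psd_and_diagonal_near_one(pop4000):
    grm = ag.compute_grm(pop4000.geno.take_samples(pop4000.ped.offspring()))
    eig = np.linalg.eigvalsh(grm.values)
    assert eig.min() >= -1e-8
    assert abs(grm.values.diagonal().mean() - 1.0) < 0.05


# ------------------------------------------------------------ A matrix

def test_amatrix_unrelated_founders_identity():
    ped = Pedigree.from_records(
        [("a", "0", "0", "M", "F0"), ("b", "0", "0", "F", "F0")]
    )
    A = ag.compute_amatrix(ped)
    assert np.allclose(A.values, np.eye(2))


def test_amatrix_full_sibs_and_parent_offspring():
    ped = Pedigree.from_records([
        ("s", "0", "0", "M", "F0"),
        ("d", "0", "0", "F", "F0"),
        ("c1", "s", "d", "M", "F1"),
        ("c2", "s", "d", "F", "F1"),
    ])
    A = ag.compute_amatrix(ped)
    i = {s: k for k, s in enumerate(A.ids)}
    assert A.values[i["c1"], i["c2"]] == pytest.approx(0.5)
    assert A.values[i["s"], i["c1"]] == pytest.approx(0.5)
    assert A.values[i["c1"], i["c1"]] == pytest.approx(1.0)


def test_amatrix_full_sib_mating_inbreeding():
    """Offspring of a full-sib mating: F = 0.25, diagonal 1.25."""
    ped = Pedigree.from_records([
        ("s", "0", "0", "M", "F0"),
        ("d", "0", "0", "F", "F0"),
        ("b1", "s", "d", "M", "F1"),
        ("b2", "s", "d", "F", "F1"),
        ("x", "b1", "b2", "M", "F2"),
    ])
    A = ag.compute_amatrix(ped)
    i = {s: k for k, s in enumerate(A.ids)}
    assert A.values[i["x"], i["x"]] == pytest.approx(1.25)


def test_amatrix_founder_priors_and_errors():
    ped = Pedigree.from_records([
        ("s", "0", "0", "M", "F0"),
        ("d", "0", "0", "F", "F0"),
        ("c", "s", "d", "M", "F1"),
    ])
    A = ag.compute_amatrix(ped, founder_relationships=[("s", "d", 0.5)])
    i = {s: k for k, s in enumerate(A.ids)}
    # related founders inbreed the offspring: diag 1 + 0.5*0.5
    assert A.values[i["c"], i["c"]] == pytest.approx(1.25)

    with pytest.raises(ValueError, match="cycle"):
        Pedigree.from_records([
            ("a", "b", "0", "M", "F0"),
            ("b", "a", "0", "M", "F0"),
        ]).topological_order()
    with pytest.raises(ValueError, match="unknown parent"):
        Pedigree.from_records([("a", "ghost", "0", "M", "F0")]).topological_order()


def test_amatrix_psd_on_simulated_pedigree(pop4000):
    A = ag.compute_amatrix(pop4000.ped)
    assert np.linalg.eigvalsh(A.values).min() >= -1e-8
    assert (A.values.diagonal() >= 1.0 - 1e-12).all()


def test_grm_fullsib_mean_matches_amatrix(pop4000):
    """Realized G and expected A agree on the full-sib average."""
    off = pop4000.ped.offspring()
    grm = ag.compute_grm(pop4000.geno.take_samples(off))
    A = ag.compute_amatrix(pop4000.ped).submatrix(off)
    pos = {s: k for k, s in enumerate(off)}
    gv, av = [], []
    for members in pop4000.ped.families().values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                gv.append(grm.values[pos[members[a]], pos[members[b]]])
                av.append(A.values[pos[members[a]], pos[members[b]]])
    assert abs(np.mean(gv) - np.mean(av)) < 0.05


# -------------------------------------------------------------- KING

def test_king_duplicate_individuals_phi_half():
    d = np.array([[0, 1, 2, 1, 0, 1], [0, 1, 2, 1, 0, 1]])
    (est,) = ag.king_kinship(toy_matrix(d))
    assert est.phi == pytest.approx(0.5)
    assert est.degree == "duplicate"


def test_king_counts_formula_direct_substitution():
    """N_Aa(i)=2, N_Aa(j)=4, N_Aa,Aa=2, N_AA,aa=0 -> phi = 0.25."""
    i_row = [1, 1, 0, 0, 0, 0]
    j_row = [1, 1, 1, 1, 0, 0]
    (est,) = ag.king_kinship(toy_matrix([i_row, j_row]))
    assert (est.n_het_i, est.n_het_j) == (2, 4)
    assert (est.n_het_het, est.n_opp_hom) == (2, 0)
    assert est.phi == pytest.approx(2 / 4 + 0.5 - 6 / 8)
    assert est.phi == pytest.approx(0.25)


def test_king_no_heterozygotes_undefined():
    (est,) = ag.king_kinship(toy_matrix([[0, 0, 2], [0, 2, 2]]))
    assert np.isnan(est.phi)
    assert est.degree == "undefined"


def test_king_parent_offspring_band(pop4000):
    parents = pop4000.ped.parents_of()
    off = pop4000.ped.offspring()
    pairs = [(o, parents[o][0]) for o in off] + [
        (o, parents[o][1]) for o in off
    ]
    ests = ag.king_kinship(pop4000.geno, pairs)
    phi = np.array([e.phi for e in ests])
    assert np.mean((phi >= 0.177) & (phi < 0.354)) >= 0.95


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=-0.5, max_value=0.6, allow_nan=False))
def test_degree_bands_total_and_ordered(phi):
    label = ag.classify_degree(phi)
    assert label in {
        "duplicate", "1st-degree", "2nd-degree", "3rd-degree", "unrelated"
    }


@pytest.mark.parametrize(
    "phi,label",
    [
        (0.25, "1st-degree"),
        (0.09, "2nd-degree"),
        (0.0, "unrelated"),
        (0.177, "1st-degree"),   # closed below
        (0.354, "duplicate"),
        (0.0884, "2nd-degree"),
        (0.05, "3rd-degree"),
    ],
)
def test_degree_band_examples(phi, label):
    assert ag.classify_degree(phi) == label


# ------------------------------------------------------------- Mantel

def _random_relmat(rng, n=12):
    X = rng.normal(size=(n, 5))
    M = X @ X.T / 5
    return RelationshipMatrix(
        ids=[f"i{k}" for k in range(n)], values=(M + M.T) / 2, kind="genomic"
    )


def test_mantel_self_and_sign_flip():
    rng = np.random.default_rng(1)
    m1 = _random_relmat(rng)
    assert ag.mantel_test(m1, m1, n_perm=99, seed=0).statistic == pytest.approx(1.0)
    m2 = RelationshipMatrix(ids=m1.ids, values=-m1.values, kind="genomic")
    assert ag.mantel_test(m1, m2, n_perm=99, seed=0).statistic == pytest.approx(-1.0)


def test_mantel_constant_matrix_rejected():
    ids = ["a", "b", "c"]
    const = RelationshipMatrix(ids=ids, values=np.eye(3), kind="pedigree")
    rng = np.random.default_rng(2)
    m = _random_relmat(rng, n=3)
    m.ids = ids
    with pytest.raises(ValueError, match="constant"):
        ag.mantel_test(const, m)


def test_mantel_matches_independent_implementation():
    """r agrees with scikit-bio's Mantel statistic on hollowed matrices."""
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    rng = np.random.default_rng(3)
    m1, m2 = _random_relmat(rng), _random_relmat(rng)
    m2.ids = m1.ids
    ours = ag.mantel_test(m1, m2, n_perm=9, seed=0).statistic

    def hollow(m):
        v = np.abs(m.values) + np.abs(m.values).T
        np.fill_diagonal(v, 0.0)
        return v

    # use symmetric non-negative versions as distances for the oracle
    h1 = RelationshipMatrix(ids=m1.ids, values=hollow(m1), kind="genomic")
    h2 = RelationshipMatrix(ids=m2.ids, values=hollow(m2), kind="genomic")
    ours_h = ag.mantel_test(h1, h2, n_perm=9, seed=0).statistic
    r, _, _ = skbio_mantel(
        DistanceMatrix(h1.values, m1.ids),
        DistanceMatrix(h2.values, m2.ids),
        permutations=0,
    )
    assert ours_h == pytest.approx(float(r), abs=1e-12)
    assert -1.0 <= ours <= 1.0


def test_mantel_null_type_one_error_controlled():
    rng = np.random.default_rng(42)
    rejections = 0
    draws = 200
    for t in range(draws):
        r = ag.mantel_test(
            _random_relmat(rng, n=15), _random_relmat(rng, n=15),
            n_perm=99, seed=t,
        )
        assert 0.0 < r.p_value <= 1.0
        rejections += r.p_value <= 0.05
    assert rejections / draws <= 0.07
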