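import numpy as np
import pytest

from snpkinpca import (
    KINSHIP_METHODS,
    KinshipAccumulator,
    finalize_kinship,
    read_kinship,
    update_accumulator,
    write_kinship,
)
from snpkinpca.kinship import (
    KinshipMatrix,
    contrib_centered_ibs,
    contrib_ibs,
    contrib_ibs_impute,
    contrib_normalized_ibs,
    contrib_pdistance,
)

from conftest import stream_dosage_matrix
from oracles import dense_kinship


def stream_kinship(G, method, ids=None):
    """Feed a sites-x-samples dosage matrix (nan = missing) through the
    single-pass accumulator."""
    G = np.asarray(G, dtype=float)
    acc = KinshipAccumulator(n_samples=G.shape[1], method=method)
    for rec, stats in stream_dosage_matrix(G):
        update_accumulator(acc, rec, stats)
    ids = ids or tuple(f"s{i}" for i in range(G.shape[1]))
    return finalize_kinship(acc, ids)


class TestContribFormulas:
    def test_centered_cross_product(self):
        assert contrib_centered_ibs(0, 2, 0.5) == -1.0
        assert contrib_centered_ibs(1, 1, 0.5) == 0.0

    def test_standardized_cross_product(self):
        assert contrib_normalized_ibs(0, 2, 0.5) == -2.0
        assert contrib_normalized_ibs(1, 1, 0.5) == 0.0

    def test_ibs_shared_allele_fraction(self):
        assert contrib_ibs(0, 2) == 0.0
        assert contrib_ibs(1, 1) == 1.0
        assert contrib_ibs(0, 1) == 0.5

    def test_ibs_impute_on_mean_dosage(self):
        # missing middle sample imputed to 2p = 1.0; pair (imputed, hom-alt)
        assert contrib_ibs_impute(1.0, 2.0, 0.5) == 0.5

    def test_pdistance_difference_fraction(self):
        assert contrib_pdistance(0, 0) == 0.0
        assert contrib_pdistance(0, 2) == 1.0
        assert contrib_pdistance(0, 1) == 0.5


def test_centered_two_sample_example():
    """Two samples, sites (0,2) and (1,1): K = ZZ' / sum 2p(1-p) = [[1,-1],[-1,1]]."""
    K = stream_kinship([[0, 2], [1, 1]], "Centered_IBS")
    np.testing.assert_allclose(K.values, [[1, -1], [-1, 1]], atol=1e-12)


def test_pdistance_limits():
    same = stream_kinship([[0, 0], [1, 1], [2, 2]], "p_distance")
    np.testing.assert_allclose(same.values, np.ones((2, 2)), atol=1e-12)
    opposite = stream_kinship([[0, 2], [2, 0]], "p_distance")
    assert opposite.values[0, 1] == 0.0
    half = stream_kinship([[0, 1], [1, 0], [0, 1]], "p_distance")
    assert half.values[0, 1] == pytest.approx(0.5)


def test_duplicate_sample_symmetry():
    rng = np.random.default_rng(3)
    G = rng.integers(0, 3, size=(40, 5)).astype(float)
    G = np.column_stack([G, G[:, 0]])  # duplicate sample 0 as sample 5
    for method in ("Normalized_IBS", "IBSKinship"):
        K = stream_kinship(G, method).values
        assert K[0, 5] == pytest.approx(K[0, 0])
        assert K[0, 5] == pytest.approx(K[5, 5])
    assert stream_kinship(G, "IBSKinship").values[0, 5] == pytest.approx(1.0)


@pytest.mark.parametrize("method", KINSHIP_METHODS)
def test_streaming_equals_dense_oracle(method):
    rng = np.random.default_rng(42)
    for _ in range(5):
        n, m = rng.integers(3, 12), rng.integers(60, 200)
        miss = rng.uniform(0, 0.3)
        G = rng.integers(0, 3, size=(m, n)).astype(float)
        G[rng.random(size=G.shape) < miss] = np.nan
        Gk = np.array([row for row in G if _polymorphic(row)])
        K = stream_kinship(Gk, method)
        expected = dense_kinship(Gk, method)
        assert np.max(np.abs(K.values - expected)) < 1e-10


def _polymorphic(row):
    called = row[~np.isnan(row)]
    return called.size > 0 and 0 < called.sum() < 2 * called.size


@pytest.mark.parametrize("method", KINSHIP_METHODS)
def test_permutation_equivariance(method):
    rng = np.random.default_rng(7)
    G = rng.integers(0, 3, size=(80, 6)).astype(float)
    perm = rng.permutation(6)
    K = stream_kinship(G, method).values
    Kp = stream_kinship(G[:, perm], method).values
    np.testing.assert_allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)


@pytest.mark.parametrize("method", KINSHIP_METHODS)
def test_site_order_invariance(method):
    rng = np.random.default_rng(11)
    G = rng.integers(0, 3, size=(100, 5)).astype(float)
    K1 = stream_kinship(G, method).values
    K2 = stream_kinship(G[rng.permutation(100)], method).values
    np.testing.assert_allclose(K1, K2, atol=1e-12)


@pytest.mark.parametrize("method", ("Centered_IBS", "Normalized_IBS"))
def test_centered_grm_is_psd_without_missing(method):
    rng = np.random.default_rng(13)
    G = rng.integers(0, 3, size=(150, 10)).astype(float)
    K = stream_kinship(G, method).values
    assert np.linalg.eigvalsh(K).min() > -1e-8


@pytest.mark.parametrize("method", ("IBSKinship", "IBSKinshipImpute", "p_distance"))
def test_ibs_like_range_and_unit_diagonal(method):
    rng = np.random.default_rng(17)
    G = rng.integers(0, 3, size=(90, 8)).astype(float)
    G[rng.random(size=G.shape) < 0.1] = np.nan
    K = stream_kinship(G, method).values
    assert (K >= -1e-12).all() and (K <= 1 + 1e-12).all()
    np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)


def test_exact_symmetry_and_m_used():
    rng = np.random.default_rng(19)
    G = rng.integers(0, 3, size=(60, 7)).astype(float)
    acc = KinshipAccumulator(n_samples=7, method="Normalized_IBS")
    m = 0
    for rec, stats in stream_dosage_matrix(G):
        update_accumulator(acc, rec, stats)
        m += 1
        assert (acc.numer == acc.numer.T).all()
        assert (acc.weight == acc.weight.T).all()
    assert acc.m_used == m
    K = finalize_kinship(acc, tuple(f"s{i}" for i in range(7)))
    assert (K.values == K.values.T).all()


def test_missing_sample_leaves_pairwise_weights_untouched():
    acc = KinshipAccumulator(n_samples=3, method="Normalized_IBS")
    for rec, stats in stream_dosage_matrix([[0.0, np.nan, 2.0]]):
        update_accumulator(acc, rec, stats)
    assert acc.weight[0, 1] == 0 and acc.weight[1, 2] == 0
    assert acc.weight[0, 2] == 1 and acc.weight[1, 1] == 0


def test_finalize_guards():
    acc = KinshipAccumulator(n_samples=2, method="IBSKinship")
    with pytest.raises(ValueError, match="no sites"):
        finalize_kinship(acc, ("a", "b"))
    # pair (a, b) never shares a called site
    for rec, stats in stream_dosage_matrix([[0.0, np.nan, 1.0], [np.nan, 0.0, 1.0]]):
        pass
    acc3 = KinshipAccumulator(n_samples=3, method="IBSKinship")
    for rec, stats in stream_dosage_matrix([[0.0, np.nan, 1.0], [np.nan, 0.0, 1.0]]):
        update_accumulator(acc3, rec, stats)
    with pytest.raises(ValueError, match=r"\(a, b\)"):
        finalize_kinship(acc3, ("a", "b", "c"))


def test_sample_count_mismatch_rejected():
    acc = KinshipAccumulator(n_samples=4, method="IBSKinship")
    for rec, stats in stream_dosage_matrix([[0.0, 1.0, 2.0]]):
        with pytest.raises(ValueError, match="samples"):
            update_accumulator(acc, rec, stats)


class TestKinshipFile:
    def test_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(23)
        G = rng.integers(0, 3, size=(50, 6)).astype(float)
        K = stream_kinship(G, "Normalized_IBS")
        path = tmp_path / "k.kinship.matrix"
        write_kinship(K, str(path))
        K2 = read_kinship(str(path))
        assert K2.sample_ids == K.sample_ids
        np.testing.assert_array_equal(K2.values, K.values)  # bit-exact

    def test_row_count_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.matrix"
        p.write_text("a\tb\tc\na\t1\t0\t0\nb\t0\t1\t0\n")
        with pytest.raises(ValueError, match="3 samples but 2 data rows"):
            read_kinship(str(p))

    def test_non_numeric_cell_names_line(self, tmp_path):
        p = tmp_path / "bad.matrix"
        p.write_text("a\tb\na\t1\t0\nb\t0\tx\n")
        with pytest.raises(ValueError, match="line 3"):
            read_kinship(str(p))

    def test_externally_authored_matrix_accepted(self, tmp_path):
        p = tmp_path / "ext.matrix"
        p.write_text("x\ty\nx\t1.0\t0.25\ny\t0.25\t1.0\n")
        K = read_kinship(str(p))
        np.testing.assert_allclose(K.values, [[1, 0.25], [0.25, 1]])


def test_accumulator_state_depends_on_n_only():
    """The streaming memory contract: consuming 10x more sites leaves the
    accumulator's arrays (identity and shape) unchanged and adds no
    per-site attributes."""
    rng = np.random.default_rng(29)
    acc = KinshipAccumulator(n_samples=6, method="Normalized_IBS")
    ids_before = (id(acc.numer), id(acc.weight))
    attrs_before = set(vars(acc))
    for m in (20, 200):
        G = rng.integers(0, 3, size=(m, 6)).astype(float)
        for rec, stats in stream_dosage_matrix(G):
            update_accumulator(acc, rec, stats)
        assert (id(acc.numer), id(acc.weight)) == ids_before
        assert acc.numer.shape == acc.weight.shape == (6, 6)
        assert set(vars(acc)) == attrs_before
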