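import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isclust import (
    CorrelationMatrix,
    ExpressionMatrix,
    build_dissimilarity_matrix,
    build_incidence_matrix,
    build_similarity_matrix,
    pairwise_correlation,
    split_similarity_dissimilarity,
)


def norm_expr(values):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(values, [f"g{i}" for i in range(m)], [f"c{j}" for j in range(n)], stage="normalized")


# -- independent Spearman oracle ------------------------------------------------

def midranks(x):
    """Average ranks computed from scratch (no scipy)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    """Product-moment correlation of midranks, written independently."""
    ra, rb = midranks(a), midranks(b)
    da, db = ra - ra.mean(), rb - rb.mean()
    return float((da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum()))


def spearman_noties_closed_form(a, b):
    """1 - 6*sum(d^2)/(m(m^2-1)); valid only without ties."""
    m = len(a)
    d = midranks(a) - midranks(b)
    return 1.0 - 6.0 * float((d**2).sum()) / (m * (m**2 - 1))


class TestPairwiseCorrelation:
    def test_monotone_pair_is_one(self):
        rho = pairwise_correlation(norm_expr([[1, 2], [2, 4], [3, 6], [4, 8]])).rho
        assert rho[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_is_minus_one(self):
        rho = pairwise_correlation(norm_expr([[1, 3], [2, 2], [3, 1]])).rho
        assert rho[0, 1] == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # d = (-1, 1, -1, 1), sum d^2 = 4, rho = 1 - 24/60 = 0.6
        rho = pairwise_correlation(norm_expr([[1, 2], [2, 1], [3, 4], [4, 3]])).rho
        assert rho[0, 1] == pytest.approx(0.6, abs=1e-12)
        assert spearman_noties_closed_form([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_matches_midrank_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = int(rng.integers(3, 25))
            n = int(rng.integers(2, 8))
            v = np.round(rng.normal(size=(m, n)), 1)  # rounding forces ties
            if np.any(v.max(axis=0) == v.min(axis=0)):
                continue
            rho = pairwise_correlation(norm_expr(v)).rho
            for i in range(n):
                for j in range(i + 1, n):
                    assert rho[i, j] == pytest.approx(spearman_oracle(v[:, i], v[:, j]), abs=1e-12)

    def test_pearson_method(self):
        v = np.random.default_rng(0).normal(size=(30, 4))
        rho = pairwise_correlation(norm_expr(v), method="pearson").rho
        expected = np.corrcoef(v, rowvar=False)
        np.testing.assert_allclose(rho, expected, atol=1e-12)

    def test_constant_cell_rejected_by_name(self):
        with pytest.raises(ValueError, match="c1"):
            pairwise_correlation(norm_expr([[1, 5], [2, 5], [3, 5]]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_invariance_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(12, 4))
        rho = pairwise_correlation(norm_expr(v)).rho
        v2 = v.copy()
        v2[:, 1] = np.exp(v2[:, 1]) * 3 + 1  # strictly increasing transform of one cell
        rho2 = pairwise_correlation(norm_expr(v2)).rho
        np.testing.assert_allclose(rho2, rho, atol=1e-12)


class TestSplit:
    def test_sign_branches_and_recomposition(self):
        rho = np.array([[1.0, 0.9, -0.5, 0.0], [0.9, 1.0, 0.2, -0.1], [-0.5, 0.2, 1.0, 0.3], [0.0, -0.1, 0.3, 1.0]])
        s, ds = split_similarity_dissimilarity(CorrelationMatrix(rho, list("abcd")))
        assert s[0, 1] == 0.9 and ds[0, 1] == 0.0
        assert s[0, 2] == 0.0 and ds[0, 2] == -0.5
        assert s[0, 3] == 0.0 and ds[0, 3] == 0.0
        assert np.all(np.diag(s) == 0) and np.all(np.diag(ds) == 0)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose((s + ds)[off], rho[off])
        # exactly one of s, ds nonzero, or both zero
        assert not np.any((s != 0) & (ds != 0))


def three_cell_parts():
    rho = np.array([[1.0, 0.9, -0.5], [0.9, 1.0, 0.2], [-0.5, 0.2, 1.0]])
    return split_similarity_dissimilarity(CorrelationMatrix(rho, list("abc")))


def brute_union_mask(values, width, negative):
    """Union rule by explicit sorted-list enumeration."""
    n = values.shape[0]
    tops = []
    for i in range(n):
        pairs = [
            (values[i, j], j)
            for j in range(n)
            if j != i and ((values[i, j] < 0) if negative else (values[i, j] > 0))
        ]
        pairs.sort(key=lambda p: (p[0] if negative else -p[0], p[1]))
        tops.append({j for _, j in pairs[:width]})
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if j in tops[i] or i in tops[j]:
                mask[i, j] = mask[j, i] = True
    return mask


class TestNeighborhoods:
    def test_top1_similarity_union(self):
        s_part, _ = three_cell_parts()
        s = build_similarity_matrix(s_part, h=1).s
        # cell 2 is cell 3's only positive partner, so s23 survives the union
        expected = np.array([[0, 0.9, 0], [0.9, 0, 0.2], [0, 0.2, 0]])
        np.testing.assert_allclose(s, expected)

    def test_top1_dissimilarity(self):
        _, ds_part = three_cell_parts()
        ds = build_dissimilarity_matrix(ds_part, q=1).ds
        expected = np.array([[0, 0, -0.5], [0, 0, 0], [-0.5, 0, 0]])
        np.testing.assert_allclose(ds, expected)

    def test_h_max_keeps_full_positive_part(self):
        rng = np.random.default_rng(2)
        rho = rng.uniform(-1, 1, size=(10, 10))
        rho = np.clip((rho + rho.T) / 2, -1, 1)
        np.fill_diagonal(rho, 1.0)
        s_part, ds_part = split_similarity_dissimilarity(CorrelationMatrix(rho, [f"c{i}" for i in range(10)]))
        np.testing.assert_allclose(build_similarity_matrix(s_part, 9).s, s_part)
        np.testing.assert_allclose(build_dissimilarity_matrix(ds_part, 9).ds, ds_part)

    def test_all_negative_gives_zero_similarity(self):
        rho = -0.5 * np.ones((4, 4))
        np.fill_diagonal(rho, 1.0)
        s_part, _ = split_similarity_dissimilarity(CorrelationMatrix(rho, list("abcd")))
        assert np.all(build_similarity_matrix(s_part, 2).s == 0)

    def test_q_zero_gives_zero_matrix(self):
        _, ds_part = three_cell_parts()
        assert np.all(build_dissimilarity_matrix(ds_part, 0).ds == 0)

    @pytest.mark.parametrize("h", [0, 3, 10])
    def test_h_bounds_enforced(self, h):
        s_part, _ = three_cell_parts()
        with pytest.raises(ValueError):
            build_similarity_matrix(s_part, h)

    def test_union_rule_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 21))
            rho = rng.uniform(-1, 1, size=(n, n))
            rho = (rho + rho.T) / 2
            np.fill_diagonal(rho, 1.0)
            s_part, ds_part = split_similarity_dissimilarity(
                CorrelationMatrix(rho, [f"c{i}" for i in range(n)])
            )
            h = int(rng.integers(1, n))
            q = int(rng.integers(0, n))
            s = build_similarity_matrix(s_part, h).s
            np.testing.assert_allclose(s, np.where(brute_union_mask(s_part, h, False), s_part, 0.0))
            ds = build_dissimilarity_matrix(ds_part, q).ds
            if q > 0:
                np.testing.assert_allclose(
                    ds, np.where(brute_union_mask(ds_part, q, True), ds_part, 0.0)
                )
            # every kept similarity is in someone's top-h list
            for i, j in zip(*np.nonzero(s)):
                assert brute_union_mask(s_part, h, False)[i, j]


class TestIncidence:
    def setup_method(self):
        s_part, ds_part = three_cell_parts()
        self.s = build_similarity_matrix(s_part, 1)
        self.ds = build_dissimilarity_matrix(ds_part, 1)

    def test_omega_zero_is_similarity_graph(self):
        np.testing.assert_allclose(build_incidence_matrix(self.s, self.ds, 0.0).w, self.s.s)

    def test_omega_one_is_dissimilarity_graph(self):
        np.testing.assert_allclose(build_incidence_matrix(self.s, self.ds, 1.0).w, self.ds.ds)

    def test_midpoint_values(self):
        w = build_incidence_matrix(self.s, self.ds, 0.4).w
        assert w[0, 1] == pytest.approx(0.54)
        assert w[0, 2] == pytest.approx(-0.2)
        assert w[1, 2] == pytest.approx(0.12)

    def test_affine_in_omega(self):
        w0 = build_incidence_matrix(self.s, self.ds, 0.0).w
        w1 = build_incidence_matrix(self.s, self.ds, 1.0).w
        for omega in (0.15, 0.5, 0.85):
            np.testing.assert_allclose(
                build_incidence_matrix(self.s, self.ds, omega).w,
                (1 - omega) * w0 + omega * w1,
                atol=1e-14,
            )

    @pytest.mark.parametrize("omega", [-0.1, 1.1])
    def test_omega_range_enforced(self, omega):
        with pytest.raises(ValueError):
            build_incidence_matrix(self.s, self.ds, omega)
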