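"""Polynomial kernel, threshold heuristic, and the greedy clustering,
checked against an independent straight-line transcription of the
clustering procedure."""

import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relmine.kernel import (
    ClusteringConfig,
    DegenerateHistogramError,
    KernelParams,
    PKMatrix,
    base_kernel,
    cluster_patterns,
    kernel_matrix,
    polynomial_kernel,
    select_threshold,
    term_vector,
)
from relmine.patterns import CandidatePattern


def _pat(*tokens):
    return CandidatePattern(tokens=tuple(tokens), pos=("verb",) * len(tokens),
                            source=("s", frozenset({"a", "b"})))


def clustering_oracle(matrix: np.ndarray, theta: float) -> list[list[int]]:
    """Literal step-by-step transcription of the greedy procedure:
    pop the first pattern; compute the average similarity to every existing
    cluster; merge into the most similar cluster if that average exceeds
    theta, else open a new cluster; repeat until the pattern set is empty."""
    remaining = list(range(matrix.shape[0]))
    clusters: list[list[int]] = []
    while remaining:
        p = remaining.pop(0)
        best_cluster = None
        best_sim = None
        for cluster in clusters:
            total = 0.0
            for v in cluster:
                total += matrix[p][v]
            avg = total / len(cluster)
            if best_sim is None or avg > best_sim:
                best_sim = avg
                best_cluster = cluster
        if best_cluster is not None and best_sim > theta:
            best_cluster.append(p)
        else:
            clusters.append([p])
    return clusters


class TestKernels:
    def test_term_vector_counts_multiplicities(self):
        assert term_vector(_pat("bind", "bind", "tightly")) == {"bind": 2, "tightly": 1}

    def test_term_vector_is_order_invariant(self):
        assert term_vector(_pat("a", "b", "a")) == term_vector(_pat("a", "a", "b"))

    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ({"a": 1, "b": 1}, {"a": 1}, 1),
            ({"a": 1}, {"b": 1}, 0),
            ({"a": 2}, {"a": 3}, 6),
        ],
    )
    def test_base_kernel_inner_product(self, u, v, expected):
        assert base_kernel(Counter(u), Counter(v)) == expected

    def test_polynomial_kernel_values(self):
        u, v = Counter({"a": 1}), Counter({"a": 1})
        assert polynomial_kernel(u, v, KernelParams(d=2, c=1)) == 4  # (1+1)^2
        assert polynomial_kernel(u, Counter({"b": 1}), KernelParams(d=3, c=0)) == 0

    def test_degree_one_zero_offset_reduces_to_base(self):
        u, v = Counter({"a": 2, "b": 1}), Counter({"a": 1, "c": 4})
        assert polynomial_kernel(u, v, KernelParams(d=1, c=0)) == base_kernel(u, v)

    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=3),
        st.lists(st.integers(0, 5), min_size=3, max_size=3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_base_kernel_cauchy_schwarz(self, xs, ys):
        u = Counter({f"t{i}": c for i, c in enumerate(xs) if c})
        v = Counter({f"t{i}": c for i, c in enumerate(ys) if c})
        lhs = base_kernel(u, v) ** 2
        rhs = base_kernel(u, u) * base_kernel(v, v)
        assert lhs <= rhs + 1e-9


class TestKernelMatrix:
    def test_single_pattern(self):
        m = kernel_matrix([_pat("bind", "bind")], KernelParams(d=2, c=1))
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == (4 + 1) ** 2

    def test_symmetry_and_duplicate_rows(self):
        pats = [_pat("bind"), _pat("bind"), _pat("activate", "strongly")]
        m = kernel_matrix(pats, KernelParams())
        assert np.array_equal(m.values, m.values.T)
        assert m.values[0, 1] == m.values[0, 0] == m.values[1, 1]

    def test_diagonal_at_least_c_to_the_d(self):
        pats = [_pat("x"), _pat("y", "z")]
        kp = KernelParams(d=3, c=2)
        m = kernel_matrix(pats, kp)
        assert (np.diag(m.values) >= kp.c**kp.d).all()


class TestSelectThreshold:
    def _matrix_with_offdiag(self, values):
        """Embed the given off-diagonal similarity multiset in a PKMatrix."""
        n = int((1 + np.sqrt(1 + 8 * len(values))) / 2)
        m = np.eye(n) * (max(values) + 1)
        iu = np.triu_indices(n, k=1)
        m[iu] = values
        m.T[iu] = values
        return PKMatrix(m, tuple(f"p{i}" for i in range(n)))

    def test_drop_interval_lower_limit(self):
        # 10 bins over [0, 10]: 50 pairs near 0.5, 40 near 1.5, 5 near 2.5,
        # 10 at the top; the third interval's count (5) is <= 20% of 40
        values = [0.5] * 50 + [1.5] * 40 + [2.5] * 5 + [10.0] * 10  # 105 = C(15,2)
        m = self._matrix_with_offdiag(values)
        theta = select_threshold(m, ClusteringConfig(n_intervals=10))
        assert theta == pytest.approx(2.0)  # lower limit of third interval

    def test_no_drop_falls_back_to_top_interval(self):
        # counts descend gently; no interval is <= 20% of its predecessor
        values = []
        for i, c in enumerate([30, 25, 20, 16, 13, 10, 8, 6, 5, 3]):  # 136 = C(17,2)
            values += [i + 0.5] * c
        m = self._matrix_with_offdiag(values)
        theta = select_threshold(m, ClusteringConfig(n_intervals=10))
        assert theta == pytest.approx(9.0 * 0.95, rel=0.01)  # last bin lower edge

    def test_two_patterns_threshold_below_similarity(self):
        m = PKMatrix(np.array([[9.0, 4.0], [4.0, 9.0]]), ("p0", "p1"))
        theta = select_threshold(m, ClusteringConfig())
        assert 0 <= theta <= 4.0

    def test_degenerate_histogram_raises_with_median_fallback(self):
        m = PKMatrix(np.full((3, 3), 4.0), ("a", "b", "c"))
        with pytest.raises(DegenerateHistogramError) as err:
            select_threshold(m)
        assert err.value.fallback == 4.0


class TestClusterPatterns:
    def test_single_pattern_single_cluster(self):
        pats = [_pat("bind")]
        m = kernel_matrix(pats)
        assert cluster_patterns(pats, m, 0.5) == [[0]]

    def test_identical_patterns_merge_below_self_similarity(self):
        pats = [_pat("bind"), _pat("bind")]
        m = kernel_matrix(pats)  # off-diagonal similarity (1+1)^2 = 4
        assert cluster_patterns(pats, m, 3.0) == [[0, 1]]

    def test_two_separated_blocks_match_oracle(self):
        pats = [
            _pat("bind"), _pat("bind", "strongly"), _pat("bind", "tightly"),
            _pat("observe"), _pat("observe", "closely"), _pat("observe", "often"),
        ]
        m = kernel_matrix(pats)
        result = cluster_patterns(pats, m, 1.5)
        assert result == clustering_oracle(m.values, 1.5)
        assert result == [[0, 1, 2], [3, 4, 5]]

    def test_negative_theta_rejected(self):
        pats = [_pat("x")]
        with pytest.raises(ValueError):
            cluster_patterns(pats, kernel_matrix(pats), -1.0)


def _random_instance(rng, n):
    vocab = ["a", "b", "c", "d", "e"]
    pats = [
        _pat(*(rng.choice(vocab) for _ in range(rng.randint(1, 4))))
        for _ in range(n)
    ]
    return pats, kernel_matrix(pats)


class TestClusteringProperties:
    def test_oracle_equivalence_on_random_instances(self):
        """Implementation matches the straight-line transcription for n <= 12."""
        rng = random.Random(20240917)
        for _ in range(200):
            n = rng.randint(1, 12)
            pats, m = _random_instance(rng, n)
            theta = rng.choice([0.0, 1.0, 2.0, 4.0, 9.0, rng.uniform(0, 16)])
            assert cluster_patterns(pats, m, theta) == clustering_oracle(m.values, theta)

    def test_partition_property(self):
        rng = random.Random(5)
        for _ in range(50):
            pats, m = _random_instance(rng, rng.randint(1, 15))
            clusters = cluster_patterns(pats, m, rng.uniform(0, 9))
            flat = sorted(i for c in clusters for i in c)
            assert flat == list(range(len(pats)))

    def test_raising_theta_never_decreases_cluster_count(self):
        rng = random.Random(11)
        for _ in range(50):
            pats, m = _random_instance(rng, rng.randint(2, 10))
            thetas = sorted(set(np.unique(m.values)) | {0.0})
            counts = [len(cluster_patterns(pats, m, float(t))) for t in thetas]
            assert counts == sorted(counts)

    def test_determinism(self):
        rng = random.Random(3)
        pats, m = _random_instance(rng, 10)
        a = cluster_patterns(pats, m, 2.0)
        b = cluster_patterns(pats, m, 2.0)
        assert a == b
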