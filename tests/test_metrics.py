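import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhdecg.metrics import dtw, mmd, similarity_report
from mhdecg.mhd_extraction import TemplateDatabase, DistortionTemplate
from mhdecg.signal_io import ValidationError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mmd_oracle(A, B, gamma):
    """Literal double-loop evaluation of the estimator."""
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    n, m = len(A), len(B)
    k = lambda a, b: np.exp(-gamma * np.sum((a - b) ** 2))
    t1 = sum(k(A[i], A[j]) for i in range(n) for j in range(n) if i != j)
    t2 = sum(k(A[i], B[j]) for i in range(n) for j in range(m))
    t3 = sum(k(B[i], B[j]) for i in range(m) for j in range(m) if i != j)
    return t1 / (n * (n - 1)) - 2 * t2 / (n * m) + t3 / (m * (m - 1))


def dtw_oracle(x, y):
    """Brute-force enumeration of every admissible monotone alignment path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + (x[i] - y[j]) ** 2
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, acc)

    walk(0, 0, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------------

class TestMmd:
    def test_identical_point_sets_give_zero(self):
        A = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert mmd(A, A.copy(), gamma=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_scalar_case(self):
        # A = {0, 0}, B = {1, 1}: 1 + 1 - 2 e^{-1}
        A, B = np.array([[0.0], [0.0]]), np.array([[1.0], [1.0]])
        assert mmd(A, B, gamma=1.0) == pytest.approx(2 - 2 * np.e ** -1,
                                                     abs=1e-12)

    @given(st.integers(2, 8), st.integers(2, 8), st.integers(1, 4),
           st.integers(0, 10_000))
    @settings(max_examples=40)
    def test_matches_double_loop_oracle(self, n, m, d, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.normal(size=(n, d)), rng.normal(size=(m, d))
        gamma = float(rng.uniform(0.1, 2.0))
        assert mmd(A, B, gamma) == pytest.approx(mmd_oracle(A, B, gamma),
                                                 abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        assert mmd(A, B, 0.5) == pytest.approx(mmd(B, A, 0.5), abs=1e-12)

    def test_same_distribution_vanishes_with_n(self):
        """Two independent draws from one distribution: MMD -> 0 as n grows,
        checked within 3 standard errors at n = 500."""
        rng = np.random.default_rng(99)
        n = 500
        A = rng.normal(size=(n, 2))
        B = rng.normal(size=(n, 2))
        gamma = 0.5
        val = mmd(A, B, gamma)
        # conservative standard error of the estimator, O(1/n)
        assert abs(val) < 3 * (4.0 / n)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            mmd(np.zeros((1, 3)), np.zeros((4, 3)), 1.0)

    def test_row_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mmd(np.zeros((3, 3)), np.zeros((3, 4)), 1.0)


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

class TestDtw:
    def test_self_distance_zero(self):
        x = np.array([0.3, -1.2, 4.0, 2.0])
        assert dtw(x, x) == 0.0

    def test_hand_case(self):
        assert dtw([1, 2, 3], [1, 3]) == pytest.approx(1.0)

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_matches_path_enumeration_oracle(self, n, m, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=m)
        assert dtw(x, y) == pytest.approx(dtw_oracle(x, y), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=15)
        assert dtw(x, y) == pytest.approx(dtw(y, x), abs=1e-10)

    def test_bounded_by_diagonal_path(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert dtw(x, y) <= np.sum((x - y) ** 2) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            dtw([], [1.0])


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def constant_db(value, n=4):
    w = np.full((250, 3), value)
    return TemplateDatabase(templates=[
        DistortionTemplate(window=w, provenance="measured") for _ in range(n)])


class TestSimilarityReport:
    def test_copy_is_maximally_similar(self, template_db):
        """A database compared against its own copy: DTW vanishes exactly;
        the unbiased-style MMD estimator drops the within-set diagonal but
        keeps the full cross mean, so it is slightly NEGATIVE for identical
        sets (never positive) — reported as computed, not clamped."""
        small = TemplateDatabase(templates=template_db.templates[:5])
        rep = similarity_report(small, small)
        for c in ("X", "Y", "Z"):
            assert -0.5 < rep.mmd_per_component[c] <= 1e-12
            assert rep.dtw_per_component[c] == pytest.approx(0.0, abs=1e-9)
        assert rep.dtw_mean == pytest.approx(0.0, abs=1e-9)
        assert rep.dtw_std == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_constant_sets_strictly_positive(self):
        rep = similarity_report(constant_db(0.0), constant_db(1.0), gamma=0.001)
        for c in ("X", "Y", "Z"):
            assert rep.mmd_per_component[c] > 0
            assert rep.dtw_per_component[c] > 0

    def test_sigma_matches_direct_recomputation(self, template_db):
        real = TemplateDatabase(templates=template_db.templates[:6])
        synth = TemplateDatabase(templates=template_db.templates[6:12])
        rep = similarity_report(real, synth)
        vals = [rep.mmd_per_component[c] for c in ("X", "Y", "Z")]
        assert rep.mmd_std == pytest.approx(float(np.std(vals)), abs=1e-12)
        dvals = [rep.dtw_per_component[c] for c in ("X", "Y", "Z")]
        assert rep.dtw_mean == pytest.approx(float(np.mean(dvals)), abs=1e-12)

    def test_aggregation_strategies_available(self, template_db):
        real = TemplateDatabase(templates=template_db.templates[:4])
        synth = TemplateDatabase(templates=template_db.templates[4:8])
        for strategy in ("mean-min", "median-median", "mean-mean"):
            rep = similarity_report(real, synth, dtw_strategy=strategy)
            assert rep.dtw_strategy == strategy
        with pytest.raises(ValidationError):
            similarity_report(real, synth, dtw_strategy="nonsense")
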