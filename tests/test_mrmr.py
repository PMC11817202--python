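"""mRMR selection: discretization, plug-in MI, greedy order, brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hjortheeg.errors import AlignmentError, ConfigurationError
from hjortheeg.mrmr import (
    REDUNDANCY_EPS,
    SelectionConfig,
    discretize,
    mrmr,
    mutual_information,
)

# ---------------------------------------------------------------------------
# independent oracle: naive greedy mRMR recomputing every MI from scratch


def mi_oracle(a, b):
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    total = 0.0
    for va in np.unique(a):
        for vb in np.unique(b):
            p_ab = np.mean((a == va) & (b == vb))
            if p_ab > 0:
                total += p_ab * np.log(p_ab / (np.mean(a == va) * np.mean(b == vb)))
    return total


def mrmr_oracle(table, labels, k, scheme, n_bins=5):
    features = [c for c in table.columns if c not in ("subject_id", "group", "epoch")]
    y = pd.factorize(labels, sort=True)[0]
    codes = {f: discretize(table[f].to_numpy(), n_bins) for f in features}
    selected = []
    while len(selected) < k:
        best, best_score = None, -np.inf
        for f in features:
            if f in selected:
                continue
            rel = mi_oracle(codes[f], y)
            if not selected:
                score = rel
            else:
                red = np.mean([mi_oracle(codes[f], codes[s]) for s in selected])
                score = rel / max(red, REDUNDANCY_EPS) if scheme == "MIQ" else rel - red
            if score > best_score:  # strict > keeps the earlier column on ties
                best, best_score = f, score
        selected.append(best)
    return selected


def random_table(rng, n_rows=60, n_features=6):
    cols = {f"f{i}": rng.standard_normal(n_rows) for i in range(n_features)}
    return pd.DataFrame(cols), rng.choice(["control", "patient"], n_rows)


# ---------------------------------------------------------------------------


class TestDiscretize:
    def test_hand_computed_equal_frequency_split(self):
        np.testing.assert_array_equal(discretize([1, 2, 3, 4, 5, 6], 3), [0, 0, 1, 1, 2, 2])

    def test_constant_column_single_code(self):
        assert set(discretize(np.full(10, 2.5), 4)) == {0}

    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(10, 80))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_equal_frequency_occupancy(self, seed, n_bins, n):
        values = np.random.default_rng(seed).standard_normal(n)  # ties a.s. absent
        counts = np.bincount(discretize(values, n_bins), minlength=n_bins)
        assert counts.max() - counts.min() <= int(np.ceil(n / n_bins)) - n // n_bins

    def test_non_finite_rejected(self):
        with pytest.raises(ConfigurationError):
            discretize([1.0, np.nan], 2)


class TestMutualInformation:
    def test_identical_two_code_vector_gives_ln2(self):
        a = np.array([0, 0, 1, 1])
        assert mutual_information(a, a) == pytest.approx(np.log(2), abs=1e-12)

    def test_product_form_joint_gives_zero(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 3, 50)
        mab, mba = mutual_information(a, b), mutual_information(b, a)
        assert mab == mba
        assert mab >= 0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(8)
        a, b = rng.integers(0, 5, 200), rng.integers(0, 4, 200)
        assert mutual_information(a, b) == pytest.approx(mi_oracle(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            mutual_information([0, 1], [0, 1, 2])


class TestMRMR:
    def _informative_table(self, rng, n=80):
        y = np.repeat(["control", "patient"], n // 2)
        y_num = (y == "patient").astype(float)
        A = y_num + 0.01 * rng.standard_normal(n)
        weak = np.where(rng.random(n) < 0.75, y_num, 1 - y_num) + 0.01 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        return pd.DataFrame({"A": A, "Acopy": A.copy(), "B": weak, "D": noise}), y

    def test_perfectly_informative_feature_first(self):
        table, y = self._informative_table(np.random.default_rng(10))
        res = mrmr(table, y, SelectionConfig(k=2))
        assert res.ordered[0] in ("A", "Acopy")  # identical relevance; first in order wins
        assert res.ordered[0] == "A"

    @pytest.mark.parametrize("scheme", ["MIQ", "MID"])
    def test_duplicate_feature_deferred_behind_weak_one(self, scheme):
        """A, then weakly informative B, and only then the exact copy of A."""
        table, y = self._informative_table(np.random.default_rng(11))
        res = mrmr(table[["A", "Acopy", "B"]], y, SelectionConfig(k=3, scheme=scheme))
        assert res.ordered == ["A", "B", "Acopy"]

    @pytest.mark.parametrize("scheme", ["MIQ", "MID"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_exhaustive_greedy_oracle(self, scheme, seed):
        rng = np.random.default_rng(100 + seed)
        table, y = random_table(rng)
        k = 4
        got = mrmr(table, y, SelectionConfig(k=k, scheme=scheme)).ordered
        assert got == mrmr_oracle(table, y, k, scheme)

    def test_first_pick_maximizes_relevance(self):
        rng = np.random.default_rng(12)
        table, y = random_table(rng)
        res = mrmr(table, y, SelectionConfig(k=3))
        assert res.relevance[0] == pytest.approx(
            max(
                mi_oracle(discretize(table[c].to_numpy(), 5), pd.factorize(y, sort=True)[0])
                for c in table.columns
            ),
            rel=1e-12,
        )

    def test_column_permutation_consistency(self):
        table, y = self._informative_table(np.random.default_rng(13))
        res = mrmr(table, y, SelectionConfig(k=3))
        permuted = table[["D", "B", "Acopy", "A"]]
        res_p = mrmr(permuted, y, SelectionConfig(k=3))
        # A and Acopy are identical columns: on ties the earlier column wins,
        # so the selected *values* agree even though the labels may swap
        rename = {"Acopy": "A"}
        assert [rename.get(f, f) for f in res.ordered] == [
            rename.get(f, f) for f in res_p.ordered
        ]

    def test_k_exceeding_feature_count_rejected(self):
        table, y = random_table(np.random.default_rng(14))
        with pytest.raises(ConfigurationError):
            mrmr(table, y, SelectionConfig(k=7))

    def test_uniform_prior_coincides_with_empirical_when_balanced(self):
        table, y = self._informative_table(np.random.default_rng(15))
        a = mrmr(table, y, SelectionConfig(k=3, class_prior="empirical"))
        b = mrmr(table, y, SelectionConfig(k=3, class_prior="uniform"))
        assert a.ordered == b.ordered
        np.testing.assert_allclose(a.relevance, b.relevance, atol=1e-12)
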