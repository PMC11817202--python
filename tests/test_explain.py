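"""LIME surrogates, channel aggregation, and rank-sum channel statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hjortheeg.errors import ConfigurationError
from hjortheeg.explain import (
    ChannelStat,
    Explanation,
    LimeConfig,
    _ranksum_z,
    aggregate_channel_importance,
    lime_explain,
    wilcoxon_map,
)

# ---------------------------------------------------------------------------
# exact rank-sum oracle: enumerate all assignments of the pooled sample


def ranksum_exact_oracle(x, y):
    """Two-sided exact p for the rank-sum statistic by full enumeration."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2
    stats = [ranks[list(idx)].sum() for idx in combinations(range(n), n1)]
    stats = np.array(stats)
    lo = np.mean(stats <= w_obs)
    hi = np.mean(stats >= w_obs)
    return min(1.0, 2 * min(lo, hi))


def make_stat_table(x_pat, x_ctl, channel="F3", band="beta", param="activity"):
    rows = []
    for i, v in enumerate(x_pat):
        rows.append({"subject_id": f"P{i}", "group": "patient", "epoch": 0,
                     f"{band}.{param}.{channel}": v})
    for i, v in enumerate(x_ctl):
        rows.append({"subject_id": f"C{i}", "group": "control", "epoch": 0,
                     f"{band}.{param}.{channel}": v})
    return pd.DataFrame(rows)


class TestLimeExplain:
    d = 6

    def _stats(self):
        rng = np.random.default_rng(0)
        mean = rng.standard_normal(self.d)
        sd = 0.5 + rng.random(self.d)
        return mean, sd

    def test_linear_model_recovered(self):
        """On a linear score the surrogate weights align with the coefficients."""
        mean, sd = self._stats()
        beta = np.array([2.0, -1.0, 0.5, 0.0, 3.0, -0.25])
        predict = lambda Z: Z @ beta
        x = mean + 0.3 * sd
        exp = lime_explain(
            predict, x, mean, sd, [f"f{i}" for i in range(self.d)],
            LimeConfig(n_samples=1000, seed=5),
        )
        target = beta * sd  # coefficients in standardized space
        cos = exp.weights @ target / np.linalg.norm(exp.weights) / np.linalg.norm(target)
        assert cos > 0.99
        assert exp.r2 > 0.99

    def test_constant_model_zero_weights(self):
        mean, sd = self._stats()
        with pytest.warns(UserWarning):
            exp = lime_explain(
                lambda Z: np.ones(len(Z)), mean, mean, sd,
                [f"f{i}" for i in range(self.d)], LimeConfig(n_samples=200, seed=1),
            )
        assert exp.degenerate
        np.testing.assert_array_equal(exp.weights, 0)

    def test_single_relevant_feature_dominates(self):
        mean, sd = self._stats()
        j = 3
        predict = lambda Z: np.tanh(Z[:, j])
        exp = lime_explain(
            predict, mean, mean, sd, [f"f{i}" for i in range(self.d)],
            LimeConfig(n_samples=1000, seed=2),
        )
        weights = np.abs(exp.weights)
        assert np.argmax(weights) == j
        assert weights[j] > 2 * np.delete(weights, j).max()

    def test_deterministic_under_seed(self):
        mean, sd = self._stats()
        beta = np.arange(self.d, dtype=float)
        args = (lambda Z: Z @ beta, mean, mean, sd, [f"f{i}" for i in range(self.d)])
        a = lime_explain(*args, LimeConfig(n_samples=300, seed=9))
        b = lime_explain(*args, LimeConfig(n_samples=300, seed=9))
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_top_k_restricts_support(self):
        mean, sd = self._stats()
        beta = np.array([5.0, 4.0, 0.01, 0.01, 0.01, 0.01])
        exp = lime_explain(
            lambda Z: Z @ beta, mean, mean, sd, [f"f{i}" for i in range(self.d)],
            LimeConfig(n_samples=1000, top_k=2, seed=3),
        )
        assert np.count_nonzero(exp.weights) == 2
        assert set(np.flatnonzero(exp.weights)) == {0, 1}


class TestAggregation:
    def _exp(self, names, weights):
        return Explanation("i", list(names), np.asarray(weights, dtype=float), 1.0)

    def test_point_mass_on_one_channel(self):
        exp = self._exp(["beta.activity.F3"], [0.7])
        imp = aggregate_channel_importance([exp], "beta")
        assert imp["F3"] == 1.0
        assert all(v == 0.0 for ch, v in imp.items() if ch != "F3")

    def test_equal_split_symmetric(self):
        exp = self._exp(["beta.activity.F3", "beta.activity.F4"], [0.4, -0.4])
        imp = aggregate_channel_importance([exp], "beta")
        assert imp["F3"] == imp["F4"] == 1.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(4)
        exps = [
            self._exp(["beta.activity.F3", "beta.activity.O1"], rng.standard_normal(2))
            for _ in range(5)
        ]
        a = aggregate_channel_importance(exps, "beta")
        b = aggregate_channel_importance(exps[::-1], "beta")
        assert a == b

    def test_other_band_features_ignored(self):
        exp = self._exp(["gamma.activity.F3"], [1.0])
        imp = aggregate_channel_importance([exp], "beta")
        assert all(v == 0.0 for v in imp.values())

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate_channel_importance([], "beta")


class TestWilcoxonMap:
    def test_textbook_exact_p(self):
        """[1,2,3] vs [4,5,6]: the 20-arrangement exact null gives p = 0.1."""
        table = make_stat_table([1, 2, 3], [4, 5, 6])
        (stat,) = wilcoxon_map(table, "activity", "beta", channels=["F3"])
        assert stat.p == pytest.approx(0.1, abs=1e-12)
        assert stat.z < 0  # patients smaller -> negative direction

    def test_sign_positive_when_patients_larger(self):
        table = make_stat_table([4.0, 5, 6, 7], [1.0, 2, 3, 3.5])
        (stat,) = wilcoxon_map(table, "activity", "beta", channels=["F3"])
        assert stat.z > 0

    @pytest.mark.parametrize("seed", range(4))
    def test_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8), rng.integers(3, 8)
        x = rng.standard_normal(n1)  # continuous: no ties
        y = rng.standard_normal(n2) + 0.5
        table = make_stat_table(x, y)
        (stat,) = wilcoxon_map(table, "activity", "beta", channels=["F3"])
        assert stat.p == pytest.approx(ranksum_exact_oracle(x, y), abs=1e-9)

    def test_z_matches_tie_corrected_formula(self):
        x = np.array([1.0, 2.0, 2.0, 5.0])
        y = np.array([2.0, 3.0, 4.0, 6.0, 7.0])
        z = _ranksum_z(x, y)
        # direct recomputation of the normal approximation
        from scipy.stats import rankdata

        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var_u = len(x) * len(y) / 12 * ((n + 1) - tie_term)
        assert z == pytest.approx((u - len(x) * len(y) / 2) / np.sqrt(var_u), abs=1e-12)

    def test_epoch_unit_uses_all_rows(self):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(6):
            grp = "patient" if s < 3 else "control"
            shift = 1.0 if grp == "patient" else 0.0
            for e in range(10):
                rows.append({"subject_id": f"S{s}", "group": grp, "epoch": e,
                             "beta.activity.F3": rng.standard_normal() + shift})
        table = pd.DataFrame(rows)
        (by_subject,) = wilcoxon_map(table, "activity", "beta", channels=["F3"])
        (by_epoch,) = wilcoxon_map(table, "activity", "beta", unit="epoch", channels=["F3"])
        assert abs(by_epoch.z) > abs(by_subject.z)  # more (pseudo-)replicates

    def test_single_group_rejected(self):
        table = make_stat_table([1, 2, 3], [])
        with pytest.raises(ConfigurationError):
            wilcoxon_map(table, "activity", "beta", channels=["F3"])

    def test_null_false_positive_rate_near_alpha(self, null_table):
        """Permuting subject labels: ~5% of channel tests reject at α=0.05."""
        rng = np.random.default_rng(17)
        per_subject = null_table.groupby("subject_id", sort=False).agg(
            **{c: (c, "mean") for c in ["beta.activity." + ch for ch in
               ("Fp1", "Fp2", "F3", "F4", "Fz", "C3", "Cz", "C4", "P3", "Pz",
                "P4", "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6")]}
        )
        values = per_subject.to_numpy()
        n_sub = values.shape[0]
        from scipy.stats import mannwhitneyu

        n_rep, hits, total = 200, 0, 0
        for _ in range(n_rep):
            perm = rng.permutation(n_sub)
            pat, ctl = perm[: n_sub // 2], perm[n_sub // 2 :]
            for j in range(values.shape[1]):
                p = mannwhitneyu(values[pat, j], values[ctl, j],
                                 alternative="two-sided", method="auto").pvalue
                hits += p < 0.05
                total += 1
        assert hits / total == pytest.approx(0.05, abs=0.03)
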