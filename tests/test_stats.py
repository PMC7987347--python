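"""Inference machinery: enumeration oracles, restricted permutations,
stratified bootstrap, mixed-model likelihood tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from wilddom.datasets import ValidationError
from wilddom.stats import (
    PermutationScheme,
    bonferroni,
    dispersion_test,
    kruskal_wallis,
    lmm_lrt,
    mann_whitney,
    mantel,
    permanova,
    spearman,
    stratified_bootstrap_mwu,
    wilcoxon_one_sample,
)


def euclidean_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(np.asarray(points, float))), ids=ids)


def permanova_f_oracle(dm: DistanceMatrix, labels: np.ndarray) -> float:
    """One-factor pseudo-F from within/total squared distances (direct formula)."""
    d2 = dm.data**2
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for level in np.unique(labels):
        idx = np.where(labels == level)[0]
        block = d2[np.ix_(idx, idx)]
        ss_within += block[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    k = len(np.unique(labels))
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestPermanova:
    def test_perfect_separation(self, rng):
        # two tight, far-apart clusters: group explains ~all variation
        points = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(50, 0.01, (5, 2))])
        meta = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5},
                            index=[f"s{i}" for i in range(10)])
        scheme = PermutationScheme(n_permutations=999, seed=0)
        res = permanova(euclidean_dm(points), meta, ["group"], scheme)
        assert res[0].effect_size > 0.999
        # only relabelings preserving the 5/5 partition tie with the observed
        # F (a 1/126 fraction of permutations), so p sits near its floor
        assert 1 / 1000 <= res[0].p_value <= 0.02

    def test_r2_partition_sums_to_one(self, small_survey):
        from wilddom.diversity import bray_curtis

        meta = small_survey.metadata
        animals = meta[meta["category"] != "primate"]
        dm = bray_curtis(small_survey.counts.subset_samples(list(animals.index)))
        scheme = PermutationScheme(
            type="within_strata", strata=animals["dyad_id"], n_permutations=99, seed=0
        )
        res = permanova(dm, animals, ["dyad_id", "status"], scheme)
        total_r2 = sum(r.effect_size for r in res)
        assert total_r2 == pytest.approx(1.0, abs=1e-10)
        # SS_total equals the independent sum d^2 / n
        d2 = dm.data ** 2
        n = d2.shape[0]
        expected_ss = d2[np.triu_indices(n, 1)].sum() / n
        assert res[-1].notes["ss_total"] == pytest.approx(expected_ss, rel=1e-10)

    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        points = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = euclidean_dm(points)
        meta = pd.DataFrame({"group": labels}, index=dm.ids)
        res = permanova(dm, meta, ["group"], PermutationScheme(seed=1), exhaustive=True)
        f_obs = permanova_f_oracle(dm, labels)
        assert res[0].statistic == pytest.approx(f_obs, rel=1e-10)
        # oracle: enumerate every relabelling of the samples
        exceed = total = 0
        for perm in itertools.permutations(range(6)):
            f_perm = permanova_f_oracle(dm, labels[list(perm)])
            exceed += f_perm >= f_obs - 1e-12
            total += 1
        assert res[0].p_value == pytest.approx(exceed / total, abs=1e-12)

    def test_restricted_permutations_stay_within_strata(self, rng):
        # factor constant within strata: restricted permutation can never
        # change its alignment, so its permutation p-value is 1
        points = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(5, 1, (4, 2))])
        dm = euclidean_dm(points)
        meta = pd.DataFrame(
            {"block": ["x"] * 4 + ["y"] * 4}, index=dm.ids
        )
        scheme = PermutationScheme(
            type="within_strata",
            strata=pd.Series(["x"] * 4 + ["y"] * 4, index=dm.ids),
            n_permutations=199,
            seed=0,
        )
        res = permanova(dm, meta, ["block"], scheme)
        assert res[0].p_value == pytest.approx(1.0)

    def test_constant_factor_errors(self, rng):
        dm = euclidean_dm(rng.normal(size=(4, 2)))
        meta = pd.DataFrame({"group": ["a"] * 4}, index=dm.ids)
        with pytest.raises(ValidationError, match="constant"):
            permanova(dm, meta, ["group"], PermutationScheme(seed=0))


class TestDispersion:
    def test_scaled_geometry_detected(self, rng):
        base = rng.normal(size=(20, 2))
        points = np.vstack([base, base * 3 + 10])
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=[f"s{i}" for i in range(40)])
        res = dispersion_test(euclidean_dm(points), groups, n_permutations=999, seed=0)
        assert res.p_value <= 0.01
        assert res.notes["group_mean_dispersion"]["b"] > res.notes["group_mean_dispersion"]["a"]

    def test_invariant_to_sample_order(self, rng):
        points = rng.normal(size=(12, 2))
        ids = [f"s{i}" for i in range(12)]
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=ids)
        dm = euclidean_dm(points, ids)
        res1 = dispersion_test(dm, groups, n_permutations=99, seed=0)
        order = ids[::-1]
        res2 = dispersion_test(dm.filter(order), groups, n_permutations=99, seed=0)
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-9)

    def test_singleton_group_errors(self, rng):
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        groups = pd.Series(["a"] * 4 + ["b"], index=dm.ids)
        with pytest.raises(ValidationError, match="at least two samples"):
            dispersion_test(dm, groups)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        dm = euclidean_dm(rng.normal(size=(8, 2)))
        res = mantel(dm, dm, n_permutations=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_statistic_matches_vectorized_oracle(self, rng):
        d1 = euclidean_dm(rng.normal(size=(7, 2)))
        d2 = euclidean_dm(rng.normal(size=(7, 2)), ids=list(d1.ids))
        res = mantel(d1, d2, n_permutations=99, seed=0)
        iu = np.triu_indices(7, 1)
        expected = np.corrcoef(d1.data[iu], d2.data[iu])[0, 1]
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_exhaustive_p_matches_enumeration(self, rng):
        d1 = euclidean_dm(rng.normal(size=(5, 2)))
        d2 = euclidean_dm(rng.normal(size=(5, 2)), ids=list(d1.ids))
        res = mantel(d1, d2, exhaustive=True)
        iu = np.triu_indices(5, 1)
        r_obs = np.corrcoef(d1.data[iu], d2.data[iu])[0, 1]
        exceed = total = 0
        for perm in itertools.permutations(range(5)):
            m = d2.data[np.ix_(perm, perm)]
            r = np.corrcoef(d1.data[iu], m[iu])[0, 1]
            exceed += abs(r) >= abs(r_obs) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(exceed / total, abs=1e-12)

    def test_id_mismatch_errors(self, rng):
        d1 = euclidean_dm(rng.normal(size=(4, 2)), ids=list("abcd"))
        d2 = euclidean_dm(rng.normal(size=(4, 2)), ids=list("abcx"))
        with pytest.raises(ValidationError, match="different ids"):
            mantel(d1, d2)


class TestRankTests:
    def test_mwu_exact_extreme_split(self):
        # all of x below all of y: U = 0, two-sided exact p = 2 / C(10,5)
        res = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)

    def test_mwu_u_matches_enumeration_oracle(self, rng):
        # exact p equals the tail fraction over all C(n1+n2, n1) rank splits
        x = rng.permutation(np.arange(1.0, 6.0))[:4]
        y = np.setdiff1d(np.arange(1.0, 11.0), x)[:5]
        res = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        u_obs = res.statistic
        us = []
        for combo in itertools.combinations(range(len(pooled)), n1):
            xs = pooled[list(combo)]
            u = sum((xi > yj) + 0.5 * (xi == yj)
                    for xi in xs for yj in np.delete(pooled, list(combo)))
            us.append(u)
        us = np.array(us)
        center = n1 * (len(pooled) - n1) / 2
        expected_p = np.mean(np.abs(us - center) >= abs(u_obs - center) - 1e-12)
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)

    def test_mwu_identical_samples(self):
        res = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0

    def test_mwu_monotone_transform_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        res1 = mann_whitney(x, y)
        res2 = mann_whitney(np.exp(x), np.exp(y))
        assert res1.statistic == res2.statistic
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_wilcoxon_all_positive_exact(self):
        res = wilcoxon_one_sample(np.arange(1.0, 9.0))
        assert res.p_value == pytest.approx(2 / 256, abs=1e-12)

    def test_wilcoxon_matches_sign_enumeration(self, rng):
        x = rng.normal(size=7)
        while len(np.unique(np.abs(x))) < 7:
            x = rng.normal(size=7)
        res = wilcoxon_one_sample(x)
        ranks = np.argsort(np.argsort(np.abs(x))) + 1
        w_obs = ranks[x > 0].sum()
        total_w = ranks.sum()
        ws = []
        for signs in itertools.product([0, 1], repeat=7):
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.array(ws)
        center = total_w / 2
        expected_p = np.mean(np.abs(ws - center) >= abs(w_obs - center) - 1e-12)
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)

    def test_wilcoxon_all_at_mu0(self):
        res = wilcoxon_one_sample(np.zeros(5))
        assert res.p_value == 1.0

    def test_kruskal_monotone_groups_and_errors(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.p_value < 0.05
        with pytest.raises(ValidationError, match="empty"):
            kruskal_wallis([[1, 2], []])

    def test_spearman_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 25, 90]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).statistic == pytest.approx(-1.0)


def test_bonferroni_examples():
    np.testing.assert_allclose(bonferroni([0.01], m=5), [0.05])
    np.testing.assert_allclose(bonferroni([0.5], m=3), [1.0])
    np.testing.assert_allclose(bonferroni([0.3]), [0.3])  # m = 1 is the identity
    with pytest.raises(ValidationError):
        bonferroni([1.5])


def make_pairs(rng, n_per_class=6, shift=0.0, noise=0.1):
    """All within-class pairs for two classes of individuals; pair value =
    sum of individual effects (+ class shift) plus small pair noise."""
    rows = []
    for cls, delta in (("g1", 0.0), ("g2", shift)):
        effects = {f"{cls}_{i}": rng.normal(0, 1) for i in range(n_per_class)}
        for a, b in itertools.combinations(sorted(effects), 2):
            rows.append(
                {
                    "ind_a": a,
                    "ind_b": b,
                    "group": cls,
                    "value": effects[a] + effects[b] + delta + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestStratifiedBootstrap:
    def test_seed_reproducibility(self, rng):
        pairs = make_pairs(rng, shift=1.0)
        r1 = stratified_bootstrap_mwu(pairs, n_bootstrap=200, seed=7)
        r2 = stratified_bootstrap_mwu(pairs, n_bootstrap=200, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic

    def test_large_shift_detected(self, rng):
        pairs = make_pairs(rng, shift=6.0, noise=0.05)
        res = stratified_bootstrap_mwu(pairs, n_bootstrap=500, seed=0)
        assert res.p_value < 0.05

    def test_p_floor_respected(self, rng):
        pairs = make_pairs(rng, shift=50.0, noise=0.01)
        res = stratified_bootstrap_mwu(pairs, n_bootstrap=300, seed=0)
        assert res.p_value >= 1 / 301

    def test_requires_two_groups(self, rng):
        pairs = make_pairs(rng)
        pairs["group"] = "only"
        with pytest.raises(ValidationError, match="two pair groups"):
            stratified_bootstrap_mwu(pairs, n_bootstrap=50, seed=0)


class TestLmmLrt:
    @staticmethod
    def simulate_longitudinal(rng, effect=0.0, n_per_group=8, sd_ind=0.5):
        rows = []
        for group, drift in (("ctrl", 0.0), ("treat", effect)):
            for i in range(n_per_group):
                intercept = rng.normal(0, sd_ind)
                for t in (0, 1, 2):
                    rows.append(
                        {
                            "individual": f"{group}{i}",
                            "group": group,
                            "time": t,
                            "y": intercept + drift * t + rng.normal(0, 0.5),
                        }
                    )
        return pd.DataFrame(rows)

    def test_lrt_nonnegative_under_null(self, rng):
        data = self.simulate_longitudinal(rng, effect=0.0)
        res = lmm_lrt(data, "y", ["time", "C(group)"], ["time"], "individual")
        assert res.statistic >= 0.0
        assert res.df == 1

    def test_planted_effect_detected(self, rng):
        data = self.simulate_longitudinal(rng, effect=2.0)
        res = lmm_lrt(data, "y", ["time", "C(group)"], ["time"], "individual")
        assert res.p_value < 0.01

    def test_non_nested_models_rejected(self, rng):
        data = self.simulate_longitudinal(rng)
        with pytest.raises(ValidationError, match="add parameters"):
            lmm_lrt(data, "y", ["time"], ["time"], "individual")
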