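"""Alpha/beta diversity: frozen examples, brute-force oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wilddom.datasets import CountTable, ValidationError
from wilddom.diversity import (
    bray_curtis,
    pathogen_metrics,
    pathogen_subset,
    rarefy,
    richness,
    shannon,
    unweighted_unifrac,
    weighted_unifrac,
)

from conftest import random_bifurcating_tree


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

class TestRarefy:
    def test_exact_depth_and_dropping(self, rng):
        table = CountTable(
            pd.DataFrame([[20, 10, 0], [5, 3, 2]], index=["big", "small"], columns=list("abc"))
        )
        out = rarefy(table, depth=20, seed=0)
        assert out.sample_ids == ["big"]
        assert out.depths().tolist() == [20]
        assert out.taxon_ids == list("abc")  # column identity preserved

    def test_depth_equal_to_total_unchanged(self):
        table = CountTable(pd.DataFrame([[7, 3]], index=["s"], columns=["a", "b"]))
        out = rarefy(table, depth=10, seed=1)
        assert out.counts.loc["s"].tolist() == [7, 3]

    def test_seed_reproducibility(self, small_table):
        a = rarefy(small_table, depth=4, seed=123)
        b = rarefy(small_table, depth=4, seed=123)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_all_below_depth_errors(self, small_table):
        with pytest.raises(ValidationError, match="below rarefaction depth"):
            rarefy(small_table, depth=10_000)

    def test_richness_never_increases(self, rng):
        counts = rng.integers(0, 30, size=(5, 12))
        counts[:, 0] += 40  # guarantee depth
        table = CountTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(5)]))
        out = rarefy(table, depth=30, seed=2)
        for sid in out.sample_ids:
            assert richness(out.counts.loc[sid]) <= richness(table.counts.loc[sid])


# ---------------------------------------------------------------------------
# shannon / richness
# ---------------------------------------------------------------------------

class TestShannon:
    @pytest.mark.parametrize(
        "counts, base, expected",
        [
            ((5, 5, 5, 5), 2, 2.0),
            ((10, 0, 0), 2, 0.0),
            ((8, 2), 2, 0.7219280948873623),  # -0.8 log2 0.8 - 0.2 log2 0.2
        ],
    )
    def test_frozen_values(self, counts, base, expected):
        assert shannon(np.array(counts), log_base=base) == pytest.approx(expected, abs=1e-12)

    def test_zero_sum_errors(self):
        with pytest.raises(ValidationError):
            shannon(np.zeros(3))

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=10).filter(lambda v: sum(v) > 0))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_uniform_maximum(self, counts):
        vec = np.array(counts)
        permuted = np.random.default_rng(0).permutation(vec)
        assert shannon(vec) == pytest.approx(shannon(permuted), abs=1e-12)
        k = richness(vec)
        if k > 0:
            uniform = np.zeros_like(vec)
            uniform[:k] = 1
            assert shannon(vec) <= shannon(uniform) + 1e-12

    def test_richness_examples(self):
        assert richness(np.array([3, 0, 1, 2])) == 3
        assert richness(np.zeros(4)) == 0


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Direct evaluation of 1 - 2 sum min / (sum a + sum b) on proportions."""
    a = a / a.sum()
    b = b / b.sum()
    return 1.0 - 2.0 * np.minimum(a, b).sum() / (a.sum() + b.sum())


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        table = CountTable(
            pd.DataFrame([[3, 1, 0], [3, 1, 0], [0, 0, 9]], index=list("xyz"))
        )
        dm = bray_curtis(table)
        assert dm["x", "y"] == pytest.approx(0.0, abs=1e-12)
        assert dm["x", "z"] == pytest.approx(1.0, abs=1e-12)

    def test_frozen_example(self):
        # sum of minima 2, totals 10 + 10 -> 1 - 4/20 = 0.8
        table = CountTable(pd.DataFrame([[6, 4, 0], [2, 0, 8]], index=["A", "B"]))
        assert bray_curtis(table)["A", "B"] == pytest.approx(0.8, abs=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 40, size=(4, 7))
            counts[:, 0] += 1  # avoid zero-sum rows
            table = CountTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(4)]))
            dm = bray_curtis(table)
            for i in range(4):
                for j in range(i + 1, 4):
                    expected = bray_curtis_oracle(
                        counts[i].astype(float), counts[j].astype(float)
                    )
                    assert dm[f"s{i}", f"s{j}"] == pytest.approx(expected, abs=1e-10)

    def test_zero_sum_sample_errors(self):
        table = CountTable(pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"]))
        with pytest.raises(ValidationError, match="zero-sum"):
            bray_curtis(table)


# ---------------------------------------------------------------------------
# UniFrac vs brute-force edge enumeration
# ---------------------------------------------------------------------------

def unifrac_oracle(tree, taxa, a, b):
    """Per-branch tally of unique/union branch length and weighted difference."""
    pa = dict(zip(taxa, a / a.sum()))
    pb = dict(zip(taxa, b / b.sum()))
    unique = union = wnum = wden = 0.0
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] or [node.name]
        in_a = any(a[taxa.index(t)] > 0 for t in tips)
        in_b = any(b[taxa.index(t)] > 0 for t in tips)
        pa_sum = sum(pa.get(t, 0.0) for t in tips)
        pb_sum = sum(pb.get(t, 0.0) for t in tips)
        if in_a != in_b:
            unique += node.length
        if in_a or in_b:
            union += node.length
        wnum += node.length * abs(pa_sum - pb_sum)
        wden += node.length * (pa_sum + pb_sum)
    return unique / union, wnum, wnum / wden


class TestUniFrac:
    def test_star_tree_example(self, star_tree):
        # A={t1,t2}, B={t2,t3}: unique branches t1,t3; union t1,t2,t3 -> 2/3
        table = CountTable(
            pd.DataFrame([[1, 1, 0, 0], [0, 1, 1, 0]], index=["A", "B"],
                         columns=["t1", "t2", "t3", "t4"])
        )
        dm = unweighted_unifrac(table, star_tree)
        assert dm["A", "B"] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_identical_samples_zero(self, star_tree):
        table = CountTable(
            pd.DataFrame([[2, 3, 0, 1], [4, 6, 0, 2]], index=["A", "B"],
                         columns=["t1", "t2", "t3", "t4"])
        )
        assert unweighted_unifrac(table, star_tree)["A", "B"] == pytest.approx(0.0, abs=1e-12)
        # same relative abundances -> weighted distance 0 as well
        assert weighted_unifrac(table, star_tree)["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_taxon_errors(self, star_tree):
        table = CountTable(pd.DataFrame([[1, 1], [1, 0]], index=["A", "B"], columns=["t1", "zz"]))
        with pytest.raises(ValidationError, match="absent from the tree"):
            unweighted_unifrac(table, star_tree)

    def test_matches_edge_enumeration_oracle(self, rng):
        taxa = [f"x{i}" for i in range(8)]
        for _ in range(50):
            tree = random_bifurcating_tree(taxa, rng)
            counts = rng.integers(0, 12, size=(2, 8))
            counts[0, rng.integers(0, 8)] += 1  # nonzero rows
            counts[1, rng.integers(0, 8)] += 1
            table = CountTable(pd.DataFrame(counts, index=["A", "B"], columns=taxa))
            exp_u, exp_w_raw, exp_w_norm = unifrac_oracle(
                tree, taxa, counts[0].astype(float), counts[1].astype(float)
            )
            got_u = unweighted_unifrac(table, tree)["A", "B"]
            got_w_norm = weighted_unifrac(table, tree, normalized=True)["A", "B"]
            got_w_raw = weighted_unifrac(table, tree, normalized=False)["A", "B"]
            assert got_u == pytest.approx(exp_u, abs=1e-10)
            assert got_w_norm == pytest.approx(exp_w_norm, abs=1e-10)
            assert got_w_raw == pytest.approx(exp_w_raw, abs=1e-10)
            assert 0.0 <= got_w_norm <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# pathogen subset / metrics
# ---------------------------------------------------------------------------

class TestPathogens:
    def test_genus_level_match(self, small_table):
        subset = pathogen_subset(small_table, ["escherichia"])
        assert subset.taxon_ids == ["t1"]

    def test_species_level_entry_matches_only_resolved_taxon(self, small_table):
        subset = pathogen_subset(small_table, ["streptococcus pneumoniae"])
        assert subset.taxon_ids == ["t2"]  # t3 is genus-only Streptococcus

    def test_no_match_gives_empty_subset(self, small_table):
        subset = pathogen_subset(small_table, ["yersinia"])
        assert subset.shape[1] == 0

    def test_metrics_zero_without_pathogens(self, small_table):
        metrics = pathogen_metrics(small_table, ["yersinia"])
        assert (metrics["pathogen_abundance"] == 0).all()
        assert (metrics["pathogen_richness"] == 0).all()

    def test_all_pathogenic_gives_abundance_one(self, small_table):
        metrics = pathogen_metrics(
            small_table, ["escherichia", "streptococcus", "harmless"]
        )
        assert metrics["pathogen_abundance"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_abundance_matches_ratio_oracle(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        taxonomy = pd.Series(
            [f"k__B;p__;c__;o__;f__;g__{'Bad' if i < 4 else 'Good'}{i};s__" for i in range(10)],
            index=taxa,
        )
        counts = rng.integers(0, 25, size=(6, 10)) + 1
        table = CountTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(6)], columns=taxa), taxonomy)
        metrics = pathogen_metrics(table, [f"bad{i}" for i in range(4)])
        expected = counts[:, :4].sum(axis=1) / counts.sum(axis=1)
        np.testing.assert_allclose(metrics["pathogen_abundance"].to_numpy(), expected, atol=1e-12)
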