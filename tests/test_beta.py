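import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from dustair import beta
from dustair.errors import ConfigurationError, DataError
from dustair.io_tables import TaxonomyTable

from conftest import make_counts


# ---------------------------------------------------------------------------
# Bray–Curtis
# ---------------------------------------------------------------------------


def bc_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return np.abs(x - y).sum() / (x + y).sum()


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((3, 1, 4), (3, 1, 4), 0.0),
            ((5, 0, 0), (0, 2, 7), 1.0),
            ((6, 2), (2, 2), 1 / 3),
        ],
    )
    def test_closed_forms(self, x, y, expected):
        assert beta.bray_curtis(x, y) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(DataError):
            beta.bray_curtis((0, 0), (0, 0))

    def test_matrix_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            table = make_counts(rng.integers(0, 50, size=(10, 10)) + 1)
            dm = beta.bray_curtis_matrix(table)
            cols = table.counts.T
            for i, j in itertools.combinations(range(10), 2):
                assert dm[i, j] == pytest.approx(bc_oracle(cols[i], cols[j]), abs=1e-12)

    @given(st.lists(st.integers(0, 100), min_size=2, max_size=20),
           st.lists(st.integers(0, 100), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bounds_and_symmetry(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        d = beta.bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(beta.bray_curtis(y, x))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def anosim_r_oracle(dm: np.ndarray, labels) -> float:
    """Classic ANOSIM R = (rB - rW) / (M/2) computed from first principles."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    ranks = stats.rankdata([dm[i, j] for i, j in pairs])
    within = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    between = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


def separated_toy():
    """Two groups of 3 with all between-distances above all within-distances."""
    d = np.zeros((6, 6))
    for i, j in itertools.combinations(range(6), 2):
        same = (i < 3) == (j < 3)
        d[i, j] = d[j, i] = (0.1 + 0.01 * (i + j)) if same else (0.8 + 0.01 * (i + j))
    return DistanceMatrix(d, ids=[f"S{i}" for i in range(6)])


class TestAnosim:
    def test_maximal_separation_r_is_one(self):
        res = beta.anosim(separated_toy(), ["a"] * 3 + ["b"] * 3,
                          n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration_two_groups_of_three(self):
        rng = np.random.default_rng(3)
        raw = rng.random((6, 6))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=list("abcdef"))
        labels = ["g1"] * 3 + ["g2"] * 3
        r_obs = anosim_r_oracle(d, labels)
        hits = 0
        labelings = set(itertools.combinations(range(6), 3))
        for combo in labelings:
            perm = ["g1" if i in combo else "g2" for i in range(6)]
            if anosim_r_oracle(d, perm) >= r_obs - 1e-12:
                hits += 1
        p_exact = hits / len(labelings)
        res = beta.anosim(dm, labels, n_permutations=4999, seed=1)
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_r_matches_skbio_reference(self):
        rng = np.random.default_rng(9)
        raw = rng.random((9, 9))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(9)])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = beta.anosim(dm, labels, n_permutations=99, seed=0)
        ref = skbio_anosim(dm, grouping=np.array(labels), permutations=99)
        assert res.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        raw = rng.random((8, 8))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        labels = ["a"] * 4 + ["b"] * 4
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        dm_sq = DistanceMatrix(d**2, ids=[str(i) for i in range(8)])
        r1 = beta.anosim(dm, labels, n_permutations=9, seed=0).r
        r2 = beta.anosim(dm_sq, labels, n_permutations=9, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_null_r_centred_on_zero(self):
        rng = np.random.default_rng(12)
        rs = []
        for _ in range(50):
            raw = rng.random((10, 10))
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0)
            dm = DistanceMatrix(d, ids=[str(i) for i in range(10)])
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            rs.append(beta.anosim(dm, labels, n_permutations=9, seed=0).r)
        assert abs(np.mean(rs)) < 0.1

    def test_group_of_one_rejected(self):
        with pytest.raises(DataError):
            beta.anosim(separated_toy(), ["a"] * 5 + ["b"], n_permutations=9, seed=0)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def mixed_taxonomy():
    return TaxonomyTable({
        "OtuF1": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                  "Lachnospiraceae", "Blautia"),
        "OtuF2": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                  "Lactobacillaceae", "Lactobacillus"),
        "OtuP1": ("Bacteria", "Proteobacteria"),
        "OtuU1": ("Bacteria",),  # unclassified below domain
    })


class TestAggregation:
    def test_equal_sample_weighting(self):
        counts = make_counts([[90, 50], [0, 0], [10, 50], [0, 0]],
                             otu_ids=["OtuF1", "OtuF2", "OtuP1", "OtuU1"],
                             sample_ids=["S1", "S2"])
        groups = {"S1": "g", "S2": "g"}
        agg = beta.aggregate_by_rank(counts, mixed_taxonomy(), "phylum", groups)
        # (0.9 + 0.5) / 2 regardless of depths
        assert agg.loc["Firmicutes", "g"] == pytest.approx(0.7)

    def test_single_sample_own_fractions(self):
        counts = make_counts([[3], [1], [4], [2]],
                             otu_ids=["OtuF1", "OtuF2", "OtuP1", "OtuU1"],
                             sample_ids=["S1"])
        agg = beta.aggregate_by_rank(counts, mixed_taxonomy(), "phylum", {"S1": "g"})
        assert agg.loc["Firmicutes", "g"] == pytest.approx(0.4)
        assert agg.loc["unclassified", "g"] == pytest.approx(0.2)

    def test_group_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        counts = make_counts(rng.integers(0, 20, size=(4, 6)) + 1,
                             otu_ids=["OtuF1", "OtuF2", "OtuP1", "OtuU1"])
        groups = {s: ("g1" if i % 2 else "g2") for i, s in enumerate(counts.sample_ids)}
        for rank in ("phylum", "genus"):
            agg = beta.aggregate_by_rank(counts, mixed_taxonomy(), rank, groups)
            assert np.allclose(agg.sum(axis=0), 1.0, atol=1e-9)

    def test_unknown_rank_rejected(self):
        counts = make_counts([[1]], otu_ids=["OtuF1"])
        with pytest.raises(ConfigurationError):
            beta.collapse_counts(counts, mixed_taxonomy(), "kingdom")


# ---------------------------------------------------------------------------
# CLR instances + BH
# ---------------------------------------------------------------------------


class TestClr:
    def test_vectors_sum_to_zero(self):
        clr = beta.clr_instances([5, 0, 12, 3], n_instances=50, seed=0)
        assert clr.shape == (50, 4)
        assert np.allclose(clr.sum(axis=1), 0.0, atol=1e-9)

    def test_symmetric_counts_have_zero_mean_clr(self):
        clr = beta.clr_instances([10, 10, 10, 10], n_instances=4000, seed=1)
        assert np.allclose(clr.mean(axis=0), 0.0, atol=0.05)

    def test_seeded_determinism(self):
        a = beta.clr_instances([1, 2, 3], n_instances=1, seed=42)
        b = beta.clr_instances([1, 2, 3], n_instances=1, seed=42)
        assert np.array_equal(a, b)


def bh_oracle(p):
    """Literal step-up rule: q_(i) = min_{j>=i} p_(j) m / j, in input order."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


class TestBhAdjust:
    def test_hand_worked_example(self):
        got = beta.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert beta.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_stepup_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(beta.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_output_dominates_input(self):
        rng = np.random.default_rng(6)
        p = rng.random(25)
        q = beta.bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            beta.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------


class TestDifferentialAbundance:
    def test_same_groups_give_zero_effects(self, flat_taxonomy):
        rng = np.random.default_rng(0)
        counts = make_counts(rng.integers(1, 100, size=(8, 6)))
        tax = flat_taxonomy(counts.otu_ids)
        res = beta.differential_abundance(counts, tax, "genus",
                                          counts.sample_ids, counts.sample_ids,
                                          n_instances=8, seed=0)
        assert np.allclose(res.table["median_clr_diff"], 0.0)
        assert (res.table["expected_p"] > 0.9).all()

    def test_planted_enrichment_detected(self, flat_taxonomy):
        rng = np.random.default_rng(1)
        base = np.full(20, 1.0)
        boosted = base.copy()
        boosted[0] *= 8.0
        a = rng.multinomial(5000, boosted / boosted.sum(), size=12).T
        b = rng.multinomial(5000, base / base.sum(), size=12).T
        counts = make_counts(np.hstack([a, b]),
                             sample_ids=[f"A{i}" for i in range(12)]
                             + [f"B{i}" for i in range(12)])
        tax = flat_taxonomy(counts.otu_ids)
        res = beta.differential_abundance(
            counts, tax, "genus", [f"A{i}" for i in range(12)],
            [f"B{i}" for i in range(12)], n_instances=32, seed=2)
        top = res.table["median_clr_diff"].idxmax()
        assert top == "Genus_0"
        assert res.table.loc[top, "bh_adjusted_p"] < 0.05
        assert res.table.loc[top, "log2_fold_diff"] == pytest.approx(
            res.table.loc[top, "median_clr_diff"] / math.log(2))

    def test_sign_convention_positive_means_higher_in_group_a(self, flat_taxonomy):
        a = np.array([[900, 910], [100, 90]])
        b = np.array([[100, 110], [900, 890]])
        counts = make_counts(np.hstack([a, b]), sample_ids=["A1", "A2", "B1", "B2"])
        tax = flat_taxonomy(counts.otu_ids)
        res = beta.differential_abundance(counts, tax, "genus", ["A1", "A2"],
                                          ["B1", "B2"], n_instances=16, seed=3)
        assert res.table.loc["Genus_0", "median_clr_diff"] > 0
        assert res.table.loc["Genus_1", "median_clr_diff"] < 0

    def test_undersized_group_rejected(self, flat_taxonomy):
        counts = make_counts([[1, 2, 3]], sample_ids=["A1", "B1", "B2"])
        with pytest.raises(DataError):
            beta.differential_abundance(counts, flat_taxonomy(counts.otu_ids),
                                        "genus", ["A1"], ["B1", "B2"])
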