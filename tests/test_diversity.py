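"""Alpha/beta diversity estimators against hand values and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from skbio.diversity.alpha import chao1 as skbio_chao1
from skbio.diversity.alpha import shannon as skbio_shannon
from skbio.diversity.alpha import simpson as skbio_simpson
from sklearn.isotonic import isotonic_regression as sklearn_isotonic

from snowcat.diversity import (
    DissimilarityMatrix,
    OtuTable,
    _pava,
    alpha_diversity,
    bray_curtis,
    chao1,
    core_microbiome,
    family_summary,
    nmds,
    observed_richness,
    rarefy,
    sequence_retention_percent,
    shannon,
    shared_otus,
    simpson,
)
from tests.conftest import make_table

counts_vectors = st.lists(st.integers(0, 50), min_size=3, max_size=12).filter(
    lambda v: sum(v) > 0
)


class TestRarefaction:
    def test_depth_equal_to_total_is_identity(self):
        t = make_table({"s1": [3, 5, 2], "s2": [4, 4, 2]})
        out = rarefy(t, depth=10, seed=0)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_single_otu_sample(self):
        t = make_table({"s1": [10, 0, 0], "s2": [5, 3, 2]})
        out = rarefy(t, depth=5, seed=0)
        assert list(out.counts.loc["s1"]) == [5, 0, 0]

    def test_depth_exceeding_smallest_library_rejected(self):
        t = make_table({"s1": [3, 2], "s2": [10, 10]})
        with pytest.raises(ValueError, match="smallest library"):
            rarefy(t, depth=6)

    def test_hypergeometric_expectation(self):
        # sample (5, 5) rarefied to 5: mean first-OTU count 2.5
        t = make_table({"s1": [5, 5]})
        draws = [
            rarefy(t, depth=5, seed=s).counts.iloc[0, 0] for s in range(10_000)
        ]
        assert np.mean(draws) == pytest.approx(2.5, abs=0.05)

    def test_proportion_preservation(self):
        t = make_table({"s1": [60, 30, 10]})
        total = np.zeros(3)
        reps = 2000
        for s in range(reps):
            total += rarefy(t, depth=50, seed=s).counts.iloc[0].to_numpy()
        assert total / (reps * 50) == pytest.approx([0.6, 0.3, 0.1], abs=0.01)


class TestAlphaDiversity:
    def test_observed_richness_counts_nonzero(self):
        t = make_table({"s1": [1, 0, 3, 7], "s2": [0, 0, 0, 0]})
        rich = observed_richness(t)
        assert rich["s1"] == 3
        assert rich["s2"] == 0

    def test_chao1_hand_value(self):
        # S_obs=10, f1=3 singletons, f2=1 doubleton -> 10 + 3*2/(2*2) = 11.5
        counts = [1, 1, 1, 2, 3, 3, 4, 5, 6, 7]
        t = make_table({"s1": counts})
        assert chao1(t)["s1"] == pytest.approx(11.5)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 0, 0], 0.0),  # single OTU
            ([3, 3, 3, 3], np.log(4)),  # uniform
            ([2, 1, 1], 1.5 * np.log(2)),  # p=(0.5,0.25,0.25) -> 1.0397
        ],
    )
    def test_shannon_hand_values(self, counts, expected):
        t = make_table({"s1": counts})
        assert shannon(t)["s1"] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts,expected",
        [([7, 0], 0.0), ([4, 4], 0.5), ([9, 1], 0.18)],
    )
    def test_simpson_hand_values(self, counts, expected):
        t = make_table({"s1": counts})
        assert simpson(t)["s1"] == pytest.approx(expected)

    def test_chao1_no_singletons_equals_observed(self):
        t = make_table({"s1": [3, 4, 5, 2, 2]})
        assert chao1(t)["s1"] == observed_richness(t)["s1"]

    @given(counts=counts_vectors)
    def test_estimators_match_skbio(self, counts):
        t = make_table({"s1": counts})
        arr = np.asarray(counts)
        assert chao1(t)["s1"] == pytest.approx(skbio_chao1(arr), rel=1e-9)
        assert shannon(t)["s1"] == pytest.approx(
            skbio_shannon(arr, base=np.e), rel=1e-9, abs=1e-12
        )
        assert simpson(t)["s1"] == pytest.approx(skbio_simpson(arr), rel=1e-9, abs=1e-12)

    @given(counts=counts_vectors)
    def test_invariants(self, counts):
        t = make_table({"s1": counts})
        alpha = alpha_diversity(t)
        obs = alpha["observed"].iloc[0]
        assert alpha["chao1"].iloc[0] >= obs
        if obs > 0:
            assert alpha["shannon"].iloc[0] <= np.log(obs) + 1e-12
        assert 0 <= alpha["simpson"].iloc[0] <= 1

    @given(counts=counts_vectors)
    def test_shannon_invariant_under_relabeling(self, counts):
        t = make_table({"s1": counts})
        t_rev = make_table({"s1": counts[::-1]})
        assert shannon(t)["s1"] == pytest.approx(shannon(t_rev)["s1"], rel=1e-12)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = make_table({"s1": [2, 3, 1], "s2": [2, 3, 1]})
        assert bray_curtis(t).values[0, 1] == 0.0

    def test_disjoint_samples_one(self):
        t = make_table({"s1": [5, 0], "s2": [0, 7]})
        assert bray_curtis(t).values[0, 1] == 1.0

    def test_hand_value(self):
        t = make_table({"s1": [2, 2, 0], "s2": [0, 2, 2]})
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.5)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        counts = {f"s{i}": list(rng.integers(0, 30, size=8)) for i in range(5)}
        t = make_table(counts)
        d = bray_curtis(t).values
        x = t.counts.to_numpy().astype(float)
        for i in range(5):
            for j in range(i + 1, 5):
                assert d[i, j] == pytest.approx(scipy_braycurtis(x[i], x[j]), rel=1e-12)

    def test_all_zero_pair_defined_as_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(make_table({"s1": [0, 0], "s2": [0, 0], "s3": [1, 1]}))
        assert d.values[0, 1] == 0.0


class TestNmds:
    def test_equilateral_triangle_embeds_exactly(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        result = nmds(d, seed=0, n_restarts=5)
        assert result.stress == pytest.approx(0.0, abs=1e-6)

    def test_recovers_exact_planar_configuration(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, size=(6, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        d /= d.max()
        result = nmds(DissimilarityMatrix(d, tuple("abcdef")), seed=0)
        assert result.stress < 1e-3

    def test_stress_history_non_increasing(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, size=(8, 3))  # 3-D data forced into 2-D
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        d /= d.max()
        result = nmds(d, seed=1, n_restarts=3)
        hist = result.stress_history
        assert all(a >= b - 1e-12 for a, b in zip(hist, hist[1:]))
        assert result.stress == pytest.approx(hist[-1])

    def test_stress_invariant_under_similarity_transform(self):
        # stress-1 depends only on ranks and relative distances
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1, size=(7, 3))
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        r1 = nmds(d / d.max(), seed=2, n_restarts=5)
        r2 = nmds(0.5 * d / d.max(), seed=2, n_restarts=5)
        assert r1.stress == pytest.approx(r2.stress, abs=1e-6)

    def test_rejects_asymmetric_input(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nmds(d)

    @given(
        y=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=40)
    )
    def test_pava_matches_sklearn(self, y):
        ours = _pava(np.asarray(y))
        ref = sklearn_isotonic(np.asarray(y))
        assert np.allclose(ours, ref, atol=1e-9)


class TestFamilySummary:
    def taxonomy(self, mapping):
        return pd.DataFrame(
            {"family": pd.Series(mapping), "genus": "g"},
        ).rename_axis("OTU_ID")

    def test_single_family(self):
        t = make_table({"s1": [3, 7]}, otus=["o1", "o2"])
        tax = self.taxonomy({"o1": "FamA", "o2": "FamA"})
        out = family_summary(t, tax, k=5)
        assert out.loc["s1", "FamA"] == pytest.approx(1.0)
        assert out.loc["s1", "other"] == 0.0

    def test_k_covers_all_families(self):
        t = make_table({"s1": [3, 7]}, otus=["o1", "o2"])
        tax = self.taxonomy({"o1": "FamA", "o2": "FamB"})
        out = family_summary(t, tax, k=10)
        assert out.loc["s1", "other"] == 0.0

    def test_top_k_merges_remainder(self):
        t = make_table({"s1": [75, 25], "s2": [75, 25]}, otus=["o1", "o2"])
        tax = self.taxonomy({"o1": "FamA", "o2": "FamB"})
        out = family_summary(t, tax, k=1)
        assert out.loc["s1", "FamA"] == pytest.approx(0.75)
        assert out.loc["s1", "other"] == pytest.approx(0.25)

    def test_rows_sum_to_one(self, default_dataset):
        out = family_summary(default_dataset.otu_table, default_dataset.taxonomy, k=20)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert out.shape[1] <= 21


class TestSharedAndCore:
    def table(self):
        return make_table(
            {
                "s1": [1, 1, 1, 0],  # presence {a,b,c}
                "s2": [0, 1, 1, 1],  # presence {b,c,d}
            },
            otus=["a", "b", "c", "d"],
        )

    def test_identical_presence_sets(self):
        t = make_table({"s1": [1, 1], "s2": [2, 3]})
        assert shared_otus(t, ["s1"], ["s2"]) == 100.0

    def test_disjoint_presence_sets(self):
        t = make_table({"s1": [1, 0], "s2": [0, 2]})
        assert shared_otus(t, ["s1"], ["s2"]) == 0.0

    def test_jaccard_hand_value(self):
        assert shared_otus(self.table(), ["s1"], ["s2"]) == pytest.approx(50.0)

    def test_groups_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            shared_otus(self.table(), ["s1"], ["s1"])

    def test_core_microbiome_intersection(self):
        t = make_table(
            {"s1": [1, 1, 0], "s2": [0, 1, 1], "s3": [0, 1, 0]},
            otus=["a", "b", "c"],
        )
        assert core_microbiome(t, [["s1"], ["s2"], ["s3"]]) == ["b"]

    def test_core_with_identical_groups(self):
        t = make_table({"s1": [1, 0, 2], "s2": [1, 0, 2]}, otus=["a", "b", "c"])
        assert core_microbiome(t, [["s1"], ["s2"]]) == ["a", "c"]

    def test_core_with_empty_group_is_empty(self):
        t = make_table({"s1": [1, 1], "s2": [0, 0]})
        assert core_microbiome(t, [["s1"], ["s2"]]) == []


def test_sequence_retention_percent():
    assert sequence_retention_percent(3, 4) == pytest.approx(75.0)
    with pytest.raises(ValueError):
        sequence_retention_percent(5, 4)
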