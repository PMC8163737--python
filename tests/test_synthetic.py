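"""Seeded synthetic-study generator: determinism, calibration, noise models."""

import numpy as np
import pandas as pd
import pytest

from snowcat import synthetic
from snowcat.diversity import observed_richness
from snowcat.synthetic import (
    CommunityCell,
    CommunityScenario,
    RateCell,
    RateScenario,
    default_scenario,
    generate_otu_table,
    generate_rates,
    generate_reference_profile,
    plate_measurements,
    simulate_dataset,
)


@pytest.fixture(scope="module")
def scenario():
    return default_scenario()


class TestDefaultScenario:
    def test_richness_anchors(self, scenario):
        community, _ = scenario
        assert community.cells[("fast", 28)].target_richness == 314
        assert community.cells[("fast", 500)].target_richness == 128
        assert community.cells[("nonsink", 28)].target_richness == 262
        assert community.cells[("nonsink", 500)].target_richness == 531

    def test_nonsink_richness_monotone_with_depth(self, scenario):
        community, _ = scenario
        targets = [community.cells[("nonsink", d)].target_richness for d in (28, 70, 128, 500)]
        assert targets == sorted(targets)

    def test_shared_fraction_decay(self, scenario):
        community, _ = scenario
        assert community.cells[("fast", 28)].shared_fraction == pytest.approx(0.53)
        assert community.cells[("fast", 500)].shared_fraction == pytest.approx(0.16)

    def test_deep_dominance_is_92_percent_over_four_otus(self, scenario):
        community, _ = scenario
        cell = community.cells[("fast", 500)]
        assert cell.dominant_mass == pytest.approx(0.92)
        dom = cell.dominant_otus()
        assert len(dom) == 4
        genera = {synthetic.DOMINANT_OTUS[g][0][2] for g, _ in cell.dominance}
        assert genera == {"Acinetobacter", "Pseudomonas"}


class TestScenarioValidation:
    def test_dominance_must_sum_below_one(self):
        with pytest.raises(ValueError, match="sum to < 1"):
            CommunityCell(target_richness=10, dominance=(("Acinetobacter", 1.0),))

    def test_richness_must_cover_dominants(self):
        with pytest.raises(ValueError, match="dominant"):
            CommunityCell(target_richness=3, dominance=(("Acinetobacter", 0.5), ("Pseudomonas", 0.3)))

    def test_non_positive_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            CommunityCell(target_richness=10, library_size=0)


class TestOtuTableGeneration:
    def test_seeded_determinism(self, scenario):
        community, _ = scenario
        t1, tax1 = generate_otu_table(community, seed=1)
        t2, tax2 = generate_otu_table(community, seed=1)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(tax1, tax2)

    def test_different_seeds_differ(self, scenario):
        community, _ = scenario
        t1, _ = generate_otu_table(community, seed=1)
        t2, _ = generate_otu_table(community, seed=2)
        assert not t1.counts.equals(t2.counts)

    def test_default_design_has_36_samples(self, default_dataset):
        table = default_dataset.otu_table
        assert len(table.sample_ids) == 36
        meta = table.metadata
        assert set(meta["fraction"]) == {"niskin", "nonsink", "fast"}
        assert set(meta["depth_m"]) == {28, 70, 128, 500}
        assert meta.groupby(["fraction", "depth_m"]).size().eq(3).all()

    def test_library_size_exact(self, default_dataset):
        sums = default_dataset.otu_table.sample_sums()
        assert (sums == synthetic.DEFAULT_LIBRARY_SIZE).all()

    def test_every_otu_has_taxonomy(self, default_dataset):
        table, tax = default_dataset.otu_table, default_dataset.taxonomy
        assert set(table.otu_ids) <= set(tax.index)
        assert tax["family"].notna().all()

    def test_degenerate_single_otu_community(self):
        cells = {
            (frac, 28): CommunityCell(target_richness=1, shared_fraction=1.0)
            for frac in ("fast", "nonsink")
        }
        scn = CommunityScenario(cells=cells, depths_m=(28,))
        table, _ = generate_otu_table(scn, seed=0)
        # all reads in one shared column per sample
        assert table.counts.shape[1] == 1
        assert (table.counts.iloc[:, 0] == synthetic.DEFAULT_LIBRARY_SIZE).all()

    def test_total_otu_pool_near_one_thousand(self, default_dataset):
        assert 850 <= len(default_dataset.otu_table.otu_ids) <= 1150


@pytest.fixture(scope="module")
def summary():
    return synthetic.calibration_summary(n_datasets=50, seed=1)


class TestCalibration:
    """Monte-Carlo calibration of the default scenario (shared 50-seed run)."""

    def test_mean_richness_within_ten_percent_of_targets(self, summary):
        rich = summary["richness"]
        rel = (rich["mean_observed"] - rich["target"]).abs() / rich["target"]
        assert (rel < 0.10).all(), rich

    def test_fast_28m_richness_near_314(self, summary):
        rich = summary["richness"].set_index(["fraction", "depth_m"])
        value = rich.loc[("fast", 28), "mean_observed"]
        assert 283 <= value <= 345

    def test_shared_otu_fraction_at_anchor_depths(self, summary):
        shared = summary["shared"].set_index("depth_m")["mean_shared_pct"]
        assert shared[28] == pytest.approx(53.0, abs=7.0)
        assert shared[500] == pytest.approx(16.0, abs=7.0)

    def test_deep_dominance_share(self, summary):
        dom = summary["dominance"].set_index("depth_m")["mean_dominant_share"]
        assert dom[500] == pytest.approx(0.92, abs=0.04)


class TestRates:
    def test_zero_cv_returns_the_mean_exactly(self):
        cells = {
            (f, d): RateCell(
                mean_leucine_pmol_l_h=10.0, mean_cells_per_ml=1e6, cv_replicates=0.0
            )
            for f in ("niskin", "nonsink", "fast")
            for d in (28,)
        }
        rates, _ = generate_rates(RateScenario(cells=cells, depths_m=(28,)), seed=0)
        assert (rates["leu_pmol_l_h"] == 10.0).all()

    def test_seeded_determinism(self, scenario):
        _, rate_scn = scenario
        r1, c1 = generate_rates(rate_scn, seed=5)
        r2, c2 = generate_rates(rate_scn, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_lognormal_mean_preserved(self):
        # law of large numbers: with mean 10 and cv 0.2, the grand mean of
        # many seeded draws stays within 2% of 10
        cells = {
            ("nonsink", 28): RateCell(
                mean_leucine_pmol_l_h=10.0, mean_cells_per_ml=1e6, cv_replicates=0.2
            )
        }
        scn = RateScenario(cells=cells, depths_m=(28,), fractions=("nonsink",))
        draws = []
        for seed in range(1000):
            rates, _ = generate_rates(scn, seed=seed)
            draws.extend(rates["leu_pmol_l_h"])
        assert np.mean(draws) == pytest.approx(10.0, rel=0.02)

    def test_cell_concentrations_positive(self, default_dataset):
        assert (default_dataset.cells["cells_per_ml"] > 0).all()


class TestReferenceProfile:
    def test_closed_form(self):
        profile = generate_reference_profile(1000.0, -1.0, [10.0, 100.0])
        assert profile.tolist() == [[10.0, 100.0], [100.0, 10.0]]

    def test_flat_exponent(self):
        profile = generate_reference_profile(7.0, 0.0, [10, 50, 500])
        assert np.allclose(profile[:, 1], 7.0)

    def test_non_positive_depth_rejected(self):
        with pytest.raises(ValueError):
            generate_reference_profile(1.0, -1.0, [0.0, 10.0])


class TestPlateMeasurements:
    def test_deconvolution_round_trip(self, default_dataset):
        """Plate-scale measurements invert exactly back to volumetric rates."""
        from snowcat import msc

        ds = default_dataset
        meas = ds.measurements
        ambient = meas[meas["msc_tag"] == "nonsink_top"].set_index(
            ["depth_m", "replicate", "rep"]
        )["value"]
        fast = meas[meas["msc_tag"] == "fast_plate"]
        truth = ds.rates.set_index(["sample_id", "rep"])["leu_pmol_l_h"]
        for _, row in fast.head(6).iterrows():
            m = msc.undilute(
                msc.FractionMeasurement(
                    "fast_plate", row["value"], row["units"], row["dilution"]
                )
            )
            amb = msc.FractionMeasurement(
                "nonsink_top",
                float(ambient.loc[(row["depth_m"], row["replicate"], row["rep"])]),
                row["units"],
            )
            value = msc.deconvolve_fast_sinking(m, amb, ds.geometry)
            assert value == pytest.approx(
                truth.loc[(row["sample_id"], row["rep"])], rel=1e-9
            )


def test_simulate_dataset_is_reproducible():
    d1 = simulate_dataset(seed=3)
    d2 = simulate_dataset(seed=3)
    pd.testing.assert_frame_equal(d1.otu_table.counts, d2.otu_table.counts)
    pd.testing.assert_frame_equal(d1.rates, d2.rates)
    pd.testing.assert_frame_equal(d1.cells, d2.cells)


def test_fast_richness_collapses_and_nonsink_rises(default_dataset):
    """Single-seed sanity check of the opposing depth trends."""
    table = default_dataset.otu_table
    rich = observed_richness(table)
    meta = table.metadata

    def mean_richness(fraction, depth):
        ids = meta.index[(meta["fraction"] == fraction) & (meta["depth_m"] == depth)]
        return float(rich.loc[ids].mean())

    assert mean_richness("fast", 28) > mean_richness("fast", 500)
    assert mean_richness("nonsink", 500) > mean_richness("nonsink", 28)
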