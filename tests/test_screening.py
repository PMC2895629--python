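import statistics

import numpy as np
import pytest

from pollenscreen.expr_model import ALL_TISSUES, POLLEN_STAGES, SampleDesign, tissue_expressed
from pollenscreen.screening import (
    ScreenConfig,
    pollen_zscore,
    profile_correlation,
    run_screens,
    screen_constitutive,
    screen_pollen_preferential,
    screen_stage_downregulated,
    screen_stage_enriched,
    stage_zscore,
)

from .conftest import dataset_from_tissue_values, random_full_dataset


class TestStageZScore:
    def test_hand_computed_example(self):
        # focal UNM median 6; reference medians 1, 2, 3 -> mu=2, SD=1, Z=4
        ds = dataset_from_tissue_values(
            {"UNM": [6.0], "callus": [1.0], "root": [2.0], "leaf": [3.0]}
        )
        row = stage_zscore(ds, "UNM").iloc[0]
        assert row["mu"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["z"] == pytest.approx(4.0)

    def test_focal_equal_to_reference_mean_gives_zero(self):
        ds = dataset_from_tissue_values(
            {"UNM": [2.0], "callus": [1.0], "root": [2.0], "leaf": [3.0]}
        )
        assert stage_zscore(ds, "UNM")["z"].iloc[0] == pytest.approx(0.0)

    def test_matches_per_gene_loop_oracle(self, rng):
        ds = random_full_dataset(rng, n_genes=50)
        for stage in ("UNM", "GPG"):
            table = stage_zscore(ds, stage)
            others = [t for t in ALL_TISSUES if t != stage]
            for gene in ds.gene_ids:
                x = statistics.median(
                    ds.intensity.loc[gene, ds.design.samples_of(stage)]
                )
                ref = [
                    statistics.median(ds.intensity.loc[gene, ds.design.samples_of(t)])
                    for t in others
                ]
                mu = statistics.mean(ref)
                sd = statistics.stdev(ref)  # sample SD, n-1
                assert table.loc[gene, "z"] == pytest.approx((x - mu) / sd, abs=1e-12)
                assert table.loc[gene, "ratio"] == pytest.approx(x / max(ref), abs=1e-12)

    def test_nonpollen_focal_rejected(self, rng):
        with pytest.raises(ValueError, match="pollen"):
            stage_zscore(random_full_dataset(rng, 5), "root")


class TestRatios:
    def test_boundary_ratio_of_two(self):
        values = {t: [5.0] for t in ALL_TISSUES}
        values["UNM"] = [10.0]
        ds = dataset_from_tissue_values(values)
        assert stage_zscore(ds, "UNM")["ratio"].iloc[0] == pytest.approx(2.0)

    def test_flat_gene_ratio_one(self):
        ds = dataset_from_tissue_values({t: [7.0] for t in ALL_TISSUES})
        assert stage_zscore(ds, "UNM")["ratio"].iloc[0] == pytest.approx(1.0)

    def test_global_rescaling_leaves_ratios_unchanged(self, rng):
        from pollenscreen.expr_model import ExpressionDataset

        ds = random_full_dataset(rng, n_genes=30)
        doubled = ExpressionDataset(
            intensity=ds.intensity * 2, calls=ds.calls, design=ds.design
        )
        for stage in POLLEN_STAGES:
            np.testing.assert_allclose(
                stage_zscore(ds, stage)["ratio"],
                stage_zscore(doubled, stage)["ratio"],
                rtol=1e-12,
            )

    def test_pollen_ratio_against_sporophytic_max(self):
        values = {t: [10.0] for t in POLLEN_STAGES}
        values.update({"callus": [2.0], "root": [4.0], "leaf": [5.0]})
        ds = dataset_from_tissue_values(values)
        table = pollen_zscore(ds, "MPG")
        assert table["ratio"].iloc[0] == pytest.approx(10.0 / 5.0)

    def test_pollen_equal_to_max_sporophytic_gives_one(self):
        values = {t: [5.0] for t in ALL_TISSUES}
        ds = dataset_from_tissue_values(values)
        assert pollen_zscore(ds, "MPG")["ratio"].iloc[0] == pytest.approx(1.0)

    def test_pollen_zscore_matches_loop_oracle(self, rng):
        ds = random_full_dataset(rng, n_genes=40)
        table = pollen_zscore(ds, "MPG")
        for gene in ds.gene_ids:
            x = statistics.median(ds.intensity.loc[gene, ds.design.samples_of("MPG")])
            ref = [
                statistics.median(ds.intensity.loc[gene, ds.design.samples_of(t)])
                for t in ("callus", "root", "leaf")
            ]
            expected = (x - statistics.mean(ref)) / statistics.stdev(ref)
            assert table.loc[gene, "z"] == pytest.approx(expected, abs=1e-12)


class TestScreens:
    def test_planted_gene_selected_at_its_stage_only(self):
        values = {t: [10.0] for t in ALL_TISSUES}
        values["UNM"] = [80.0]
        ds = dataset_from_tissue_values(values)
        enriched = screen_stage_enriched(ds)
        assert enriched["UNM"] == {"g0"}
        for stage in ("BCP", "TCP", "MPG", "GPG"):
            assert enriched[stage] == set()

    def test_flat_gene_selected_nowhere(self):
        ds = dataset_from_tissue_values({t: [50.0] for t in ALL_TISSUES})
        enriched = screen_stage_enriched(ds)
        assert all(not genes for genes in enriched.values())

    def test_enriched_sets_pairwise_disjoint_on_random_data(self, rng):
        lenient = ScreenConfig(enriched_ratio=2.0, enriched_z=0.5)
        for _ in range(5):
            ds = random_full_dataset(rng, n_genes=100)
            enriched = screen_stage_enriched(ds, lenient)
            stages = list(enriched)
            for i, s in enumerate(stages):
                for t in stages[i + 1:]:
                    assert not (enriched[s] & enriched[t])

    def test_downregulated_planted_gene_recovered(self):
        values = {t: [80.0] for t in ALL_TISSUES}
        values["UNM"] = [10.0]
        ds = dataset_from_tissue_values(values)
        # constant replicates make the reference SD zero-floored; add jitter
        rng = np.random.default_rng(0)
        ds.intensity *= 1 + 0.01 * rng.standard_normal(ds.intensity.shape)
        down = screen_stage_downregulated(ds)
        assert "g0" in down["UNM"]

    def test_strict_downregulation_is_subset_of_lenient(self, default_sim):
        ds, _, _ = default_sim
        lenient = screen_stage_downregulated(ds)
        strict = screen_stage_downregulated(ds, ScreenConfig(down_z=-3.75))
        for stage in lenient:
            assert strict[stage] <= lenient[stage]

    def test_lowering_threshold_never_shrinks_selection(self, default_sim):
        ds, _, _ = default_sim
        base = screen_stage_enriched(ds)
        looser = screen_stage_enriched(ds, ScreenConfig(enriched_ratio=1.5, enriched_z=3.0))
        for stage in base:
            assert base[stage] <= looser[stage]

    def test_preferential_flags_and_union(self):
        values = {t: [10.0] for t in ALL_TISSUES}
        values["MPG"] = [100.0]
        ds = dataset_from_tissue_values(values)
        rng = np.random.default_rng(0)
        ds.intensity *= 1 + 0.01 * rng.standard_normal(ds.intensity.shape)
        selected, flags = screen_pollen_preferential(ds)
        assert selected == {"g0"}
        assert bool(flags.loc["g0", "MPG"])

    def test_gene_high_in_root_not_preferential(self):
        values = {t: [10.0] for t in ALL_TISSUES}
        values["root"] = [100.0]
        ds = dataset_from_tissue_values(values)
        selected, _ = screen_pollen_preferential(ds)
        assert selected == set()

    def test_stage_enriched_contained_in_preferential(self, default_sim):
        ds, _, _ = default_sim
        result = run_screens(ds)
        enriched_union = set().union(*result.enriched.values())
        assert enriched_union <= result.preferential

    def test_constitutive_equals_intersection_of_expressed_sets(self, default_sim):
        ds, _, _ = default_sim
        table, _ = tissue_expressed(ds, min_present_reps=2)
        brute = set(table.index)
        for tissue in ds.design.tissues:
            brute &= set(table.index[table[tissue]])
        assert screen_constitutive(ds) == brute

    def test_absent_class_not_constitutive(self, default_sim):
        ds, _, truth = default_sim
        assert not (set(truth.of_class("absent")) & screen_constitutive(ds))


class TestProfileCorrelation:
    def test_identical_profiles_correlate_perfectly(self):
        base = [1.0, 5.0, 9.0]
        ds = dataset_from_tissue_values({t: base for t in ALL_TISSUES})
        corr = profile_correlation(ds)
        assert corr.loc["MPG", "GPG"] == pytest.approx(1.0)

    def test_matrix_symmetric_unit_diagonal(self, rng):
        corr = profile_correlation(random_full_dataset(rng, 30))
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
        assert ((corr.values >= -1 - 1e-12) & (corr.values <= 1 + 1e-12)).all()

    def test_mature_and_germinated_strongly_correlated_in_simulation(self):
        from pollenscreen.synthetic_data import SimulationConfig, simulate_dataset

        # template c1 is identical at MPG and GPG; with only that pattern and
        # no MPG/GPG stage effects, the two profiles differ by noise alone
        cfg = SimulationConfig(
            seed=21, n_genes=2000, cv=0.05, stage_enriched_prop=0.0,
            stage_down_prop=0.0, pattern_mix=(0.0, 1.0, 0.0, 0.0, 0.0),
        )
        ds, _, _ = simulate_dataset(cfg)
        corr = profile_correlation(ds)
        assert corr.loc["MPG", "GPG"] > 0.95

    def test_zero_variance_profile_reported_missing(self):
        values = {t: [3.0, 3.0, 3.0] for t in ALL_TISSUES}
        values["UNM"] = [1.0, 5.0, 9.0]
        values["BCP"] = [2.0, 4.0, 8.0]
        ds = dataset_from_tissue_values(values)
        corr = profile_correlation(ds)
        assert np.isnan(corr.loc["callus", "UNM"])
        assert corr.loc["UNM", "BCP"] == pytest.approx(
            np.corrcoef([1, 5, 9], [2, 4, 8])[0, 1]
        )
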