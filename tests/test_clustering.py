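import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from pollenscreen.clustering import (
    StandardizedProfiles,
    chi_square_cluster_category,
    cluster_patterns,
    cluster_subset_share,
    select_cluster_number,
    standardize_profiles,
    summarize_cluster_table,
)
from pollenscreen.expr_model import ALL_TISSUES, POLLEN_STAGES
from pollenscreen.synthetic_data import PATTERN_NAMES, PATTERN_TEMPLATES

from .conftest import dataset_from_tissue_values


def template_profiles(
    n_per_template: int, cv: float, seed: int
) -> tuple[StandardizedProfiles, pd.Series]:
    """Row-standardized profiles drawn from the five temporal templates."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    sigma = np.sqrt(np.log(1 + cv * cv))
    for name in PATTERN_NAMES:
        mean = 1.0 + 7.0 * PATTERN_TEMPLATES[name]
        noisy = mean * rng.lognormal(-sigma**2 / 2, sigma, size=(n_per_template, 5))
        rows.append(noisy)
        labels += [name] * n_per_template
    values = np.vstack(rows)
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, keepdims=True
    )
    index = pd.Index([f"g{i}" for i in range(len(values))])
    profiles = StandardizedProfiles(
        profiles=pd.DataFrame(values, index=index, columns=list(POLLEN_STAGES)),
        dropped=[],
    )
    return profiles, pd.Series(labels, index=index)


class TestStandardize:
    def test_rows_have_zero_mean_unit_variance(self):
        values = {t: [1.0, 10.0] for t in ALL_TISSUES}
        for i, t in enumerate(POLLEN_STAGES):
            values[t] = [float(i + 1), float(10 * (i + 1))]
        ds = dataset_from_tissue_values(values)
        result = standardize_profiles(ds)
        arr = result.profiles.to_numpy()
        np.testing.assert_allclose(arr.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(arr.var(axis=1), 1.0, atol=1e-9)

    def test_constant_profile_dropped_and_listed(self):
        values = {t: [5.0, 1.0] for t in ALL_TISSUES}
        values["MPG"] = [5.0, 9.0]  # g0 constant across stages, g1 not
        ds = dataset_from_tissue_values(values)
        result = standardize_profiles(ds)
        assert result.dropped == ["g0"]
        assert list(result.profiles.index) == ["g1"]

    def test_invariant_to_per_gene_affine_transform(self):
        base = np.array([1.0, 2.0, 4.0, 8.0, 3.0])
        values = {t: [float(v)] for t, v in zip(POLLEN_STAGES, base)}
        values.update({t: [1.0] for t in ("callus", "root", "leaf")})
        ds1 = dataset_from_tissue_values(values)
        shifted = {t: [3.0 * v[0] + 10.0] for t, v in values.items()}
        ds2 = dataset_from_tissue_values(shifted)
        np.testing.assert_allclose(
            standardize_profiles(ds1).profiles.to_numpy(),
            standardize_profiles(ds2).profiles.to_numpy(),
            atol=1e-12,
        )


class TestClusterPatterns:
    def test_recovers_planted_templates(self):
        profiles, planted = template_profiles(100, cv=0.05, seed=3)
        model = cluster_patterns(profiles, k=5, seed=0)
        ct = pd.crosstab(model.assignments, planted)
        r, c = linear_sum_assignment(-ct.values)
        agreement = ct.values[r, c].sum() / ct.values.sum()
        assert agreement >= 0.98

    def test_k_below_two_rejected(self):
        profiles, _ = template_profiles(5, cv=0.05, seed=1)
        with pytest.raises(ValueError):
            cluster_patterns(profiles, k=1)

    def test_same_seed_identical_assignments(self):
        profiles, _ = template_profiles(30, cv=0.1, seed=2)
        a = cluster_patterns(profiles, k=5, seed=7).assignments
        b = cluster_patterns(profiles, k=5, seed=7).assignments
        pd.testing.assert_series_equal(a, b)

    def test_canonical_labels_stable_across_seeds(self):
        profiles, _ = template_profiles(60, cv=0.05, seed=4)
        reference = cluster_patterns(profiles, k=5, seed=0).assignments
        for seed in range(1, 11):
            other = cluster_patterns(profiles, k=5, seed=seed).assignments
            assert adjusted_rand_score(reference, other) == pytest.approx(1.0)
            # canonicalization makes the label strings themselves agree
            assert (reference == other).all()

    def test_more_clusters_than_distinct_profiles_rejected(self):
        values = np.tile(np.array([[-1.0, -0.5, 0.0, 0.5, 1.0]]), (4, 1))
        values = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
        profiles = StandardizedProfiles(
            profiles=pd.DataFrame(values, columns=list(POLLEN_STAGES)), dropped=[]
        )
        with pytest.raises(ValueError, match="distinct"):
            cluster_patterns(profiles, k=2)


class TestChiSquare:
    def test_perfect_two_by_two_association(self):
        assignments = pd.Series(["c0"] * 10 + ["c1"] * 10)
        categories = pd.Series(["A"] * 10 + ["B"] * 10)
        chi2, df, p, table = chi_square_cluster_category(assignments, categories)
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_five_by_six_degrees_of_freedom(self, rng):
        assignments = pd.Series([f"c{i % 5}" for i in range(600)])
        categories = pd.Series([f"cat{rng.integers(0, 6)}" for _ in range(600)])
        _, df, _, table = chi_square_cluster_category(assignments, categories)
        assert table.shape == (5, 6)
        assert df == 20

    def test_matches_cellwise_oracle(self, rng):
        assignments = pd.Series([f"c{rng.integers(0, 4)}" for _ in range(400)])
        categories = pd.Series([f"cat{rng.integers(0, 5)}" for _ in range(400)])
        chi2, df, _, table = chi_square_cluster_category(assignments, categories)
        observed = table.to_numpy(dtype=float)
        expected = (
            observed.sum(axis=1, keepdims=True)
            * observed.sum(axis=0, keepdims=True)
            / observed.sum()
        )
        oracle = ((observed - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(oracle, abs=1e-10)
        assert df == (observed.shape[0] - 1) * (observed.shape[1] - 1)

    def test_degenerate_table_rejected(self):
        assignments = pd.Series(["c0"] * 10)
        categories = pd.Series(["A"] * 5 + ["B"] * 5)
        with pytest.raises(ValueError):
            chi_square_cluster_category(assignments, categories)


@pytest.fixture(scope="module")
def linked():
    profiles, planted = template_profiles(80, cv=0.05, seed=5)
    rng = np.random.default_rng(6)
    cats = []
    for pat in planted:
        if rng.random() < 0.8:
            cats.append(f"grp{PATTERN_NAMES.index(pat)}")
        else:
            cats.append(f"grp{rng.integers(0, 6)}")
    return profiles, pd.Series(cats, index=planted.index)


class TestSelection:

    def test_planted_five_templates_select_k5(self, linked):
        profiles, categories = linked
        best_k, trace = select_cluster_number(profiles, categories, (3, 7), seed=0)
        assert best_k == 5
        assert list(trace.records["k"]) == [3, 4, 5, 6, 7]

    def test_shuffled_categories_show_no_association(self, linked):
        profiles, categories = linked
        shuffled = pd.Series(
            np.random.default_rng(0).permutation(categories.to_numpy()),
            index=categories.index,
        )
        best_k, trace = select_cluster_number(profiles, shuffled, (3, 7), seed=0)
        assert trace.records["p"].min() > 0.01

    def test_single_k_range(self, linked):
        profiles, categories = linked
        best_k, trace = select_cluster_number(profiles, categories, (3, 3), seed=0)
        assert best_k == 3
        assert len(trace.records) == 1


class TestClusterTable:
    def test_row_totals_and_grand_total(self, rng):
        genes = pd.Index([f"g{i}" for i in range(300)])
        assignments = pd.Series(
            [f"c{rng.integers(0, 5)}" for _ in genes], index=genes
        )
        categories = pd.Series(
            [f"grp{rng.integers(0, 6)}" for _ in genes], index=genes
        )
        table = summarize_cluster_table(assignments, categories)
        assert (table["Total"] == categories.value_counts().sort_index()).all()
        assert table["Total"].sum() == len(genes)

    @pytest.mark.parametrize(
        "counts,share",
        [((13, 31, 16, 13, 7), 75.0), ((6, 13, 3, 3, 2), pytest.approx(100 * 22 / 27))],
    )
    def test_late_cluster_share(self, counts, share):
        assert cluster_subset_share(list(counts), [0, 1, 2]) == pytest.approx(share)

    def test_empty_category_share_is_nan(self):
        assert np.isnan(cluster_subset_share([0, 0, 0, 0, 0], [0, 1, 2]))
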