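"""Pair assembly, negative sampling, scaling and scenario splits."""

import numpy as np
import pytest

from dtiforge.containers import InteractionCatalog
from dtiforge.exceptions import CatalogError, SplitError
from dtiforge.pairs import (
    SplitSpec,
    assemble_pairs,
    build_pair_dataset,
    make_split,
    sample_negatives,
    scale_features,
)
from dtiforge.synthetic import generate_world, plant_interactions

from conftest import make_matrix


class TestAssembly:
    def test_concatenated_dimension(self, toy_catalog):
        samples = assemble_pairs(toy_catalog, [("d1", "t1")], +1)
        assert samples[0].vector.shape == (12,)

    def test_same_pair_identical(self, toy_catalog):
        a, b = assemble_pairs(toy_catalog, [("d2", "t3"), ("d2", "t3")], -1)
        np.testing.assert_array_equal(a.vector, b.vector)

    def test_unknown_id_named(self, toy_catalog):
        with pytest.raises(CatalogError, match="d9"):
            assemble_pairs(toy_catalog, [("d9", "t1")], +1)

    def test_benchmark_scale_dimension(self):
        drugs = make_matrix(["d"], 1080, seed=0)
        targets = make_matrix(["t"], 1080, seed=1)
        cat = InteractionCatalog(drugs=drugs, targets=targets, positives=set())
        assert assemble_pairs(cat, [("d", "t")], +1)[0].vector.shape == (2160,)


class TestNegativeSampling:
    def test_exhausts_noninteraction_space(self, toy_catalog):
        neg = sample_negatives(toy_catalog, n=5, seed=0)
        got = {(s.drug_id, s.target_id) for s in neg}
        all_pairs = {(d, t) for d in ["d1", "d2", "d3"] for t in ["t1", "t2", "t3"]}
        assert got == all_pairs - toy_catalog.positives
        assert all(s.label == -1 for s in neg)

    def test_zero_requested(self, toy_catalog):
        assert sample_negatives(toy_catalog, n=0) == []

    def test_seed_contract(self, toy_catalog):
        a = sample_negatives(toy_catalog, n=3, seed=5)
        b = sample_negatives(toy_catalog, n=3, seed=5)
        c = sample_negatives(toy_catalog, n=3, seed=6)
        assert [(s.drug_id, s.target_id) for s in a] == [(s.drug_id, s.target_id) for s in b]
        assert [(s.drug_id, s.target_id) for s in a] != [(s.drug_id, s.target_id) for s in c]

    def test_oversized_request_reports_counts(self, toy_catalog):
        with pytest.raises(CatalogError, match="6.*5|5.*6"):
            sample_negatives(toy_catalog, n=6)

    def test_rejection_and_enumeration_paths_agree_distributionally(self):
        """Both sampler paths draw uniformly from the same complement set."""
        drugs = make_matrix([f"d{i}" for i in range(4)], 3, seed=0)
        targets = make_matrix([f"t{i}" for i in range(4)], 3, seed=1)
        cat = InteractionCatalog(drugs=drugs, targets=targets,
                                 positives={("d0", "t0"), ("d1", "t1")})
        counts_small, counts_large = {}, {}
        for seed in range(300):
            for s in sample_negatives(cat, n=3, seed=seed):  # rejection path
                counts_small[(s.drug_id, s.target_id)] = counts_small.get(
                    (s.drug_id, s.target_id), 0) + 1
            for s in sample_negatives(cat, n=10, seed=seed):  # enumeration path
                counts_large[(s.drug_id, s.target_id)] = counts_large.get(
                    (s.drug_id, s.target_id), 0) + 1
        assert set(counts_small) == set(counts_large)  # same support: the complement
        # uniformity: every complement pair drawn within 4 sigma of expectation
        exp = 300 * 3 / 14
        sigma = np.sqrt(exp * (1 - 3 / 14))
        assert all(abs(c - exp) < 4 * sigma for c in counts_small.values())

    def test_default_yields_class_balance(self, toy_catalog):
        ds = build_pair_dataset(toy_catalog, seed=0)
        assert (ds.y == 1).sum() == (ds.y == -1).sum() == 4
        negs = {(d, t) for d, t, y in zip(ds.drug_ids, ds.target_ids, ds.y) if y == -1}
        assert not negs & toy_catalog.positives


class TestScaling:
    def test_maps_train_range_to_unit_interval(self, toy_catalog):
        ds = build_pair_dataset(toy_catalog, seed=0)
        scaled, _, scaler = scale_features(ds)
        assert scaled.X.min() == pytest.approx(-1)
        assert scaled.X.max() == pytest.approx(1)
        assert np.all(scaled.X >= -1) and np.all(scaled.X <= 1)

    def test_linear_map_and_constant_convention(self):
        import dataclasses

        from dtiforge.pairs import FeatureScaler

        X = np.array([[0.0, 2.0], [10.0, 2.0]])
        scaler = FeatureScaler.fit(X)
        out = scaler.transform(X)
        np.testing.assert_allclose(out[:, 0], [-1, 1])
        np.testing.assert_allclose(out[:, 1], [0, 0])  # constant -> 0
        probe = scaler.transform(np.array([[20.0, 2.0]]))
        assert probe[0, 0] == pytest.approx(3.0)  # outside range, not clipped

    def test_inverse_recovers_train(self, toy_catalog):
        ds = build_pair_dataset(toy_catalog, seed=0)
        scaled, _, scaler = scale_features(ds)
        np.testing.assert_allclose(scaler.inverse_transform(scaled.X), ds.X, atol=1e-9)

    def test_joint_mode_uses_all_data(self, toy_catalog):
        ds = build_pair_dataset(toy_catalog, seed=0)
        half = len(ds) // 2
        a = ds.subset(np.arange(half))
        b = ds.subset(np.arange(half, len(ds)))
        _, (sb,), _ = scale_features(a, [b], mode="joint")
        assert sb.X.min() >= -1 - 1e-12 and sb.X.max() <= 1 + 1e-12


def sparse_dataset(seed, n_drugs=40, n_targets=30, density=0.02):
    world, catalog = generate_world(n_drugs=n_drugs, n_targets=n_targets, seed=seed)
    positives, _ = plant_interactions(world, density)
    catalog.positives = positives
    return build_pair_dataset(catalog, seed=seed)


class TestSplits:
    def test_scenario_one_sizes(self, rng):
        ds = sparse_dataset(0)
        train, test = make_split(ds, SplitSpec("I", 0.2, 3))
        assert len(test) == round(len(ds) * 0.2)
        assert len(train) + len(test) == len(ds)

    @pytest.mark.parametrize("seed", range(5))
    def test_scenario_two_membership(self, seed):
        """Test drugs are new, test targets known, and the split partitions."""
        ds = sparse_dataset(seed)
        train, test = make_split(ds, SplitSpec("II", 0.5, seed))
        train_d, train_t = train.entity_sets()
        assert not set(test.drug_ids) & train_d
        assert set(test.target_ids) <= train_t
        assert len(train) + len(test) == len(ds)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_scenario_three_membership(self, seed):
        ds = sparse_dataset(seed)
        train, test = make_split(ds, SplitSpec("III", 0.5, seed))
        train_d, train_t = train.entity_sets()
        assert set(test.drug_ids) <= train_d
        assert not set(test.target_ids) & train_t
        assert len(train) + len(test) == len(ds)

    @pytest.mark.parametrize("seed", range(5))
    def test_scenario_four_membership(self, seed):
        """Test entities fully disjoint from train; train keeps its initial size."""
        ds = sparse_dataset(seed)
        train, test = make_split(ds, SplitSpec("IV", 0.5, seed))
        train_d, train_t = train.entity_sets()
        assert not set(test.drug_ids) & train_d
        assert not set(test.target_ids) & train_t
        assert len(train) == len(ds) - round(len(ds) * 0.5)
        assert len(train) + len(test) <= len(ds)

    def test_determinism(self):
        ds = sparse_dataset(1)
        a = make_split(ds, SplitSpec("II", 0.5, 7))
        b = make_split(ds, SplitSpec("II", 0.5, 7))
        assert a[1].pairs == b[1].pairs

    def test_scenario_four_empty_test_advises(self, toy_catalog):
        ds = build_pair_dataset(toy_catalog, seed=0)
        with pytest.raises(SplitError, match="test_fraction"):
            make_split(ds, SplitSpec("IV", 0.2, 0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(Exception):
            SplitSpec("V", 0.2, 0)
        with pytest.raises(Exception):
            SplitSpec("I", 1.2, 0)
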