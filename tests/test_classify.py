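"""CVA fitting, projection, typicality, ellipses and accuracy."""

import numpy as np
import pytest

from otomorph.classify import (
    classification_accuracy,
    classify,
    confidence_ellipse,
    filter_singleton_groups,
    fit_cva,
    project,
    typicality,
)
from otomorph.types import EstimationError, SpecimenRecord, ValidationError


def make_records(sizes):
    labels = ["aquatic", "aerial", "terrestrial", "fossorial", "arboreal"]
    records = []
    i = 0
    for label, n in zip(labels, sizes):
        for _ in range(n):
            records.append(SpecimenRecord(f"s{i}", f"t{i}", ecology=label))
            i += 1
    return records


def gaussian_groups(rng, n_per=20, k=5, sep=10.0, groups=("aquatic", "aerial", "terrestrial")):
    """Groups with unit within-group covariance, separated along axes."""
    X, labels = [], []
    for gi, g in enumerate(groups):
        mean = np.zeros(k)
        mean[gi % k] = sep * gi
        X.append(rng.normal(size=(n_per, k)) + mean)
        labels += [g] * n_per
    return np.vstack(X), labels


class TestFilterSingletons:
    def test_drops_single_member_group(self):
        records = make_records([30, 20, 10, 1, 0])
        kept, dropped = filter_singleton_groups(records)
        assert len(dropped) == 1 and dropped[0].ecology == "fossorial"
        assert len(kept) == 60

    def test_no_singletons_unchanged(self):
        records = make_records([5, 5, 5, 2, 3])
        kept, dropped = filter_singleton_groups(records)
        assert kept == records and dropped == []

    def test_two_singletons_match_frequency_tally(self):
        from collections import Counter

        records = make_records([4, 1, 3, 1, 2])
        kept, dropped = filter_singleton_groups(records)
        counts = Counter(r.ecology for r in records)
        assert {r.ecology for r in dropped} == {g for g, c in counts.items() if c == 1}
        assert len(kept) + len(dropped) == len(records)

    def test_too_few_groups_error(self):
        with pytest.raises(ValidationError):
            filter_singleton_groups(make_records([3, 1, 0, 0, 0]))


class TestFitCVA:
    def test_planted_direction_recovery(self, rng):
        k = 6
        n_per = 500  # large so the sample within-covariance is close to I
        X = rng.normal(size=(2 * n_per, k))
        X[n_per:, 0] += 10.0  # 10 within-group SDs along coordinate 0
        labels = ["aquatic"] * n_per + ["terrestrial"] * n_per
        model = fit_cva(X, labels)
        cv1 = model.canonical_basis[:, 0]
        cos = abs(cv1[0]) / np.linalg.norm(cv1)
        assert cos > 0.99

    def test_two_groups_one_axis(self, rng):
        X, labels = gaussian_groups(rng, groups=("aquatic", "aerial"))
        assert fit_cva(X, labels).n_axes == 1

    def test_within_group_variance_normalized(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        labels_arr = np.asarray(labels, dtype=object)
        for j in range(model.n_axes):
            pooled = 0.0
            for g in model.groups:
                s = model.training_scores[labels_arr == g, j]
                pooled += np.sum((s - s.mean()) ** 2)
            pooled /= len(labels) - len(model.groups)
            assert pooled == pytest.approx(1.0, abs=1e-6)

    def test_singular_within_covariance_advises_smaller_k(self, rng):
        X = rng.normal(size=(8, 10))
        labels = ["aquatic"] * 4 + ["aerial"] * 4
        with pytest.raises(EstimationError):
            fit_cva(X, labels)

    def test_cva_of_canonical_scores_is_identity_up_to_sign(self, rng):
        X, labels = gaussian_groups(rng)
        m1 = fit_cva(X, labels)
        m2 = fit_cva(m1.training_scores, labels)
        S = m2.canonical_basis
        # basis of the second fit must be signed permutation-free identity-like
        assert np.allclose(np.abs(S), np.eye(m1.n_axes), atol=1e-6)


class TestProject:
    def test_group_mean_maps_to_canonical_mean(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        for gi in range(len(model.groups)):
            assert np.allclose(
                project(model, model.group_means_pc[gi]), model.group_means[gi], atol=1e-9
            )

    def test_affine_property(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        a, b = rng.normal(size=(2, X.shape[1]))
        assert np.allclose(
            project(model, a) - project(model, b),
            (a - b) @ model.canonical_basis,
            atol=1e-10,
        )

    def test_training_scores_self_consistency(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        re = np.stack([project(model, x) for x in X])
        assert np.allclose(re, model.training_scores, atol=1e-9)

    def test_dimension_mismatch(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        with pytest.raises(ValidationError):
            project(model, np.zeros(X.shape[1] + 1))


class TestTypicality:
    def test_specimen_at_group_mean(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        res = typicality(model, model.group_means_pc[0], n_perm=200, seed=0)
        g0 = model.groups[0]
        assert res.distances[g0] == pytest.approx(0.0, abs=1e-9)
        assert res.typicality_p[g0] == pytest.approx(1.0)
        assert res.assigned_group == g0

    def test_far_specimen_minimal_typicality(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        res = typicality(model, np.full(X.shape[1], 1e3), n_perm=200, seed=0)
        for g in model.groups:
            assert res.typicality_p[g] == pytest.approx(1.0 / 201.0)

    def test_likelihoods_sum_to_one_and_argmax(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        res = typicality(model, rng.normal(size=X.shape[1]), n_perm=150, seed=1)
        assert sum(res.likelihoods.values()) == pytest.approx(1.0, abs=1e-9)
        assert res.assigned_group == max(res.likelihoods, key=res.likelihoods.get)

    def test_deterministic_under_seed(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        x = rng.normal(size=X.shape[1])
        r1 = typicality(model, x, n_perm=150, seed=7)
        r2 = typicality(model, x, n_perm=150, seed=7)
        assert r1.typicality_p == r2.typicality_p


class TestMahalanobisInvariance:
    def test_invertible_linear_transform(self, rng):
        X, labels = gaussian_groups(rng)
        M = rng.normal(size=(X.shape[1], X.shape[1])) + 3 * np.eye(X.shape[1])
        m1 = fit_cva(X, labels)
        m2 = fit_cva(X @ M, labels)
        x = rng.normal(size=X.shape[1])
        from otomorph.classify import _mahalanobis_sq

        d1 = _mahalanobis_sq(m1, x)
        d2 = _mahalanobis_sq(m2, x @ M)
        assert np.allclose(d1, d2, atol=1e-6)


class TestEllipse:
    def test_isotropic_unit_covariance_radius(self, rng):
        # three groups so that two canonical axes exist
        n_per = 3000
        X = np.vstack([
            rng.normal(size=(n_per, 3)),
            rng.normal(size=(n_per, 3)) + [50, 0, 0],
            rng.normal(size=(n_per, 3)) + [0, 50, 0],
        ])
        labels = ["aquatic"] * n_per + ["aerial"] * n_per + ["terrestrial"] * n_per
        model = fit_cva(X, labels)
        center, semi, angle = confidence_ellipse(model, "aquatic", level=0.95)
        # canonical axes have unit pooled within-group variance
        assert np.all(np.abs(semi - 2.4477) < 0.12)

    def test_zero_level_degenerates_to_point(self, rng):
        X, labels = gaussian_groups(rng)
        model = fit_cva(X, labels)
        _, semi, _ = confidence_ellipse(model, "aquatic", level=0.0)
        assert np.allclose(semi, 0.0)

    def test_small_group_error(self, rng):
        X, labels = gaussian_groups(rng, n_per=10)
        X = np.vstack([X, rng.normal(size=(2, X.shape[1])) + 30])
        labels = labels + ["arboreal"] * 2
        model = fit_cva(X, labels)
        with pytest.raises(ValidationError):
            confidence_ellipse(model, "arboreal")


class TestAccuracy:
    def test_perfect_separation(self, rng):
        X, labels = gaussian_groups(rng, sep=50.0)
        assert classification_accuracy(X, labels) == 1.0

    def test_shuffled_labels_hit_chance_level(self, rng):
        k = 4
        X = rng.normal(size=(400, k))
        labels = list(np.repeat(["aquatic", "aerial", "terrestrial", "arboreal"], 100))
        rng.shuffle(labels)
        # leave-one-out removes the resubstitution optimism bias
        acc = classification_accuracy(X, labels, mode="loo")
        assert abs(acc - 0.25) < 0.07

    def test_loo_not_more_optimistic_than_resubstitution(self):
        accs = []
        for rep in range(20):
            g = np.random.default_rng(rep)
            X, labels = gaussian_groups(g, n_per=12, sep=1.5)  # overlapping groups
            r = classification_accuracy(X, labels, mode="resubstitution")
            l = classification_accuracy(X, labels, mode="loo")
            accs.append(r - l)
        assert np.mean(accs) >= 0.0
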