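"""Forward fit, inversion, schemes, recentering, and transform equivariance."""

import numpy as np
import pytest

from iembench import (
    BasisKindError,
    InvalidParameterError,
    LeakageError,
    RankDeficiencyError,
    ShapeMismatchError,
    TransformMatrix,
    apply_transform,
    average_by_condition,
    fit_forward_model,
    invert_model,
    make_bimodal_transform,
    make_cosine_basis,
    make_delta_basis,
    predict_channel_responses,
    recenter_profiles,
    run_scheme,
)


def ols_weights_oracle(B, C):
    """Explicit normal-equations solve, independent of the fit path."""
    return B @ C.T @ np.linalg.inv(C @ C.T)


def per_trial_inversion_oracle(W, B):
    """Column-by-column normal-equations inversion."""
    WtW_inv = np.linalg.inv(W.T @ W)
    return np.column_stack([WtW_inv @ W.T @ B[:, t] for t in range(B.shape[1])])


class TestPredict:
    def test_unit_peak_at_channel_center(self, cosine8):
        C = predict_channel_responses(cosine8.centers, cosine8)
        assert np.allclose(np.diag(C.values), 1.0)
        assert C.values.min() >= 0 and C.values.max() <= 1.0

    def test_delta_basis_gives_permuted_identity(self, space):
        delta = make_delta_basis(8, space)
        order = np.roll(delta.centers, 3)
        C = predict_channel_responses(order, delta)
        assert np.allclose(C.values, np.eye(8)[:, np.roll(np.arange(8), 3)])

    def test_transformed_prediction_is_matrix_product(self, cosine8, rng):
        T = make_bimodal_transform(8, 0.5)
        transformed = apply_transform(cosine8, T)
        thetas = rng.uniform(0, 180, 17)
        direct = predict_channel_responses(thetas, transformed).values
        product = T.entries @ predict_channel_responses(thetas, cosine8).values
        assert np.max(np.abs(direct - product)) < 1e-10


class TestForwardFit:
    def test_self_fit_recovers_identity(self, cosine8, rng):
        C = predict_channel_responses(rng.uniform(0, 180, 24), cosine8).values
        W = fit_forward_model(C, C)
        assert np.allclose(W.values, np.eye(8), atol=1e-8)
        assert np.allclose(W.fit_r2, 1.0)

    def test_scaled_self_fit(self, cosine8, rng):
        C = predict_channel_responses(rng.uniform(0, 180, 24), cosine8).values
        W = fit_forward_model(2.0 * C, C)
        assert np.allclose(W.values, 2.0 * np.eye(8), atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        B = rng.normal(size=(4, 12))
        C = rng.normal(size=(3, 12))
        W = fit_forward_model(B, C)
        assert np.max(np.abs(W.values - ols_weights_oracle(B, C))) < 1e-8

    def test_rank_deficient_design_rejected(self, rng):
        C = np.ones((3, 12)) * rng.normal(size=12)  # rank-1 design
        with pytest.raises(RankDeficiencyError, match="channels"):
            fit_forward_model(rng.normal(size=(4, 12)), C)

    def test_too_few_trials_rejected(self, cosine8, rng):
        C = predict_channel_responses(cosine8.centers[:4], cosine8).values
        with pytest.raises(ShapeMismatchError):
            fit_forward_model(rng.normal(size=(4, 4)), C)


class TestInversion:
    def test_identity_weights_pass_data_through(self, rng):
        B = rng.normal(size=(5, 9))
        assert np.allclose(invert_model(np.eye(5), B), B)

    def test_exact_recovery_on_column_space(self, rng):
        W = rng.normal(size=(10, 4))
        c = rng.normal(size=(4, 7))
        assert np.max(np.abs(invert_model(W, W @ c) - c)) < 1e-10

    def test_matches_per_trial_oracle(self, rng):
        W = rng.normal(size=(8, 5))
        B = rng.normal(size=(8, 11))
        assert np.max(
            np.abs(invert_model(W, B) - per_trial_inversion_oracle(W, B))
        ) < 1e-8

    def test_rank_and_shape_errors(self, rng):
        with pytest.raises(RankDeficiencyError):
            invert_model(np.ones((6, 3)), rng.normal(size=(6, 4)))
        with pytest.raises(ShapeMismatchError):
            invert_model(rng.normal(size=(6, 3)), rng.normal(size=(5, 4)))


class TestRunScheme:
    def test_fixed_model_reconstructs_every_test_trial_once(
        self, noiseless_dataset, cosine8
    ):
        rec = run_scheme(noiseless_dataset, cosine8, scheme="fixed_model")
        n_test = np.sum(noiseless_dataset.trial_split == "test")
        assert rec.values.shape == (8, n_test)
        assert len(np.unique(rec.trial_indices)) == n_test

    def test_kfold_covers_all_trials_disjointly(self, noisy_dataset, cosine8):
        rec = run_scheme(noisy_dataset, cosine8, scheme="kfold", n_folds=4)
        assert sorted(rec.trial_indices) == list(range(noisy_dataset.n_trials))
        folds = rec.details["folds"]
        # per-cell balance: each cell's trials spread evenly over folds
        for o in np.unique(noisy_dataset.trial_orientation):
            for c in (0, 1):
                cell = folds[
                    (noisy_dataset.trial_orientation == o)
                    & (noisy_dataset.trial_condition == c)
                ]
                counts = np.bincount(cell, minlength=4)
                assert counts.max() - counts.min() <= 1

    def test_leave_one_trial_out(self, noiseless_dataset, cosine8):
        n = noiseless_dataset.n_trials
        rec = run_scheme(noiseless_dataset, cosine8, scheme="kfold", n_folds=n)
        assert rec.values.shape == (8, n)
        assert np.bincount(rec.details["folds"]).max() == 1

    def test_overlapping_partitions_rejected(self, noiseless_dataset, cosine8):
        with pytest.raises(LeakageError):
            run_scheme(
                noiseless_dataset,
                cosine8,
                scheme="fixed_model",
                train_indices=np.arange(10),
                test_indices=np.arange(5, 15),
            )

    def test_unknown_scheme_rejected(self, noiseless_dataset, cosine8):
        with pytest.raises(InvalidParameterError):
            run_scheme(noiseless_dataset, cosine8, scheme="bootstrap")


class TestTransformEquivariance:
    """The central algebraic claim: an invertible change of basis acts on
    reconstructions as the same linear map, leaving fit quality intact."""

    def test_bimodal_reconstruction_is_transform_of_unimodal(
        self, noisy_dataset, cosine8
    ):
        T = make_bimodal_transform(8, 0.5)
        rec_u = run_scheme(noisy_dataset, cosine8, scheme="fixed_model")
        rec_t = run_scheme(
            noisy_dataset, apply_transform(cosine8, T), scheme="fixed_model"
        )
        assert np.max(np.abs(rec_t.values - T.entries @ rec_u.values)) < 1e-8

    def test_training_residuals_invariant_to_basis(self, noisy_dataset, cosine8):
        T = make_bimodal_transform(8, 0.5)
        transformed = apply_transform(cosine8, T)
        train = np.flatnonzero(noisy_dataset.trial_split == "train")
        B = noisy_dataset.activations[:, train]
        rss = []
        for b in (cosine8, transformed):
            C = predict_channel_responses(
                noisy_dataset.trial_orientation[train], b
            ).values
            W = fit_forward_model(B, C)
            rss.append(np.sum((B - W.values @ C) ** 2))
        assert abs(rss[0] - rss[1]) <= 1e-8 * rss[0]


class TestRecentering:
    def test_reference_orientation_leaves_profile_unchanged(self, cosine8, rng):
        values = rng.normal(size=(8, 1))
        ref = cosine8.centers[4]  # default reference slot k//2
        out = recenter_profiles(values, [ref], cosine8)
        assert np.array_equal(out[0], values[:, 0])

    def test_shift_equivariance_by_one_channel_step(self, cosine8, rng):
        values = rng.normal(size=(8, 2))
        base = recenter_profiles(values, [cosine8.centers[2]] * 2, cosine8)
        stepped = recenter_profiles(values, [cosine8.centers[3]] * 2, cosine8)
        assert np.allclose(stepped, np.roll(base, -1, axis=1))

    def test_noiseless_average_peaks_at_reference_slot(
        self, noiseless_dataset, cosine8
    ):
        rec = run_scheme(noiseless_dataset, cosine8, scheme="fixed_model")
        aligned = recenter_profiles(rec.values, rec.trial_orientation, cosine8)
        for profile in average_by_condition(aligned, rec.trial_condition).values():
            assert int(np.argmax(profile)) == 4

    def test_transformed_basis_refused_with_typed_error(self, cosine8, rng):
        transformed = apply_transform(cosine8, make_bimodal_transform(8, 0.5))
        with pytest.raises(BasisKindError, match="lineage"):
            recenter_profiles(rng.normal(size=(8, 1)), [0.0], transformed)

    def test_off_center_orientation_rejected(self, cosine8, rng):
        with pytest.raises(InvalidParameterError):
            recenter_profiles(rng.normal(size=(8, 1)), [13.0], cosine8)
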