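"""Forward-model fitting, inversion and channel-response reconstruction.

The inverted encoding model proceeds in three linear steps.  With ``B`` the
signals x trials activation matrix and ``C`` the k x trials matrix of
predicted channel responses (each channel of the basis evaluated at each
trial's stimulus feature):

1. forward fit:  ``W = argmin || B - W C ||_F^2``  (ordinary least squares
   per signal; ``W`` is signals x channels),
2. inversion:    ``C_hat = (W^T W)^-1 W^T B_test``  (least-squares channel
   estimate per test trial, in arbitrary units),
3. recentering:  each trial's k-vector is circularly shifted so the channel
   tuned to that trial's stimulus sits at a common reference slot, after
   which trials can be averaged within condition.

Because every step is linear, replacing the basis by ``T @ basis`` for any
invertible ``T`` changes the fitted weights to ``W T^-1`` and the
reconstructions to ``T C_hat`` — fit quality is untouched and the original
profiles are recoverable via ``T^-1``.  That equivariance is the property
this package exists to demonstrate, and it is what makes between-condition
comparisons under a *fixed* encoding model robust to the choice of basis.

Plain OLS is used throughout (no regularisation): a ridge penalty would
break exact transform equivariance unless the penalty itself were
transformed alongside the basis.  Rank problems raise typed errors instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet, circular_distance
from .errors import (
    BasisKindError,
    InvalidParameterError,
    LeakageError,
    RankDeficiencyError,
    ShapeMismatchError,
)
from .simulate import SimulatedDataset

__all__ = [
    "ChannelResponseMatrix",
    "EncodingWeights",
    "ChannelResponseProfile",
    "Reconstruction",
    "predict_channel_responses",
    "fit_forward_model",
    "invert_model",
    "run_scheme",
    "recenter_profiles",
    "average_by_condition",
]

#: Relative singular-value cutoff for rank checks in fits and inversions.
RANK_RTOL = 1e-10


@dataclass
class ChannelResponseMatrix:
    """k x trials matrix of modeled or reconstructed channel responses."""

    values: np.ndarray  # k x trials, arbitrary units
    channel_centers: np.ndarray  # degrees
    basis: BasisSet | None = None

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass
class EncodingWeights:
    """Signals x channels weight matrix from the forward fit."""

    values: np.ndarray  # signals x k, arbitrary units
    fit_r2: np.ndarray  # proportion of training variance explained, per signal

    @property
    def n_signals(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ChannelResponseProfile:
    """A single k-vector of channel responses, in arbitrary units."""

    values: np.ndarray
    recentered: bool = False
    center_reference: float | None = None  # feature the profile is aligned to
    condition: int | None = None


@dataclass
class Reconstruction:
    """Per-trial reconstructed channel responses with their trial labels."""

    values: np.ndarray  # k x n_test
    trial_indices: np.ndarray  # positions in the source dataset
    trial_orientation: np.ndarray
    trial_condition: np.ndarray
    basis: BasisSet
    scheme: str
    weights: EncodingWeights | None = None  # single W for fixed_model
    details: dict = field(default_factory=dict)


def predict_channel_responses(orientations, basis: BasisSet) -> ChannelResponseMatrix:
    """Predicted (design) channel responses for a sequence of stimuli.

    Column ``t`` holds every channel evaluated at ``orientations[t]``,
    using the exact closed form for each basis kind.
    """
    return ChannelResponseMatrix(
        values=basis.evaluate(orientations),
        channel_centers=basis.centers,
        basis=basis,
    )


def _as_matrix(C) -> np.ndarray:
    return C.values if isinstance(C, ChannelResponseMatrix) else np.asarray(C, float)


def fit_forward_model(train_activations, C) -> EncodingWeights:
    """Ordinary-least-squares forward fit ``W = argmin ||B - W C||^2``.

    Parameters
    ----------
    train_activations : ndarray, signals x trials
        Measured activations ``B`` for the training trials.
    C : ChannelResponseMatrix or ndarray, k x trials
        Predicted channel responses for the same trials.

    Returns
    -------
    EncodingWeights
        ``W`` (signals x k) and the per-signal proportion of training
        variance explained.

    Raises
    ------
    ShapeMismatchError
        If trial counts disagree or there are fewer trials than channels.
    RankDeficiencyError
        If ``C`` lacks full row rank (channels dimension deficient).
    """
    B = np.asarray(train_activations, dtype=float)
    Cm = _as_matrix(C)
    k, n = Cm.shape
    if B.shape[1] != n:
        raise ShapeMismatchError(
            f"activations have {B.shape[1]} trials but C has {n}"
        )
    if n < k:
        raise ShapeMismatchError(f"need at least k={k} training trials, got {n}")
    sv = np.linalg.svd(Cm, compute_uv=False)
    if sv[-1] <= RANK_RTOL * sv[0]:
        raise RankDeficiencyError(
            f"predicted channel-response matrix is rank deficient along the "
            f"channels dimension (k={k}, smallest singular value {sv[-1]:.3e})"
        )
    # Solve C^T W^T = B^T for each signal's weight row.
    Wt, *_ = np.linalg.lstsq(Cm.T, B.T, rcond=None)
    W = Wt.T
    resid = B - W @ Cm
    ss_res = (resid**2).sum(axis=1)
    centered = B - B.mean(axis=1, keepdims=True)
    ss_tot = (centered**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return EncodingWeights(values=W, fit_r2=r2)


def invert_model(W: EncodingWeights | np.ndarray, test_activations) -> np.ndarray:
    """Invert the fitted forward model on held-out activations.

    Returns the least-squares channel estimate per trial,
    ``C_hat = (W^T W)^-1 W^T B_test`` (k x trials, arbitrary units).

    Raises
    ------
    RankDeficiencyError
        If ``W`` lacks full column rank.
    ShapeMismatchError
        If the signal counts of ``W`` and the activations disagree.
    """
    Wm = W.values if isinstance(W, EncodingWeights) else np.asarray(W, float)
    B = np.asarray(test_activations, dtype=float)
    if B.ndim == 1:
        B = B[:, np.newaxis]
    if B.shape[0] != Wm.shape[0]:
        raise ShapeMismatchError(
            f"W maps {Wm.shape[0]} signals but activations have {B.shape[0]}"
        )
    sv = np.linalg.svd(Wm, compute_uv=False)
    if sv[-1] <= RANK_RTOL * sv[0]:
        raise RankDeficiencyError(
            f"weight matrix is rank deficient along the channels dimension "
            f"(k={Wm.shape[1]}, smallest singular value {sv[-1]:.3e})"
        )
    C_hat, *_ = np.linalg.lstsq(Wm, B, rcond=None)
    return C_hat


def _balanced_folds(orientations, conditions, n_folds: int) -> np.ndarray:
    """Fold index per trial; trials within each cell are dealt round-robin
    (in dataset order) so folds stay balanced across cells."""
    n = len(orientations)
    if not 2 <= n_folds <= n:
        raise InvalidParameterError(
            f"n_folds must be between 2 and the trial count {n}, got {n_folds}"
        )
    folds = np.empty(n, dtype=int)
    counter = 0
    for o in np.unique(np.asarray(orientations)):
        for c in np.unique(np.asarray(conditions)):
            idx = np.flatnonzero(
                (np.asarray(orientations) == o) & (np.asarray(conditions) == c)
            )
            for i in idx:
                folds[i] = counter % n_folds
                counter += 1
    return folds


def run_scheme(
    dataset: SimulatedDataset,
    basis: BasisSet,
    scheme: str = "fixed_model",
    *,
    n_folds: int | None = None,
    train_indices=None,
    test_indices=None,
) -> Reconstruction:
    """Reconstruct channel responses under a training scheme.

    ``fixed_model`` estimates a single weight matrix on a designated
    training partition (by default the dataset's balanced train half,
    which contains equal numbers of trials from every orientation and
    condition) and uses it to reconstruct every test trial — all
    conditions pass through the same model so they can be compared on
    equal footing.  ``kfold`` cross-validates within the dataset: trials
    are dealt into cell-balanced folds and each fold is reconstructed by
    a model fit on the remaining folds; ``n_folds`` equal to the trial
    count gives leave-one-trial-out.

    Every test trial is reconstructed exactly once.

    Raises
    ------
    LeakageError
        If explicit train and test partitions overlap.
    """
    B = dataset.activations

    if scheme == "fixed_model":
        if train_indices is None:
            train_idx = np.flatnonzero(dataset.trial_split == "train")
        else:
            train_idx = np.asarray(train_indices, dtype=int)
        if test_indices is None:
            if train_indices is None:
                test_idx = np.flatnonzero(dataset.trial_split == "test")
            else:
                mask = np.ones(dataset.n_trials, dtype=bool)
                mask[train_idx] = False
                test_idx = np.flatnonzero(mask)
        else:
            test_idx = np.asarray(test_indices, dtype=int)
        overlap = np.intersect1d(train_idx, test_idx)
        if overlap.size:
            raise LeakageError(
                f"training and test partitions share {overlap.size} trial(s), "
                f"e.g. trial {overlap[0]}"
            )
        C_train = predict_channel_responses(
            dataset.trial_orientation[train_idx], basis
        )
        W = fit_forward_model(B[:, train_idx], C_train)
        values = invert_model(W, B[:, test_idx])
        return Reconstruction(
            values=values,
            trial_indices=test_idx,
            trial_orientation=dataset.trial_orientation[test_idx],
            trial_condition=dataset.trial_condition[test_idx],
            basis=basis,
            scheme="fixed_model",
            weights=W,
            details={"n_train": len(train_idx)},
        )

    if scheme == "kfold":
        if n_folds is None:
            raise InvalidParameterError("kfold scheme requires n_folds")
        folds = _balanced_folds(
            dataset.trial_orientation, dataset.trial_condition, n_folds
        )
        values = np.empty((basis.k, dataset.n_trials))
        for f in range(n_folds):
            test_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            C_train = predict_channel_responses(
                dataset.trial_orientation[train_idx], basis
            )
            W = fit_forward_model(B[:, train_idx], C_train)
            values[:, test_idx] = invert_model(W, B[:, test_idx])
        all_idx = np.arange(dataset.n_trials)
        return Reconstruction(
            values=values,
            trial_indices=all_idx,
            trial_orientation=dataset.trial_orientation,
            trial_condition=dataset.trial_condition,
            basis=basis,
            scheme="kfold",
            weights=None,
            details={"n_folds": n_folds, "folds": folds},
        )

    raise InvalidParameterError(
        f"unknown scheme {scheme!r}; expected 'fixed_model' or 'kfold'"
    )


def _channel_index(theta: float, centers: np.ndarray, period: float) -> int:
    d = circular_distance(theta, centers, period)
    i = int(np.argmin(d))
    if d[i] > 1e-6 * period:
        raise InvalidParameterError(
            f"stimulus orientation {theta} does not coincide with any channel "
            f"centre; recentering requires stimuli at the channel centres"
        )
    return i


def recenter_profiles(
    profiles,
    trial_orientations,
    basis: BasisSet,
    *,
    center_index: int | None = None,
) -> np.ndarray:
    """Circularly align each trial's profile on its true stimulus feature.

    The channel tuned to the trial's orientation is shifted to a common
    reference slot (``k // 2`` by default, i.e. the channel centred at
    ``period/2``), after which profiles can be averaged across trials and
    conditions.  Requires a unimodal basis (cosine or delta) whose evenly
    spaced centres coincide with the stimulus orientations.

    Returns a trials x k array.

    Raises
    ------
    BasisKindError
        For a transformed basis: a bimodal or otherwise reshaped channel
        has no single preferred feature to align on.  Map the profiles
        back through the lineage inverse first.
    """
    if basis.kind == "transformed":
        raise BasisKindError(
            "cannot recenter profiles from a transformed basis: a bimodal or "
            "otherwise reshaped channel is not tuned to a single feature "
            "value; multiply by the inverse of the basis lineage to return "
            "to the canonical channels first"
        )
    values = _as_matrix(profiles)
    k = basis.k
    if values.shape[0] != k:
        raise ShapeMismatchError(
            f"profiles have {values.shape[0]} channels but basis has k={k}"
        )
    thetas = np.atleast_1d(np.asarray(trial_orientations, dtype=float))
    if values.shape[1] != len(thetas):
        raise ShapeMismatchError(
            f"{values.shape[1]} profiles but {len(thetas)} trial orientations"
        )
    m = k // 2 if center_index is None else int(center_index)
    out = np.empty((len(thetas), k))
    for t, theta in enumerate(thetas):
        i = _channel_index(theta, basis.centers, basis.space.period)
        # slot j receives the channel i + (j - m), wrapping circularly
        out[t] = values[(i + np.arange(k) - m) % k, t]
    return out


def average_by_condition(
    recentered: np.ndarray, conditions
) -> dict[int, np.ndarray]:
    """Arithmetic mean profile per condition from a trials x k array."""
    conditions = np.asarray(conditions)
    return {
        int(c): recentered[conditions == c].mean(axis=0)
        for c in np.unique(conditions)
    }
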