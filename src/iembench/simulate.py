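"""Neuron-population voxel simulator with condition-wise gain.

Each simulated voxel aggregates a private population of orientation-tuned
neurons.  A neuron with preferred orientation ``c``, tuning bandwidth
``sigma`` and amplitude ``a`` responds to a stimulus at orientation
``theta`` with a circular Gaussian:

    r(theta) = a * exp(-d(theta, c)^2 / (2 * sigma^2))

where ``d`` is circular distance.  On every trial, i.i.d. Gaussian noise
(SD ``noise_sd``) is added to each neuron's response *before* the
condition's multiplicative gain is applied, so the gain scales signal and
noise together; the voxel activation is the sum over its neurons.  Trials
cover every orientation x condition cell equally and are split into
balanced train/test halves.

The full generative ground truth (configuration and sampled populations)
travels with the dataset, so recovered quantities can be compared against
the modeled ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .basis import circular_distance
from .errors import InvalidParameterError

__all__ = [
    "SimConfig",
    "NeuronPopulation",
    "SimulatedDataset",
    "TrialView",
    "sample_populations",
    "neuron_response",
    "simulate_dataset",
    "assign_balanced_split",
    "split_train_test",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated experiment.

    Defaults reproduce the demonstration regime: 100 voxels of 100 neurons
    each, 8 orientations x 2 conditions with gains 1.0 and 1.8, and neural
    noise SD 0 (noiseless) or 10 (noisy Monte-Carlo regime).
    """

    n_voxels: int = 100
    n_neurons_per_voxel: int = 100
    orientations: tuple = ()  # empty -> 8 evenly spaced in [0, period)
    n_trials_per_cell: int = 8
    gains: tuple = (1.0, 1.8)
    noise_sd: float = 0.0
    tuning_sd_range: tuple = (10.0, 40.0)
    amplitude_range: tuple = (0.5, 1.5)
    seed: int = 0
    period: float = 180.0

    def __post_init__(self):
        object.__setattr__(self, "gains", tuple(float(g) for g in self.gains))
        object.__setattr__(
            self, "tuning_sd_range", tuple(float(x) for x in self.tuning_sd_range)
        )
        object.__setattr__(
            self, "amplitude_range", tuple(float(x) for x in self.amplitude_range)
        )
        if self.orientations:
            object.__setattr__(
                self, "orientations", tuple(float(o) for o in self.orientations)
            )
        else:
            object.__setattr__(
                self,
                "orientations",
                tuple(self.period * i / 8 for i in range(8)),
            )
        self.validate()

    def validate(self) -> None:
        if self.n_voxels < 1 or self.n_neurons_per_voxel < 1:
            raise InvalidParameterError("voxel and neuron counts must be >= 1")
        if self.n_trials_per_cell < 1:
            raise InvalidParameterError("n_trials_per_cell must be >= 1")
        if any(g <= 0 for g in self.gains):
            raise InvalidParameterError(f"gains must be positive, got {self.gains}")
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name, rng_ in (
            ("tuning_sd_range", self.tuning_sd_range),
            ("amplitude_range", self.amplitude_range),
        ):
            if len(rng_) != 2 or rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise InvalidParameterError(
                    f"{name} must be positive and ordered, got {rng_}"
                )
        if self.period <= 0:
            raise InvalidParameterError(f"period must be positive, got {self.period}")
        if any(not (0 <= o < self.period) for o in self.orientations):
            raise InvalidParameterError(
                f"orientations must lie in [0, {self.period}), got {self.orientations}"
            )

    @property
    def n_conditions(self) -> int:
        return len(self.gains)

    @property
    def n_trials(self) -> int:
        return len(self.orientations) * self.n_conditions * self.n_trials_per_cell

    def to_dict(self) -> dict:
        return {
            "n_voxels": self.n_voxels,
            "n_neurons_per_voxel": self.n_neurons_per_voxel,
            "orientations": list(self.orientations),
            "n_trials_per_cell": self.n_trials_per_cell,
            "gains": list(self.gains),
            "noise_sd": self.noise_sd,
            "tuning_sd_range": list(self.tuning_sd_range),
            "amplitude_range": list(self.amplitude_range),
            "seed": self.seed,
            "period": self.period,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class NeuronPopulation:
    """Tuning parameters of the neurons inside one voxel."""

    centers: np.ndarray  # preferred orientations, degrees, in [0, period)
    bandwidths: np.ndarray  # tuning SD sigma, degrees, > 0
    amplitudes: np.ndarray  # peak response, response units, > 0

    @property
    def n(self) -> int:
        return len(self.centers)


@dataclass
class TrialView:
    """A read-only slice of a dataset's trials (e.g. the train half)."""

    activations: np.ndarray  # signals x trials
    orientations: np.ndarray  # degrees per trial
    conditions: np.ndarray  # condition index per trial
    indices: np.ndarray  # positions in the parent dataset

    @property
    def n_trials(self) -> int:
        return self.activations.shape[1]


@dataclass
class SimulatedDataset:
    """Simulated activations plus labels and full generative ground truth."""

    activations: np.ndarray  # voxels x trials, response units
    trial_orientation: np.ndarray  # degrees per trial
    trial_condition: np.ndarray  # 0-based condition index per trial
    trial_split: np.ndarray  # "train" / "test" per trial
    config: SimConfig
    populations: list = field(default_factory=list)

    @property
    def n_signals(self) -> int:
        return self.activations.shape[0]

    @property
    def n_trials(self) -> int:
        return self.activations.shape[1]


def neuron_response(theta, center, sigma, amplitude, period: float = 180.0):
    """Circular-Gaussian tuned response of a single neuron (noiseless).

    Raises
    ------
    InvalidParameterError
        If ``sigma <= 0``.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise InvalidParameterError(f"tuning sigma must be positive, got {sigma}")
    d = circular_distance(theta, center, period)
    return np.asarray(amplitude) * np.exp(-(d**2) / (2.0 * np.asarray(sigma) ** 2))


def sample_populations(
    config: SimConfig, rng: np.random.Generator
) -> list[NeuronPopulation]:
    """Draw one independent neuron population per voxel.

    Centres are uniform on ``[0, period)``; bandwidths and amplitudes are
    uniform on their configured ranges.  Fully reproducible from the
    generator's state.
    """
    nv, nn = config.n_voxels, config.n_neurons_per_voxel
    centers = rng.uniform(0.0, config.period, size=(nv, nn))
    bandwidths = rng.uniform(*config.tuning_sd_range, size=(nv, nn))
    amplitudes = rng.uniform(*config.amplitude_range, size=(nv, nn))
    return [
        NeuronPopulation(centers[v], bandwidths[v], amplitudes[v]) for v in range(nv)
    ]


def assign_balanced_split(
    orientations: Sequence[float], conditions: Sequence[int]
) -> np.ndarray:
    """Assign trials to balanced train/test halves, cell by cell.

    Within every (orientation, condition) cell the first half of the
    trials (in dataset order) goes to "train" and the second half to
    "test", so both halves contain exactly half of each cell.

    Raises
    ------
    InvalidParameterError
        If any cell has an odd number of trials.
    """
    orientations = np.asarray(orientations, dtype=float)
    conditions = np.asarray(conditions)
    split = np.empty(len(orientations), dtype=object)
    for o in np.unique(orientations):
        for c in np.unique(conditions):
            idx = np.flatnonzero((orientations == o) & (conditions == c))
            if len(idx) % 2 != 0:
                raise InvalidParameterError(
                    f"cell (orientation={o}, condition={c}) has an odd trial "
                    f"count {len(idx)}; a balanced half-split is impossible"
                )
            half = len(idx) // 2
            split[idx[:half]] = "train"
            split[idx[half:]] = "test"
    return split.astype(str)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic experiment from the configuration.

    Per trial with orientation ``theta`` and condition ``c``, every
    neuron's response is ``neuron_response(theta, ...) + N(0, noise_sd)``,
    then the whole population response is multiplied by ``gains[c]``; the
    voxel activation is the sum over its neurons.  The entire dataset is a
    pure function of the configuration (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    pops = sample_populations(config, rng)
    nv, nn = config.n_voxels, config.n_neurons_per_voxel
    oris = np.asarray(config.orientations)

    # Noiseless per-neuron responses to each orientation: (voxels, neurons, oris)
    centers = np.stack([p.centers for p in pops])
    bandwidths = np.stack([p.bandwidths for p in pops])
    amplitudes = np.stack([p.amplitudes for p in pops])
    d = circular_distance(centers[..., None], oris[None, None, :], config.period)
    tuned = amplitudes[..., None] * np.exp(-(d**2) / (2.0 * bandwidths[..., None] ** 2))

    n_trials = config.n_trials
    noise = rng.normal(0.0, config.noise_sd, size=(nv, nn, n_trials))

    activations = np.empty((nv, n_trials))
    trial_orientation = np.empty(n_trials)
    trial_condition = np.empty(n_trials, dtype=int)
    t = 0
    for oi in range(len(oris)):
        for c in range(config.n_conditions):
            for _ in range(config.n_trials_per_cell):
                resp = tuned[:, :, oi] + noise[:, :, t]
                activations[:, t] = config.gains[c] * resp.sum(axis=1)
                trial_orientation[t] = oris[oi]
                trial_condition[t] = c
                t += 1

    split = assign_balanced_split(trial_orientation, trial_condition)
    return SimulatedDataset(
        activations=activations,
        trial_orientation=trial_orientation,
        trial_condition=trial_condition,
        trial_split=split,
        config=config,
        populations=pops,
    )


def split_train_test(dataset: SimulatedDataset) -> tuple[TrialView, TrialView]:
    """Return the balanced train and test halves as disjoint views."""
    views = []
    for label in ("train", "test"):
        idx = np.flatnonzero(dataset.trial_split == label)
        views.append(
            TrialView(
                activations=dataset.activations[:, idx],
                orientations=dataset.trial_orientation[idx],
                conditions=dataset.trial_condition[idx],
                indices=idx,
            )
        )
    return views[0], views[1]
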