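"""Circular feature spaces and channel basis sets.

An inverted encoding model describes measured activity as a weighted sum of
hypothetical information *channels*, each tuned to a region of a circular
stimulus-feature space (here, orientation with a 180 degree period).  This
module constructs the canonical raised-cosine basis, the orthogonal delta
("stick") basis, and invertible linear transforms of either — including the
bimodal "xform" used to demonstrate that between-condition differences
survive a change of basis.

A canonical raised-cosine channel centred at ``c`` has sensitivity

    f(theta) = (1/2 + 1/2 * cos(2*pi*d(theta, c) / period)) ** p

where ``d`` is circular distance and ``p`` the cosine exponent.  Channels
are unit-normalised (value 1 at their own centre) and nonnegative.  Because
the raised cosine to the power ``p`` contains Fourier harmonics only up to
order ``p``, the sum over ``k`` evenly spaced channels is exactly constant
whenever ``p <= k - 1`` — the channels tile the feature space with flat
coverage.  The default exponent is ``k - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, RankDeficiencyError, ShapeMismatchError

__all__ = [
    "FeatureSpace",
    "BasisSet",
    "TransformMatrix",
    "circular_distance",
    "make_cosine_basis",
    "make_delta_basis",
    "make_bimodal_transform",
    "apply_transform",
]

#: Relative singular-value cutoff below which a transform counts as singular.
INVERTIBILITY_RTOL = 1e-8


def circular_distance(a, b, period: float = 180.0):
    """Shortest distance between feature values on a circle.

    Parameters
    ----------
    a, b : array_like
        Feature values in degrees; broadcast against each other.
    period : float
        Circumference of the feature space (180 for orientation).

    Returns
    -------
    ndarray or float
        ``min(|a - b| mod period, period - |a - b| mod period)``,
        always in ``[0, period / 2]``.
    """
    if period <= 0:
        raise InvalidParameterError(f"period must be positive, got {period}")
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.minimum(d, period - d)


@dataclass(frozen=True)
class FeatureSpace:
    """A circular 1-D stimulus feature axis with an evaluation grid.

    Parameters
    ----------
    period : float
        Circumference in degrees; 180 for orientation.
    grid_size : int
        Number of evenly spaced evaluation points in ``[0, period)``.
    """

    period: float = 180.0
    grid_size: int = 180

    def __post_init__(self):
        if self.period <= 0:
            raise InvalidParameterError(f"period must be positive, got {self.period}")
        if self.grid_size < 2:
            raise InvalidParameterError(
                f"grid_size must be at least 2, got {self.grid_size}"
            )

    @property
    def grid(self) -> np.ndarray:
        """Evenly spaced evaluation points in ``[0, period)``."""
        return np.arange(self.grid_size) * (self.period / self.grid_size)

    def distance(self, a, b):
        """Circular distance between ``a`` and ``b`` in this space."""
        return circular_distance(a, b, self.period)


def _raised_cosine(d, exponent: float):
    """Raised cosine of circular distance, unit peak, zero at period/2."""
    # d is already a circular distance for some period; caller scales it.
    return (0.5 + 0.5 * np.cos(d)) ** exponent


@dataclass
class BasisSet:
    """A set of ``k`` channel sensitivity functions over a feature space.

    Attributes
    ----------
    space : FeatureSpace
        The feature axis the channels live on.
    centers : ndarray, shape (k,)
        Preferred feature of each channel, degrees.
    values : ndarray, shape (k, grid_size)
        Channel sensitivities evaluated on ``space.grid`` (arbitrary units).
    kind : str
        ``"cosine"``, ``"delta"`` or ``"transformed"``.
    exponent : float or None
        Cosine power for (the canonical ancestor of) cosine bases.
    lineage : ndarray, shape (k, k)
        Cumulative linear transform relating these channels to the canonical
        basis they were built from (identity for canonical bases).
    origin_kind : str
        Kind of the canonical ancestor (``"cosine"`` or ``"delta"``); used
        for closed-form evaluation of transformed bases.
    """

    space: FeatureSpace
    centers: np.ndarray
    values: np.ndarray
    kind: str
    exponent: float | None = None
    lineage: np.ndarray = field(default=None)  # type: ignore[assignment]
    origin_kind: str = "cosine"

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lineage is None:
            self.lineage = np.eye(self.k)
        else:
            self.lineage = np.asarray(self.lineage, dtype=float)

    @property
    def k(self) -> int:
        """Number of channels."""
        return len(self.centers)

    def evaluate(self, thetas) -> np.ndarray:
        """Evaluate every channel at the given feature values (closed form).

        Returns a ``(k, len(thetas))`` matrix.  Transformed bases are
        evaluated as ``lineage @ canonical`` so the result is exact rather
        than grid-interpolated.
        """
        thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
        canonical = _evaluate_canonical(
            thetas, self.centers, self.space, self.origin_kind, self.exponent
        )
        if self.kind == "transformed":
            return self.lineage @ canonical
        return canonical

    def copy(self) -> "BasisSet":
        return BasisSet(
            space=self.space,
            centers=self.centers.copy(),
            values=self.values.copy(),
            kind=self.kind,
            exponent=self.exponent,
            lineage=self.lineage.copy(),
            origin_kind=self.origin_kind,
        )


def _evaluate_canonical(thetas, centers, space, origin_kind, exponent):
    d = space.distance(thetas[np.newaxis, :], np.asarray(centers)[:, np.newaxis])
    if origin_kind == "cosine":
        return _raised_cosine(2.0 * np.pi * d / space.period, exponent)
    if origin_kind == "delta":
        # Exact indicator: 1 where the stimulus coincides with the centre.
        tol = 1e-9 * space.period
        return (d < tol).astype(float)
    raise InvalidParameterError(f"unknown origin kind {origin_kind!r}")


def make_cosine_basis(
    k: int, exponent: float | None = None, space: FeatureSpace | None = None
) -> BasisSet:
    """Build ``k`` unit-normalised raised-cosine channels tiling the space.

    Centres sit at ``period * i / k`` for ``i = 0 .. k-1``.  The default
    exponent is ``k - 1``, the largest power for which the channel sum is
    exactly constant over the grid (flat coverage).

    Raises
    ------
    InvalidParameterError
        If ``k < 2`` or ``exponent < 1``.
    """
    if k < 2:
        raise InvalidParameterError(f"need at least 2 channels, got k={k}")
    if exponent is None:
        exponent = k - 1
    if exponent < 1:
        raise InvalidParameterError(f"cosine exponent must be >= 1, got {exponent}")
    space = space or FeatureSpace()
    centers = space.period * np.arange(k) / k
    d = space.distance(space.grid[np.newaxis, :], centers[:, np.newaxis])
    values = _raised_cosine(2.0 * np.pi * d / space.period, exponent)
    return BasisSet(
        space=space,
        centers=centers,
        values=values,
        kind="cosine",
        exponent=float(exponent),
        origin_kind="cosine",
    )


def make_delta_basis(k: int, space: FeatureSpace | None = None) -> BasisSet:
    """Build ``k`` orthogonal delta ("stick") channels.

    Each channel is 1 at its own centre and 0 elsewhere; no smoothness is
    imposed on the model.  Stimulus features used downstream must coincide
    with the channel centres.  On the stored grid matrix each stick is
    placed at the grid point nearest its centre (display only; evaluation
    at feature values uses the exact indicator).
    """
    if k < 2:
        raise InvalidParameterError(f"need at least 2 channels, got k={k}")
    space = space or FeatureSpace()
    centers = space.period * np.arange(k) / k
    values = np.zeros((k, space.grid_size))
    for i, c in enumerate(centers):
        values[i, int(np.argmin(space.distance(space.grid, c)))] = 1.0
    return BasisSet(
        space=space,
        centers=centers,
        values=values,
        kind="delta",
        exponent=None,
        origin_kind="delta",
    )


@dataclass
class TransformMatrix:
    """A ``k x k`` invertible linear transform mixing channels.

    Attributes
    ----------
    entries : ndarray, shape (k, k)
    condition_number : float
        Ratio of largest to smallest singular value (diagnostic).
    """

    entries: np.ndarray
    condition_number: float = field(init=False)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[0] != self.entries.shape[1]:
            raise ShapeMismatchError(
                f"transform must be square, got shape {self.entries.shape}"
            )
        sv = np.linalg.svd(self.entries, compute_uv=False)
        self.condition_number = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf

    @property
    def k(self) -> int:
        return self.entries.shape[0]

    def require_invertible(self, rtol: float = INVERTIBILITY_RTOL) -> None:
        """Raise :class:`RankDeficiencyError` if the smallest singular value
        falls below ``rtol`` times the largest."""
        sv = np.linalg.svd(self.entries, compute_uv=False)
        if sv[-1] <= rtol * sv[0]:
            raise RankDeficiencyError(
                "transform is numerically singular: smallest singular value "
                f"{sv[-1]:.3e} <= {rtol:g} x largest {sv[0]:.3e}"
            )

    def inverse(self) -> "TransformMatrix":
        """The inverse transform (raises if numerically singular)."""
        self.require_invertible()
        return TransformMatrix(np.linalg.inv(self.entries))


def make_bimodal_transform(k: int, alpha: float = 0.5) -> TransformMatrix:
    """Transform turning unimodal channels into bimodal ones.

    ``T = I + alpha * S`` where ``S`` is the circular shift-by-``k/2``
    permutation: each transformed channel is its original self plus
    ``alpha`` times the channel tuned half a period away, producing two
    modes separated by ``period / 2``.  Because ``S`` is an involution its
    eigenvalues are +/-1, so ``T`` has eigenvalues ``1 +/- alpha`` and is
    invertible for any ``alpha`` strictly between 0 and 1.

    Raises
    ------
    InvalidParameterError
        If ``k`` is odd or ``alpha`` is outside ``(0, 1)`` (``alpha = 1``
        would make ``T`` singular).
    """
    if k < 2 or k % 2 != 0:
        raise InvalidParameterError(f"bimodal transform needs even k >= 2, got {k}")
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError(
            f"alpha must lie strictly between 0 and 1, got {alpha}"
        )
    shift = np.roll(np.eye(k), k // 2, axis=1)
    return TransformMatrix(np.eye(k) + alpha * shift)


def apply_transform(basis: BasisSet, transform: TransformMatrix) -> BasisSet:
    """Mix channels by an invertible linear transform.

    New channel values are ``T @ old values`` (rows mixed); the lineage is
    composed so the canonical basis can always be recovered via the
    lineage inverse.

    Raises
    ------
    ShapeMismatchError
        If ``T`` is not ``k x k`` for this basis.
    RankDeficiencyError
        If ``T`` is numerically singular.
    """
    if transform.k != basis.k:
        raise ShapeMismatchError(
            f"transform is {transform.k}x{transform.k} but basis has k={basis.k}"
        )
    transform.require_invertible()
    return BasisSet(
        space=basis.space,
        centers=basis.centers.copy(),
        values=transform.entries @ basis.values,
        kind="transformed",
        exponent=basis.exponent,
        lineage=transform.entries @ basis.lineage,
        origin_kind=basis.origin_kind,
    )
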