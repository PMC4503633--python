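"""Sample spaces for conformational ensembles and their metric geometry.

Entropy estimation from nearest-neighbor distances needs two ingredients
per sample space: a distance function and the volume-of-a-ball law under
the space's natural measure.  Four spaces are supported:

``torus``
    Periodic torsion-angle space.  Per-angle circular distances (with
    periodicities ``theta_i``, typically 2*pi) are combined in quadrature.
``euclidean``
    Ordinary R^s, used for ligand translation vectors in angstrom.
``rotation``
    The proper rotation group SO(3), points given as 3x3 matrices.  The
    distance between two rotations is the angle of the composite rotation
    R2^-1 R1, which lies in [0, pi]; ball volumes follow the Haar measure
    normalised so that the whole group has volume 4*pi^2.
``line``
    One-dimensional Euclidean space, used for heights above a binding
    surface.

All angles are radians internally; file I/O converts from degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "MetricSpace",
    "distance",
    "pairwise_distances",
    "ball_volume",
    "rotation_angle_density",
    "rotation_angle",
    "is_rotation_matrix",
    "validate_rotation_matrices",
    "quaternion_to_matrix",
    "BallVolumeWarning",
]

_KINDS = ("torus", "euclidean", "rotation", "line")

#: Total Haar volume of SO(3) in the normalisation of the rotation metric.
ROTATION_SPACE_VOLUME = 4.0 * np.pi**2

_ORTHO_TOL = 1e-8


class BallVolumeWarning(UserWarning):
    """Raised when a ball radius exceeds the range where the volume law is exact."""


@dataclass(frozen=True)
class MetricSpace:
    """A sample space: kind, dimension and (for tori) periodicities.

    Use the constructors :meth:`torus`, :meth:`euclidean`, :meth:`rotation`
    and :meth:`line` rather than calling the dataclass directly.
    """

    kind: str
    dimension: int
    periodicities: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown space kind {self.kind!r}; expected one of {_KINDS}")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.kind == "rotation" and self.dimension != 3:
            raise ValueError("rotation space has fixed dimension 3")
        if self.kind == "line" and self.dimension != 1:
            raise ValueError("line space has fixed dimension 1")
        if self.kind == "torus":
            if self.periodicities is None:
                object.__setattr__(
                    self, "periodicities", tuple(2.0 * np.pi for _ in range(self.dimension))
                )
            if len(self.periodicities) != self.dimension:
                raise ValueError("need one periodicity per torus dimension")
            if any(p <= 0 for p in self.periodicities):
                raise ValueError("periodicities must be positive")
        elif self.periodicities is not None:
            raise ValueError(f"periodicities only apply to torus spaces, not {self.kind!r}")

    # -- constructors -------------------------------------------------
    @classmethod
    def torus(cls, periodicities=None, dimension: int | None = None) -> "MetricSpace":
        """Torsion-angle torus; default periodicity 2*pi per angle."""
        if periodicities is not None:
            periodicities = tuple(float(p) for p in np.atleast_1d(periodicities))
            return cls("torus", len(periodicities), periodicities)
        if dimension is None:
            raise ValueError("give either periodicities or dimension")
        return cls("torus", int(dimension))

    @classmethod
    def euclidean(cls, dimension: int = 3) -> "MetricSpace":
        return cls("euclidean", int(dimension))

    @classmethod
    def rotation(cls) -> "MetricSpace":
        return cls("rotation", 3)

    @classmethod
    def line(cls) -> "MetricSpace":
        return cls("line", 1)

    # -- derived quantities -------------------------------------------
    @property
    def log_uniform_volume(self) -> float | None:
        """log of the total volume of the space, if it is finite.

        This is the entropy (in kB) of the uniform distribution on the
        space: sum(log theta_i) for a torus, log(4*pi^2) for rotations.
        Unbounded spaces return None; a reference volume must then be
        supplied by the caller.
        """
        if self.kind == "torus":
            return float(np.sum(np.log(self.periodicities)))
        if self.kind == "rotation":
            return float(np.log(ROTATION_SPACE_VOLUME))
        return None

    @property
    def max_distance(self) -> float | None:
        if self.kind == "torus":
            return float(np.sqrt(np.sum((np.asarray(self.periodicities) / 2.0) ** 2)))
        if self.kind == "rotation":
            return float(np.pi)
        return None

    def coerce_points(self, points) -> np.ndarray:
        """Validate and normalise an array of points for this space.

        Returns shape (n, s) for torus/euclidean/line and (n, 3, 3) for
        rotations.  Rotation matrices are checked for orthonormality and
        unit determinant; quaternion input of shape (n, 4) is converted
        (the double cover q / -q maps to the same matrix).
        """
        points = np.asarray(points, dtype=float)
        if self.kind == "rotation":
            if points.ndim == 2 and points.shape[1] == 4:
                points = quaternion_to_matrix(points)
            if points.ndim == 2 and points.shape == (3, 3):
                points = points[None]
            if points.ndim != 3 or points.shape[1:] != (3, 3):
                raise ValueError("rotation samples must have shape (n, 3, 3) or (n, 4)")
            validate_rotation_matrices(points)
            return points
        if points.ndim == 1:
            points = points[:, None] if self.dimension == 1 else points[None, :]
        if points.ndim != 2 or points.shape[1] != self.dimension:
            raise ValueError(
                f"points have dimension {points.shape[-1]}, space expects {self.dimension}"
            )
        return points


# ---------------------------------------------------------------------
# rotation-matrix utilities
# ---------------------------------------------------------------------

def is_rotation_matrix(matrix: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        return False
    if not np.allclose(matrix.T @ matrix, np.eye(3), atol=max(tol, 1e-8) * 10):
        return False
    return bool(np.isclose(np.linalg.det(matrix), 1.0, atol=max(tol, 1e-8) * 10))


def validate_rotation_matrices(matrices: np.ndarray, tol: float = 1e-7) -> None:
    """Reject arrays that are not proper rotation matrices.

    Tolerance is loose enough for matrices accumulated through floating
    point superpositions but rejects reflections and shears outright.
    """
    matrices = np.asarray(matrices, dtype=float)
    gram = np.einsum("nij,nik->njk", matrices, matrices)
    if not np.allclose(gram, np.eye(3), atol=tol):
        raise ValueError("non-orthonormal rotation matrix")
    if not np.allclose(np.linalg.det(matrices), 1.0, atol=tol):
        raise ValueError("improper rotation (determinant != +1)")


def quaternion_to_matrix(quaternions: np.ndarray) -> np.ndarray:
    """Unit quaternions (w, x, y, z), shape (n, 4), to rotation matrices."""
    from scipy.spatial.transform import Rotation

    q = np.asarray(quaternions, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm quaternion")
    q = q / norms[:, None]
    # scipy uses scalar-last ordering
    mats = Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()
    return mats[0] if single else mats


def rotation_angle(matrices: np.ndarray) -> np.ndarray:
    """Rotation angle(s) in [0, pi] of one or more rotation matrices."""
    matrices = np.asarray(matrices, dtype=float)
    single = matrices.ndim == 2
    matrices = matrices.reshape(-1, 3, 3)
    tr = np.einsum("nii->n", matrices)
    ang = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
    return float(ang[0]) if single else ang


# ---------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------

def _torus_component_distance(delta: np.ndarray, periods: np.ndarray) -> np.ndarray:
    # circular distance per angle: theta/2 - |theta/2 - |d| mod theta|
    wrapped = np.abs(delta) % periods
    return periods / 2.0 - np.abs(periods / 2.0 - wrapped)


def distance(space: MetricSpace, x, y) -> float:
    """Distance between two points of ``space``."""
    if space.kind == "rotation":
        pair = space.coerce_points(np.stack([np.asarray(x, float), np.asarray(y, float)]))
        composite_trace = float(np.sum(pair[0] * pair[1]))  # tr(R2^T R1)
        return float(np.arccos(np.clip((composite_trace - 1.0) / 2.0, -1.0, 1.0)))
    x = space.coerce_points(x)[0]
    y = space.coerce_points(y)[0]
    if space.kind == "torus":
        comp = _torus_component_distance(x - y, np.asarray(space.periodicities))
        return float(np.sqrt(np.sum(comp**2)))
    return float(np.linalg.norm(x - y))


def pairwise_distances(space: MetricSpace, points, others=None) -> np.ndarray:
    """Full distance matrix between ``points`` and ``others`` (default: itself).

    Brute force and exact in every supported metric.  Rotation distances
    use tr(R2^T R1) = <R1, R2>_F computed as a single matrix product.
    """
    X = space.coerce_points(points)
    Y = X if others is None else space.coerce_points(others)
    if space.kind == "rotation":
        gram = X.reshape(len(X), 9) @ Y.reshape(len(Y), 9).T
        return np.arccos(np.clip((gram - 1.0) / 2.0, -1.0, 1.0))
    if space.kind == "torus":
        periods = np.asarray(space.periodicities)
        delta = X[:, None, :] - Y[None, :, :]
        comp = _torus_component_distance(delta, periods)
        return np.sqrt(np.sum(comp**2, axis=-1))
    from scipy.spatial.distance import cdist

    return cdist(X, Y)


# ---------------------------------------------------------------------
# ball volumes and the rotation-angle measure
# ---------------------------------------------------------------------

def _euclidean_ball_volume(s: int, r: np.ndarray) -> np.ndarray:
    log_unit = (s / 2.0) * np.log(np.pi) - gammaln(s / 2.0 + 1.0)
    return np.exp(log_unit) * r**s


def ball_volume(space: MetricSpace, r):
    """Volume of the metric ball of radius ``r`` under the space's measure.

    Euclidean/line/torus balls use the hypersphere law
    ``pi^(s/2) r^s / Gamma(s/2 + 1)``; rotation balls use the Haar volume
    ``4*pi*(r - sin r)`` which reaches 4*pi^2 at r = pi.

    On a torus the hypersphere law stops being exact once ``r`` exceeds
    half the smallest periodicity (the ball wraps around); the uncorrected
    value is still returned but a :class:`BallVolumeWarning` is emitted.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("ball radius must be nonnegative")
    if space.kind == "rotation":
        if np.any(r > np.pi + 1e-12):
            raise ValueError("rotation distances cannot exceed pi")
        return 4.0 * np.pi * (r - np.sin(r))
    if space.kind == "torus":
        half_min = min(space.periodicities) / 2.0
        if np.any(r > half_min):
            warnings.warn(
                f"ball radius beyond half the minimum periodicity ({half_min:.4g}); "
                "hypersphere volume is uncorrected",
                BallVolumeWarning,
                stacklevel=2,
            )
        return _euclidean_ball_volume(space.dimension, r)
    return _euclidean_ball_volume(space.dimension, r)


def rotation_angle_density(theta):
    """Density of the rotation angle under Haar-uniform rotations.

    ``(1 - cos(theta)) / pi`` on [0, pi]; integrates to one.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > np.pi + 1e-12):
        raise ValueError("rotation angle must lie in [0, pi]")
    return (1.0 - np.cos(theta)) / np.pi
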