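"""The k-nearest-neighbor entropy estimator and derived quantities.

For n samples of an s-dimensional variable the unbiased estimator reads

    S_k(n) = (s/n) * sum_i log R_{i,k}
             + log( n * pi^(s/2) / Gamma(s/2 + 1) )
             - L_{k-1} + gamma

where R_{i,k} is the distance of sample i from its k-th nearest neighbor,
gamma is Euler's constant and L_0 = 0, L_j = sum_{i<=j} 1/i.  The middle
term is log(n * V1) with V1 the unit-radius ball volume, so for spaces
with a non-Euclidean ball law (the rotation group) the estimator
generalises to

    S_k(n) = (1/n) * sum_i log( n * V(R_{i,k}) ) - L_{k-1} + gamma

with V the exact ball-volume law of the space.  Entropies are reported in
kB units (natural logarithm); the *absolute* value depends on the unit of
distance, which cancels when a reference entropy is subtracted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .spaces import BallVolumeWarning, MetricSpace, ball_volume, pairwise_distances

__all__ = [
    "SampleSet",
    "EntropyEstimate",
    "knn_distances",
    "entropy_knn",
    "entropy_profile",
    "relative_to_uniform",
    "mutual_information",
    "product_space",
    "entropy_to_kcal_per_mol",
    "EULER_GAMMA",
    "STANDARD_STATE_VOLUME_A3",
    "KB_KCAL_PER_MOL_K",
]

logger = logging.getLogger(__name__)

EULER_GAMMA = float(np.euler_gamma)

#: Volume per molecule at the 1 M standard state, in cubic angstrom
#: (1e27 A^3 per litre / Avogadro's number).
STANDARD_STATE_VOLUME_A3 = 1.0e27 / 6.02214076e23

#: Boltzmann constant times Avogadro's number, kcal/(mol K).
KB_KCAL_PER_MOL_K = 0.0019872041

# maximum chunk of the pairwise distance matrix held in memory at once
_CHUNK_ROWS = 512


def _harmonic(j: int) -> float:
    return sum(1.0 / i for i in range(1, j + 1))


@dataclass
class SampleSet:
    """n samples of a conformational variable living in a metric space."""

    points: np.ndarray
    space: MetricSpace

    def __post_init__(self) -> None:
        self.points = self.space.coerce_points(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def s(self) -> int:
        return self.space.dimension

    def deduplicated(self) -> tuple["SampleSet", int]:
        """Drop exact duplicate points (keeping first occurrences in order)."""
        flat = self.points.reshape(self.n, -1)
        _, first = np.unique(flat, axis=0, return_index=True)
        keep = np.sort(first)
        dropped = self.n - len(keep)
        if dropped == 0:
            return self, 0
        return SampleSet(self.points[keep], self.space), dropped


@dataclass(frozen=True)
class EntropyEstimate:
    """An entropy value in kB units together with its provenance."""

    value: float
    k: int
    n: int
    s: int
    mean_nn_distance: float
    reference: float = 0.0
    reference_name: str = "absolute"
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_absolute(self) -> bool:
        return self.reference_name == "absolute"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        rel = "" if self.is_absolute else f" relative to {self.reference_name}"
        return (
            f"S = {self.value:.4f} kB{rel} "
            f"(k={self.k}, n={self.n}, s={self.s}, <R_k>={self.mean_nn_distance:.4g})"
        )


def knn_distances(samples: SampleSet, k: int = 1) -> np.ndarray:
    """Distance of every sample to its k-th nearest neighbor.

    Brute force over the exact metric of the space, computed in row
    chunks so that the full n x n matrix is never materialised.  A
    KD-tree fast path is used for Euclidean/line spaces.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = samples.n
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got n={n}")
    if samples.space.kind in ("euclidean", "line"):
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1, algorithm="kd_tree")
        nn.fit(samples.points)
        dist, _ = nn.kneighbors(samples.points)
        return dist[:, k]
    out = np.empty(n)
    for start in range(0, n, _CHUNK_ROWS):
        stop = min(start + _CHUNK_ROWS, n)
        block = pairwise_distances(samples.space, samples.points[start:stop], samples.points)
        rows = np.arange(stop - start)
        block[rows, np.arange(start, stop)] = np.inf  # exclude self
        out[start:stop] = np.partition(block, k - 1, axis=1)[:, k - 1]
    return out


def _estimate_from_nn(samples: SampleSet, rk: np.ndarray, k: int,
                      extra_warnings: tuple[str, ...]) -> EntropyEstimate:
    n = samples.n
    s = samples.s
    space = samples.space
    warn: list[str] = list(extra_warnings)
    if np.any(rk == 0):
        warn.append("zero-nn-distance")
        rk = np.where(rk == 0, np.finfo(float).tiny, rk)
    mean_rk = float(np.mean(rk))
    if space.kind == "torus" and mean_rk > min(space.periodicities) / 2.0:
        warn.append("uncorrected-volume")
    if space.kind == "rotation" and mean_rk > np.pi / 2.0:
        warn.append("uncorrected-volume")
    if space.kind == "rotation":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BallVolumeWarning)
            vol = ball_volume(space, rk)
        # r - sin(r) underflows to zero for near-duplicate rotations
        vol = np.maximum(vol, np.finfo(float).tiny)
        value = float(np.mean(np.log(n * vol))) - _harmonic(k - 1) + EULER_GAMMA
    else:
        log_unit_ball = (s / 2.0) * math.log(math.pi) - float(gammaln(s / 2.0 + 1.0))
        value = (
            s * float(np.mean(np.log(rk)))
            + math.log(n)
            + log_unit_ball
            - _harmonic(k - 1)
            + EULER_GAMMA
        )
    if warn:
        logger.warning("entropy_knn: %s (k=%d, n=%d)", ", ".join(warn), k, n)
    return EntropyEstimate(
        value=value, k=k, n=n, s=s, mean_nn_distance=mean_rk, warnings=tuple(warn)
    )


def entropy_knn(samples: SampleSet, k: int = 1) -> EntropyEstimate:
    """Absolute differential entropy of the sampled distribution, in kB.

    Exact duplicate samples carry no volume information and would make
    log R_{i,k} diverge; duplicates beyond the first occurrence are
    dropped with a warning and the estimate computed on the remainder.
    """
    deduped, dropped = samples.deduplicated()
    extra = (f"dropped-{dropped}-duplicate-samples",) if dropped else ()
    if deduped.n <= k:
        raise ValueError(
            f"need more than k={k} distinct samples, got {deduped.n} (of {samples.n})"
        )
    rk = knn_distances(deduped, k)
    est = _estimate_from_nn(deduped, rk, k, extra)
    return est


def entropy_profile(samples: SampleSet, k_max: int) -> list[tuple[float, float]]:
    """(mean k-NN distance, entropy) pairs for k = 1 .. k_max.

    The mean neighbor distance grows with k and plays the role of the
    resolution at which the density is probed: as it grows, detail is
    smoothed away and the entropy estimate rises toward the uniform value.
    """
    deduped, dropped = samples.deduplicated()
    extra = (f"dropped-{dropped}-duplicate-samples",) if dropped else ()
    if k_max >= deduped.n:
        raise ValueError("k_max must be smaller than the number of distinct samples")
    n = deduped.n
    # one chunked pass collecting the k_max smallest neighbor distances per row
    smallest = np.empty((n, k_max))
    for start in range(0, n, _CHUNK_ROWS):
        stop = min(start + _CHUNK_ROWS, n)
        block = pairwise_distances(deduped.space, deduped.points[start:stop], deduped.points)
        rows = np.arange(stop - start)
        block[rows, np.arange(start, stop)] = np.inf
        part = np.partition(block, k_max - 1, axis=1)[:, :k_max]
        smallest[start:stop] = np.sort(part, axis=1)
    profile = []
    for k in range(1, k_max + 1):
        est = _estimate_from_nn(deduped, smallest[:, k - 1], k, extra)
        profile.append((est.mean_nn_distance, est.value))
    return profile


def relative_to_uniform(
    estimate: EntropyEstimate,
    space: MetricSpace,
    reference_volume: float | None = None,
) -> EntropyEstimate:
    """Subtract the uniform-distribution reference entropy of ``space``.

    torus: sum(log theta_i); rotation: log(4 pi^2); 3-D euclidean
    translations: log(1660 A^3), the 1 M standard state; line (and
    euclidean of other dimension): a caller-supplied reference volume.
    """
    if not estimate.is_absolute:
        raise ValueError("estimate already has a reference subtracted")
    if reference_volume is not None:
        ref = math.log(reference_volume)
        name = "caller-supplied"
    elif space.kind in ("torus", "rotation"):
        ref = space.log_uniform_volume
        name = "uniform-torus" if space.kind == "torus" else "uniform-rotation"
    elif space.kind == "euclidean" and space.dimension == 3:
        ref = math.log(STANDARD_STATE_VOLUME_A3)
        name = "1M-standard-state"
    else:
        raise ValueError(
            f"{space.kind} space of dimension {space.dimension} needs an explicit "
            "reference volume"
        )
    return replace(
        estimate, value=estimate.value - ref, reference=ref, reference_name=name
    )


def product_space(a: MetricSpace, b: MetricSpace) -> MetricSpace:
    """Joint space of two independent coordinates (for mutual information)."""
    if a.kind == "torus" and b.kind == "torus":
        return MetricSpace.torus(tuple(a.periodicities) + tuple(b.periodicities))
    flat = {"euclidean", "line"}
    if a.kind in flat and b.kind in flat:
        return MetricSpace.euclidean(a.dimension + b.dimension)
    raise ValueError(f"no product space for kinds {a.kind!r} and {b.kind!r}")


def mutual_information(a: SampleSet, b: SampleSet, k: int = 1) -> float:
    """I(a; b) = S(a) + S(b) - S(a, b), each term via the kNN estimator.

    The uniform references of the marginal spaces cancel against the
    joint, so the result is reference-free (kB units).  Independent
    samples give values scattered around zero within estimator noise.
    """
    if a.n != b.n:
        raise ValueError(f"sample sets differ in length ({a.n} vs {b.n})")
    joint_space = product_space(a.space, b.space)
    pa = a.points.reshape(a.n, -1)
    pb = b.points.reshape(b.n, -1)
    joint = SampleSet(np.hstack([pa, pb]), joint_space)
    s_a = entropy_knn(a, k).value
    s_b = entropy_knn(b, k).value
    s_ab = entropy_knn(joint, k).value
    return s_a + s_b - s_ab


def entropy_to_kcal_per_mol(entropy_kb: float, temperature: float = 300.0) -> float:
    """-T*dS in kcal/mol for an entropy change given in kB units."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -entropy_kb * KB_KCAL_PER_MOL_K * temperature
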