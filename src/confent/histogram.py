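"""Histogram (binned) entropy estimators used as comparators.

Translational entropies bin the 3-D displacement vectors on a cubic grid
(0.133 angstrom default bin width, anchored at the sample centroid) and
subtract the 1 M standard-state reference.

Rotational entropies convert each rotation matrix into an axis direction
(azimuth phi, polar psi) and a signed rotation angle theta restricted to
[-pi/2, pi/2], then bin the three angles on an equal-measure grid: phi
uniform, psi uniform in cos(psi), theta with equal increments of the Haar
angle measure integral of (1 - cos theta).  With 10 x 10 x 100 bins every
bin covers the same Haar fraction of the rotation group, so a uniform
distribution of rotations maps to the zero of the relative entropy.

Because the theta range is capped at pi/2, the binned region covers only
the Haar fraction f = (pi/2 - 1)/pi of the whole group; samples with a
larger rotation angle are left out of the bins (with a warning) but still
count in the normalisation.  Each bin is credited its *true* Haar
fraction under the canonical axis choice: the hemisphere rule places
every axis at cos(psi) >= 0, so a psi-bin's measure is proportional to
the overlap of its cos range with [0, 1] (lower-hemisphere bins have
measure zero and can never be occupied).  This keeps the estimate a
genuine entropy relative to the uniform distribution over all rotations:
uniform input reads ~0 and a uniform cap of angle pi/2 reads log f.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .estimators import STANDARD_STATE_VOLUME_A3, EntropyEstimate
from .spaces import validate_rotation_matrices

__all__ = [
    "BinSpec",
    "histogram_entropy_translational",
    "equal_measure_rotation_bins",
    "histogram_entropy_rotational",
    "rotation_to_axis_angle_signed",
    "THETA_RANGE_HAAR_FRACTION",
]

logger = logging.getLogger(__name__)

#: Haar fraction of the rotation group with rotation angle <= pi/2.
THETA_RANGE_HAAR_FRACTION = (np.pi / 2.0 - 1.0) / np.pi


def _plogp(counts: np.ndarray, n_total: int) -> float:
    p = counts[counts > 0] / n_total
    return float(-np.sum(p * np.log(p)))


def histogram_entropy_translational(
    points: np.ndarray, bin_width: float = 0.133
) -> EntropyEstimate:
    """Binned entropy of 3-D translation vectors vs the 1 M standard state.

    S = -sum p_i log p_i + log(bin volume) - log(1660 A^3), with bins of
    the given width anchored at the sample centroid.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of translation vectors")
    if len(points) == 0:
        raise ValueError("empty input")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    # anchor the grid at the sample minimum: translation invariant and
    # flush with data whose support is a whole number of bins wide
    origin = points.min(axis=0)
    idx = np.floor((points - origin) / bin_width).astype(np.int64)
    _, counts = np.unique(idx, axis=0, return_counts=True)
    n = len(points)
    value = _plogp(counts, n) + 3.0 * math.log(bin_width) - math.log(STANDARD_STATE_VOLUME_A3)
    return EntropyEstimate(
        value=value,
        k=0,
        n=n,
        s=3,
        mean_nn_distance=math.nan,
        reference=math.log(STANDARD_STATE_VOLUME_A3),
        reference_name="1M-standard-state",
    )


@dataclass(frozen=True)
class BinSpec:
    """Equal-measure binning of the axis-angle rotation parameterisation."""

    phi_edges: np.ndarray    # azimuth of the rotation axis, [0, 2 pi]
    psi_edges: np.ndarray    # polar angle of the rotation axis, [0, pi]
    theta_edges: np.ndarray  # signed rotation angle, [-pi/2, pi/2]

    @property
    def n_bins(self) -> int:
        return (
            (len(self.phi_edges) - 1)
            * (len(self.psi_edges) - 1)
            * (len(self.theta_edges) - 1)
        )


def _theta_measure(theta: float) -> float:
    # cumulative (unnormalised) angle measure from -pi/2: integral of 1 - cos
    return (theta + np.pi / 2.0) - (np.sin(theta) + 1.0)


def equal_measure_rotation_bins(
    n_phi: int = 10, n_psi: int = 10, n_theta: int = 100
) -> BinSpec:
    """Bins with identical Haar measure in each (phi, psi, theta) cell.

    phi: uniform on [0, 2 pi); psi: equal increments of cos(psi) on
    [0, pi]; theta: equal increments of the integral of (1 - cos theta)
    on [-pi/2, pi/2].
    """
    if min(n_phi, n_psi, n_theta) < 1:
        raise ValueError("bin counts must be >= 1")
    phi_edges = np.linspace(0.0, 2.0 * np.pi, n_phi + 1)
    psi_edges = np.arccos(np.linspace(1.0, -1.0, n_psi + 1))
    total = _theta_measure(np.pi / 2.0)
    targets = np.linspace(0.0, total, n_theta + 1)
    theta_edges = np.empty(n_theta + 1)
    theta_edges[0], theta_edges[-1] = -np.pi / 2.0, np.pi / 2.0
    for j in range(1, n_theta):
        theta_edges[j] = brentq(
            lambda t, m=targets[j]: _theta_measure(t) - m, -np.pi / 2.0, np.pi / 2.0,
            xtol=1e-14,
        )
    return BinSpec(phi_edges, psi_edges, theta_edges)


def rotation_to_axis_angle_signed(
    rotations: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, psi, theta) per rotation, theta signed in [-pi, pi].

    The axis is fixed to the hemisphere with positive z (ties broken by
    positive x, then positive y) and theta negated whenever the axis had
    to be flipped, so that (axis, theta) and (-axis, -theta) collapse to
    one representative.  The identity maps to axis +z, theta 0.
    """
    from scipy.spatial.transform import Rotation

    rotations = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
    rotvec = Rotation.from_matrix(rotations).as_rotvec()
    theta = np.linalg.norm(rotvec, axis=1)
    axis = np.zeros_like(rotvec)
    nz = theta > 1e-12
    axis[nz] = rotvec[nz] / theta[nz, None]
    axis[~nz] = (0.0, 0.0, 1.0)
    sign = np.where(
        axis[:, 2] != 0.0,
        np.sign(axis[:, 2]),
        np.where(axis[:, 0] != 0.0, np.sign(axis[:, 0]), np.sign(axis[:, 1])),
    )
    sign = np.where(sign == 0.0, 1.0, sign)
    axis *= sign[:, None]
    theta = theta * sign
    phi = np.mod(np.arctan2(axis[:, 1], axis[:, 0]), 2.0 * np.pi)
    psi = np.arccos(np.clip(axis[:, 2], -1.0, 1.0))
    return phi, psi, theta


def histogram_entropy_rotational(rotations: np.ndarray, bins: BinSpec) -> EntropyEstimate:
    """Binned rotational entropy relative to uniform (Haar) rotations.

    Each occupied bin contributes p_i * (log V_i - log p_i) with V_i its
    Haar fraction of the full group under the canonical axis-angle
    representation; p_i is normalised by the total sample count,
    including samples whose rotation angle exceeds pi/2 and therefore
    falls outside the binned range (these are flagged).
    """
    rotations = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
    if len(rotations) == 0:
        raise ValueError("empty input")
    validate_rotation_matrices(rotations)
    phi, psi, theta = rotation_to_axis_angle_signed(rotations)
    n = len(rotations)
    in_range = np.abs(theta) <= np.pi / 2.0 + 1e-12
    n_out = int(n - np.count_nonzero(in_range))
    warn: tuple[str, ...] = ()
    if n_out:
        warn = (f"{n_out}-rotations-beyond-pi/2-left-unbinned",)
        logger.warning(
            "histogram_entropy_rotational: %d of %d rotation angles exceed pi/2 "
            "and fall outside the binned range", n_out, n,
        )
    iphi = np.clip(np.searchsorted(bins.phi_edges, phi[in_range], side="right") - 1,
                   0, len(bins.phi_edges) - 2)
    ipsi = np.clip(np.searchsorted(bins.psi_edges, psi[in_range], side="right") - 1,
                   0, len(bins.psi_edges) - 2)
    ith = np.clip(np.searchsorted(bins.theta_edges, theta[in_range], side="right") - 1,
                  0, len(bins.theta_edges) - 2)
    flat = (iphi * (len(bins.psi_edges) - 1) + ipsi) * (len(bins.theta_edges) - 1) + ith
    occupied, counts = np.unique(flat, return_counts=True)
    p = counts / n
    # Haar fraction per bin: uniform in phi and in the theta measure, but
    # the canonical axis lives on the upper hemisphere, so a psi-bin's
    # weight is the overlap of its cos range with [0, 1].
    cos_edges = np.cos(bins.psi_edges)  # decreasing from 1 to -1
    cos_hi = np.clip(cos_edges[:-1], 0.0, 1.0)
    cos_lo = np.clip(cos_edges[1:], 0.0, 1.0)
    psi_weight = cos_hi - cos_lo  # sums to 1 over the hemisphere
    n_theta = len(bins.theta_edges) - 1
    n_psi = len(bins.psi_edges) - 1
    ipsi_occ = (occupied // n_theta) % n_psi
    log_v = (
        math.log(THETA_RANGE_HAAR_FRACTION)
        - math.log(len(bins.phi_edges) - 1)
        - math.log(n_theta)
        + np.log(psi_weight[ipsi_occ])
    )
    value = float(np.sum(p * (log_v - np.log(p))))
    return EntropyEstimate(
        value=value,
        k=0,
        n=n,
        s=3,
        mean_nn_distance=math.nan,
        reference=math.log(4.0 * np.pi**2),
        reference_name="uniform-rotation",
        warnings=warn,
    )
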