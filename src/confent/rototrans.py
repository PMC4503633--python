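"""Rototranslational binding-entropy workflow.

The pose of a bound ligand relative to its receptor is reduced, snapshot
by snapshot, to a rotation matrix and a translation vector:

1. the overall rototranslation of the complex is removed by
   least-squares superposition of receptor *frame* atoms onto a
   reference snapshot;
2. a rigid three-atom *triad* on the ligand (by default the central
   residue's N, CA, C) is superposed onto its reference position; the
   resulting rotation matrix and the displacement of the triad centroid
   describe the rototranslational state.

Nearest-neighbor entropies of the rotation and translation samples are
then referenced to the uniform-rotation state (log 4 pi^2) and the 1 M
translational standard state (log 1660 A^3).  Rotational and
translational degrees of freedom are treated as independent; this is a
simplification that can underestimate the loss when they are correlated.

A surface-bound variant handles molecules adsorbed on a plane: the
translational entropy is one-dimensional (height above the plane,
against a caller-supplied reference length) and the rotational entropy
receives a +log(2 pi) credit for the free spin about the surface normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimators import (
    KB_KCAL_PER_MOL_K,
    EntropyEstimate,
    SampleSet,
    entropy_knn,
    relative_to_uniform,
)
from .spaces import MetricSpace

__all__ = [
    "RigidTransform",
    "RototransSampleSet",
    "RototransReport",
    "kabsch_superpose",
    "extract_rototranslation",
    "extract_ensemble",
    "select_reference_triad",
    "rototrans_entropy",
    "surface_bound_entropy",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation, y = R x + t (angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class RototransSampleSet:
    """Per-snapshot ligand poses relative to the receptor frame."""

    rotations: np.ndarray     # (T, 3, 3)
    translations: np.ndarray  # (T, 3), triad-centroid displacements
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, float).reshape(-1, 3, 3)
        self.translations = np.asarray(self.translations, float).reshape(-1, 3)
        if len(self.rotations) != len(self.translations):
            raise ValueError("rotations and translations differ in length")
        if len(self.rotations) < 2:
            raise ValueError("need at least two snapshots")


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns the proper rotation + translation mapping ``mobile`` onto
    ``target`` and the RMSD after the fit.  Reflections are never
    returned; collinear or degenerate point sets are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected matching (m, 3) point sets")
    if len(mobile) < 3:
        raise ValueError("need at least three paired points")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - r @ cm
    fitted = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return RigidTransform(r, t), rmsd


def extract_rototranslation(
    snapshot_frame: np.ndarray,
    snapshot_triad: np.ndarray,
    reference_frame: np.ndarray,
    reference_triad: np.ndarray,
) -> RigidTransform:
    """Ligand pose of one snapshot relative to the receptor reference frame.

    The snapshot's frame atoms are superposed onto the reference frame
    (removing global motion of the complex); the transform returned then
    maps the reference triad onto the aligned snapshot triad.  The
    translation is the displacement of the triad centroid.
    """
    snapshot_triad = np.asarray(snapshot_triad, dtype=float)
    if snapshot_triad.shape != (3, 3):
        raise ValueError("triad must consist of exactly three atoms")
    align, _ = kabsch_superpose(snapshot_frame, reference_frame)
    triad_aligned = align.apply(snapshot_triad)
    pose, _ = kabsch_superpose(np.asarray(reference_triad, float), triad_aligned)
    translation = triad_aligned.mean(axis=0) - np.asarray(reference_triad, float).mean(axis=0)
    return RigidTransform(pose.rotation, translation)


def extract_ensemble(
    frame_traj: np.ndarray,
    triad_traj: np.ndarray,
    reference_index: int = 0,
    reference_frame: np.ndarray | None = None,
    reference_triad: np.ndarray | None = None,
) -> RototransSampleSet:
    """Extract per-snapshot poses for a whole trajectory.

    The reference defaults to snapshot ``reference_index``; explicit
    reference coordinates (e.g. a starting structure) may be supplied
    instead.
    """
    frame_traj = np.asarray(frame_traj, dtype=float)
    triad_traj = np.asarray(triad_traj, dtype=float)
    if reference_frame is None:
        reference_frame = frame_traj[reference_index]
    if reference_triad is None:
        reference_triad = triad_traj[reference_index]
    rotations = np.empty((len(frame_traj), 3, 3))
    translations = np.empty((len(frame_traj), 3))
    for i, (frame, triad) in enumerate(zip(frame_traj, triad_traj)):
        tf = extract_rototranslation(frame, triad, reference_frame, reference_triad)
        rotations[i] = tf.rotation
        translations[i] = tf.translation
    return RototransSampleSet(rotations, translations, reference_index)


def select_reference_triad(
    candidates: dict[str, np.ndarray]
) -> list[tuple[str, float]]:
    """Rank candidate atom triads by their post-fit fluctuation.

    ``candidates`` maps a label to a (T, 3, 3) trajectory of triad
    coordinates *after* superposition on the receptor frame.  Triads are
    ranked by the root-mean-square fluctuation of their atoms about the
    trajectory mean (smallest first -- most rigid, hence most decoupled
    from internal dynamics); ties keep input order.
    """
    if not candidates:
        raise ValueError("no candidate triads given")
    ranked = []
    for name, traj in candidates.items():
        traj = np.asarray(traj, dtype=float)
        mean = traj.mean(axis=0)
        rmsf = float(np.sqrt(np.mean(np.sum((traj - mean) ** 2, axis=-1))))
        ranked.append((name, rmsf))
    ranked.sort(key=lambda item: item[1])  # stable: ties keep input order
    return ranked


@dataclass(frozen=True)
class RototransReport:
    """Binding-entropy report for one ensemble (kB units; kcal/mol at T)."""

    s_rot: float
    s_trans: float
    s_total: float
    minus_t_ds_kcal_mol: float
    mean_nn_distance_rot: float
    mean_nn_distance_trans: float
    n: int
    k: int
    temperature: float
    warnings: tuple[str, ...]


def rototrans_entropy(
    samples: RototransSampleSet, k: int = 1, temperature: float = 300.0
) -> RototransReport:
    """Rotational + translational binding entropy of a bound ensemble.

    S_trans references the 1 M standard state (1660 A^3 per molecule),
    S_rot the uniform distribution of rotations (4 pi^2); both are
    negative for any genuinely restricted bound state, up to estimator
    noise.
    """
    rot_est = relative_to_uniform(
        entropy_knn(SampleSet(samples.rotations, MetricSpace.rotation()), k),
        MetricSpace.rotation(),
    )
    trans_est = relative_to_uniform(
        entropy_knn(SampleSet(samples.translations, MetricSpace.euclidean(3)), k),
        MetricSpace.euclidean(3),
    )
    total = rot_est.value + trans_est.value
    return RototransReport(
        s_rot=rot_est.value,
        s_trans=trans_est.value,
        s_total=total,
        minus_t_ds_kcal_mol=-total * KB_KCAL_PER_MOL_K * temperature,
        mean_nn_distance_rot=rot_est.mean_nn_distance,
        mean_nn_distance_trans=trans_est.mean_nn_distance,
        n=len(samples.rotations),
        k=k,
        temperature=temperature,
        warnings=tuple(rot_est.warnings) + tuple(trans_est.warnings),
    )


def surface_bound_entropy(
    plane_distances: np.ndarray,
    rotations: np.ndarray,
    reference_length: float,
    k: int = 1,
) -> dict[str, EntropyEstimate]:
    """Entropies of a molecule bound to a surface.

    ``plane_distances`` are heights above the surface plane (angstrom);
    their entropy is estimated in one dimension and referenced to the
    caller-supplied ``reference_length`` (the 1-D standard state, which
    has no universal convention).  The rotational entropy relative to
    uniform receives +log(2 pi) because any spin about the surface
    normal remains free in the bound state.
    """
    if reference_length is None or reference_length <= 0:
        raise ValueError("a positive 1-D reference length is required")
    heights = np.asarray(plane_distances, dtype=float).reshape(-1, 1)
    line = MetricSpace.line()
    s_trans = relative_to_uniform(
        entropy_knn(SampleSet(heights, line), k), line, reference_volume=reference_length
    )
    rot_space = MetricSpace.rotation()
    rot_abs = entropy_knn(SampleSet(rotations, rot_space), k)
    rot_rel = relative_to_uniform(rot_abs, rot_space)
    s_rot_corrected = EntropyEstimate(
        value=rot_rel.value + math.log(2.0 * math.pi),
        k=rot_rel.k,
        n=rot_rel.n,
        s=rot_rel.s,
        mean_nn_distance=rot_rel.mean_nn_distance,
        reference=rot_rel.reference - math.log(2.0 * math.pi),
        reference_name="uniform-rotation+normal-spin-credit",
        warnings=rot_rel.warnings,
    )
    return {"s_trans_1d": s_trans, "s_rot_corrected": s_rot_corrected}
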