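"""Rigid-body superposition (Kabsch) and RMSD/RMSF stability metrics.

The Kabsch algorithm finds the proper rotation + translation minimising the
least-squares deviation between two equal-length point sets.  If the
optimal orthogonal matrix is a reflection (det = -1) the smallest singular
axis is flipped so a proper rotation is always returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MetricSeries, Trajectory
from .errors import DegenerateGeometryError
from .selections import SelectionSpec, resolve_selection


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with det(rotation) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(RigidTransform, rmsd)`` where the transform maps mobile
    coordinates into the reference frame and ``rmsd`` is the root mean
    squared residual after the transform, in the units of the inputs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")

    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    m = mobile - mob_c
    r = reference - ref_c
    # collinearity check: rank of either centred set < 2
    if np.linalg.matrix_rank(m, tol=1e-8) < 2 or np.linalg.matrix_rank(r, tol=1e-8) < 2:
        raise DegenerateGeometryError("points are collinear; rotation is not unique")

    h = m.T @ r
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = ref_c - rot @ mob_c
    moved = m @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - r) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans), rmsd


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    align_sel: SelectionSpec = "protein name CA",
    measure_sel: SelectionSpec | None = None,
) -> MetricSeries:
    """Per-frame RMSD of ``measure_sel`` after aligning ``align_sel``.

    Each frame is superposed onto the reference frame using the alignment
    selection only; the RMSD is then evaluated over the measurement
    selection (defaults to the alignment selection).  The reference frame
    defaults to the first frame.
    """
    align_idx = resolve_selection(traj.topology, align_sel)
    measure_idx = (
        align_idx if measure_sel is None else resolve_selection(traj.topology, measure_sel)
    )
    ref = traj.frame(reference_frame)
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        tf, _ = kabsch_superpose(traj.coords[i][align_idx], ref[align_idx])
        moved = tf.apply(traj.coords[i][measure_idx])
        values[i] = np.sqrt(np.mean(np.sum((moved - ref[measure_idx]) ** 2, axis=1)))
    return MetricSeries(name="rmsd", units="A", times=traj.times.copy(), values=values)


def rmsf(
    traj: Trajectory,
    align_sel: SelectionSpec = "protein name CA",
    measure_sel: SelectionSpec | None = None,
):
    """Root-mean-square fluctuation per measured atom about the mean structure.

    Frames are first aligned on ``align_sel`` (onto frame 0), the mean
    structure is computed in a single pass, and the RMSF of each atom in
    ``measure_sel`` about that mean is returned as
    ``(atom_indices, res_ids, rmsf_values)``.
    """
    traj.require_frames(2, "RMSF")
    align_idx = resolve_selection(traj.topology, align_sel)
    measure_idx = (
        align_idx if measure_sel is None else resolve_selection(traj.topology, measure_sel)
    )
    ref = traj.frame(0)
    aligned = np.empty((traj.n_frames, measure_idx.size, 3))
    for i in range(traj.n_frames):
        tf, _ = kabsch_superpose(traj.coords[i][align_idx], ref[align_idx])
        aligned[i] = tf.apply(traj.coords[i][measure_idx])
    mean = aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    return measure_idx, traj.topology.res_ids[measure_idx], fluct
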