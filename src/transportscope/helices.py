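"""Helix-axis fitting, domain tilt angles, hinge angles, and state vectors.

A helix (or pooled helix group) axis is the principal axis of its C-alpha
coordinates -- the direction of largest variance of the centred points.
The sign of the axis is fixed by the residue order: the direction points
from the N-terminal end toward the C-terminal end, optionally flipped by a
per-helix polarity so that every axis reports the intracellular-to-
extracellular orientation regardless of how the helix threads the
membrane.  Tilt angles are unsigned angles between oriented axes in
[0, 180] degrees and are frame-internal, hence invariant under any global
rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import MetricSeries, Topology, Trajectory
from .errors import DegenerateGeometryError, TopologyMismatchError
from .selections import SelectionConfig, resolve_selection
from .superpose import kabsch_superpose


@dataclass
class HelixAxis:
    """Centroid + oriented unit direction of a fitted helix axis."""

    centroid: np.ndarray
    direction: np.ndarray
    residue_range: Optional[tuple[int, int]] = None


def fit_helix_axis(ca_coords: np.ndarray, polarity: int = 1,
                   residue_range: Optional[tuple[int, int]] = None) -> HelixAxis:
    """Principal-axis fit to ordered C-alpha coordinates.

    ``polarity`` is +1 when the N->C direction of the residue order runs
    intracellular -> extracellular, -1 when it runs the other way; the
    returned direction always reports IC -> EC under that convention.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[0] < 4:
        raise DegenerateGeometryError("helix axis fit needs >= 4 C-alpha points")
    centroid = ca.mean(axis=0)
    centred = ca - centroid
    # principal axis = top eigenvector of the covariance
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    direction = v[:, -1]
    nc = ca[-1] - ca[0]
    if np.dot(direction, nc) < 0:
        direction = -direction
    direction = polarity * direction
    return HelixAxis(centroid=centroid, direction=direction / np.linalg.norm(direction),
                     residue_range=residue_range)


def tilt_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Unsigned angle between two oriented axes, degrees in [0, 180]."""
    c = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def group_axis(
    topology: Topology,
    frame_coords: np.ndarray,
    tm_names: Sequence[str],
    sel_cfg: SelectionConfig,
    polarity: int = 1,
) -> HelixAxis:
    """Axis of a helix group: principal axis of the pooled C-alphas.

    Pooling (rather than averaging per-helix axes) keeps the fit robust
    when member helices differ in length.  The sign is fixed toward the
    pooled N->C displacement of the members.
    """
    idx = sel_cfg.tm_group_selection(tm_names, topology, ca_only=True)
    return fit_helix_axis(frame_coords[idx], polarity=polarity)


def tilt_angle_series(
    traj: Trajectory,
    pairs: Sequence[tuple[Sequence[str], Sequence[str]]],
    sel_cfg: SelectionConfig,
    polarities: Optional[dict[str, int]] = None,
) -> dict[str, MetricSeries]:
    """Per-frame tilt angles for each (groupA, groupB) TM-name pair.

    Pair keys are rendered ``"TMa+TMb/TMc"`` style from the member names.
    Hinge angles (e.g. TM1a against TM1b) are expressed as pairs of
    sub-range TM names.  No global alignment is applied: angles are
    internal to each frame.
    """
    polarities = polarities or {}

    def pol(names) -> int:
        ps = {polarities.get(n, 1) for n in names}
        return 1 if 1 in ps or not ps else -1

    out: dict[str, MetricSeries] = {}
    for group_a, group_b in pairs:
        name = "+".join(group_a) + "/" + "+".join(group_b)
        values = np.empty(traj.n_frames)
        for i in range(traj.n_frames):
            ax_a = group_axis(traj.topology, traj.coords[i], group_a, sel_cfg, pol(group_a))
            ax_b = group_axis(traj.topology, traj.coords[i], group_b, sel_cfg, pol(group_b))
            values[i] = tilt_angle(ax_a, ax_b)
        out[name] = MetricSeries(name=name, units="deg",
                                 times=traj.times.copy(), values=values)
    return out


@dataclass
class StateVectorResult:
    """Bundle axis of a frame against labelled reference conformations."""

    axis: HelixAxis
    nearest_label: str
    angle_to_each: dict[str, float]


def bundle_state_vector(
    topology: Topology,
    frame_coords: np.ndarray,
    sel_cfg: SelectionConfig,
    references: Sequence[tuple[str, Topology, np.ndarray]],
) -> StateVectorResult:
    """Classify a frame's bundle orientation against reference structures.

    The frame is superposed onto each reference via the scaffold C-alphas;
    the angle between the frame's four-helix-bundle axis and the
    reference's own bundle axis (both expressed in the reference frame) is
    reported, and the nearest reference label returned.  Ties break toward
    the earlier reference in the given order, so permuting equally-distant
    references is the only order dependence.
    """
    if not references:
        raise ValueError("at least one reference structure is required")
    scaf = sel_cfg.scaffold_ca(topology)
    bund = sel_cfg.bundle_ca(topology)

    angles: dict[str, float] = {}
    frame_axis_in_ref = None
    for label, ref_top, ref_coords in references:
        ref_scaf = sel_cfg.scaffold_ca(ref_top)
        ref_bund = sel_cfg.bundle_ca(ref_top)
        if ref_scaf.size != scaf.size:
            raise TopologyMismatchError(
                f"reference {label!r}: scaffold has {ref_scaf.size} C-alphas, "
                f"frame has {scaf.size}"
            )
        tf, _ = kabsch_superpose(frame_coords[scaf], ref_coords[ref_scaf])
        moved_bundle = tf.apply(frame_coords[bund])
        frame_axis = fit_helix_axis(moved_bundle)
        ref_axis = fit_helix_axis(ref_coords[ref_bund])
        angles[label] = tilt_angle(frame_axis, ref_axis)
        if frame_axis_in_ref is None:
            frame_axis_in_ref = frame_axis

    nearest = min(angles, key=lambda k: (angles[k], list(angles).index(k)))
    return StateVectorResult(axis=frame_axis_in_ref, nearest_label=nearest,
                             angle_to_each=angles)
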