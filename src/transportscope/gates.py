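"""Gate distance traces and hysteresis-based state-change detection.

A "gate" is a salt bridge or hydrogen-bonding pair tracked as the shortest
heavy-atom distance between two small atom groups (e.g. the carboxylate
oxygens of a glutamate against the guanidinium nitrogens of an arginine).
State changes use a two-threshold hysteresis with a dwell requirement so
that thermal chatter around a single cutoff does not produce event storms.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .core import MetricSeries, Trajectory
from .errors import EmptyInputError
from .selections import GateDefinition, resolve_selection


def min_pairwise_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum Euclidean distance over all cross pairs of two point sets."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("min_pairwise_distance: empty point set")
    return float(cdist(a, b).min())


def gate_distance_series(traj: Trajectory, gate: GateDefinition) -> MetricSeries:
    """Per-frame shortest distance between the gate's two groups, in A."""
    idx_a = resolve_selection(traj.topology, gate.group_a)
    idx_b = resolve_selection(traj.topology, gate.group_b)
    values = np.array(
        [min_pairwise_distance(f[idx_a], f[idx_b]) for f in traj.coords]
    )
    return MetricSeries(name=gate.name, units="A", times=traj.times.copy(), values=values)


def detect_state_change(
    series: MetricSeries, gate: GateDefinition, min_dwell: int = 5
) -> list[tuple[str, int]]:
    """Detect break/reform events on a gate distance trace.

    The gate becomes *broken* when the distance exceeds ``broken_cutoff``
    for at least ``min_dwell`` consecutive frames, and *reformed* when it
    drops below ``formed_cutoff`` for at least ``min_dwell`` frames.  Each
    event is reported at the first frame of its qualifying run.  The
    initial state is taken from the first frame (broken if above the broken
    cutoff, formed otherwise), so a trace that starts broken yields a
    reform event first.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    v = np.asarray(series.values, dtype=float)
    events: list[tuple[str, int]] = []
    state = "broken" if len(v) and v[0] > gate.broken_cutoff else "formed"
    run_start = None
    run_len = 0
    for i, x in enumerate(v):
        if state == "formed":
            qualifying = x > gate.broken_cutoff
        else:
            qualifying = x < gate.formed_cutoff
        if qualifying:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= min_dwell:
                events.append(("break" if state == "formed" else "reform", run_start))
                state = "broken" if state == "formed" else "formed"
                run_len = 0
        else:
            run_len = 0
    return events
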