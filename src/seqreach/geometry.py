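"""Task geometry for the 8-movement sequential reaching task.

Four circular targets (1 cm diameter) are arranged around a central "via"
target.  Targets 1 and 4 sit on the y-axis, 10 cm above and below the via;
targets 2 and 3 sit at a 5-cm radius with a configurable angular split
(126 degrees in the canonical task) between them, symmetric about the
y-axis.  A trial starts in the via target and runs the number sequence
1-3-2-4 with a via passage between every outward reach, i.e. the waypoint
sequence via-1-via-3-via-2-via-4-via: 8 movements, 7 transitions.

The coordinate frame puts the origin at the via center with +y toward
target 1; all lengths are centimeters.  Downstream metrics are invariant
under rigid motion of this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Canonical waypoint sequence: 9 waypoints -> 8 movements -> 7 transitions.
REACH_SEQUENCE: tuple[str, ...] = ("via", "1", "via", "3", "via", "2", "via", "4", "via")


@dataclass(frozen=True)
class TaskGeometry:
    """Positions and radii of the reaching task, in centimeters."""

    via_center: np.ndarray
    target_centers: np.ndarray  # shape (4, 2); rows are targets 1..4
    target_radius: float = 0.5
    proximity_radius: float = 2.0
    reach_sequence: tuple[str, ...] = REACH_SEQUENCE

    def waypoint(self, label: str) -> np.ndarray:
        """Center of the named waypoint ('via' or '1'..'4')."""
        if label == "via":
            return self.via_center
        idx = int(label) - 1
        if not 0 <= idx < len(self.target_centers):
            raise ParameterError(f"unknown waypoint label {label!r}")
        return self.target_centers[idx]

    @property
    def sequence_points(self) -> np.ndarray:
        """Waypoint centers along the reach sequence, shape (9, 2)."""
        return np.array([self.waypoint(lbl) for lbl in self.reach_sequence])

    @property
    def n_movements(self) -> int:
        return len(self.reach_sequence) - 1

    @property
    def n_transitions(self) -> int:
        return len(self.reach_sequence) - 2

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0)) -> "TaskGeometry":
        """Rigidly rotated/translated copy (used for invariance checks)."""
        th = np.deg2rad(rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.asarray(translation, dtype=float)
        return TaskGeometry(
            via_center=R @ self.via_center + t,
            target_centers=self.target_centers @ R.T + t,
            target_radius=self.target_radius,
            proximity_radius=self.proximity_radius,
            reach_sequence=self.reach_sequence,
        )


def build_geometry(
    angle_split: float = 126.0,
    mirror: bool = False,
    long_radius: float = 10.0,
    short_radius: float = 5.0,
    target_radius: float = 0.5,
    proximity_radius: float = 2.0,
) -> TaskGeometry:
    """Construct the task geometry.

    Parameters
    ----------
    angle_split
        Angle in degrees between targets 2 and 3 as seen from the via
        target (canonical value 126).
    mirror
        If True, place targets 2/3 in the lower half-plane (symmetric
        about -y instead of +y).  The task only fixes their radius and
        separation, so the orientation is configurable.
    """
    if not 0.0 < angle_split < 180.0:
        raise ParameterError(f"angle_split must lie in (0, 180) degrees, got {angle_split}")
    if long_radius <= 0 or short_radius <= 0:
        raise ParameterError("target radii must be positive")

    via = np.zeros(2)
    t1 = np.array([0.0, long_radius])
    t4 = np.array([0.0, -long_radius])
    half = np.deg2rad(angle_split) / 2.0
    ysign = -1.0 if mirror else 1.0
    t2 = np.array([short_radius * np.sin(half), ysign * short_radius * np.cos(half)])
    t3 = np.array([-short_radius * np.sin(half), ysign * short_radius * np.cos(half)])
    return TaskGeometry(
        via_center=via,
        target_centers=np.array([t1, t2, t3, t4]),
        target_radius=target_radius,
        proximity_radius=proximity_radius,
    )
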