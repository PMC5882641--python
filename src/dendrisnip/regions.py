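"""Bounding volumes for dendritic fields.

The growth model constrains each dendritic tree to a specified volume; a
candidate segment whose distal end leaves the region is treated like a
collision (the growing tip retracts and redraws its direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class Cone:
    """Solid cone with apex at the soma.

    ``axis`` is the dendritic-field direction, ``half_angle_deg`` the opening
    half-angle and ``height`` the maximal extent along the axis, in um.
    """

    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    half_angle_deg: float = 35.0
    height: float = 200.0

    def __post_init__(self) -> None:
        self.axis = _unit(self.axis)

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        h = float(p @ self.axis)
        if h < 0.0 or h > self.height:
            return False
        r = np.linalg.norm(p - h * self.axis)
        return r <= h * np.tan(np.radians(self.half_angle_deg)) + 1e-9


@dataclass
class Hemisphere:
    """Half-ball of given ``radius`` on the ``axis`` side of the soma."""

    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    radius: float = 150.0

    def __post_init__(self) -> None:
        self.axis = _unit(self.axis)

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return float(p @ self.axis) >= -1e-9 and np.linalg.norm(p) <= self.radius + 1e-9


@dataclass
class Ball:
    radius: float = 200.0

    def contains(self, point) -> bool:
        return np.linalg.norm(np.asarray(point, dtype=float)) <= self.radius + 1e-9
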