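"""Morphometric read-outs: lengths, branch counts, angles, Sholl profiles.

All quantities are computed on the segments that still physically exist
(state != removed); repaired segments count as undamaged.  Branch-level
quantities are recomputed topologically from the surviving forest, so that a
branch point whose daughter subtree was snipped away is no longer counted as
a bifurcation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .neuron import ROOT, Neuron, SegmentState

__all__ = [
    "MorphometrySummary",
    "ShollProfile",
    "Ratios",
    "summarize",
    "sholl",
    "ratio_to_control",
]


@dataclass
class MorphometrySummary:
    total_length: float = 0.0
    n_branch_points: int = 0
    n_branches: int = 0
    mean_branch_length: float = 0.0
    n_primaries: int = 0
    mean_bifurcation_angle: float = float("nan")
    per_order: dict[int, tuple[int, float]] = field(default_factory=dict)  # order -> (count, mean length)
    compartment: str = "all"


@dataclass
class ShollProfile:
    radii: np.ndarray
    intersections: np.ndarray
    compartment: str = "all"


@dataclass
class Ratios:
    """Irradiated-over-control fractions of total length, branch number and
    branch points (tL/tL0, BN/BN0, BP/BP0)."""

    tl: float
    bn: float
    bp: float


def _present(neuron: Neuron, compartment: str):
    segs = []
    for s in neuron.segments.values():
        if s.state is SegmentState.REMOVED:
            continue
        if compartment != "all":
            br = neuron.branches.get(s.branch_id)
            if br is None or br.compartment != compartment:
                continue
        segs.append(s)
    return segs


def summarize(neuron: Neuron, compartment: str = "all") -> MorphometrySummary:
    """Morphometric summary of the surviving arbor of one compartment."""
    segs = _present(neuron, compartment)
    if not segs:
        warnings.warn(f"compartment {compartment!r} has no surviving segments")
        return MorphometrySummary(compartment=compartment)

    ids = {s.id for s in segs}
    by_id = {s.id: s for s in segs}
    kids: dict[int, list[int]] = {}
    roots: list[int] = []
    for s in segs:
        if s.parent_id == ROOT or s.parent_id not in ids:
            roots.append(s.id)
        else:
            kids.setdefault(s.parent_id, []).append(s.id)

    total_length = float(sum(s.length for s in segs))
    bp_ids = [sid for sid in ids if len(kids.get(sid, [])) >= 2]
    n_bp = len(bp_ids)
    n_prim = len(roots)
    n_branches = 2 * n_bp + n_prim

    angles = []
    for sid in bp_ids:
        d = [by_id[c].direction for c in kids[sid][:2]]
        cosang = float(np.clip(d[0] @ d[1], -1.0, 1.0))
        angles.append(math.degrees(math.acos(cosang)))

    # condensed branches: start at roots and at bifurcation daughters
    per_order: dict[int, list[float]] = {}
    stack = [(r, 1) for r in reversed(roots)]
    while stack:
        head, order = stack.pop()
        length = 0.0
        cur = head
        while True:
            length += by_id[cur].length
            ks = kids.get(cur, [])
            if len(ks) == 1:
                cur = ks[0]
            else:
                if len(ks) >= 2:
                    for k in reversed(ks):
                        stack.append((k, order + 1))
                break
        per_order.setdefault(order, []).append(length)

    per_order_tbl = {o: (len(v), float(np.mean(v))) for o, v in sorted(per_order.items())}
    return MorphometrySummary(
        total_length=total_length,
        n_branch_points=n_bp,
        n_branches=n_branches,
        mean_branch_length=total_length / n_branches if n_branches else 0.0,
        n_primaries=n_prim,
        mean_bifurcation_angle=float(np.mean(angles)) if angles else float("nan"),
        per_order=per_order_tbl,
        compartment=compartment,
    )


def sholl(neuron: Neuron, radius_step: float = 10.0, compartment: str = "all",
          max_radius: float | None = None) -> ShollProfile:
    """Sholl profile: dendrite crossings of concentric spheres about the soma.

    A segment crosses the sphere of radius R when its two endpoints straddle
    it (|start| < R <= |end| or the reverse); each crossing of each segment
    counts.  The radius-0 entry reports the number of surviving primaries
    (spheres conceptually start at the soma surface).  Segments are short
    relative to the default 10 um step, so chord crossings (both endpoints
    outside, midpoint inside) are neglected.
    """
    if radius_step <= 0:
        raise ValueError("radius_step must be positive")
    segs = _present(neuron, compartment)
    center = neuron.soma_position
    if not segs:
        return ShollProfile(np.array([0.0]), np.array([0]), compartment)
    a = np.array([np.linalg.norm(s.start - center) for s in segs])
    b = np.array([np.linalg.norm(s.end - center) for s in segs])
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    rmax = max_radius if max_radius is not None else float(hi.max())
    n_spheres = max(1, int(math.ceil(rmax / radius_step - 1e-9)))
    radii = radius_step * np.arange(0, n_spheres + 1)
    counts = np.zeros(len(radii), dtype=int)
    counts[0] = sum(1 for s in segs if s.parent_id == ROOT)
    for i, r in enumerate(radii[1:], start=1):
        counts[i] = int(np.sum((lo < r) & (r <= hi)))
    return ShollProfile(radii, counts, compartment)


def ratio_to_control(irradiated: MorphometrySummary, control: MorphometrySummary) -> Ratios:
    """Element-wise irradiated/control ratios (tL/tL0, BN/BN0, BP/BP0)."""
    if control.total_length <= 0 or control.n_branches <= 0 or control.n_branch_points <= 0:
        raise ZeroDivisionError("control morphometry has a zero denominator")
    return Ratios(
        tl=irradiated.total_length / control.total_length,
        bn=irradiated.n_branches / control.n_branches,
        bp=irradiated.n_branch_points / control.n_branch_points,
    )
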