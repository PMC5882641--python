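"""Hand-built toy neurons with exactly known morphometrics (test oracles)."""

from __future__ import annotations

import math

import numpy as np

from .neuron import ROOT, Branch, BranchPoint, Neuron, Segment

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("chain10", "ybranch", "binary2", "shollfork")


def _add_chain(n: Neuron, branch: Branch, points: list[np.ndarray], radius: float,
               parent_seg: int, order: int) -> int:
    """Append segments along consecutive points; returns the last segment id."""
    prev = parent_seg
    for a, b in zip(points, points[1:]):
        seg = Segment(
            id=len(n.segments), parent_id=prev, branch_id=branch.id,
            branch_order=order, start=a, end=b, radius=radius,
        )
        n.add_segment(seg)
        prev = seg.id
    return prev


def make_fixture(name: str) -> Neuron:
    """Deterministic toy neuron by name.

    * ``chain10`` — 10 collinear segments of length 2 along +z (tL = 20, no
      branch points).
    * ``ybranch`` — one primary of length 10 along +z, then two daughters of
      length 5 at +/-30 degrees in the xz-plane (tL = 20, 1 branch point,
      3 branches, bifurcation angle 60 degrees).
    * ``binary2`` — symmetric two-level binary tree: 3 branch points,
      7 branches, 4 tips.
    * ``shollfork`` — primary to (0,0,10) in two segments, daughters of
      length 11 at +/-30 degrees, whose endpoints pass radius 20; with a
      5 um Sholl step the crossings are (1,1,2,2) at r=(5,10,15,20).
    """
    if name == "chain10":
        n = Neuron("GCL", soma_radius=1.0)
        br = n.add_branch(Branch(id=0, order=1, parent_branch_point_id=ROOT))
        pts = [np.array([0.0, 0.0, 2.0 * k]) for k in range(11)]
        _add_chain(n, br, pts, radius=1.0, parent_seg=ROOT, order=1)
        return n

    if name in ("ybranch", "shollfork"):
        n = Neuron("GCL", soma_radius=1.0)
        trunk = n.add_branch(Branch(id=0, order=1, parent_branch_point_id=ROOT))
        top = np.array([0.0, 0.0, 10.0])
        pts = [np.zeros(3), np.array([0.0, 0.0, 5.0]), top]
        last = _add_chain(n, trunk, pts, radius=1.0, parent_seg=ROOT, order=1)
        bp = n.add_branch_point(BranchPoint(id=0, parent_segment_id=last, position=top))
        length = 5.0 if name == "ybranch" else 11.0
        s, c = math.sin(math.radians(30.0)), math.cos(math.radians(30.0))
        daughters = []
        for sign in (+1, -1):
            br = n.add_branch(Branch(id=len(n.branches), order=2, parent_branch_point_id=0))
            d = np.array([sign * s, 0.0, c])
            _add_chain(n, br, [top, top + length * d], radius=0.5, parent_seg=last, order=2)
            daughters.append(br.id)
        bp.daughter_branch_ids = tuple(daughters)
        return n

    if name == "binary2":
        n = Neuron("GCL", soma_radius=1.0)
        trunk = n.add_branch(Branch(id=0, order=1, parent_branch_point_id=ROOT))
        top = np.array([0.0, 0.0, 8.0])
        last = _add_chain(n, trunk, [np.zeros(3), top], radius=1.0, parent_seg=ROOT, order=1)
        bp0 = n.add_branch_point(BranchPoint(id=0, parent_segment_id=last, position=top))
        first_level = []
        for sign in (+1, -1):
            br = n.add_branch(Branch(id=len(n.branches), order=2, parent_branch_point_id=0))
            d = np.array([sign * math.sin(math.radians(45.0)), 0.0, math.cos(math.radians(45.0))])
            end = top + 6.0 * d
            sid = _add_chain(n, br, [top, end], radius=0.7, parent_seg=last, order=2)
            first_level.append((br.id, sid, end, d))
        bp0.daughter_branch_ids = tuple(b for b, *_ in first_level)
        for bid, sid, end, d in first_level:
            bp = n.add_branch_point(BranchPoint(
                id=len(n.branch_points), parent_segment_id=sid, position=end,
            ))
            grand = []
            for sign in (+1, -1):
                br = n.add_branch(Branch(id=len(n.branches), order=3, parent_branch_point_id=bp.id))
                # rotate d by +/-30 degrees in the xz-plane
                ang = math.atan2(d[0], d[2]) + sign * math.radians(30.0)
                dd = np.array([math.sin(ang), 0.0, math.cos(ang)])
                _add_chain(n, br, [end, end + 4.0 * dd], radius=0.5, parent_seg=sid, order=3)
                grand.append(br.id)
            bp.daughter_branch_ids = tuple(grand)
        return n

    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
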