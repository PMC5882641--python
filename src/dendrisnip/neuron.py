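"""Tree data model for in-silico neurons.

A neuron is a forest of rooted trees of cylindrical *segments* attached to the
soma.  Segments are grouped into *branches* (maximal unbranched chains) joined
at *branch points* (bifurcations).  Every segment, branch and branch point
carries a unique integer ID so that structural changes (radiation-induced
snips, removals) can be tracked segment by segment.

Conventions
-----------
* Coordinates are right-handed Cartesian, in micrometres, soma at the origin.
* A segment's ``parent_id`` is ``ROOT`` (-1) for the first segment of a
  primary dendrite.
* Branch order is 1 for primary dendrites and increments at each bifurcation.
* "Branch number" counts maximal unbranched sections, so for binary trees
  ``n_branches = 2 * n_branch_points + n_primaries``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

ROOT = -1

__all__ = [
    "ROOT",
    "SegmentState",
    "Segment",
    "Branch",
    "BranchPoint",
    "Neuron",
    "validate",
]


class SegmentState(str, enum.Enum):
    """Damage state of a single segment."""

    INTACT = "intact"
    DAMAGED = "damaged"
    REPAIRED = "repaired"  # reported as undamaged in all morphometrics
    SNIPPED = "snipped"
    REMOVED = "removed"  # excluded from all read-outs


@dataclass
class Segment:
    """One cylindrical dendritic element.

    Geometry is the axis from ``start`` to ``end`` with constant ``radius``;
    at creation the growth model uses an aspect ratio of 1:1, i.e. a length of
    twice the radius.
    """

    id: int
    parent_id: int
    branch_id: int
    branch_order: int
    start: np.ndarray
    end: np.ndarray
    radius: float
    state: SegmentState = SegmentState.INTACT

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def volume(self) -> float:
        """Cylinder volume pi * r^2 * L in um^3 (the dose-response input)."""
        return math.pi * self.radius**2 * self.length

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        n = np.linalg.norm(d)
        return d / n if n > 0 else d


@dataclass
class Branch:
    """Maximal unbranched chain of segments."""

    id: int
    segment_ids: list[int] = field(default_factory=list)
    order: int = 1
    parent_branch_point_id: int = ROOT
    compartment: str = "dendrite"  # "dendrite" (GCL) | "apical" | "basal"


@dataclass
class BranchPoint:
    """Bifurcation at the distal end of ``parent_segment_id``."""

    id: int
    parent_segment_id: int
    position: np.ndarray
    daughter_branch_ids: tuple[int, int] | tuple = ()

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


class Neuron:
    """A rooted forest of dendritic segments attached to a soma."""

    def __init__(
        self,
        neuron_class: str = "GCL",
        soma_position: Iterable[float] = (0.0, 0.0, 0.0),
        soma_radius: float = 5.0,
    ) -> None:
        self.neuron_class = neuron_class
        self.soma_position = np.asarray(soma_position, dtype=float)
        self.soma_radius = float(soma_radius)
        self.segments: dict[int, Segment] = {}
        self.branches: dict[int, Branch] = {}
        self.branch_points: dict[int, BranchPoint] = {}
        self._children: dict[int, list[int]] = {}
        self.metadata: dict = {}

    # ---------------------------------------------------------------- basics
    def __len__(self) -> int:
        return len(self.segments)

    def add_segment(self, segment: Segment) -> Segment:
        if segment.id in self.segments:
            raise ValueError(f"duplicate segment id {segment.id}")
        self.segments[segment.id] = segment
        self._children.setdefault(segment.parent_id, []).append(segment.id)
        if segment.branch_id in self.branches:
            self.branches[segment.branch_id].segment_ids.append(segment.id)
        return segment

    def add_branch(self, branch: Branch) -> Branch:
        if branch.id in self.branches:
            raise ValueError(f"duplicate branch id {branch.id}")
        self.branches[branch.id] = branch
        return branch

    def add_branch_point(self, bp: BranchPoint) -> BranchPoint:
        if bp.id in self.branch_points:
            raise ValueError(f"duplicate branch point id {bp.id}")
        self.branch_points[bp.id] = bp
        return bp

    def children(self, segment_id: int) -> list[int]:
        return self._children.get(segment_id, [])

    def root_segment_ids(self) -> list[int]:
        return list(self._children.get(ROOT, []))

    def iter_segments(self, include_removed: bool = True) -> Iterator[Segment]:
        for seg in self.segments.values():
            if include_removed or seg.state is not SegmentState.REMOVED:
                yield seg

    def present_ids(self) -> list[int]:
        """IDs of segments that still physically exist (not removed)."""
        return [s.id for s in self.segments.values() if s.state is not SegmentState.REMOVED]

    # ------------------------------------------------------------- topology
    def distal_subtree(self, segment_id: int) -> set[int]:
        """``segment_id`` plus every segment whose root-ward path passes
        through it (used by the snip-propagation rule)."""
        if segment_id not in self.segments:
            raise KeyError(f"unknown segment id {segment_id}")
        out: set[int] = set()
        stack = [segment_id]
        while stack:
            sid = stack.pop()
            if sid in out:
                continue
            out.add(sid)
            stack.extend(self._children.get(sid, []))
        return out

    def n_primaries(self) -> int:
        return len(self.root_segment_ids())

    def n_branch_points(self) -> int:
        return len(self.branch_points)

    def copy(self) -> "Neuron":
        """Cheap structural copy (shares coordinate arrays, copies states)."""
        other = Neuron(self.neuron_class, self.soma_position.copy(), self.soma_radius)
        for seg in self.segments.values():
            other.segments[seg.id] = Segment(
                seg.id, seg.parent_id, seg.branch_id, seg.branch_order,
                seg.start, seg.end, seg.radius, seg.state,
            )
        other.branches = {
            b.id: Branch(b.id, list(b.segment_ids), b.order, b.parent_branch_point_id, b.compartment)
            for b in self.branches.values()
        }
        other.branch_points = {
            bp.id: BranchPoint(bp.id, bp.parent_segment_id, bp.position, bp.daughter_branch_ids)
            for bp in self.branch_points.values()
        }
        other._children = {k: list(v) for k, v in self._children.items()}
        other.metadata = dict(self.metadata)
        return other

    # ----------------------------------------------------------------- JSON
    def to_json(self) -> str:
        doc = {
            "neuron_class": self.neuron_class,
            "soma_position": self.soma_position.tolist(),
            "soma_radius": self.soma_radius,
            "metadata": self.metadata,
            "segments": [
                {
                    "id": s.id, "parent_id": s.parent_id, "branch_id": s.branch_id,
                    "branch_order": s.branch_order, "start": s.start.tolist(),
                    "end": s.end.tolist(), "radius": s.radius, "state": s.state.value,
                }
                for s in self.segments.values()
            ],
            "branches": [
                {
                    "id": b.id, "segment_ids": b.segment_ids, "order": b.order,
                    "parent_branch_point_id": b.parent_branch_point_id,
                    "compartment": b.compartment,
                }
                for b in self.branches.values()
            ],
            "branch_points": [
                {
                    "id": p.id, "parent_segment_id": p.parent_segment_id,
                    "position": p.position.tolist(),
                    "daughter_branch_ids": list(p.daughter_branch_ids),
                }
                for p in self.branch_points.values()
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Neuron":
        doc = json.loads(text)
        n = cls(doc["neuron_class"], doc["soma_position"], doc["soma_radius"])
        n.metadata = doc.get("metadata", {})
        for b in doc["branches"]:
            n.add_branch(Branch(b["id"], [], b["order"], b["parent_branch_point_id"], b["compartment"]))
        for s in doc["segments"]:
            n.add_segment(Segment(
                s["id"], s["parent_id"], s["branch_id"], s["branch_order"],
                np.array(s["start"]), np.array(s["end"]), s["radius"],
                SegmentState(s["state"]),
            ))
        for p in doc["branch_points"]:
            n.add_branch_point(BranchPoint(
                p["id"], p["parent_segment_id"], np.array(p["position"]),
                tuple(p["daughter_branch_ids"]),
            ))
        return n


# -------------------------------------------------------------------------
# validation
# -------------------------------------------------------------------------

def validate(
    neuron: Neuron,
    *,
    check_geometry: bool = False,
    radius_bounds: tuple[float, float] = (0.2, 3.0),
    tol: float = 1e-6,
) -> list[str]:
    """Check structural invariants; return a list of human-readable violations.

    Always checked: ID resolvability, parent contiguity (a segment starts where
    its parent ends), acyclicity/forest structure, branch path consistency and
    the binary-tree branch counting identity.  With ``check_geometry=True`` the
    growth-model geometry contracts are checked too (length = 2 x radius,
    radius within ``radius_bounds``); hand-built toy fixtures and externally
    reconstructed morphologies are not required to satisfy those.
    """
    v: list[str] = []
    segs = neuron.segments

    for seg in segs.values():
        if seg.parent_id != ROOT and seg.parent_id not in segs:
            v.append(f"segment {seg.id}: parent_id {seg.parent_id} unresolvable")
        if seg.branch_id not in neuron.branches:
            v.append(f"segment {seg.id}: branch_id {seg.branch_id} unresolvable")
        if seg.parent_id != ROOT and seg.parent_id in segs:
            gap = np.linalg.norm(seg.start - segs[seg.parent_id].end)
            if gap > tol:
                v.append(f"segment {seg.id}: start does not meet parent end (gap {gap:.3g} um)")
        if check_geometry and seg.state is not SegmentState.REMOVED:
            lo, hi = radius_bounds
            if not (lo - tol <= seg.radius <= hi + tol):
                v.append(f"segment {seg.id}: radius {seg.radius:.3g} outside [{lo}, {hi}] um")
            if abs(seg.length - 2.0 * seg.radius) > max(tol, 1e-6 * seg.radius):
                v.append(f"segment {seg.id}: length {seg.length:.3g} != 2 x radius")

    # forest: walk from roots, every segment reached exactly once
    reached: set[int] = set()
    for rid in neuron.root_segment_ids():
        stack = [rid]
        while stack:
            sid = stack.pop()
            if sid in reached:
                v.append(f"segment {sid}: reachable from more than one path (cycle or shared child)")
                continue
            reached.add(sid)
            stack.extend(neuron.children(sid))
    for sid in segs:
        if sid not in reached:
            v.append(f"segment {sid}: not reachable from any root (orphan or cycle)")

    # branches: unbranched paths terminating at a tip or a bifurcation
    for br in neuron.branches.values():
        ids = br.segment_ids
        for a, b in zip(ids, ids[1:]):
            if b not in segs or a not in segs:
                continue
            if segs[b].parent_id != a:
                v.append(f"branch {br.id}: segments {a} -> {b} are not parent-linked")
        for sid in ids[:-1]:
            if len(neuron.children(sid)) != 1:
                v.append(f"branch {br.id}: interior segment {sid} has a bifurcation")
        if ids:
            nc = len(neuron.children(ids[-1]))
            if nc not in (0, 2):
                v.append(f"branch {br.id}: terminal segment {ids[-1]} has {nc} daughters (expected 0 or 2)")

    for bp in neuron.branch_points.values():
        if bp.parent_segment_id not in segs:
            v.append(f"branch point {bp.id}: parent segment {bp.parent_segment_id} unresolvable")
        for bid in bp.daughter_branch_ids:
            if bid not in neuron.branches:
                v.append(f"branch point {bp.id}: daughter branch {bid} unresolvable")

    n_br, n_bp, n_prim = len(neuron.branches), len(neuron.branch_points), neuron.n_primaries()
    if neuron.segments and n_br != 2 * n_bp + n_prim:
        v.append(
            f"branch counting identity violated: {n_br} branches != 2*{n_bp} branch points + {n_prim} primaries"
        )
    return v
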