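"""SWC morphology I/O (the NeuroMorpho.org interchange format).

Standard 7-column dialect: ``index type x y z radius parent``, 1-based
indices, parent ``-1`` for roots.  The soma is written as a single type-1
point; dendrites use type 3 (basal / unspecified) or 4 (apical).  Segment
damage states are not representable in SWC: removed segments are omitted,
any other non-intact state is dropped with a warning.
"""

from __future__ import annotations

import warnings
from os import PathLike
from typing import IO, Union

import numpy as np

from .neuron import ROOT, Branch, BranchPoint, Neuron, Segment, SegmentState

__all__ = ["write_swc", "read_swc", "SwcError"]

_TYPE_BY_COMPARTMENT = {"apical": 4, "basal": 3, "dendrite": 3}
_COMPARTMENT_BY_TYPE = {4: "apical", 3: "dendrite"}

Pathish = Union[str, PathLike, IO[str]]


class SwcError(ValueError):
    """Malformed or structurally invalid SWC content."""


def _opened(dest: Pathish, mode: str):
    if hasattr(dest, "read") or hasattr(dest, "write"):
        return dest, False
    return open(dest, mode), True


def write_swc(neuron: Neuron, destination: Pathish) -> None:
    """Write ``neuron`` to SWC, dropping states (see module docstring)."""
    segs = [s for s in neuron.segments.values() if s.state is not SegmentState.REMOVED]
    if any(s.state not in (SegmentState.INTACT, SegmentState.REMOVED) for s in neuron.segments.values()):
        warnings.warn("segment damage states are not representable in SWC and were dropped")
    segs.sort(key=lambda s: s.id)
    index = {s.id: i + 2 for i, s in enumerate(segs)}  # 1 is the soma

    fh, close = _opened(destination, "w")
    try:
        fh.write("# SWC export (dendrisnip); soma as single type-1 point\n")
        sx, sy, sz = neuron.soma_position
        fh.write(f"1 1 {sx:.6f} {sy:.6f} {sz:.6f} {neuron.soma_radius:.6f} -1\n")
        for s in segs:
            t = _TYPE_BY_COMPARTMENT.get(
                neuron.branches[s.branch_id].compartment if s.branch_id in neuron.branches else "dendrite", 3
            )
            parent = 1 if s.parent_id == ROOT else index[s.parent_id]
            x, y, z = s.end
            fh.write(f"{index[s.id]} {t} {x:.6f} {y:.6f} {z:.6f} {s.radius:.6f} {parent}\n")
    finally:
        if close:
            fh.close()


def read_swc(source: Pathish, neuron_class: str = "GCL") -> Neuron:
    """Parse an SWC file into a :class:`Neuron`.

    Forward parent references are permitted (samples are resolved after the
    whole file is read).  The first type-1 root sample becomes the soma; every
    other sample becomes a segment from its parent sample's position to its
    own.  Branches, branch points and orders are reconstructed topologically.
    """
    fh, close = _opened(source, "r")
    try:
        lines = fh.readlines()
    finally:
        if close:
            fh.close()

    samples: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SwcError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            idx, typ = int(cols[0]), int(cols[1])
            xyz = np.array([float(cols[2]), float(cols[3]), float(cols[4])])
            radius, parent = float(cols[5]), int(cols[6])
        except ValueError as exc:
            raise SwcError(f"line {lineno}: {exc}") from exc
        if idx in samples:
            raise SwcError(f"line {lineno}: duplicate sample index {idx}")
        samples[idx] = (typ, xyz, radius, parent)

    for idx, (_, _, _, parent) in samples.items():
        if parent != -1 and parent not in samples:
            raise SwcError(f"sample {idx}: parent {parent} does not exist")

    # cycle check via iterative root-ward walk
    for idx in samples:
        seen = set()
        cur = idx
        while cur != -1:
            if cur in seen:
                raise SwcError(f"cyclic parent references involving sample {cur}")
            seen.add(cur)
            cur = samples[cur][3]

    soma_idx = None
    for idx in sorted(samples):
        typ, _, _, parent = samples[idx]
        if parent == -1 and typ == 1:
            soma_idx = idx
            break

    if soma_idx is not None:
        _, soma_pos, soma_rad, _ = samples[soma_idx]
    else:
        soma_pos, soma_rad = np.zeros(3), 1.0

    neuron = Neuron(neuron_class=neuron_class, soma_position=soma_pos, soma_radius=soma_rad)

    children: dict[int, list[int]] = {}
    for idx in sorted(samples):
        if idx == soma_idx:
            continue
        parent = samples[idx][3]
        key = -1 if (parent == -1 or parent == soma_idx) else parent
        children.setdefault(key, []).append(idx)

    # walk branches from the roots
    next_bp = 0
    stack: list[tuple[int, int, int]] = []  # (sample idx, order, parent_bp_id)
    for r in children.get(-1, []):
        stack.append((r, 1, ROOT))
    stack.reverse()
    while stack:
        head, order, parent_bp = stack.pop()
        typ = samples[head][0]
        br = neuron.add_branch(Branch(
            id=len(neuron.branches), order=order, parent_branch_point_id=parent_bp,
            compartment=_COMPARTMENT_BY_TYPE.get(typ, "dendrite"),
        ))
        cur = head
        while True:
            typ, xyz, radius, parent = samples[cur]
            if parent == -1 or parent == soma_idx:
                parent_seg = ROOT
                start = soma_pos
            else:
                parent_seg = parent
                start = samples[parent][1]
            neuron.add_segment(Segment(
                id=cur, parent_id=parent_seg,
                branch_id=br.id, branch_order=order,
                start=start, end=xyz, radius=radius,
            ))
            kids = children.get(cur, [])
            if len(kids) == 1:
                cur = kids[0]
            elif len(kids) == 0:
                break
            else:
                bp = neuron.add_branch_point(BranchPoint(
                    id=next_bp, parent_segment_id=cur, position=xyz,
                ))
                next_bp += 1
                daughters = []
                for k in kids:
                    stack.append((k, order + 1, bp.id))
                    daughters.append(k)
                break
        # daughter branch ids get fixed up after all branches exist
    # second pass: fill daughter_branch_ids from topology
    first_seg_to_branch = {}
    for b in neuron.branches.values():
        if b.segment_ids:
            first_seg_to_branch[b.segment_ids[0]] = b.id
    for bp in neuron.branch_points.values():
        kids = neuron.children(bp.parent_segment_id)
        bp.daughter_branch_ids = tuple(first_seg_to_branch[k] for k in kids if k in first_seg_to_branch)
    return neuron
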