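"""Stochastic dendritic growth engine.

Cylindrical segments are grown outward from the soma.  At every step a
growing tip either elongates or bifurcates; the branching probability is

    P_br = alpha * (1 - exp(-beta * L_i))

where ``L_i`` is the distance grown since the soma or the previous branch
point (measured in segment steps by default, with a config switch to um) and
``alpha`` is an order-dependent maximum branching probability.  Radii taper
with every elongation step and drop by 1/sqrt(2) at bifurcations (equal
daughters conserving cross-sectional area, R_p^2 = R_d1^2 + R_d2^2) until the
tip floor of 0.2 um; a tip then elongates at constant radius for an
exponentially distributed terminal length and stops.  Growing segments that
collide with existing branches (capsule-capsule test) or leave the bounding
volume are retracted and redrawn in a new random direction.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .neuron import ROOT, Branch, BranchPoint, Neuron, Segment
from .regions import Ball, Cone, Hemisphere

__all__ = [
    "AngleModel",
    "CompartmentSpec",
    "GrowthParams",
    "GrowthError",
    "branching_probability",
    "daughter_radius",
    "elongation_step",
    "self_avoidance_check",
    "grow_neuron",
    "grow_population",
]

_SQRT2 = math.sqrt(2.0)


class GrowthError(RuntimeError):
    pass


# ---------------------------------------------------------------- parameters


@dataclass
class AngleModel:
    """Branch half-angle and elongation-wobble distributions (degrees).

    Daughters deviate from the parent direction by half-angles drawn from a
    clipped Normal in a random plane containing the parent axis (the two
    daughters on opposite sides), so the mean full bifurcation angle is about
    twice ``half_angle_mean_deg``.  Elongation directions wobble by a small
    Normal tilt about the previous direction.
    """

    half_angle_mean_deg: float = 28.0
    half_angle_sd_deg: float = 7.0
    half_angle_min_deg: float = 8.0
    half_angle_max_deg: float = 70.0
    wobble_sd_deg: float = 4.0


@dataclass
class CompartmentSpec:
    """Growth constants for one dendritic compartment (field)."""

    label: str = "dendrite"
    n_primaries: int = 1
    primary_directions: list | None = None  # unit vectors; default arranged on the field axis
    initial_radius: float = 3.0
    taper_rate: float = 0.02
    alpha_schedule: dict[int, float] = field(default_factory=lambda: {1: 0.1})
    # terminal length ~ Gamma(shape, mean/shape): mean terminal_length_mean,
    # coefficient of variation 1/sqrt(shape)
    terminal_length_mean: float = 40.0
    terminal_length_shape: float = 4.0
    bounding_volume: Cone | Hemisphere | Ball = field(default_factory=Cone)
    angle_model: AngleModel | None = None


@dataclass
class GrowthParams:
    """All constants of the growth model for one neuron class."""

    neuron_class: str = "GCL"
    beta: float = 0.264
    li_units: str = "steps"  # "steps" | "um"
    tip_radius: float = 0.2
    soma_radius: float = 5.0
    angle_model: AngleModel = field(default_factory=AngleModel)
    compartments: list[CompartmentSpec] = field(default_factory=lambda: [CompartmentSpec()])
    max_retraction_retries: int = 10
    # collide iff axis distance < tolerance * (r1 + r2); the slack below 1
    # tolerates the partial interpenetration that is inevitable where sibling
    # capsules fan out of a shared branch point, while still rejecting
    # retracing or crossing trajectories
    collision_tolerance: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.tip_radius):
            raise ValueError("tip_radius must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        for comp in self.compartments:
            if comp.initial_radius <= self.tip_radius:
                raise ValueError("initial_radius must exceed tip_radius")


def _alpha_for_order(schedule: dict[int, float], order: int) -> float:
    """The schedule defines the branching orders: orders below the smallest
    key use the smallest key's alpha; orders above the largest key do not
    branch (elongation-only), which bounds the topological depth."""
    if order in schedule:
        return schedule[order]
    keys = sorted(schedule)
    if not keys or order > keys[-1]:
        return 0.0
    if order < keys[0]:
        return schedule[keys[0]]
    # gap inside the schedule: use the nearest smaller order
    below = [k for k in keys if k < order]
    return schedule[below[-1]]


# ------------------------------------------------------------ local geometry


def _basis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(v, a)
    u /= np.linalg.norm(u)
    return u, np.cross(v, u)


def _tilt(v: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Unit vector at angle ``theta`` from ``v`` toward azimuth ``phi``."""
    u, w = _basis(v)
    return math.cos(theta) * v + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * w)


def _seg_seg_distance(p1: np.ndarray, q1: np.ndarray, P2: np.ndarray, Q2: np.ndarray) -> np.ndarray:
    """Min distance between segment (p1,q1) and each segment (P2[i],Q2[i])."""
    d1 = q1 - p1
    d2 = Q2 - P2
    r = p1 - P2
    a = float(d1 @ d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = r @ d1
    b = d2 @ d1
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-12, np.clip((b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0.0, 1.0), 0.0)
        t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
        t_cl = np.clip(t, 0.0, 1.0)
        need = t != t_cl
        s = np.where(need, np.clip((b * t_cl - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0, s)
    close1 = p1 + np.outer(s, d1)
    close2 = P2 + d2 * t_cl[:, None]
    return np.linalg.norm(close1 - close2, axis=1)


# ----------------------------------------------------------- spec operations


def branching_probability(L_i: float, alpha: float, beta: float) -> float:
    """Branching probability ``alpha * (1 - exp(-beta * L_i))``.

    Monotone nondecreasing in ``L_i`` and bounded above by ``alpha``.
    """
    if L_i < 0:
        raise ValueError("L_i must be nonnegative")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return alpha * (1.0 - math.exp(-beta * L_i))


def daughter_radius(parent_radius: float, tip_radius: float = 0.2) -> float:
    """Equal-daughter radius from R_p^2 = 2 R_d^2, floored at the tip radius."""
    return max(parent_radius / _SQRT2, tip_radius)


def elongation_step(segment: Segment, params: GrowthParams, rng: np.random.Generator,
                    taper_rate: float | None = None) -> Segment:
    """Candidate child continuing ``segment``: tapered radius, length twice the
    new radius, direction wobbled per the angle model (not yet committed)."""
    if taper_rate is None:
        taper_rate = params.compartments[0].taper_rate
    new_r = max(segment.radius * (1.0 - taper_rate), params.tip_radius)
    am = params.angle_model
    theta = abs(rng.normal(0.0, math.radians(am.wobble_sd_deg)))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    d = _tilt(segment.direction, theta, phi) if theta > 0 else segment.direction
    end = segment.end + 2.0 * new_r * d
    return Segment(id=-1, parent_id=segment.id, branch_id=segment.branch_id,
                   branch_order=segment.branch_order, start=segment.end, end=end, radius=new_r)


def self_avoidance_check(neuron: Neuron, candidate: Segment,
                         tolerance: float = 0.8) -> str:
    """Capsule-capsule test of ``candidate`` against the existing arbor.

    Returns ``"accept"`` or ``"collide"``.  The candidate's parent and its
    siblings at the same attachment point are excluded; a small overlap
    tolerance keeps consecutive co-axial steps (which formally touch) from
    self-colliding.
    """
    exclude = {candidate.parent_id}
    exclude.update(neuron.children(candidate.parent_id))
    if candidate.parent_id in neuron.segments:
        gp = neuron.segments[candidate.parent_id].parent_id
        exclude.update(neuron.children(gp))  # parent's siblings share a joint
    else:
        exclude.update(neuron.root_segment_ids())  # primaries all meet at the soma
    others = [s for s in neuron.segments.values() if s.id not in exclude]
    if not others:
        return "accept"
    P = np.array([s.start for s in others])
    Q = np.array([s.end for s in others])
    R = np.array([s.radius for s in others])
    d = _seg_seg_distance(candidate.start, candidate.end, P, Q)
    return "collide" if np.any(d < tolerance * (candidate.radius + R)) else "accept"


# -------------------------------------------------------------- the engine


@dataclass
class _Tip:
    seg_idx: int
    branch_id: int
    order: int
    steps_since_bp: int
    um_since_bp: float
    direction: np.ndarray
    radius: float
    comp_idx: int
    terminal_remaining: float | None = None


class _Engine:
    def __init__(self, params: GrowthParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.neuron = Neuron(params.neuron_class, soma_radius=params.soma_radius)
        cap = 4096
        self.starts = np.empty((cap, 3))
        self.ends = np.empty((cap, 3))
        self.radii = np.empty(cap)
        self.n = 0
        self.retraction_count = 0

    # -- storage -----------------------------------------------------------
    def _ensure(self, extra: int) -> None:
        if self.n + extra <= len(self.radii):
            return
        cap = max(2 * len(self.radii), self.n + extra)
        for name in ("starts", "ends"):
            buf = np.empty((cap, 3))
            buf[: self.n] = getattr(self, name)[: self.n]
            setattr(self, name, buf)
        buf = np.empty(cap)
        buf[: self.n] = self.radii[: self.n]
        self.radii = buf

    def _commit(self, parent_idx: int, branch_id: int, order: int,
                start: np.ndarray, end: np.ndarray, radius: float) -> int:
        self._ensure(1)
        idx = self.n
        self.starts[idx] = start
        self.ends[idx] = end
        self.radii[idx] = radius
        self.n += 1
        self.neuron.add_segment(Segment(
            id=idx, parent_id=parent_idx if parent_idx >= 0 else ROOT,
            branch_id=branch_id, branch_order=order,
            start=start.copy(), end=end.copy(), radius=radius,
        ))
        return idx

    # -- geometry ----------------------------------------------------------
    def _collides(self, p0: np.ndarray, p1: np.ndarray, rc: float,
                  exclude: tuple[int, ...]) -> bool:
        if self.n == 0:
            return False
        d = _seg_seg_distance(p0, p1, self.starts[: self.n], self.ends[: self.n])
        thresh = self.p.collision_tolerance * (rc + self.radii[: self.n])
        hit = d < thresh
        for idx in exclude:
            if 0 <= idx < self.n:
                hit[idx] = False
        return bool(hit.any())

    def _free(self, comp: CompartmentSpec, p0: np.ndarray, p1: np.ndarray,
              rc: float, exclude: tuple[int, ...]) -> bool:
        return comp.bounding_volume.contains(p1) and not self._collides(p0, p1, rc, exclude)

    def _exclusions(self, parent_idx: int) -> tuple[int, ...]:
        """Parent, siblings and parent's siblings: capsules meeting at the
        same joint or branch point formally touch and are not collisions."""
        ex = [parent_idx]
        ex.extend(self.neuron.children(parent_idx))
        gp = self.neuron.segments[parent_idx].parent_id
        # children(ROOT) are the primaries, which all meet at the soma
        ex.extend(self.neuron.children(gp))
        return tuple(ex)

    # -- growth ------------------------------------------------------------
    def seed_primaries(self) -> deque:
        tips: deque[_Tip] = deque()
        for ci, comp in enumerate(self.p.compartments):
            dirs = comp.primary_directions
            if dirs is None:
                axis = comp.bounding_volume.axis if hasattr(comp.bounding_volume, "axis") else np.array([0, 0, 1.0])
                if comp.n_primaries == 1:
                    dirs = [axis]
                else:
                    # evenly spread about the field axis, 45 deg off-axis
                    dirs = [
                        _tilt(np.asarray(axis, float), math.radians(45.0),
                              2.0 * math.pi * k / comp.n_primaries)
                        for k in range(comp.n_primaries)
                    ]
            for d in dirs[: comp.n_primaries]:
                d = np.asarray(d, dtype=float)
                d = d / np.linalg.norm(d)
                br = self.neuron.add_branch(Branch(
                    id=len(self.neuron.branches), order=1,
                    parent_branch_point_id=ROOT, compartment=comp.label,
                ))
                r0 = comp.initial_radius
                start = np.zeros(3)
                end = start + 2.0 * r0 * d
                idx = self._commit(-1, br.id, 1, start, end, r0)
                tips.append(_Tip(idx, br.id, 1, 1, 2.0 * r0, d, r0, ci))
        return tips

    def _terminal_budget(self, comp: CompartmentSpec) -> float:
        k = comp.terminal_length_shape
        return float(self.rng.gamma(k, comp.terminal_length_mean / k))

    def _redraw_direction(self, base: np.ndarray, attempt: int, wobble_sd_deg: float) -> np.ndarray:
        if attempt == 0:
            theta = abs(self.rng.normal(0.0, math.radians(wobble_sd_deg)))
        else:
            theta = self.rng.uniform(0.0, math.radians(75.0))
        phi = self.rng.uniform(0.0, 2.0 * math.pi)
        return _tilt(base, theta, phi)

    def elongate(self, tip: _Tip) -> bool:
        comp = self.p.compartments[tip.comp_idx]
        am = comp.angle_model or self.p.angle_model
        new_r = max(tip.radius * (1.0 - comp.taper_rate), self.p.tip_radius)
        length = 2.0 * new_r
        start = self.ends[tip.seg_idx]
        exclude = self._exclusions(tip.seg_idx)
        for attempt in range(self.p.max_retraction_retries + 1):
            d = self._redraw_direction(tip.direction, attempt, am.wobble_sd_deg)
            end = start + length * d
            if self._free(comp, start, end, new_r, exclude):
                break
            self.retraction_count += 1
        else:
            return False
        idx = self._commit(tip.seg_idx, tip.branch_id, tip.order, start, end, new_r)
        tip.seg_idx = idx
        tip.direction = d
        tip.radius = new_r
        tip.steps_since_bp += 1
        tip.um_since_bp += length
        if tip.terminal_remaining is None and new_r <= self.p.tip_radius + 1e-12:
            tip.terminal_remaining = self._terminal_budget(comp)
        if tip.terminal_remaining is not None:
            tip.terminal_remaining -= length
            if tip.terminal_remaining <= 0:
                return False
        return True

    def branch(self, tip: _Tip) -> list[_Tip] | None:
        comp = self.p.compartments[tip.comp_idx]
        am = comp.angle_model or self.p.angle_model
        r_d = daughter_radius(tip.radius, self.p.tip_radius)
        length = 2.0 * r_d
        start = self.ends[tip.seg_idx]
        lo = math.radians(am.half_angle_min_deg)
        hi = math.radians(am.half_angle_max_deg)
        mu = math.radians(am.half_angle_mean_deg)
        sd = math.radians(am.half_angle_sd_deg)
        exclude = self._exclusions(tip.seg_idx)
        for _ in range(self.p.max_retraction_retries + 1):
            phi = self.rng.uniform(0.0, 2.0 * math.pi)
            th1 = float(np.clip(self.rng.normal(mu, sd), lo, hi))
            th2 = float(np.clip(self.rng.normal(mu, sd), lo, hi))
            d1 = _tilt(tip.direction, th1, phi)
            d2 = _tilt(tip.direction, th2, phi + math.pi)
            e1 = start + length * d1
            e2 = start + length * d2
            if (self._free(comp, start, e1, r_d, exclude)
                    and self._free(comp, start, e2, r_d, exclude)):
                break
            self.retraction_count += 1
        else:
            return None
        bp = self.neuron.add_branch_point(BranchPoint(
            id=len(self.neuron.branch_points), parent_segment_id=tip.seg_idx,
            position=start.copy(),
        ))
        out: list[_Tip] = []
        daughters = []
        for d, e in ((d1, e1), (d2, e2)):
            br = self.neuron.add_branch(Branch(
                id=len(self.neuron.branches), order=tip.order + 1,
                parent_branch_point_id=bp.id, compartment=comp.label,
            ))
            daughters.append(br.id)
            idx = self._commit(tip.seg_idx, br.id, tip.order + 1, start, e, r_d)
            t = _Tip(idx, br.id, tip.order + 1, 1, length, d, r_d, tip.comp_idx)
            if r_d <= self.p.tip_radius + 1e-12:
                t.terminal_remaining = self._terminal_budget(comp) - length
                if t.terminal_remaining <= 0:
                    t = None  # daughter exhausted immediately; keep the segment
            if t is not None:
                out.append(t)
        bp.daughter_branch_ids = tuple(daughters)
        return out

    def run(self) -> Neuron:
        tips = self.seed_primaries()
        while tips:
            tip = tips.popleft()
            comp = self.p.compartments[tip.comp_idx]
            in_terminal = tip.terminal_remaining is not None
            if not in_terminal:
                L_i = float(tip.steps_since_bp) if self.p.li_units == "steps" else tip.um_since_bp
                alpha = _alpha_for_order(comp.alpha_schedule, tip.order)
                p_br = branching_probability(L_i, alpha, self.p.beta)
            else:
                p_br = 0.0
            if p_br > 0.0 and self.rng.random() < p_br:
                new_tips = self.branch(tip)
                if new_tips is not None:
                    tips.extend(new_tips)
                    continue  # this tip ends at the bifurcation
                # fall through: could not place daughters, elongate instead
            if self.elongate(tip):
                tips.append(tip)
        if self.n == 0:
            raise GrowthError(f"growth failed to place any segment (seed={self.p.seed})")
        self.neuron.metadata.update(
            n_segments=self.n, retractions=self.retraction_count,
        )
        return self.neuron


def grow_neuron(params: GrowthParams, seed=None) -> Neuron:
    """Grow one neuron; fully reproducible from ``(params, seed)``."""
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    engine = _Engine(params, rng)
    neuron = engine.run()
    neuron.metadata["seed"] = repr(seed)
    return neuron


def grow_population(params: GrowthParams, n: int, base_seed: int) -> list[Neuron]:
    """Grow ``n`` independent neurons with per-neuron streams derived from
    ``(base_seed, index)`` so each member is individually reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [grow_neuron(params, seed=(base_seed, i)) for i in range(n)]
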