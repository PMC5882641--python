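"""Growth engine: branching law, radii, self-avoidance, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrisnip import (
    Neuron,
    Segment,
    branching_probability,
    daughter_radius,
    grow_neuron,
    grow_population,
    summarize,
)
from dendrisnip.growth import GrowthParams, elongation_step, self_avoidance_check, _seg_seg_distance
from dendrisnip.neuron import ROOT, Branch
from conftest import mini_growth_params


# ------------------------------------------------------------ branching law


def test_branching_probability_values():
    assert branching_probability(0.0, 0.2, 0.264) == 0.0
    assert branching_probability(1e9, 0.2, 0.264) == pytest.approx(0.2)
    assert branching_probability(10.0, 0.2, 0.264) == pytest.approx(0.18572774608872278)


@given(
    L=st.floats(0, 1e3), dL=st.floats(0, 1e3),
    alpha=st.floats(0, 1), beta=st.floats(0.001, 10),
)
@settings(max_examples=200, deadline=None)
def test_branching_probability_monotone_and_bounded(L, dL, alpha, beta):
    p1 = branching_probability(L, alpha, beta)
    p2 = branching_probability(L + dL, alpha, beta)
    assert 0.0 <= p1 <= p2 <= alpha


def test_branching_probability_domain_errors():
    with pytest.raises(ValueError):
        branching_probability(-1.0, 0.2, 0.264)
    with pytest.raises(ValueError):
        branching_probability(1.0, 1.5, 0.264)
    with pytest.raises(ValueError):
        branching_probability(1.0, 0.2, 0.0)


# ------------------------------------------------------------ radius rules


def test_daughter_radius_cross_section_conserving():
    r_d = daughter_radius(3.0)
    assert r_d == pytest.approx(2.1213203435596424)
    assert 3.0**2 == pytest.approx(2 * r_d**2, abs=1e-12)


def test_daughter_radius_floor():
    assert daughter_radius(0.2 * math.sqrt(2)) == pytest.approx(0.2)
    assert daughter_radius(0.01) == 0.2


@given(r=st.floats(0.3, 3.0))
@settings(max_examples=50, deadline=None)
def test_daughter_radius_identity(r):
    d = daughter_radius(r, tip_radius=0.0)
    assert r**2 == pytest.approx(2 * d**2, rel=1e-12)


def _tip_segment(radius=3.0):
    return Segment(id=0, parent_id=ROOT, branch_id=0, branch_order=1,
                   start=np.zeros(3), end=np.array([0, 0, 2.0 * radius]), radius=radius)


def test_elongation_step_taper_and_length():
    params = mini_growth_params()
    rng = np.random.default_rng(0)
    child = elongation_step(_tip_segment(3.0), params, rng, taper_rate=0.02)
    assert child.radius == pytest.approx(2.94)
    assert child.length == pytest.approx(5.88)
    np.testing.assert_allclose(child.start, [0, 0, 6.0])


def test_elongation_step_zero_taper_zero_wobble_collinear():
    params = mini_growth_params()
    params.angle_model.wobble_sd_deg = 0.0
    rng = np.random.default_rng(0)
    child = elongation_step(_tip_segment(1.0), params, rng, taper_rate=0.0)
    assert child.radius == 1.0
    np.testing.assert_allclose(child.direction, [0, 0, 1.0], atol=1e-12)


# ----------------------------------------------------------- self-avoidance


def _chain_neuron(k=3, radius=0.5):
    n = Neuron()
    n.add_branch(Branch(id=0))
    for i in range(k):
        n.add_segment(Segment(
            id=i, parent_id=i - 1 if i else ROOT, branch_id=0, branch_order=1,
            start=np.array([0, 0, 2.0 * radius * i]),
            end=np.array([0, 0, 2.0 * radius * (i + 1)]), radius=radius,
        ))
    return n


def test_first_segment_always_accepted():
    n = Neuron()
    n.add_branch(Branch(id=0))
    cand = Segment(id=99, parent_id=ROOT, branch_id=0, branch_order=1,
                   start=np.zeros(3), end=np.array([0, 0, 1.0]), radius=0.5)
    assert self_avoidance_check(n, cand) == "accept"


def test_retracing_candidate_collides_via_grandparent():
    n = _chain_neuron(3)
    last = n.segments[2]
    cand = Segment(id=99, parent_id=2, branch_id=0, branch_order=1,
                   start=last.end, end=last.start - np.array([0, 0, 0.9]),
                   radius=last.radius)
    assert self_avoidance_check(n, cand) == "collide"


def test_straight_continuation_accepted():
    n = _chain_neuron(3)
    last = n.segments[2]
    cand = Segment(id=99, parent_id=2, branch_id=0, branch_order=1,
                   start=last.end, end=last.end + np.array([0, 0, 1.0]),
                   radius=last.radius)
    assert self_avoidance_check(n, cand) == "accept"


def test_parallel_branches_10um_apart_accepted():
    n = _chain_neuron(3)
    # second primary 10 um away in x
    n.add_branch(Branch(id=1))
    n.add_segment(Segment(id=10, parent_id=ROOT, branch_id=1, branch_order=1,
                          start=np.array([10.0, 0, 0]), end=np.array([10.0, 0, 1.0]),
                          radius=0.5))
    cand = Segment(id=99, parent_id=10, branch_id=1, branch_order=1,
                   start=np.array([10.0, 0, 1.0]), end=np.array([10.0, 0, 2.0]),
                   radius=0.5)
    assert self_avoidance_check(n, cand) == "accept"


def test_no_nonadjacent_overlaps_in_grown_neuron():
    """Post hoc capsule scan honouring the engine's adjacency rule."""
    params = mini_growth_params()
    n = grow_neuron(params, seed=5)
    segs = sorted(n.segments.values(), key=lambda s: s.id)
    P = np.array([s.start for s in segs])
    Q = np.array([s.end for s in segs])
    R = np.array([s.radius for s in segs])
    for s in segs:
        exclude = {s.id, s.parent_id}
        exclude.update(n.children(s.id))
        exclude.update(n.children(s.parent_id))
        if s.parent_id in n.segments:
            exclude.update(n.children(n.segments[s.parent_id].parent_id))
        else:
            exclude.update(n.root_segment_ids())
        d = _seg_seg_distance(s.start, s.end, P, Q)
        mask = np.ones(len(segs), dtype=bool)
        for e in exclude:
            if 0 <= e < len(segs):
                mask[e] = False
        assert not np.any(d[mask] < params.collision_tolerance * (s.radius + R[mask]))


# ------------------------------------------------------------- whole trees


def test_zero_alpha_gives_unbranched_dendrite():
    params = mini_growth_params(alpha=0.0)
    n = grow_neuron(params, seed=1)
    assert len(n.branch_points) == 0
    assert len(n.branches) == 1


def test_growth_is_deterministic():
    params = mini_growth_params()
    a = grow_neuron(params, seed=123)
    b = grow_neuron(params, seed=123)
    assert a.to_json() == b.to_json()


def test_population_member_reproducible():
    params = mini_growth_params()
    pop = grow_population(params, 3, base_seed=9)
    again = grow_neuron(params, seed=(9, 2))
    assert pop[2].to_json() == again.to_json()


def test_radii_nonincreasing_and_aspect_ratio(gcl_neuron):
    for s in gcl_neuron.segments.values():
        assert s.length == pytest.approx(2 * s.radius, rel=1e-9)
        if s.parent_id != ROOT:
            assert s.radius <= gcl_neuron.segments[s.parent_id].radius + 1e-12


def test_more_branching_probability_more_branch_points():
    """One-sided comparison of mean branch points over 100 neurons each."""
    lo = [len(grow_neuron(mini_growth_params(alpha=0.08), seed=(1, i)).branch_points)
          for i in range(100)]
    hi = [len(grow_neuron(mini_growth_params(alpha=0.25), seed=(1, i)).branch_points)
          for i in range(100)]
    assert np.mean(hi) > np.mean(lo)


def test_per_order_branch_counts_unimodal(gcl_population):
    """Branch number vs order rises to a single peak then falls."""
    counts = {}
    for n in gcl_population:
        for order, (cnt, _) in summarize(n).per_order.items():
            counts[order] = counts.get(order, 0) + cnt
    seq = [counts[o] for o in sorted(counts)]
    peak = int(np.argmax(seq))
    assert all(a <= b for a, b in zip(seq[:peak], seq[1:peak + 1]))
    assert all(a >= b for a, b in zip(seq[peak:], seq[peak + 1:]))


def test_ca1_has_both_compartments(ca1_population):
    n = ca1_population[0]
    comps = {b.compartment for b in n.branches.values()}
    assert comps == {"apical", "basal"}
    assert summarize(n, "apical").n_primaries == 1
    assert summarize(n, "basal").n_primaries == 3
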