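"""Damage model: dose response, SSA kinetics, snip propagation, population
correction — each against closed forms or brute-force enumeration."""

import math

import numpy as np
import pytest

from dendrisnip import (
    DamageParams,
    SegmentState,
    assign_initial_damage,
    characteristic_dose,
    damage_probability,
    damage_preset,
    gillespie_kinetics,
    irradiate_experiment,
    irradiate_single,
    select_and_apply_snips,
    single_to_population,
    snip_rate_constants,
    summarize,
)
from dendrisnip.damage import DamageSubstrate
from dendrisnip.growth import grow_neuron
from conftest import mini_growth_params

GCL_GAMMA = damage_preset("GCL-gamma")


# ------------------------------------------------------------ dose response


def test_characteristic_dose_half_saturation():
    # V^eta == K is the Hill half-saturation point
    V = GCL_GAMMA.K ** (1.0 / GCL_GAMMA.eta)
    assert characteristic_dose(V, GCL_GAMMA) == pytest.approx(GCL_GAMMA.D_m / 2)


def test_characteristic_dose_saturates_at_Dm():
    assert characteristic_dose(1e12, GCL_GAMMA) == pytest.approx(3000.0)


def test_characteristic_dose_frozen_value():
    # r = 0.3 um segment: V = pi * 0.09 * 0.6
    V = math.pi * 0.09 * 0.6
    assert characteristic_dose(V, GCL_GAMMA) == pytest.approx(502.2805581136149, rel=1e-9)


def test_characteristic_dose_monotone_in_volume():
    v = np.linspace(0.01, 5.0, 200)
    dd = characteristic_dose(v, GCL_GAMMA)
    assert np.all(np.diff(dd) > 0)


def test_characteristic_dose_domain_error():
    with pytest.raises(ValueError):
        characteristic_dose(0.0, GCL_GAMMA)


def test_damage_probability_anchors():
    V = 0.5
    Dd = characteristic_dose(V, GCL_GAMMA)
    assert damage_probability(0.0, V, GCL_GAMMA) == 0.0
    assert damage_probability(Dd, V, GCL_GAMMA) == pytest.approx(1 - math.exp(-1))
    assert damage_probability(2 * Dd, V, GCL_GAMMA) == pytest.approx(1 - math.exp(-2))


def test_damage_probability_small_segments_more_sensitive():
    p_small = damage_probability(1.0, 0.05, GCL_GAMMA)
    p_large = damage_probability(1.0, 1.0, GCL_GAMMA)
    assert p_small > p_large


def test_snip_rate_constants_linear_quadratic():
    a_r, a_s = snip_rate_constants(0.0, GCL_GAMMA)
    assert (a_r, a_s) == (0.0, 0.0)
    _, s1 = snip_rate_constants(1.0, GCL_GAMMA)
    _, s2 = snip_rate_constants(2.0, GCL_GAMMA)
    assert s2 >= 2 * s1  # convexity for b >= 0
    a_r10, a_s10 = snip_rate_constants(10.0, GCL_GAMMA)
    assert a_r10 == pytest.approx(0.5 * a_s10)
    # mean resolution time at 10 Gy well inside the 30-day window
    assert 1.0 / (a_r10 + a_s10) <= 6.0


def test_all_damage_resolved_by_30_days_for_low_dose():
    a_r, a_s = snip_rate_constants(0.5, GCL_GAMMA)
    assert math.exp(-(a_r + a_s) * 30.0) < 0.01


# ---------------------------------------------------------------- assignment


def test_assign_no_dose_no_damage(gcl_neuron):
    damaged, _ = assign_initial_damage(gcl_neuron, 0.0, GCL_GAMMA, np.random.default_rng(0))
    assert damaged == []


def test_assign_huge_dose_damages_nearly_all(gcl_neuron):
    damaged, p = assign_initial_damage(gcl_neuron, 1e6, GCL_GAMMA, np.random.default_rng(0))
    assert len(damaged) > 0.99 * len(gcl_neuron.segments)


def test_assign_ordered_by_increasing_probability(gcl_neuron):
    damaged, p = assign_initial_damage(gcl_neuron, 1.0, GCL_GAMMA, np.random.default_rng(1))
    probs = [p[sid] for sid in damaged]
    assert probs == sorted(probs)


def test_assign_matches_binomial_oracle(gcl_neuron):
    """Mean damaged count over 1000 trials within 3 SE of sum(P_d)."""
    sub = DamageSubstrate(gcl_neuron)
    p = sub.p_damage(1.0, GCL_GAMMA)
    rng = np.random.default_rng(7)
    counts = [int(np.sum(rng.random(sub.n) < p)) for _ in range(1000)]
    se = math.sqrt(float(np.sum(p * (1 - p))) / 1000)
    assert abs(np.mean(counts) - p.sum()) < 3 * se


# ------------------------------------------------------------------ kinetics


def test_gillespie_zero_damaged_flat():
    traj = gillespie_kinetics(0, 5.0, 30.0, GCL_GAMMA, np.random.default_rng(0), n_total=50)
    assert len(traj.event_times) == 0
    assert traj.counts_at(30.0) == (50, 0, 0)


def test_gillespie_conservation_along_trajectory():
    traj = gillespie_kinetics(200, 2.0, 60.0, GCL_GAMMA, np.random.default_rng(3), n_total=500)
    for t, s0, sd, ss in traj.time_course:
        assert s0 + sd + ss == 500
        assert min(s0, sd, ss) >= 0


def test_gillespie_mean_matches_exponential_decay():
    """SSA mean trajectory at S_d(0)=1e4 tracks n*exp(-(aR+aS)t) within 1%."""
    n0, n_rep = 10_000, 25
    a_r, a_s = snip_rate_constants(1.0, GCL_GAMMA)
    lam = a_r + a_s
    rng = np.random.default_rng(5)
    trajs = [gillespie_kinetics(n0, 1.0, 30.0, GCL_GAMMA, rng) for _ in range(n_rep)]
    for frac in (0.3, 0.7, 1.0):
        t = frac / lam
        mean_sd = np.mean([tr.counts_at(t)[1] for tr in trajs])
        assert mean_sd == pytest.approx(n0 * math.exp(-lam * t), rel=0.01)


def test_gillespie_asymptotic_snip_fraction():
    """Snipped fraction -> alpha_S/(alpha_R+alpha_S) = 2/3, within 3 SE."""
    rng = np.random.default_rng(11)
    n_trials, n0 = 1000, 10
    snipped = sum(
        gillespie_kinetics(n0, 1.0, 1e4, GCL_GAMMA, rng).snipped_at(1e4)
        for _ in range(n_trials)
    )
    total = n_trials * n0
    p = 2.0 / 3.0
    se = math.sqrt(p * (1 - p) / total)
    assert abs(snipped / total - p) < 3 * se


def test_gillespie_protracted_mode_not_implemented():
    params = damage_preset("GCL-gamma")
    params.exposure_mode = "protracted"
    with pytest.raises(NotImplementedError):
        gillespie_kinetics(10, 1.0, 30.0, params, np.random.default_rng(0))


# ---------------------------------------------------------- snip propagation


def test_snip_single_tip_removes_only_it(ybranch):
    tip = 3
    out = select_and_apply_snips(ybranch, [tip], 1)
    removed = {s.id for s in out.segments.values() if s.state is SegmentState.REMOVED}
    assert removed == {tip}


def test_snip_root_removes_whole_tree(ybranch):
    out = select_and_apply_snips(ybranch, [0], 1)
    removed = {s.id for s in out.segments.values() if s.state is SegmentState.REMOVED}
    assert removed == set(ybranch.segments)


def test_proximal_snip_dominates(ybranch):
    # snips on the trunk's 2nd segment and one daughter tip: the proximal
    # snip removes the suffix and both daughters
    out = select_and_apply_snips(ybranch, [3, 1], 2)
    removed = {s.id for s in out.segments.values() if s.state is SegmentState.REMOVED}
    assert removed == ybranch.distal_subtree(1)


def test_unsnipped_damaged_marked_repaired(ybranch):
    out = select_and_apply_snips(ybranch, [0, 3], 1)
    assert out.segments[0].state is SegmentState.REPAIRED
    assert out.segments[3].state is SegmentState.REMOVED


def test_snip_propagation_matches_brute_force_on_random_trees():
    """Removal set == union of distal subtrees; applying twice is a no-op."""
    for i in range(100):
        neuron = grow_neuron(mini_growth_params(alpha=0.2), seed=(100, i))
        ids = sorted(neuron.segments)
        rng = np.random.default_rng(i)
        k = rng.integers(1, max(2, len(ids) // 5))
        snips = list(rng.choice(ids, size=k, replace=False))
        out = select_and_apply_snips(neuron, snips, len(snips))
        removed = {s.id for s in out.segments.values() if s.state is SegmentState.REMOVED}
        brute = set()
        for sid in snips:
            brute |= neuron.distal_subtree(sid)
        assert removed == brute
        # idempotence: reapplying the removal pass changes nothing
        again = select_and_apply_snips(out, [], 0)
        removed2 = {s.id for s in again.segments.values() if s.state is SegmentState.REMOVED}
        assert removed2 == removed


# ----------------------------------------------------- population conversion


def test_population_factor_at_characteristic_dose():
    assert single_to_population(1.0, 25.0, GCL_GAMMA) == pytest.approx(math.exp(-1))
    assert single_to_population(0.8, 0.0, GCL_GAMMA) == 0.8


def test_population_requires_D0():
    with pytest.raises(ValueError, match="D0"):
        single_to_population(1.0, 1.0, damage_preset("CA1-apical-proton"))


def test_population_arithmetic():
    params = DamageParams(D_m=2000, eta=3, D0=10.0 / math.log(2))  # F_N(10) = 0.5
    assert single_to_population(0.8, 10.0, params) == pytest.approx(0.4)


# ------------------------------------------------------------- experiments


def test_substrate_metrics_match_neuron_path(gcl_neuron):
    """Array fast path agrees with the tree-mutating reference path."""
    sub = DamageSubstrate(gcl_neuron)
    rng = np.random.default_rng(42)
    damaged, _ = assign_initial_damage(gcl_neuron, 5.0, GCL_GAMMA, rng)
    k = len(damaged) // 2
    out = select_and_apply_snips(gcl_neuron, damaged, k)
    ref = summarize(out)
    idx_of = {int(i): j for j, i in enumerate(sub.ids)}
    sites = np.array([idx_of[s] for s in damaged[len(damaged) - k:]], dtype=int)
    tl, bn, bp = sub.metrics(sub.removal_mask(sites))
    assert tl == pytest.approx(ref.total_length)
    assert bn == ref.n_branches
    assert bp == ref.n_branch_points


def test_zero_dose_all_ratios_one(gcl_neuron):
    res = irradiate_experiment([gcl_neuron], [0.0], [10.0, 30.0], GCL_GAMMA,
                               n_trials=3, base_seed=0)
    singles = res.table[res.table["mode"] == "single"]
    ratios = singles[singles.metric.isin(["tl", "bn", "bp"])]
    assert np.allclose(ratios["mean"], 1.0)
    assert np.allclose(ratios["sem"], 0.0)


def test_ratios_nonincreasing_in_time_per_trial(gcl_neuron):
    outs = irradiate_single(gcl_neuron, 2.0, [5.0, 10.0, 30.0], GCL_GAMMA,
                            np.random.default_rng(3))
    tls = [o.single_ratios.tl for o in outs]
    assert tls[0] >= tls[1] >= tls[2]
    snips = [len(o.snipped_ids) for o in outs]
    assert snips[0] <= snips[1] <= snips[2]


def test_population_below_single_for_positive_dose(gcl_neuron):
    res = irradiate_experiment([gcl_neuron], [1.0, 5.0], [30.0], GCL_GAMMA,
                               n_trials=4, base_seed=1)
    tbl = res.table[res.table.metric == "tl"].pivot_table(
        index="dose", columns="mode", values="mean")
    assert (tbl["population"] < tbl["single"]).all()


def test_mean_damage_monotone_in_dose(gcl_neuron):
    res = irradiate_experiment([gcl_neuron], [1.0, 10.0], [30.0], GCL_GAMMA,
                               n_trials=10, base_seed=2)
    tbl = res.table[(res.table.metric == "tl") & (res.table["mode"] == "population")]
    lo = tbl[tbl.dose == 1.0]["mean"].item()
    hi = tbl[tbl.dose == 10.0]["mean"].item()
    assert hi < lo
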