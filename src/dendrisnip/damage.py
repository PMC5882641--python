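"""Radiation-induced dendritic damage model.

Two components:

1. A probabilistic per-segment damage assignment.  A segment of volume
   ``V_s`` (um^3) exposed to an average dose ``D`` (Gy) is damaged with

       P_d = 1 - exp(-D / D_d),      D_d = D_m * V_s^eta / (K + V_s^eta)

   where ``D_d`` is the characteristic dose at which 37% of segments stay
   undamaged — a Hill-type function of segment volume, so small distal
   segments are the most radiosensitive.

2. First-order kinetics of the damaged pool.  Each damaged segment is
   eventually repaired (rate ``alpha_R``) or snipped (rate ``alpha_S``); for
   acute exposure the ODE system

       dS0/dt = +alpha_R S_d,  dSd/dt = -(alpha_R + alpha_S) S_d,
       dSs/dt = +alpha_S S_d

   is solved exactly as a stochastic jump process (Gillespie's direct
   method), since segments are discrete.  ``alpha_S`` is linear-quadratic in
   dose and ``alpha_R`` a fixed fraction of it (default 0.5).

Snip events are mapped onto the most damage-probable segments still in the
damaged pool; a snipped segment takes its whole distal subtree with it.
Population-level read-outs multiply single-neuron ratios by the surviving
fraction of neurons, F_N = exp(-D / D_0).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import Ratios, ShollProfile, ratio_to_control, sholl, summarize
from .neuron import ROOT, Neuron, SegmentState

__all__ = [
    "DamageParams",
    "DamageOutcome",
    "KineticsResult",
    "characteristic_dose",
    "damage_probability",
    "snip_rate_constants",
    "assign_initial_damage",
    "gillespie_kinetics",
    "select_and_apply_snips",
    "single_to_population",
    "DamageSubstrate",
    "irradiate_single",
    "irradiate_experiment",
    "ExperimentResult",
]


@dataclass
class DamageParams:
    """Damage-model constants for one neuron type / radiation quality.

    ``K`` has units um^(3*eta) so that ``V_s`` enters in um^3; ``D_m`` is the
    saturation characteristic dose; ``D0`` (optional) converts single-neuron
    ratios to population ratios.  ``alphaS_a``/``alphaS_b`` are the linear and
    quadratic coefficients of the dose-dependent snip rate constant
    (1/(Gy day), 1/(Gy^2 day)); their defaults make essentially all damage
    resolve by 30 days post exposure for doses of 0.5 Gy and above.
    """

    K: float = 0.01
    D_m: float = 3000.0
    eta: float = 3.5
    D0: float | None = None
    alphaS_a: float = 0.205
    alphaS_b: float = 0.004
    repair_fraction: float = 0.5
    exposure_mode: str = "acute"
    alpha_d: float = 0.0  # protracted-exposure damage rate; parsed, unused in acute mode

    def __post_init__(self) -> None:
        if self.K <= 0 or self.D_m <= 0 or self.eta <= 0:
            raise ValueError("K, D_m and eta must be positive")
        if self.repair_fraction < 0:
            raise ValueError("repair_fraction must be nonnegative")


@dataclass
class KineticsResult:
    """One stochastic trajectory of the damaged-segment pool."""

    n_total: int  # S0 + Sd + Ss at all times
    n_damaged0: int
    event_times: np.ndarray  # sorted
    event_is_snip: np.ndarray  # bool, parallel to event_times
    t_end: float

    def snipped_at(self, t: float) -> int:
        k = bisect.bisect_right(self.event_times.tolist(), t)
        return int(np.count_nonzero(self.event_is_snip[:k]))

    def repaired_at(self, t: float) -> int:
        k = bisect.bisect_right(self.event_times.tolist(), t)
        return k - int(np.count_nonzero(self.event_is_snip[:k]))

    def counts_at(self, t: float) -> tuple[int, int, int]:
        """(S0, Sd, Ss) at time ``t``; S0 counts undamaged + repaired."""
        s = self.snipped_at(t)
        r = self.repaired_at(t)
        return (self.n_total - self.n_damaged0 + r, self.n_damaged0 - r - s, s)

    @property
    def time_course(self) -> list[tuple[float, int, int, int]]:
        out = [(0.0, *self.counts_at(0.0))]
        for t in self.event_times:
            out.append((float(t), *self.counts_at(float(t))))
        if not self.event_times.size or self.event_times[-1] < self.t_end:
            out.append((self.t_end, *self.counts_at(self.t_end)))
        return out


@dataclass
class DamageOutcome:
    """Per-trial record of one (neuron, dose) irradiation."""

    dose: float
    time: float
    trial_seed: object
    damaged_ids: set[int]
    repaired_ids: set[int]
    snipped_ids: set[int]
    time_course: list[tuple[float, int, int, int]]
    single_ratios: Ratios
    population_ratios: Ratios | None
    sholl_post: ShollProfile | None = None


# ----------------------------------------------------------- dose response


def characteristic_dose(V_s, params: DamageParams):
    """Hill-type characteristic dose D_d(V_s); saturates at D_m."""
    V = np.asarray(V_s, dtype=float)
    if np.any(V <= 0):
        raise ValueError("segment volume must be positive")
    Veta = V**params.eta
    out = params.D_m * Veta / (params.K + Veta)
    return float(out) if np.isscalar(V_s) else out


def damage_probability(D: float, V_s, params: DamageParams):
    """P_d = 1 - exp(-D / D_d(V_s)); increasing in dose, decreasing in volume."""
    if D < 0:
        raise ValueError("dose must be nonnegative")
    Dd = characteristic_dose(V_s, params)
    return 1.0 - np.exp(-D / Dd) if not np.isscalar(V_s) else 1.0 - math.exp(-D / Dd)


def snip_rate_constants(D: float, params: DamageParams) -> tuple[float, float]:
    """(alpha_R, alpha_S) per day at dose ``D``; alpha_S = a*D + b*D^2."""
    if D < 0:
        raise ValueError("dose must be nonnegative")
    a_s = params.alphaS_a * D + params.alphaS_b * D * D
    return params.repair_fraction * a_s, a_s


def single_to_population(single_ratio: float, D: float, params: DamageParams) -> float:
    """Population ratio = F_N * single ratio with F_N = exp(-D / D_0)."""
    if D < 0:
        raise ValueError("dose must be nonnegative")
    if params.D0 is None:
        raise ValueError(
            "population conversion requires D0 (the 37% neuron-survival dose); "
            "set DamageParams.D0 for this preset"
        )
    return math.exp(-D / params.D0) * single_ratio


# -------------------------------------------------------------- assignment


def assign_initial_damage(neuron: Neuron, D: float, params: DamageParams,
                          rng: np.random.Generator) -> tuple[list[int], dict[int, float]]:
    """Flag each segment damaged with probability P_d(D, V_s).

    Returns the damaged IDs ordered by increasing P_d (ties broken by ID) and
    the per-segment probability map.
    """
    segs = sorted(
        (s for s in neuron.segments.values() if s.state is not SegmentState.REMOVED),
        key=lambda s: s.id,
    )
    vols = np.array([s.volume for s in segs])
    ids = np.array([s.id for s in segs])
    p = damage_probability(D, vols, params) if len(segs) else np.array([])
    u = rng.random(len(segs))
    hit = u < p
    order = np.lexsort((ids[hit], p[hit]))
    damaged = [int(i) for i in ids[hit][order]]
    return damaged, {int(i): float(q) for i, q in zip(ids, p)}


# ----------------------------------------------------------------- kinetics


def gillespie_kinetics(n_damaged: int, D: float, t_end: float, params: DamageParams,
                       rng: np.random.Generator, n_total: int | None = None) -> KineticsResult:
    """Exact SSA over the two first-order channels repair/snip.

    Starting from ``S_d = n_damaged`` the total event rate is
    ``(alpha_R + alpha_S) * S_d``; each event is a snip with probability
    ``alpha_S / (alpha_R + alpha_S)``.  Conservation S0 + Sd + Ss holds by
    construction.
    """
    if n_damaged < 0:
        raise ValueError("n_damaged must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if params.exposure_mode != "acute":
        raise NotImplementedError("only acute exposure kinetics are implemented")
    if n_total is None:
        n_total = n_damaged
    a_r, a_s = snip_rate_constants(D, params)
    total_rate_1 = a_r + a_s
    times: list[float] = []
    snips: list[bool] = []
    t = 0.0
    s_d = n_damaged
    if total_rate_1 > 0:
        p_snip = a_s / total_rate_1
        while s_d > 0:
            t += rng.exponential(1.0 / (total_rate_1 * s_d))
            if t > t_end:
                break
            times.append(t)
            snips.append(rng.random() < p_snip)
            s_d -= 1
    return KineticsResult(
        n_total=n_total, n_damaged0=n_damaged,
        event_times=np.array(times), event_is_snip=np.array(snips, dtype=bool),
        t_end=t_end,
    )


# ---------------------------------------------------------------- snipping


def select_and_apply_snips(neuron: Neuron, ordered_damaged_ids: list[int],
                           snipped_count: int, in_place: bool = False) -> Neuron:
    """Mark the ``snipped_count`` highest-P_d damaged segments snipped, the
    rest repaired, then remove everything distal to any snip site
    (inclusive).  A snip site distal to a more proximal snip is absorbed by
    the same removal pass.  Returns a (by default new) neuron.
    """
    if snipped_count > len(ordered_damaged_ids):
        raise ValueError("snipped_count exceeds the damaged set")
    out = neuron if in_place else neuron.copy()
    snip_ids = ordered_damaged_ids[len(ordered_damaged_ids) - snipped_count:]
    repaired = ordered_damaged_ids[: len(ordered_damaged_ids) - snipped_count]
    for sid in repaired:
        out.segments[sid].state = SegmentState.REPAIRED
    for sid in snip_ids:
        out.segments[sid].state = SegmentState.SNIPPED
    removed: set[int] = set()
    for sid in snip_ids:
        if sid not in removed:
            removed |= out.distal_subtree(sid)
    for sid in removed:
        out.segments[sid].state = SegmentState.REMOVED
    return out


# ------------------------------------------------------------- fast substrate


class DamageSubstrate:
    """Array view of a neuron (optionally one compartment) for Monte-Carlo
    irradiation without copying the tree per trial."""

    def __init__(self, neuron: Neuron, compartment: str = "all"):
        self.neuron = neuron
        self.compartment = compartment
        segs = []
        for s in neuron.segments.values():
            if s.state is SegmentState.REMOVED:
                continue
            if compartment != "all":
                br = neuron.branches.get(s.branch_id)
                if br is None or br.compartment != compartment:
                    continue
            segs.append(s)
        segs.sort(key=lambda s: s.id)
        self.ids = np.array([s.id for s in segs], dtype=int)
        idx_of = {int(i): k for k, i in enumerate(self.ids)}
        self.parent = np.array(
            [idx_of.get(s.parent_id, -1) for s in segs], dtype=int
        )
        self.children: list[list[int]] = [[] for _ in segs]
        for k, pk in enumerate(self.parent):
            if pk >= 0:
                self.children[pk].append(k)
        self.lengths = np.array([s.length for s in segs])
        self.volumes = np.array([s.volume for s in segs])
        center = neuron.soma_position
        a = np.array([np.linalg.norm(s.start - center) for s in segs])
        b = np.array([np.linalg.norm(s.end - center) for s in segs])
        self.r_lo, self.r_hi = np.minimum(a, b), np.maximum(a, b)
        self.n = len(segs)
        self.control = self.metrics(np.zeros(self.n, dtype=bool))
        self._p_cache: dict[tuple[float, int], np.ndarray] = {}

    def p_damage(self, D: float, params: DamageParams) -> np.ndarray:
        key = (D, id(params))
        if key not in self._p_cache:
            self._p_cache[key] = damage_probability(D, self.volumes, params) if self.n else np.array([])
        return self._p_cache[key]

    def removal_mask(self, snip_indices: np.ndarray) -> np.ndarray:
        removed = np.zeros(self.n, dtype=bool)
        stack = list(snip_indices)
        while stack:
            k = stack.pop()
            if removed[k]:
                continue
            removed[k] = True
            stack.extend(self.children[k])
        return removed

    def metrics(self, removed: np.ndarray) -> tuple[float, int, int]:
        """(total length, branch number, branch points) of the kept arbor."""
        kept = ~removed
        tl = float(self.lengths[kept].sum())
        kept_child_count = np.zeros(self.n, dtype=int)
        src = kept & (self.parent >= 0)
        np.add.at(kept_child_count, self.parent[src], 1)
        bp = int(np.count_nonzero(kept & (kept_child_count >= 2)))
        prim = int(np.count_nonzero(kept & (self.parent < 0)))
        return tl, 2 * bp + prim, bp

    def sholl_counts(self, removed: np.ndarray, radii: np.ndarray) -> np.ndarray:
        kept = ~removed
        lo, hi = self.r_lo[kept], self.r_hi[kept]
        counts = np.zeros(len(radii), dtype=int)
        for i, r in enumerate(radii):
            if r == 0:
                counts[i] = int(np.count_nonzero(kept & (self.parent < 0)))
            else:
                counts[i] = int(np.sum((lo < r) & (r <= hi)))
        return counts


def _ordered_damaged(p: np.ndarray, u: np.ndarray) -> np.ndarray:
    hit = np.flatnonzero(u < p)
    return hit[np.lexsort((hit, p[hit]))]  # ascending P_d, ties by index


def irradiate_single(neuron: Neuron, dose: float, times, params: DamageParams,
                     rng: np.random.Generator, compartment: str = "all",
                     sholl_step: float | None = None,
                     substrate: DamageSubstrate | None = None) -> list[DamageOutcome]:
    """One Monte-Carlo trial: damage assignment, one shared kinetics
    trajectory, snips applied at each checkpoint time.

    ``times`` are checkpoints of a single trajectory, not independent re-runs.
    """
    sub = substrate if substrate is not None else DamageSubstrate(neuron, compartment)
    times = sorted(float(t) for t in np.atleast_1d(times))
    p = sub.p_damage(dose, params)
    u = rng.random(sub.n)
    ordered = _ordered_damaged(p, u)
    traj = gillespie_kinetics(len(ordered), dose, max(times), params, rng, n_total=sub.n)
    tl0, bn0, bp0 = sub.control
    outcomes = []
    for t in times:
        k_snip = traj.snipped_at(t)
        k_rep = traj.repaired_at(t)
        sites = ordered[len(ordered) - k_snip:] if k_snip else np.array([], dtype=int)
        removed = sub.removal_mask(sites)
        tl, bn, bp = sub.metrics(removed)
        single = Ratios(tl / tl0, bn / bn0, bp / bp0 if bp0 else 1.0)
        pop = None
        if params.D0 is not None:
            f = math.exp(-dose / params.D0)
            pop = Ratios(f * single.tl, f * single.bn, f * single.bp)
        prof = None
        if sholl_step is not None:
            rmax = float(sub.r_hi.max()) if sub.n else 0.0
            radii = sholl_step * np.arange(0, int(math.ceil(rmax / sholl_step)) + 1)
            prof = ShollProfile(radii, sub.sholl_counts(removed, radii), compartment)
        repaired_order_ids = sub.ids[ordered[:k_rep]] if k_rep else np.array([], dtype=int)
        outcomes.append(DamageOutcome(
            dose=dose, time=t, trial_seed=None,
            damaged_ids=set(int(i) for i in sub.ids[ordered]),
            repaired_ids=set(int(i) for i in repaired_order_ids),
            snipped_ids=set(int(i) for i in sub.ids[sites]),
            time_course=traj.time_course,
            single_ratios=single, population_ratios=pop, sholl_post=prof,
        ))
    return outcomes


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    sholl: dict | None = None  # (dose, time) -> (radii, mean intersections)


def irradiate_experiment(neurons, doses, times, params: DamageParams,
                         n_trials: int = 20, base_seed: int = 0,
                         compartment: str = "all",
                         sholl_step: float | None = None) -> ExperimentResult:
    """Full Monte-Carlo dose/time grid over a population of neurons.

    For each (neuron, dose, trial), damage is assigned once, one kinetics
    trajectory is run to the last read-out time, and snips are applied at
    each checkpoint.  Returns mean +/- SEM over neurons x trials of the
    single-neuron and (when D0 is set) population-corrected ratios, plus mean
    snip counts, and optionally mean Sholl profiles.
    """
    doses = [float(d) for d in doses]
    times = sorted(float(t) for t in times)
    if not doses or not times or not list(neurons):
        raise ValueError("neurons, doses and times must be nonempty")
    subs = [DamageSubstrate(nrn, compartment) for nrn in neurons]
    samples: dict[tuple, list] = {}
    sholl_acc: dict[tuple, list] = {}
    for i, sub in enumerate(subs):
        for j, D in enumerate(doses):
            for k in range(n_trials):
                rng = np.random.default_rng((base_seed, i, j, k))
                outs = irradiate_single(sub.neuron, D, times, params, rng,
                                        compartment, sholl_step, substrate=sub)
                for out in outs:
                    key = (D, out.time)
                    rec = [out.single_ratios.tl, out.single_ratios.bn,
                           out.single_ratios.bp, float(len(out.snipped_ids))]
                    if out.population_ratios is not None:
                        rec += [out.population_ratios.tl, out.population_ratios.bn,
                                out.population_ratios.bp]
                    samples.setdefault(key, []).append(rec)
                    if sholl_step is not None:
                        sholl_acc.setdefault(key, []).append(out.sholl_post)
    rows = []
    for (D, t), recs in samples.items():
        arr = np.array(recs)
        names = [("tl", "single"), ("bn", "single"), ("bp", "single"), ("n_snips", "single")]
        if arr.shape[1] > 4:
            names += [("tl", "population"), ("bn", "population"), ("bp", "population")]
        for col, (metric, mode) in enumerate(names):
            vals = arr[:, col]
            sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
            rows.append(dict(dose=D, time=t, metric=metric, mode=mode,
                             mean=float(vals.mean()), sem=sem, n=len(vals)))
    table = pd.DataFrame(rows).sort_values(["dose", "time", "mode", "metric"]).reset_index(drop=True)
    sholl_out = None
    if sholl_step is not None:
        sholl_out = {}
        for key, profs in sholl_acc.items():
            nmax = max(len(p.radii) for p in profs)
            radii = profs[int(np.argmax([len(p.radii) for p in profs]))].radii
            acc = np.zeros(nmax)
            for p in profs:
                acc[: len(p.intersections)] += p.intersections
            sholl_out[key] = (radii, acc / len(profs))
    return ExperimentResult(table=table, sholl=sholl_out)
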