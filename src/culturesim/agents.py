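"""Forager behavior: heritable parameters, safety checking, the decision
cascade, the food-choice rule and movement primitives.

Grouping follows an attraction-alignment scheme: a forager is *safe* when
enough group mates are within SAFESPACE; unsafe foragers move toward the
centroid of the other members, and on regaining safety align their heading
with neighbors in ALIGNSPACE.  Local enhancement is never implemented
directly -- it emerges from this cohesive grouping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .environment import wrap_delta
from .learning import exploration_probability, stimulus_enhancement_probability

# action codes
MOVE, SEARCH, MOVETOFOOD, EAT, MOVETOGROUP, OBSERVE, NOTHING = range(7)
ACTION_NAMES = ("MOVE", "SEARCH", "MOVETOFOOD", "EAT",
                "MOVETOGROUP", "OBSERVE", "NOTHING")

# heritable-parameter bounds: mutation draws are clipped to these and the
# mutation sd is one fifth of the upper bound
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 20.0),
    "phi": (0.0, 1.0),
    "sigma": (0.0, 20.0),
    "epsilon": (0.0, 1.0),
    "lam": (0.0, 1.0),
    "gamma": (0.0, 1.0),
    "omega": (0.0, 1.0),
    "tau": (0.01, 1.0),
}
PARAM_NAMES = tuple(PARAM_BOUNDS)


@dataclass
class HeritableParams:
    """The eight evolvable per-forager parameters (fixed within a lifetime).

    delta: MOVE distance (m); phi: update rate of the environment
    expectation; sigma: selectivity exponent; epsilon: exploration rate;
    lam: reinforcement learning rate; gamma: stimulus-enhancement strength;
    omega: probability to OBSERVE when safe; tau: OBSERVE duration (min).
    """

    delta: float = 5.0
    phi: float = 0.05
    sigma: float = 5.0
    epsilon: float = 0.05
    lam: float = 0.9
    gamma: float = 0.0
    omega: float = 0.0
    tau: float = 1.0

    def validate(self) -> None:
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in PARAM_NAMES)


@dataclass
class MovementConstants:
    """Spatial perception and locomotion constants (meters / minutes)."""

    safespace: float = 17.0
    safe_neighbors: int = 9
    alignspace: float = 20.0
    copyspace: float = 20.0
    reach: float = 0.9
    view: float = 2.0
    view_max_items: int = 20
    step: float = 1.0
    movetogroup_step: float = 1.0       # meters covered per MOVETOGROUP event
    meters_per_minute: float = 30.0     # 0.5 m/s
    heading_jitter_sd: float = 0.1      # radians of turning noise per MOVE
    align_on_transition_only: bool = True   # align heading only when safety
                                            # is regained, not every safe cycle
    strict_safety: bool = False         # require the full neighbor count even
                                        # in groups too small to provide it


def food_choice_probability(a_ir: float, a_ie: float, sigma: float,
                            P_E: float, P_S: float) -> float:
    """P_F = min(1, (a_ir/a_ie)^sigma + P_E + P_S).

    The power term is 0 for types with no positive expected reward (naive
    a_ir = 0, or learned-to-be-worthless a_ir <= 0), so unknown types are
    only sampled through exploration or social stimulation.  A forager with
    a_ir >= a_ie accepts with certainty.
    """
    if a_ie <= 0.0:
        raise ValueError("environment expectation a_ie must be positive")
    if a_ir >= a_ie:
        return 1.0
    if a_ir <= 0.0:
        p = P_E + P_S
    else:
        p = (a_ir / a_ie) ** sigma + P_E + P_S
    return p if p < 1.0 else 1.0


def update_env_expectation(a_ie: float, phi: float, stomach_full: bool) -> float:
    """Selectivity feedback at digestion: shrink a_ie by (1-phi) after an
    unfilled stomach, grow it by (1+phi) after a full one."""
    return a_ie * (1.0 + phi) if stomach_full else a_ie * (1.0 - phi)


def select_next_action(safe: bool, omega: float, hungry: bool,
                       has_target: bool, target_in_reach: bool,
                       last_was_search: bool, u_observe: float) -> int:
    """The decision cascade, evaluated after every completed action.

    Order: regain safety first; then OBSERVE with probability omega; idle
    when not hungry; approach/eat a held food target; MOVE after a fruitless
    SEARCH; otherwise SEARCH.
    """
    if not safe:
        return MOVETOGROUP
    if u_observe < omega:
        return OBSERVE
    if not hungry:
        return NOTHING
    if has_target:
        return EAT if target_in_reach else MOVETOFOOD
    if last_was_search:
        return MOVE
    return SEARCH


def safety_scan(pop, i: int, consts: MovementConstants, rng,
                need_demonstrator: bool) -> tuple[bool, int, float, float, int]:
    """One pass over the forager's group mates: safety, demonstrator draw
    and the centroid displacement.

    Returns (safe, demonstrator, centroid_dx, centroid_dy, n_others).  Safe
    iff at least ``safe_neighbors`` group members are within SAFESPACE (a
    lone group member is trivially safe: there is no group to rejoin).
    Unless ``strict_safety`` is set, the requirement is capped at the number
    of other members so that shrunken groups are not permanently unsafe.
    With ``need_demonstrator``, a demonstrator is independently drawn
    uniformly from members within COPYSPACE that are currently processing
    and consuming a resource (see also :func:`draw_demonstrator` for the
    lazy variant used when only the OBSERVE action needs one).
    """
    members = pop.groups[pop.group_id[i]]
    n_others = len(members) - 1
    if n_others <= 0:
        return True, -1, 0.0, 0.0, 0
    required = consts.safe_neighbors
    if not consts.strict_safety and required > n_others:
        required = n_others
    side = pop.side
    half = 0.5 * side
    x = pop.x[i]
    y = pop.y[i]
    safe_r2 = consts.safespace * consts.safespace
    copy_r2 = consts.copyspace * consts.copyspace
    count = 0
    eaters: list[int] = []
    action = pop.action
    px = pop.x
    py = pop.y
    sx = 0.0
    sy = 0.0
    for j in members:
        if j == i:
            continue
        dx = px[j] - x
        if dx > half:
            dx -= side
        elif dx < -half:
            dx += side
        dy = py[j] - y
        if dy > half:
            dy -= side
        elif dy < -half:
            dy += side
        sx += dx
        sy += dy
        d2 = dx * dx + dy * dy
        if d2 <= safe_r2:
            count += 1
        if need_demonstrator and d2 <= copy_r2 and action[j] == EAT:
            eaters.append(j)
    dem = eaters[rng.integer(len(eaters))] if eaters else -1
    return count >= required, dem, sx / n_others, sy / n_others, n_others


def draw_demonstrator(pop, i: int, consts: MovementConstants, rng) -> int:
    """Uniform draw from group mates within COPYSPACE currently in EAT."""
    members = pop.groups[pop.group_id[i]]
    side = pop.side
    half = 0.5 * side
    x = pop.x[i]
    y = pop.y[i]
    copy_r2 = consts.copyspace * consts.copyspace
    action = pop.action
    eaters: list[int] = []
    for j in members:
        if j == i or action[j] != EAT:
            continue
        dx = pop.x[j] - x
        if dx > half:
            dx -= side
        elif dx < -half:
            dx += side
        dy = pop.y[j] - y
        if dy > half:
            dy -= side
        elif dy < -half:
            dy += side
        if dx * dx + dy * dy <= copy_r2:
            eaters.append(j)
    if not eaters:
        return -1
    return eaters[rng.integer(len(eaters))]


def check_safe(pop, i: int, consts: MovementConstants, rng,
               need_demonstrator: bool) -> tuple[bool, int]:
    """Safety check plus demonstrator draw (see :func:`safety_scan`)."""
    safe, dem, _, _, _ = safety_scan(pop, i, consts, rng, need_demonstrator)
    return safe, dem


def group_centroid_delta(pop, i: int) -> tuple[float, float, int]:
    """Wrapped displacement from forager i to the centroid of the *other*
    members of its group; returns (dx, dy, n_others)."""
    members = pop.groups[pop.group_id[i]]
    side = pop.side
    x = pop.x[i]
    y = pop.y[i]
    sx = 0.0
    sy = 0.0
    n = 0
    for j in members:
        if j == i:
            continue
        sx += wrap_delta(pop.x[j] - x, side)
        sy += wrap_delta(pop.y[j] - y, side)
        n += 1
    if n == 0:
        return 0.0, 0.0, 0
    return sx / n, sy / n, n


def align_heading(pop, i: int, consts: MovementConstants) -> float:
    """Circular-mean heading of other group members within ALIGNSPACE;
    falls back to the forager's own heading when nobody is close enough."""
    members = pop.groups[pop.group_id[i]]
    side = pop.side
    x = pop.x[i]
    y = pop.y[i]
    r2 = consts.alignspace * consts.alignspace
    sc = 0.0
    ss = 0.0
    found = False
    for j in members:
        if j == i:
            continue
        dx = wrap_delta(pop.x[j] - x, side)
        dy = wrap_delta(pop.y[j] - y, side)
        if dx * dx + dy * dy <= r2:
            sc += math.cos(pop.heading[j])
            ss += math.sin(pop.heading[j])
            found = True
    if not found:
        return pop.heading[i]
    return math.atan2(ss, sc)


def advance(pop, i: int, dist: float) -> None:
    """Move forager i ``dist`` meters along its heading (torus wrap)."""
    side = pop.side
    h = pop.heading[i]
    pop.x[i] = (pop.x[i] + dist * math.cos(h)) % side
    pop.y[i] = (pop.y[i] + dist * math.sin(h)) % side


def move_toward(pop, i: int, dx: float, dy: float, max_step: float) -> float:
    """Turn toward the wrapped displacement (dx, dy) and advance at most
    ``max_step`` meters; returns the distance actually moved."""
    dist = math.hypot(dx, dy)
    if dist == 0.0:
        return 0.0
    pop.heading[i] = math.atan2(dy, dx)
    step = dist if dist < max_step else max_step
    advance(pop, i, step)
    return step


def search_items(pop, i: int, env, consts: MovementConstants,
                 se_window: float, now: float, rng) -> int:
    """One SEARCH: assess up to 20 items in view in random order and return
    the first accepted item id, or -1.

    Types under an active satiation aversion are ignored outright (expired
    aversions are dropped on the fly).  Acceptance of each remaining item is
    a Bernoulli draw with the food-choice probability, built from the
    exploration term P_E and the stimulus-enhancement term P_S.
    """
    cands = env.items_in_view(pop.x[i], pop.y[i], pop.heading[i], rng,
                              consts.view, consts.view_max_items)
    if not cands:
        return -1
    mem_a = pop.mem_a[i]
    mem_c = pop.mem_c[i]
    a_ie = pop.a_env[i]
    sigma = pop.p_sigma[i]
    eps = pop.p_epsilon[i]
    gamma = pop.p_gamma[i]
    se_type = pop.se_type[i]
    se_time = pop.se_time[i]
    aversions = pop.aversions[i]
    item_type = env.item_type
    for item in cands:
        t_id = item_type[item]
        if aversions:
            expiry = aversions.get(t_id)
            if expiry is not None:
                if now < expiry:
                    continue
                del aversions[t_id]
        P_E = exploration_probability(eps, mem_c[t_id])
        P_S = stimulus_enhancement_probability(gamma, se_type, se_time,
                                               t_id, now, se_window)
        p = food_choice_probability(mem_a[t_id], a_ie, sigma, P_E, P_S)
        if p >= 1.0 or rng.uniform() < p:
            return item
    return -1
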