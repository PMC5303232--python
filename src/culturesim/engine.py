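"""Event-based simulation engine.

Foragers live in a priority queue keyed by the completion time of their
current action; the forager with the least time remaining acts next, so
actions of different foragers overlap in time.  Life-history bookkeeping
(metabolism, digestion, deaths/births, group splitting) and environmental
change run on a one-minute tick interleaved with the forager queue; ticks
at a given instant resolve before forager events at the same instant.

Two independent random streams drive a run: the *environment* stream
(world generation and environmental change) and the *behavior* stream
(everything foragers do), plus a third stream for mutation.  Two runs that
share the environment seed but differ in the behavior seed experience the
exact same world and the same schedule of environmental change -- the
paired design used by the traditions analysis.
"""

from __future__ import annotations

import heapq
import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import agents, learning
from .agents import (EAT, MOVE, MOVETOFOOD, MOVETOGROUP, NOTHING, OBSERVE,
                     SEARCH, HeritableParams, MovementConstants, PARAM_NAMES)
from .demography import (LifeHistoryConfig, mutate_params, select_reproducer,
                         split_group)
from .environment import EnvironmentConfig, generate_environment, wrap_delta
from .learning import SocialLearningConstants
from .rng import StreamRNG

logger = logging.getLogger("culturesim")

SLM_MODES = ("LE", "SE", "OL", "solitary")

MIN_ACTION_MINUTES = 0.01   # floor on action duration; keeps the queue moving


@dataclass
class SimulationConfig:
    """Complete description of one run."""

    env: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    life: LifeHistoryConfig = field(default_factory=LifeHistoryConfig)
    social: SocialLearningConstants = field(default_factory=SocialLearningConstants)
    movement: MovementConstants = field(default_factory=MovementConstants)
    base_params: HeritableParams = field(default_factory=HeritableParams)
    slm_mode: str = "LE"               # LE | SE | OL | solitary
    evolution_enabled: bool = False    # mutate heritable params at birth
    duration_years: float = 5.0
    snapshot_years: tuple = ()         # defaults to (duration_years,)
    n_groups: int = 2
    seed_env: int = 1
    seed_behavior: int = 2
    seed_mutation: int | None = None   # derived from seed_behavior if None
    stagger_initial_ages: bool = True
    search_minutes: float = 1.0
    nothing_minutes: float = 1.0

    def validate(self) -> None:
        if self.slm_mode not in SLM_MODES:
            raise ValueError(f"unknown slm_mode {self.slm_mode!r}")
        self.env.validate()
        self.life.validate()
        self.base_params.validate()
        if self.duration_years <= 0:
            raise ValueError("duration_years must be positive")

    def effective_params(self) -> HeritableParams:
        """Base params with the social knobs the mode forbids forced to 0."""
        p = replace(self.base_params)
        if self.slm_mode in ("LE", "solitary"):
            p.gamma = 0.0
            p.omega = 0.0
        elif self.slm_mode == "SE":
            p.omega = 0.0
        elif self.slm_mode == "OL":
            p.gamma = 0.0
        return p

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snapshot_years"] = list(self.snapshot_years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (("env", EnvironmentConfig), ("life", LifeHistoryConfig),
                         ("social", SocialLearningConstants),
                         ("movement", MovementConstants),
                         ("base_params", HeritableParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "snapshot_years" in d:
            d["snapshot_years"] = tuple(d["snapshot_years"])
        return cls(**d)


class EventQueue:
    """Min-heap of (completion time, arrival order, forager slot, seq).

    Pop order is nondecreasing in time with FIFO tie-breaking.  Entries for
    dead foragers are invalidated lazily: the caller compares the stored
    ``seq`` against the forager's current sequence number.
    """

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, int, int]] = []
        self._counter = 0

    def __len__(self) -> int:
        return len(self._heap)

    def push(self, time: float, forager: int, seq: int) -> None:
        heapq.heappush(self._heap, (time, self._counter, forager, seq))
        self._counter += 1

    def pop(self) -> tuple[float, int, int]:
        """Remove and return (time, forager, seq) of the earliest entry."""
        if not self._heap:
            raise IndexError("pop from empty event queue")
        time, _, forager, seq = heapq.heappop(self._heap)
        return time, forager, seq


@dataclass
class Snapshot:
    """Cross-section of the living population at a named simulation year.

    ``repertoires`` is a long table (forager_id, type_id, d, t, a) holding
    the cumulative lifetime consumption counts d_ir, processing experience
    t_ir and expected rewards a_ir of every living forager; the resource
    type table at snapshot time is carried along so skill-dependent measures
    can be recomputed without the engine.
    """

    year: float
    foragers: pd.DataFrame
    repertoires: pd.DataFrame
    R: int
    type_Q: np.ndarray
    type_H: np.ndarray
    type_S: np.ndarray
    env_census: dict

    def repertoire_matrix(self, group_id: int | None = None,
                          column: str = "d",
                          width: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(forager ids, dense n x R matrix of ``column``) for one group
        (or the whole population when ``group_id`` is None).

        ``width`` pads the type axis so snapshots taken before and after
        environmental change mints new type ids stay comparable.
        """
        rows = self.foragers
        if group_id is not None:
            rows = rows[rows["group_id"] == group_id]
        ids = rows["forager_id"].to_numpy()
        mat = np.zeros((len(ids), max(self.R, width or 0)))
        pos = {fid: k for k, fid in enumerate(ids)}
        rep = self.repertoires
        for fid, tid, val in zip(rep["forager_id"].to_numpy(),
                                 rep["type_id"].to_numpy(),
                                 rep[column].to_numpy()):
            k = pos.get(fid)
            if k is not None:
                mat[k, tid] = val
        return ids, mat


@dataclass
class RunResult:
    """Snapshots plus a manifest describing the run."""

    config: SimulationConfig
    snapshots: list
    manifest: dict

    def snapshot_at(self, year: float) -> Snapshot:
        for s in self.snapshots:
            if abs(s.year - year) < 1e-9:
                return s
        raise KeyError(f"no snapshot at year {year}")

    def to_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        manifest = dict(self.manifest)
        manifest["config"] = self.config.to_dict()
        manifest["snapshot_years"] = [s.year for s in self.snapshots]
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        for s in self.snapshots:
            tag = f"{s.year:g}"
            s.foragers.to_csv(os.path.join(path, f"year_{tag}_foragers.csv"),
                              index=False)
            s.repertoires.to_csv(os.path.join(path, f"year_{tag}_repertoires.csv"),
                                 index=False)
            types = pd.DataFrame({"type_id": np.arange(s.R), "Q": s.type_Q,
                                  "H": s.type_H, "S": s.type_S})
            types.to_csv(os.path.join(path, f"year_{tag}_types.csv"), index=False)

    @classmethod
    def from_dir(cls, path: str) -> "RunResult":
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        config = SimulationConfig.from_dict(manifest.pop("config"))
        years = manifest.pop("snapshot_years")
        snapshots = []
        for year in years:
            tag = f"{year:g}"
            foragers = pd.read_csv(os.path.join(path, f"year_{tag}_foragers.csv"))
            reps = pd.read_csv(os.path.join(path, f"year_{tag}_repertoires.csv"))
            types = pd.read_csv(os.path.join(path, f"year_{tag}_types.csv"))
            snapshots.append(Snapshot(
                year=year, foragers=foragers, repertoires=reps,
                R=len(types), type_Q=types["Q"].to_numpy(),
                type_H=types["H"].to_numpy(), type_S=types["S"].to_numpy(),
                env_census={}))
        return cls(config=config, snapshots=snapshots, manifest=manifest)


class Population:
    """Flat state of the N forager slots (dead slots are reused at birth)."""

    def __init__(self, N: int, R: int, side: float) -> None:
        self.N = N
        self.R = R
        self.side = side
        self.x = [0.0] * N
        self.y = [0.0] * N
        self.heading = [0.0] * N
        self.group_id = [0] * N
        self.groups: dict[int, list[int]] = {}
        self.uid = list(range(N))
        self.next_uid = N
        self.birth_time = np.zeros(N)
        self.h = np.zeros(N)
        self.pending_energy = np.zeros(N)
        self.ledger_food = np.zeros(N)     # energy credited at digestion
        self.ledger_repro = np.zeros(N)    # reproduction costs paid
        self.action = [NOTHING] * N
        self.action_end = [0.0] * N
        self.eat_type = [-1] * N
        self.food_target = [-1] * N
        self.last_search = [False] * N
        self.prev_safe = [True] * N
        self.se_type = [-1] * N
        self.se_time = [0.0] * N
        self.aversions: list[dict[int, float]] = [dict() for _ in range(N)]
        self.stomach = np.zeros((N, R), dtype=np.int64)
        self.stomach_total = [0] * N
        self.mem_a = np.zeros((N, R))
        self.mem_c = np.zeros((N, R))
        self.mem_t = np.zeros((N, R))
        self.d = np.zeros((N, R), dtype=np.int64)
        self.a_env = np.zeros(N)
        self.seq = [0] * N
        # heritable parameters, one list per parameter
        for name in PARAM_NAMES:
            setattr(self, "p_" + name, [0.0] * N)

    def add_type(self) -> None:
        """Grow every per-type memory column by one naive entry (a new
        resource type was minted by environmental change)."""
        self.R += 1
        zero = np.zeros((self.N, 1))
        self.mem_a = np.hstack([self.mem_a, zero])
        self.mem_c = np.hstack([self.mem_c, zero])
        self.mem_t = np.hstack([self.mem_t, zero])
        self.d = np.hstack([self.d, np.zeros((self.N, 1), dtype=np.int64)])
        self.stomach = np.hstack([self.stomach,
                                  np.zeros((self.N, 1), dtype=np.int64)])

    def set_params(self, i: int, values: tuple[float, ...]) -> None:
        for name, v in zip(PARAM_NAMES, values):
            getattr(self, "p_" + name)[i] = v

    def get_params(self, i: int) -> tuple[float, ...]:
        return tuple(getattr(self, "p_" + name)[i] for name in PARAM_NAMES)

    def ages_years(self, now: float, year_minutes: float) -> np.ndarray:
        return (now - self.birth_time) / year_minutes


class Simulation:
    """One configured run; ``run()`` executes it and returns a RunResult."""

    def __init__(self, config: SimulationConfig) -> None:
        config.validate()
        self.config = config
        self.env_gen = np.random.default_rng(config.seed_env)
        self.rng = StreamRNG(config.seed_behavior)
        mseed = config.seed_mutation
        if mseed is None:
            mseed = (config.seed_behavior * 2654435761 + 97) % (2**31 - 1)
        self.mut_rng = StreamRNG(mseed)
        self.env = generate_environment(config.env, self.env_gen)
        self.year_minutes = config.life.year_minutes
        self._solitary = config.slm_mode == "solitary"
        self.pop = self._init_population()
        self.queue = EventQueue()
        self.snapshots: list[Snapshot] = []
        self.deaths = 0
        self.births = 0
        self.splits = 0
        self.next_gid = max(self.pop.groups) + 1 if self.pop.groups else 0
        self.deaths_this_year = 0
        self.viable = True
        self.halted_at: float | None = None
        self.population_size_checks: set[int] = set()
        self.death_birth_cycles = 0
        self.total_items_consumed = 0
        self.max_group_size = max((len(m) for m in self.pop.groups.values()),
                                  default=0)

    # ---- initialization ---------------------------------------------

    def _init_population(self) -> Population:
        cfg = self.config
        N = cfg.life.N
        pop = Population(N, cfg.env.R, cfg.env.world_side)
        params = cfg.effective_params()
        params.validate()
        ptuple = params.as_tuple()
        a0 = cfg.env.quality_mean if cfg.env.quality_mean > 0 else 0.1
        rng = self.rng
        solitary = cfg.slm_mode == "solitary"
        n_groups = N if solitary else min(cfg.n_groups, N)
        centers = [(rng.uniform() * pop.side, rng.uniform() * pop.side)
                   for _ in range(n_groups)]
        for i in range(N):
            g = i if solitary else i % n_groups
            cx, cy = centers[g]
            r = 5.0 * math.sqrt(rng.uniform())
            th = rng.uniform() * 2 * math.pi
            pop.x[i] = (cx + r * math.cos(th)) % pop.side
            pop.y[i] = (cy + r * math.sin(th)) % pop.side
            pop.heading[i] = rng.uniform() * 2 * math.pi
            pop.group_id[i] = g
            pop.groups.setdefault(g, []).append(i)
            pop.set_params(i, ptuple)
            pop.a_env[i] = a0
            pop.h[i] = cfg.life.initial_energy
            if cfg.stagger_initial_ages:
                pop.birth_time[i] = -rng.uniform() * cfg.life.max_age_minutes
        return pop

    # ---- main loop ---------------------------------------------------

    def run(self) -> RunResult:
        cfg = self.config
        pop = self.pop
        t_end = cfg.duration_years * self.year_minutes
        snap_years = tuple(cfg.snapshot_years) or (cfg.duration_years,)
        self._snap_minutes = {round(y * self.year_minutes, 6): y for y in snap_years}
        if 0.0 in self._snap_minutes:
            self._take_snapshot(self._snap_minutes.pop(0.0), 0.0)
        for i in range(pop.N):
            self.queue.push(0.0, i, pop.seq[i])
        next_tick = 1.0
        queue = self.queue
        while len(queue):
            time, i, seq = queue.pop()
            if time > t_end:
                while next_tick <= t_end and self.viable:
                    self._tick(next_tick)
                    next_tick += 1.0
                break
            while next_tick <= time and self.viable:
                self._tick(next_tick)
                next_tick += 1.0
            if not self.viable:
                break
            if seq != pop.seq[i]:
                continue
            self._act(i, time)
        manifest = {
            "seed_env": cfg.seed_env,
            "seed_behavior": cfg.seed_behavior,
            "slm_mode": cfg.slm_mode,
            "viable": self.viable,
            "halted_at_minutes": self.halted_at,
            "deaths": self.deaths,
            "births": self.births,
            "group_splits": self.splits,
            "environmental_changes": self.env.n_changes,
            "items_consumed": self.total_items_consumed,
            "population_sizes_observed": sorted(self.population_size_checks),
            "death_birth_cycles": self.death_birth_cycles,
            "max_group_size_observed": self.max_group_size,
        }
        return RunResult(config=cfg, snapshots=self.snapshots, manifest=manifest)

    # ---- life-history tick ------------------------------------------

    def _tick(self, m: float) -> None:
        cfg = self.config
        pop = self.pop
        life = cfg.life
        # year boundary: growth first, then snapshots and viability audit
        year_pos = m % self.year_minutes
        if year_pos == 0.0:
            self.env.annual_growth()
            self.deaths_this_year = 0
        key = round(m, 6)
        if key in self._snap_minutes:
            self._take_snapshot(self._snap_minutes[key], m)
        # environmental change (environment stream, so paired runs agree);
        # a minted type gets a fresh naive memory column, while history for
        # the retired id (counts, experience) is deliberately preserved
        replaced = self.env.environmental_change_step(1.0, self.env_gen,
                                                      self.year_minutes)
        for old, new in replaced:
            if new != old:
                pop.add_type()
            logger.debug("t=%.0f environmental change: type %d -> %d", m, old, new)
        # metabolism
        pop.h -= life.metabolism_per_min
        # digestion
        if m % life.digestion_interval == 0.0:
            self._digestion(m)
        # deaths: old age, starvation, stochastic hazard
        ages = m - pop.birth_time
        dead = (pop.h <= 0.0) | (ages >= life.max_age_minutes)
        if life.stochastic_death_hazard > 0.0:
            u = self.rng.gen.random(pop.N)
            dead |= u < life.stochastic_death_hazard
        if dead.any():
            for i in np.nonzero(dead)[0]:
                self._death_birth(int(i), m)

    def _digestion(self, m: float) -> None:
        pop = self.pop
        life = self.config.life
        cap = life.stomach_capacity
        for i in range(pop.N):
            e = pop.pending_energy[i]
            if e != 0.0:
                pop.h[i] += e
                pop.ledger_food[i] += e
                pop.pending_energy[i] = 0.0
            full = pop.stomach_total[i] >= cap
            pop.a_env[i] = max(agents.update_env_expectation(
                pop.a_env[i], pop.p_phi[i], full), 1e-12)
            if pop.stomach_total[i]:
                pop.stomach[i, :] = 0
                pop.stomach_total[i] = 0
            av = pop.aversions[i]
            if av:
                for t_id in [t for t, exp in av.items() if m >= exp]:
                    del av[t_id]

    def _death_birth(self, i: int, now: float) -> None:
        pop = self.pop
        cfg = self.config
        life = cfg.life
        self.deaths += 1
        self.deaths_this_year += 1
        # inviability: a death rate far beyond demographic turnover means the
        # population cannot pay its way (reproduction costs exceed income)
        limit = life.viability_deaths_per_year or 20 * life.N
        if self.deaths_this_year > limit and self.viable:
            self.viable = False
            self.halted_at = now
        parent = select_reproducer(pop.h, life.selection_exponent, self.rng,
                                   exclude=i)
        pop.h[parent] -= life.reproduction_cost
        pop.ledger_repro[parent] += life.reproduction_cost
        # remove the dead forager from its group
        old_gid = pop.group_id[i]
        members = pop.groups[old_gid]
        members.remove(i)
        if not members:
            del pop.groups[old_gid]
        # the offspring takes over the slot, in its parent's group
        gid = pop.group_id[parent]
        pop.group_id[i] = gid
        group = pop.groups[gid]
        group.append(i)
        pop.uid[i] = pop.next_uid
        pop.next_uid += 1
        pop.x[i] = pop.x[parent]
        pop.y[i] = pop.y[parent]
        pop.heading[i] = self.rng.uniform() * 2 * math.pi
        pop.birth_time[i] = now
        pop.h[i] = life.initial_energy
        pop.pending_energy[i] = 0.0
        pop.ledger_food[i] = 0.0
        pop.ledger_repro[i] = 0.0
        pop.eat_type[i] = -1
        pop.food_target[i] = -1
        pop.last_search[i] = False
        pop.prev_safe[i] = True
        pop.se_type[i] = -1
        pop.se_time[i] = 0.0
        pop.aversions[i] = {}
        pop.stomach[i, :] = 0
        pop.stomach_total[i] = 0
        pop.mem_a[i, :] = 0.0
        pop.mem_c[i, :] = 0.0
        pop.mem_t[i, :] = 0.0
        pop.d[i, :] = 0
        pop.a_env[i] = cfg.env.quality_mean if cfg.env.quality_mean > 0 else 0.1
        parent_params = pop.get_params(parent)
        if cfg.evolution_enabled:
            parent_params = mutate_params(parent_params, life.mutation_rate,
                                          self.mut_rng)
        pop.set_params(i, parent_params)
        pop.action[i] = NOTHING
        pop.action_end[i] = now
        pop.seq[i] += 1
        self.queue.push(now, i, pop.seq[i])
        self.births += 1
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("t=%.0f death of forager slot %d; forager %d born to "
                         "parent slot %d in group %d", now, i, pop.uid[i],
                         parent, gid)
        # group splitting
        if len(group) > life.G and cfg.slm_mode != "solitary":
            keep, leave = split_group(group, self.rng)
            pop.groups[gid] = keep
            new_gid = self.next_gid
            self.next_gid += 1
            pop.groups[new_gid] = leave
            for j in leave:
                pop.group_id[j] = new_gid
            self.splits += 1
            logger.debug("t=%.0f group %d split: %d stay, %d form group %d",
                         now, gid, len(keep), len(leave), new_gid)
        # audits after the completed death-birth cycle: total population and
        # the largest group (splitting must keep every group within G)
        self.population_size_checks.add(sum(len(g) for g in pop.groups.values()))
        self.death_birth_cycles += 1
        largest = max(len(g) for g in pop.groups.values())
        if largest > self.max_group_size:
            self.max_group_size = largest

    # ---- forager events ---------------------------------------------

    def _act(self, i: int, now: float) -> None:
        """One forager event: safety scan, decision cascade, action effect.

        Structured as a single flat function because it runs millions of
        times per simulated year; the decision logic mirrors
        :func:`culturesim.agents.select_next_action` exactly (the cascade is
        unit-tested against that function).
        """
        cfg = self.config
        pop = self.pop
        mov = cfg.movement
        rng = self.rng
        env = self.env
        # CHECKSAFE feeds the stimulus-enhancement memory, so the eater scan
        # runs every cycle only when SE is active; observational learning
        # draws its demonstrator lazily inside the OBSERVE branch
        need_dem = pop.p_gamma[i] > 0.0
        if self._solitary:
            safe, dem, cdx, cdy, n_others = True, -1, 0.0, 0.0, 0
        else:
            safe, dem, cdx, cdy, n_others = agents.safety_scan(
                pop, i, mov, rng, need_dem)
        if dem >= 0:
            pop.se_type[i] = pop.eat_type[dem]
            pop.se_time[i] = now
        if safe and (not pop.prev_safe[i] or not mov.align_on_transition_only):
            pop.heading[i] = agents.align_heading(pop, i, mov)
        pop.prev_safe[i] = safe

        # ---- decision cascade + action effect (effects at action start)
        mpm = mov.meters_per_minute
        action = -1
        if not safe:
            action = MOVETOGROUP
            if n_others:
                agents.move_toward(pop, i, cdx, cdy, mov.movetogroup_step)
            # the full travel quantum is budgeted even when the centroid is
            # nearer: an unsafe forager at the centroid of a dispersed group
            # can only wait for the others to close in
            duration = mov.movetogroup_step / mpm
        else:
            omega = pop.p_omega[i]
            if omega > 0.0 and rng.uniform() < omega:
                action = OBSERVE
                duration = tau = pop.p_tau[i]
                if dem < 0 and not self._solitary:
                    dem = agents.draw_demonstrator(pop, i, mov, rng)
                if dem >= 0 and pop.action[dem] == EAT and pop.eat_type[dem] >= 0:
                    rt = pop.eat_type[dem]
                    gain = learning.observational_learning_gain(
                        cfg.social.K, tau, pop.action_end[dem] - now,
                        cfg.social.M, pop.mem_t[dem, rt], pop.mem_t[i, rt])
                    if gain > 0.0:
                        pop.mem_t[i, rt] += gain
            elif pop.stomach_total[i] >= cfg.life.stomach_capacity:
                action = NOTHING
                duration = cfg.nothing_minutes
            else:
                target = pop.food_target[i]
                if target >= 0 and not env.available[target]:
                    target = -1
                    pop.food_target[i] = -1
                if target >= 0:
                    side = pop.side
                    half = 0.5 * side
                    dx = env.item_x[target] - pop.x[i]
                    if dx > half:
                        dx -= side
                    elif dx < -half:
                        dx += side
                    dy = env.item_y[target] - pop.y[i]
                    if dy > half:
                        dy -= side
                    elif dy < -half:
                        dy += side
                    if dx * dx + dy * dy <= mov.reach * mov.reach:
                        action = EAT
                        self._process_and_eat(i, target, now)
                        duration = cfg.social.M
                    else:
                        action = MOVETOFOOD
                        step = math.sqrt(dx * dx + dy * dy) - 0.8 * mov.reach
                        moved = agents.move_toward(pop, i, dx, dy, step)
                        duration = moved / mpm
                elif pop.last_search[i]:
                    action = MOVE
                    if mov.heading_jitter_sd > 0.0:
                        pop.heading[i] += rng.normal(0.0, mov.heading_jitter_sd)
                    delta = pop.p_delta[i]
                    agents.advance(pop, i, delta)
                    duration = delta / mpm
                else:
                    action = SEARCH
                    pop.food_target[i] = agents.search_items(
                        pop, i, env, mov, cfg.social.se_window, now, rng)
                    duration = cfg.search_minutes

        pop.last_search[i] = action == SEARCH
        if action != EAT:
            pop.eat_type[i] = -1
        pop.action[i] = action
        end = now + (duration if duration > MIN_ACTION_MINUTES else MIN_ACTION_MINUTES)
        pop.action_end[i] = end
        self.queue.push(end, i, pop.seq[i])

    def _process_and_eat(self, i: int, item: int, now: float) -> None:
        """One EAT event: experience, skill, reward, reinforcement,
        certainty, consumption, stomach and the satiation aversion."""
        cfg = self.config
        pop = self.pop
        env = self.env
        r = int(env.item_type[item])
        env.consume_item(item)
        self.total_items_consumed += 1
        lam = pop.p_lam[i]
        t_new = pop.mem_t[i, r] + cfg.social.M
        pop.mem_t[i, r] = t_new
        s = learning.skill_level(t_new, env.H[r], int(env.S[r]))
        e = learning.realized_reward(env.Q[r], s, cfg.env.Z, self.rng)
        a_prev = pop.mem_a[i, r]
        pop.mem_c[i, r] = learning.update_certainty(pop.mem_c[i, r], lam, e, a_prev)
        pop.mem_a[i, r] = learning.update_association(a_prev, lam, e)
        pop.d[i, r] += 1
        pop.pending_energy[i] += e
        pop.stomach[i, r] += 1
        pop.stomach_total[i] += 1
        pop.eat_type[i] = r
        pop.food_target[i] = -1
        cap = cfg.life.stomach_capacity
        if pop.stomach_total[i] >= cap:
            mode = cfg.life.satiation_mode
            expiry = now + cfg.life.digestion_interval
            if mode == "modal":
                pop.aversions[i][int(pop.stomach[i].argmax())] = expiry
            elif mode == "all":
                if pop.stomach[i, r] >= cap:
                    pop.aversions[i][r] = expiry
            else:  # any: avert every type present in the full stomach
                for t_id in np.nonzero(pop.stomach[i])[0]:
                    pop.aversions[i][int(t_id)] = expiry

    # ---- snapshots ---------------------------------------------------

    def _take_snapshot(self, year: float, now: float) -> None:
        pop = self.pop
        rows = {
            "forager_id": list(pop.uid),
            "group_id": list(pop.group_id),
            "age_years": (now - pop.birth_time) / self.year_minutes,
            "energy": pop.h.copy(),
            "a_env": pop.a_env.copy(),
        }
        for name in PARAM_NAMES:
            rows[name] = list(getattr(pop, "p_" + name))
        foragers = pd.DataFrame(rows)
        fids: list[int] = []
        tids: list[int] = []
        ds: list[int] = []
        ts: list[float] = []
        as_: list[float] = []
        for i in range(pop.N):
            nz = np.nonzero((pop.d[i] > 0) | (pop.mem_t[i] > 0))[0]
            for t_id in nz:
                fids.append(pop.uid[i])
                tids.append(int(t_id))
                ds.append(int(pop.d[i, t_id]))
                ts.append(float(pop.mem_t[i, t_id]))
                as_.append(float(pop.mem_a[i, t_id]))
        repertoires = pd.DataFrame({
            "forager_id": fids, "type_id": tids, "d": ds, "t": ts, "a": as_})
        env = self.env
        census = {
            "total_items": env.n_items,
            "available_items": int(env.available.sum()),
            "environmental_changes": env.n_changes,
        }
        self.snapshots.append(Snapshot(
            year=year, foragers=foragers, repertoires=repertoires,
            R=env.n_types, type_Q=env.Q.copy(), type_H=env.H.copy(),
            type_S=env.S.copy(), env_census=census))


def run_simulation(config: SimulationConfig) -> RunResult:
    """Build and execute one run."""
    return Simulation(config).run()
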