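"""Spatial resource environment: types, patches, items, growth and change.

The world is a square torus populated by circular patches of resource items.
Each resource *type* r has a quality ``Q_r`` (the maximal per-item energy
reward, drawn from N(quality_mean, quality_sd)), a practice time ``H_r``
for half-maximal processing skill, and a sigmoid shape exponent ``S_r``
drawn uniformly from {1,2,3,4}.  Patches belong to one of ``n_patch_types``
patch types; a patch type owns five resource types that occur nowhere else,
and every individual patch carries three of those five.

Items disappear when consumed and reappear at the exact same position at the
annual growth step.  Environmental change replaces a randomly chosen type
with a brand-new one (new quality and shape, same global difficulty) at a
fixed per-minute probability; all items of the old type become the new type
and foragers are naive about it.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .rng import StreamRNG

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ResourceTypeSpec:
    """One resource type: identity, quality and task difficulty."""

    type_id: int
    Q: float          # maximal per-item energy reward
    H: float          # practice minutes for half-maximal skill
    S: int            # sigmoid shape exponent, in {1,2,3,4}

    def __post_init__(self) -> None:
        if self.S not in (1, 2, 3, 4):
            raise ValueError(f"S must be in 1..4, got {self.S}")
        if self.H <= 0:
            raise ValueError("H must be positive")


@dataclass
class EnvironmentConfig:
    """Geometry and composition of the resource world (defaults: full scale)."""

    R: int = 250                      # number of resource types
    n_patch_types: int = 50
    types_per_patch_type: int = 5
    types_per_patch: int = 3
    n_patches: int = 24500
    items_per_patch: int = 1200
    patch_radius: float = 10.0        # meters
    world_side: float = 6325.0        # meters (~40 km^2)
    ec_per_year: float = 0.0          # resource types replaced per year (EC)
    Z: float = 0.005                  # reward-noise standard deviation
    H: float = 1.0                    # global task difficulty applied to all types
    quality_mean: float = 0.1
    quality_sd: float = 0.1
    clip_quality: bool = False        # clip negative Q draws at 0
    layout_mode: str = "mixed"        # mixed-patches | pure-patches | random scatter
    change_mode: str = "replace"      # replace | quality (redraw Q, keep familiarity)
    grid_cell: float = 4.0            # item-index cell size (view diameter)

    def validate(self) -> None:
        counts = (self.R, self.n_patch_types, self.types_per_patch_type,
                  self.types_per_patch, self.n_patches, self.items_per_patch)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.types_per_patch > self.types_per_patch_type:
            raise ValueError("types_per_patch must not exceed types_per_patch_type")
        if self.ec_per_year < 0:
            raise ValueError("ec_per_year must be >= 0")
        if self.layout_mode not in ("mixed", "pure", "random"):
            raise ValueError(f"unknown layout_mode {self.layout_mode!r}")
        if self.change_mode not in ("replace", "quality"):
            raise ValueError(f"unknown change_mode {self.change_mode!r}")
        if self.layout_mode == "mixed" and self.R < self.n_patch_types * self.types_per_patch_type:
            raise ValueError(
                "mixed layout requires R >= n_patch_types * types_per_patch_type")


class SpatialIndex:
    """Uniform-grid index over item positions on the torus.

    Membership is static (items keep their position for life); availability
    is filtered at query time.  Correctness, not performance, is contractual:
    the test suite checks range queries against brute-force scans.
    """

    def __init__(self, xs: np.ndarray, ys: np.ndarray, side: float, cell: float) -> None:
        self.side = side
        self.ncell = max(1, int(side // cell))
        self.cell = side / self.ncell
        buckets: dict[tuple[int, int], list[int]] = {}
        cx = (xs // self.cell).astype(np.int64) % self.ncell
        cy = (ys // self.cell).astype(np.int64) % self.ncell
        for i in range(len(xs)):
            buckets.setdefault((int(cx[i]), int(cy[i])), []).append(i)
        # membership is static, so cells hold frozen index arrays that the
        # range query can filter vectorized
        self.cells: dict[tuple[int, int], np.ndarray] = {
            k: np.asarray(v, dtype=np.int64) for k, v in buckets.items()}

    def candidates(self, x: float, y: float, radius: float) -> np.ndarray:
        """Item ids in all cells overlapping the disc of ``radius`` at (x, y)."""
        reach = int(radius // self.cell) + 1
        cx = int(x // self.cell) % self.ncell
        cy = int(y // self.cell) % self.ncell
        out: list[np.ndarray] = []
        n = self.ncell
        cells = self.cells
        for dx in range(-reach, reach + 1):
            for dy in range(-reach, reach + 1):
                bucket = cells.get(((cx + dx) % n, (cy + dy) % n))
                if bucket is not None:
                    out.append(bucket)
        if not out:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(out)


def wrap_delta(d: float, side: float) -> float:
    """Signed displacement on a circle of circumference ``side``."""
    if d > 0.5 * side:
        return d - side
    if d < -0.5 * side:
        return d + side
    return d


class Environment:
    """The generated world: type table, patch table, item table, item index."""

    def __init__(self, config: EnvironmentConfig,
                 Q: np.ndarray, H: np.ndarray, S: np.ndarray,
                 patch_x: np.ndarray, patch_y: np.ndarray,
                 patch_type: np.ndarray, patch_members: np.ndarray,
                 item_type: np.ndarray, item_x: np.ndarray,
                 item_y: np.ndarray, item_patch: np.ndarray) -> None:
        self.config = config
        self.Q = Q
        self.H = H
        self.S = S
        self.patch_x = patch_x
        self.patch_y = patch_y
        self.patch_type = patch_type
        self.patch_members = patch_members
        self.item_type = item_type
        self.item_x = item_x
        self.item_y = item_y
        self.item_patch = item_patch
        self.available = np.ones(len(item_type), dtype=bool)
        self.index = SpatialIndex(item_x, item_y, config.world_side, config.grid_cell)
        self.n_changes = 0   # environmental-change events applied so far

    # ---- queries -----------------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.item_type)

    @property
    def n_types(self) -> int:
        """Number of type ids ever minted (grows under environmental
        change; ids of replaced types are retired, never reused)."""
        return len(self.Q)

    def type_spec(self, type_id: int) -> ResourceTypeSpec:
        return ResourceTypeSpec(type_id, float(self.Q[type_id]),
                                float(self.H[type_id]), int(self.S[type_id]))

    def type_census(self) -> np.ndarray:
        """Item counts per type (available or not)."""
        return np.bincount(self.item_type, minlength=self.n_types)

    def items_in_view(self, x: float, y: float, heading: float,
                      rng: StreamRNG, radius: float = 2.0,
                      max_n: int = 20) -> list[int]:
        """Up to ``max_n`` available items in the forward half-disc, in
        uniform random order.

        The viewing region is the half-disc of ``radius`` centered on
        (x, y) and facing ``heading``; candidates come from the grid index
        and are filtered exactly (torus metric).
        """
        cand = self.index.candidates(x, y, radius)
        n_cand = len(cand)
        if n_cand == 0:
            return []
        side = self.config.world_side
        half = 0.5 * side
        hx = math.cos(heading)
        hy = math.sin(heading)
        r2 = radius * radius
        if n_cand < 64:
            # scalar path: cheaper than numpy dispatch for sparse worlds
            avail = self.available
            ix = self.item_x
            iy = self.item_y
            hits = []
            for i in cand:
                if not avail[i]:
                    continue
                dx = ix[i] - x
                if dx > half:
                    dx -= side
                elif dx < -half:
                    dx += side
                dy = iy[i] - y
                if dy > half:
                    dy -= side
                elif dy < -half:
                    dy += side
                if dx * dx + dy * dy <= r2 and dx * hx + dy * hy >= 0.0:
                    hits.append(int(i))
        else:
            dx = self.item_x[cand] - x
            dy = self.item_y[cand] - y
            np.subtract(dx, side, out=dx, where=dx > half)
            np.add(dx, side, out=dx, where=dx < -half)
            np.subtract(dy, side, out=dy, where=dy > half)
            np.add(dy, side, out=dy, where=dy < -half)
            keep = ((dx * dx + dy * dy <= r2)
                    & (dx * hx + dy * hy >= 0.0)
                    & self.available[cand])
            hits = [int(i) for i in cand[keep]]
        rng.shuffle(hits)
        if len(hits) > max_n:
            del hits[max_n:]
        return hits

    # ---- state transitions -------------------------------------------

    def consume_item(self, item_id: int) -> None:
        """Mark an item unavailable; consuming twice is a contract violation."""
        if not self.available[item_id]:
            raise ValueError(f"item {item_id} is not available")
        self.available[item_id] = False

    def annual_growth(self) -> None:
        """Regrow every consumed item at its original position (and current type)."""
        self.available[:] = True

    def environmental_change_step(self, dt_minutes: float, rng: np.random.Generator,
                                  year_minutes: float) -> list[tuple[int, int]]:
        """Run ``dt_minutes`` worth of per-minute replacement trials.

        Each minute one *living* type is replaced with probability
        EC / year_minutes.  In ``replace`` mode the old id is retired and a
        brand-new type id is minted (fresh quality and shape, same global
        difficulty); all items of the old type become the new type, and
        foragers are naive about it by construction.  Consumption history
        and skills for the retired id are untouched — they refer to a
        resource that no longer exists.  In ``quality`` mode the type stays
        familiar and only its quality is redrawn.  Returns (old_id, new_id)
        pairs (old == new in quality mode).
        """
        if self.config.ec_per_year <= 0:
            return []
        p = self.config.ec_per_year / year_minutes
        if dt_minutes == 1.0:
            n_events = 1 if rng.random() < p else 0
        else:
            n_events = int(rng.binomial(int(round(dt_minutes)), p))
        replaced: list[tuple[int, int]] = []
        living = None
        for _ in range(n_events):
            if living is None:
                living = sorted(set(np.unique(self.item_type)))
            old = int(living[int(rng.integers(len(living)))])
            q = float(rng.normal(self.config.quality_mean, self.config.quality_sd))
            if self.config.clip_quality:
                q = max(q, 0.0)
            if self.config.change_mode == "replace":
                new = self.n_types
                self.Q = np.append(self.Q, q)
                self.H = np.append(self.H, self.config.H)
                self.S = np.append(self.S, int(rng.integers(1, 5)))
                self.item_type[self.item_type == old] = new
                living[living.index(old)] = new
            else:
                new = old
                self.Q[old] = q
            replaced.append((old, new))
            self.n_changes += 1
        return replaced

    # ---- serialization -----------------------------------------------

    def to_dir(self, path: str, seed: int | None = None) -> None:
        """Write the environment as a CSV pair plus a JSON header."""
        os.makedirs(path, exist_ok=True)
        types = pd.DataFrame({
            "type_id": np.arange(self.n_types),
            "Q": self.Q, "H": self.H, "S": self.S,
        })
        types.to_csv(os.path.join(path, "types.csv"), index=False)
        items = pd.DataFrame({
            "item_id": np.arange(self.n_items),
            "type_id": self.item_type,
            "x": self.item_x, "y": self.item_y,
            "patch_id": self.item_patch,
        })
        items.to_csv(os.path.join(path, "items.csv"), index=False)
        header = {"config": asdict(self.config), "environment_seed": seed}
        with open(os.path.join(path, "environment.json"), "w") as fh:
            json.dump(header, fh, indent=2)

    @classmethod
    def from_dir(cls, path: str) -> "Environment":
        with open(os.path.join(path, "environment.json")) as fh:
            header = json.load(fh)
        config = EnvironmentConfig(**header["config"])
        types = pd.read_csv(os.path.join(path, "types.csv"))
        items = pd.read_csv(os.path.join(path, "items.csv"))
        n_patches = int(items["patch_id"].max()) + 1 if len(items) else 0
        return cls(
            config,
            Q=types["Q"].to_numpy(float),
            H=types["H"].to_numpy(float),
            S=types["S"].to_numpy(np.int64),
            patch_x=np.zeros(n_patches), patch_y=np.zeros(n_patches),
            patch_type=np.zeros(n_patches, dtype=np.int64),
            patch_members=np.zeros((n_patches, config.types_per_patch), dtype=np.int64),
            item_type=items["type_id"].to_numpy(np.int64),
            item_x=items["x"].to_numpy(float),
            item_y=items["y"].to_numpy(float),
            item_patch=items["patch_id"].to_numpy(np.int64),
        )


def generate_resource_types(config: EnvironmentConfig,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the (Q, H, S) table for ``config.R`` resource types."""
    Q = rng.normal(config.quality_mean, config.quality_sd, size=config.R)
    if config.clip_quality:
        Q = np.clip(Q, 0.0, None)
    H = np.full(config.R, float(config.H))
    S = rng.integers(1, 5, size=config.R)
    return Q, H, S


def generate_environment(config: EnvironmentConfig,
                         rng: np.random.Generator) -> Environment:
    """Build a world from a config and an environment RNG stream.

    Patch centers are uniform in the square (overlap permitted) and items
    are uniform within the patch disc.  In ``mixed`` layout patch type k
    owns resource types [k*5, k*5+5) and each patch draws 3 of those 5;
    ``pure`` patches carry a single type; ``random`` scatters items
    uniformly with uniformly random types and no patch structure.
    """
    config.validate()
    Q, H, S = generate_resource_types(config, rng)
    n_p = config.n_patches
    n_items = n_p * config.items_per_patch
    side = config.world_side

    if config.layout_mode == "random":
        item_x = rng.random(n_items) * side
        item_y = rng.random(n_items) * side
        item_type = rng.integers(config.R, size=n_items)
        item_patch = np.full(n_items, -1, dtype=np.int64)
        patch_x = np.empty(0)
        patch_y = np.empty(0)
        patch_type = np.empty(0, dtype=np.int64)
        patch_members = np.empty((0, config.types_per_patch), dtype=np.int64)
        return Environment(config, Q, H, S, patch_x, patch_y, patch_type,
                           patch_members, item_type, item_x, item_y, item_patch)

    patch_x = rng.random(n_p) * side
    patch_y = rng.random(n_p) * side
    patch_type = rng.integers(config.n_patch_types, size=n_p)

    if config.layout_mode == "pure":
        members_per = 1
        patch_members = (patch_type % config.R).reshape(-1, 1).astype(np.int64)
    else:
        members_per = config.types_per_patch
        tppt = config.types_per_patch_type
        patch_members = np.empty((n_p, members_per), dtype=np.int64)
        for p in range(n_p):
            pool = patch_type[p] * tppt + rng.choice(tppt, size=members_per,
                                                     replace=False)
            patch_members[p] = pool

    ipp = config.items_per_patch
    # items uniform in the patch disc (sqrt-radius trick), types uniform
    # over the patch's member types
    u = rng.random(n_items)
    theta = rng.random(n_items) * TWO_PI
    r = config.patch_radius * np.sqrt(u)
    item_patch = np.repeat(np.arange(n_p), ipp)
    item_x = (patch_x[item_patch] + r * np.cos(theta)) % side
    item_y = (patch_y[item_patch] + r * np.sin(theta)) % side
    member_pick = rng.integers(members_per, size=n_items)
    item_type = patch_members[item_patch, member_pick]

    return Environment(config, Q, H, S, patch_x, patch_y, patch_type,
                       patch_members, item_type, item_x, item_y, item_patch)
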