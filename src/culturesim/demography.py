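"""Energy budget, mortality, selection-weighted reproduction and group
splitting.

Deaths (old age, starvation, or a stochastic per-minute hazard) immediately
trigger a birth, keeping the population at constant size N.  The parent is
drawn with probability proportional to energy raised to the selection
exponent W (=3), so a doubling of energy gives an 8-fold higher chance to
reproduce.  Offspring inherit the parent's heritable parameters with a
per-parameter mutation chance; groups that outgrow the maximum size G split
uniformly at random into two equal halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import PARAM_BOUNDS, PARAM_NAMES

ENERGY_FLOOR = 1e-12   # keeps the selection lottery well-defined


@dataclass
class LifeHistoryConfig:
    """Demographic and energetic parameters.

    ``metabolism_per_min`` and ``stochastic_death_hazard`` are calibration
    constants: the defaults keep a competent forager in positive energy
    balance and make accidental death rare relative to old age.
    """

    N: int = 100                       # population size (constant)
    G: int = 20                        # maximum group size
    metabolism_per_min: float = 0.01   # energy per minute
    digestion_interval: float = 100.0  # minutes
    stomach_capacity: int = 20         # items per digestion cycle
    reproduction_cost: float = 5000.0
    max_age_years: float = 20.0
    stochastic_death_hazard: float = 2e-6   # per-minute death probability
    mutation_rate: float = 0.05
    selection_exponent: float = 3.0    # W
    year_days: int = 360
    day_minutes: int = 720
    initial_energy: float = 100.0      # energy stake of a newborn
    satiation_mode: str = "modal"      # modal | all | any
    viability_deaths_per_year: int = 0  # halt threshold; 0 -> 20 * N

    @property
    def year_minutes(self) -> float:
        return float(self.year_days * self.day_minutes)

    @property
    def max_age_minutes(self) -> float:
        return self.max_age_years * self.year_minutes

    def validate(self) -> None:
        if self.N <= 0 or self.G <= 0:
            raise ValueError("N and G must be positive")
        if self.satiation_mode not in ("modal", "all", "any"):
            raise ValueError(f"unknown satiation_mode {self.satiation_mode!r}")
        for name in ("digestion_interval", "reproduction_cost", "max_age_years",
                     "initial_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def selection_weights(energies: np.ndarray, W: float) -> np.ndarray:
    """Reproduction weights h^W; energies are floored at a small positive
    value so the lottery is defined even for starving foragers."""
    h = np.maximum(np.asarray(energies, dtype=float), ENERGY_FLOOR)
    return h ** W


def select_reproducer(energies: np.ndarray, W: float, rng,
                      exclude: int = -1) -> int:
    """Draw a parent index with probability h_i^W / sum_j h_j^W.

    ``exclude`` removes one forager (the one being replaced) from the
    lottery.  If every candidate is at the energy floor the draw degenerates
    to uniform automatically.
    """
    w = selection_weights(energies, W)
    if 0 <= exclude < len(w):
        w[exclude] = 0.0
    total = w.sum()
    u = rng.uniform() * total
    return int(np.searchsorted(np.cumsum(w), u, side="right").clip(0, len(w) - 1))


def mutate_params(parent: tuple[float, ...], mutation_rate: float,
                  rng) -> tuple[float, ...]:
    """Inherit the eight heritable parameters, each independently mutating
    with ``mutation_rate`` to N(parent value, max/5), clipped to bounds."""
    out = list(parent)
    for k, name in enumerate(PARAM_NAMES):
        if rng.uniform() < mutation_rate:
            lo, hi = PARAM_BOUNDS[name]
            v = rng.normal(out[k], hi / 5.0)
            out[k] = min(max(v, lo), hi)
    return tuple(out)


def split_group(members: list[int], rng) -> tuple[list[int], list[int]]:
    """Partition a group uniformly at random into two equal-size halves
    (sizes differ by one when the group is odd)."""
    pool = list(members)
    rng.shuffle(pool)
    half = len(pool) // 2
    return pool[half:], pool[:half]
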