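"""Ready-made simulation scenarios.

``desk_config`` is a reduced scenario sized to run in seconds-to-minutes on
one CPU while keeping the full-scale scenario's key proportions: the same
patch cover fraction (~19% of the world), a per-lifetime consumption budget
that stays well below diet saturation relative to the type pool, groups at
half the full maximum size, and a compressed year so that several
non-overlapping generations fit in a short run.  ``tradition_config`` is
the one-group variant used to measure traditions, and ``solitary_config``
isolates asocial learning.  ``paper_scale_config`` is the full published
geometry (250 types, 24500 patches, 100 foragers, 360 x 720-minute years);
it is provided for completeness but needs cluster-scale compute.
"""

from __future__ import annotations

from dataclasses import replace

from .agents import HeritableParams, MovementConstants
from .demography import LifeHistoryConfig
from .engine import SimulationConfig
from .environment import EnvironmentConfig
from .learning import SocialLearningConstants

#: Stand-in "evolved" parameter values used to initialize non-evolutionary
#: runs: a high reinforcement learning rate, strong selectivity, exploration
#: at the low end that still lets solitary foragers bootstrap a diet, and
#: full-length observation bouts.
EVOLVED_PARAMS = HeritableParams(
    delta=5.0, phi=0.05, sigma=10.0, epsilon=0.05,
    lam=0.9, gamma=0.3, omega=0.1, tau=1.0,
)


def desk_config(slm_mode: str = "LE", H: float = 1.0,
                seed_env: int = 1, seed_behavior: int = 2,
                duration_years: float = 5.0,
                snapshot_years: tuple = (),
                **overrides) -> SimulationConfig:
    """Reduced two-group scenario: N=20 foragers, 50 resource types in 200
    patches, 3600-minute years, 5-year lifespans."""
    env = EnvironmentConfig(
        R=50, n_patch_types=10, types_per_patch_type=5, types_per_patch=3,
        n_patches=200, items_per_patch=150, world_side=570.0,
        ec_per_year=1.0, H=H,
    )
    # G=12 leaves a few births of headroom above the two groups of 10, so
    # group lineages are not reshuffled by a split after every net birth
    life = LifeHistoryConfig(
        N=20, G=12, metabolism_per_min=0.004, reproduction_cost=50.0,
        max_age_years=5.0, stochastic_death_hazard=2e-5,
        year_days=30, day_minutes=120, initial_energy=100.0,
    )
    cfg = SimulationConfig(
        env=env, life=life,
        social=SocialLearningConstants(),
        # more than half the group must be in SAFESPACE so that stable
        # sub-clusters cannot drift apart; for desk groups of <=10 that is 6
        # (the count is capped at group size - 1 for shrunken groups)
        # regrouping covers 10 m per event (same speed, coarser
        # re-evaluation) to keep the event count manageable at desk scale
        movement=MovementConstants(safe_neighbors=6, movetogroup_step=10.0),
        base_params=replace(EVOLVED_PARAMS),
        slm_mode=slm_mode,
        duration_years=duration_years,
        snapshot_years=snapshot_years,
        n_groups=2,
        seed_env=seed_env, seed_behavior=seed_behavior,
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    return cfg


def tradition_config(H: float = 1.0, slm_mode: str = "LE",
                     seed_env: int = 1, seed_behavior: int = 2,
                     duration_years: float = 15.0,
                     snapshot_years: tuple = (10.0, 15.0)) -> SimulationConfig:
    """Desk design for measuring traditions: one full-size stable group.

    All 20 foragers form a single group of the full-scale size, so the
    lineage is never reshuffled by splits (births exactly balance deaths in
    a one-group population) and the group-level repertoire has a stable
    carrier with a large pair sample; the between-group reference comes
    entirely from the environment-matched paired run.  The safety
    requirement (11 of 19) exceeds half the group so it cannot fission into
    two self-stable sub-clusters, and regrouping is re-evaluated every 15 m
    of travel to keep the event count of the large tight group manageable.
    """
    cfg = desk_config(slm_mode=slm_mode, H=H, seed_env=seed_env,
                      seed_behavior=seed_behavior,
                      duration_years=duration_years,
                      snapshot_years=snapshot_years)
    cfg.n_groups = 1
    cfg.life.G = 24
    cfg.movement.safe_neighbors = 11
    cfg.movement.movetogroup_step = 15.0
    # a patch must feed the whole 20-member group for a few digestion
    # cycles, as at full scale (1200 items / 20 foragers); desk patches of
    # 150 are stripped in minutes and leave the group starving mid-travel
    cfg.env.items_per_patch = 900
    # a single group re-treads its own depleted backtrail in a 570-m world;
    # more patches over a wider torus restore route diversity (same ~19%
    # patch cover)
    cfg.env.n_patches = 500
    cfg.env.world_side = 900.0
    return cfg


def solitary_config(H: float = 1.0, seed_env: int = 1, seed_behavior: int = 2,
                    duration_years: float = 2.0, N: int = 5,
                    equal_quality: bool = False) -> SimulationConfig:
    """Solitary foragers (no grouping, no social learning); with
    ``equal_quality`` every resource type has the same quality, isolating
    the familiarity-bias feedback from quality differences."""
    cfg = desk_config(slm_mode="solitary", H=H, seed_env=seed_env,
                      seed_behavior=seed_behavior,
                      duration_years=duration_years)
    cfg.life.N = N
    if equal_quality:
        cfg.env.quality_sd = 0.0
    return cfg


def paper_scale_config(slm_mode: str = "LE", H: float = 1.0,
                       seed_env: int = 1, seed_behavior: int = 2,
                       duration_years: float = 120.0) -> SimulationConfig:
    """The full published scenario (cluster-scale compute)."""
    return SimulationConfig(
        env=EnvironmentConfig(ec_per_year=5.0, H=H),
        life=LifeHistoryConfig(),
        social=SocialLearningConstants(),
        movement=MovementConstants(),
        base_params=replace(EVOLVED_PARAMS),
        slm_mode=slm_mode,
        duration_years=duration_years,
        snapshot_years=(20.0, 100.0, 120.0),
        n_groups=5,
        seed_env=seed_env, seed_behavior=seed_behavior,
    )
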