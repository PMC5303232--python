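"""Asocial and social learning rules.

Foragers are born knowing nothing: expected rewards a_ir, certainty c_ir and
processing experience t_ir are all zero and there is no forgetting.  Asocial
learning combines exploration (certainty-gated), a skill sigmoid in practice
time, and Rescorla-Wagner reinforcement of expected rewards.  Stimulus
enhancement raises the probability of choosing a recently observed resource
type; observational learning transfers processing experience from a more
skilled demonstrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SocialLearningConstants:
    """Fixed social-learning scales."""

    K: float = 0.1            # effectiveness of observational learning
    M: float = 1.0            # maximal processing/consumption time (minutes)
    se_window: float = 30.0   # minutes a social observation can stimulate choice


@dataclass
class LearningMemory:
    """Per-forager long-term memory over the R resource types.

    ``a``: expected reward per type; ``c``: certainty about that reward;
    ``t``: cumulative processing experience in minutes; ``a_env``: expected
    quality of the environment (the selectivity reference point).
    """

    a: np.ndarray
    c: np.ndarray
    t: np.ndarray
    a_env: float

    @classmethod
    def naive(cls, n_types: int, a_env: float) -> "LearningMemory":
        return cls(np.zeros(n_types), np.zeros(n_types), np.zeros(n_types), a_env)


def exploration_probability(epsilon: float, c_ir: float) -> float:
    """P_E = epsilon * (1 - min(1, c_ir)).

    Certainty can exceed 1 in principle, so it is clamped before entering
    the probability; a completely unfamiliar type (c=0) is explored at the
    full rate epsilon.
    """
    c = c_ir if c_ir < 1.0 else 1.0
    return epsilon * (1.0 - c)


def update_certainty(c_ir: float, lam: float, e_ir: float, a_ir: float) -> float:
    """c' = (1-lam) c + lam (1 - min(1, |(e-a)/e|)).

    A realized reward of exactly zero carries no information about relative
    accuracy; the discrepancy is then treated as maximal so certainty decays
    toward zero rather than inflating.
    """
    if e_ir == 0.0:
        return (1.0 - lam) * c_ir
    disc = abs((e_ir - a_ir) / e_ir)
    if disc > 1.0:
        disc = 1.0
    return (1.0 - lam) * c_ir + lam * (1.0 - disc)


def skill_level(t_ir: float, H_r: float, S_r: int) -> float:
    """Sigmoid skill s = t^S / (H^S + t^S): 0 at t=0, 1/2 at t=H, -> 1."""
    if t_ir <= 0.0:
        return 0.0
    ts = t_ir ** S_r
    return ts / (H_r ** S_r + ts)


def realized_reward(Q_r: float, s_ir: float, Z: float, rng) -> float:
    """e = Q * s + N(0, Z) environmental noise."""
    if Z == 0.0:
        return Q_r * s_ir
    return Q_r * s_ir + rng.normal(0.0, Z)


def update_association(a_ir: float, lam: float, e_ir: float) -> float:
    """Rescorla-Wagner reinforcement: a' = a + lam (e - a)."""
    return a_ir + lam * (e_ir - a_ir)


def stimulus_enhancement_probability(gamma: float, se_type: int, se_time: float,
                                     type_id: int, now: float,
                                     window: float = 30.0) -> float:
    """P_S = gamma if the single remembered observation matches ``type_id``
    and happened within ``window`` minutes, else 0."""
    if se_type == type_id and se_type >= 0 and now - se_time <= window:
        return gamma
    return 0.0


def observational_learning_gain(K: float, tau_i: float, p_k: float, M: float,
                                t_kr: float, t_ir: float) -> float:
    """Experience transfer from demonstrator k to observer i.

    delta_t = max(K * (o/M) * (t_kr - t_ir), 0) with effective observation
    time o = min(tau_i, p_k); no gain from a demonstrator at or below the
    observer's own experience.  Observation carries no reward information.
    """
    o = tau_i if tau_i < p_k else p_k
    gain = K * (o / M) * (t_kr - t_ir)
    return gain if gain > 0.0 else 0.0
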