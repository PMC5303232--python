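"""Cultural metrics computed from snapshots.

A forager's *behavioral repertoire* is its vector of per-type lifetime
consumption counts d_ir.  Repertoire similarity between two groups is the
mean pairwise cosine of member repertoires.  A *traditional difference* is
within-group similarity across a generation-spanning interval minus the
between-group similarity against an environment-matched paired run, which
controls for population-wide convergence on the same high-quality
resources.  *Cumulative cultural change* is the proportional change of a
population-mean repertoire measure (total energy intake, repertoire
quality, repertoire diversity, or average skill) between an early year --
the most a single lifetime of learning can achieve -- and a late year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .learning import skill_level

MEASURE_NAMES = ("total_energy", "repertoire_quality",
                 "repertoire_diversity", "average_skill")


# ---------------------------------------------------------------- similarity

def repertoire_similarity(group_a: np.ndarray, group_b: np.ndarray,
                          ids_a=None, ids_b=None) -> float:
    """Mean pairwise cosine similarity between two groups of repertoires.

    ``group_a``/``group_b`` are (n_foragers, R) count matrices.  Pairs of
    the same forager (matching ids, as when a group is compared with itself
    at one point in time) are excluded; the mean is taken over the pairs
    actually summed.  Foragers with an all-zero repertoire have no defined
    direction and are dropped with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be nonempty 2-D count matrices")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    keep_a = na > 0
    keep_b = nb > 0
    if not keep_a.all() or not keep_b.all():
        warnings.warn("dropping foragers with empty repertoires "
                      "(cosine undefined)", stacklevel=2)
    if ids_a is not None:
        ids_a = np.asarray(ids_a)[keep_a]
    if ids_b is not None:
        ids_b = np.asarray(ids_b)[keep_b]
    a = a[keep_a] / na[keep_a, None]
    b = b[keep_b] / nb[keep_b, None]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("no forager with a nonempty repertoire")
    cos = a @ b.T
    if ids_a is not None and ids_b is not None:
        mask = ids_a[:, None] != ids_b[None, :]
    else:
        mask = np.ones_like(cos, dtype=bool)
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        raise ValueError("no valid forager pairs to compare")
    # count vectors are nonnegative, so cosines live in [0, 1]; clip guards
    # against rounding spill just outside
    return float(np.clip(cos[mask], 0.0, 1.0).mean())


def within_group_similarity_over_time(run, group_id: int,
                                      y1: float, y2: float) -> float | None:
    """Similarity of one group's repertoires between two snapshot years.

    All cross-snapshot member pairs are included (forager ids never repeat,
    so the same-individual exclusion cannot trigger when the interval spans
    at least a maximum lifespan).  Returns None when the group is missing at
    either year.
    """
    s1 = run.snapshot_at(y1)
    s2 = run.snapshot_at(y2)
    width = max(s1.R, s2.R)
    ids1, m1 = s1.repertoire_matrix(group_id, width=width)
    ids2, m2 = s2.repertoire_matrix(group_id, width=width)
    if len(ids1) == 0 or len(ids2) == 0:
        return None
    return repertoire_similarity(m1, m2, ids1, ids2)


def between_group_similarity_paired(run, paired_run, group_id: int,
                                    year: float,
                                    weight_by_size: bool = False) -> float | None:
    """Mean similarity between a focal group and every group of an
    environment-matched independent run at the same year.

    The two runs must share the environment seed (same world, same schedule
    of environmental change) so that between-group similarity is not
    inflated by relatedness or deflated by direct competition.
    """
    if run.manifest.get("seed_env") != paired_run.manifest.get("seed_env"):
        raise ValueError("paired runs must share the environment seed")
    focal = run.snapshot_at(year)
    other = paired_run.snapshot_at(year)
    width = max(focal.R, other.R)
    ids_f, m_f = focal.repertoire_matrix(group_id, width=width)
    if len(ids_f) == 0:
        return None
    sims = []
    sizes = []
    for gid in sorted(other.foragers["group_id"].unique()):
        ids_o, m_o = other.repertoire_matrix(int(gid), width=width)
        if len(ids_o) == 0:
            continue
        sims.append(repertoire_similarity(m_f, m_o, ids_f, ids_o))
        sizes.append(len(ids_o))
    if not sims:
        return None
    if weight_by_size:
        return float(np.average(sims, weights=sizes))
    return float(np.mean(sims))


def traditional_difference(run, paired_run, group_id: int,
                           y1: float, y2: float) -> float | None:
    """Within-group similarity over [y1, y2] minus between-group similarity
    against the paired run at y2; positive values indicate a group-specific
    repertoire inherited across generations."""
    within = within_group_similarity_over_time(run, group_id, y1, y2)
    if within is None:
        return None
    between = between_group_similarity_paired(run, paired_run, group_id, y2)
    if between is None:
        return None
    return within - between


def traditional_differences_all(run, paired_run, y1: float,
                                y2: float) -> dict[int, float]:
    """Traditional-difference score for every focal group present at both
    years (missing groups are skipped)."""
    s1 = run.snapshot_at(y1)
    s2 = run.snapshot_at(y2)
    gids = sorted(set(s1.foragers["group_id"]) & set(s2.foragers["group_id"]))
    out: dict[int, float] = {}
    for gid in gids:
        score = traditional_difference(run, paired_run, int(gid), y1, y2)
        if score is not None:
            out[int(gid)] = score
    return out


# ------------------------------------------------------------------ measures

@dataclass
class CulturalMeasures:
    """The four per-forager repertoire measures."""

    total_energy: float
    repertoire_quality: float
    repertoire_diversity: float
    average_skill: float

    def get(self, name: str) -> float:
        return getattr(self, name)


def cultural_measures(d: np.ndarray, Q: np.ndarray, s: np.ndarray) -> CulturalMeasures:
    """Measures for one forager.

    ``d``: per-type consumption counts; ``Q``: type qualities; ``s``: the
    forager's current skill per type.  Diet proportions z and the diversity
    sum run over consumed types only; the per-item reward entering total
    energy is the forager's current skill-dependent reward Q_r * s_ir.
    An empty repertoire has no defined measures (all NaN).
    """
    d = np.asarray(d, dtype=float)
    total = d.sum()
    if total <= 0:
        return CulturalMeasures(np.nan, np.nan, np.nan, np.nan)
    consumed = d > 0
    z = d[consumed] / total
    e = Q[consumed] * s[consumed]
    return CulturalMeasures(
        total_energy=float(np.sum(d[consumed] * e)),
        repertoire_quality=float(np.sum(z * Q[consumed])),
        repertoire_diversity=float(-np.sum(z * np.log(z))),
        average_skill=float(np.sum(z * s[consumed])),
    )


def snapshot_measures(snapshot) -> pd.DataFrame:
    """Per-forager measures for every living forager in a snapshot; skill is
    recomputed from stored experience and the snapshot's type table."""
    ids, d_mat = snapshot.repertoire_matrix(None, "d")
    _, t_mat = snapshot.repertoire_matrix(None, "t")
    Q = snapshot.type_Q
    H = snapshot.type_H
    S = snapshot.type_S
    rows = []
    for k, fid in enumerate(ids):
        s = np.array([skill_level(t_mat[k, r], H[r], int(S[r]))
                      for r in range(snapshot.R)])
        m = cultural_measures(d_mat[k], Q, s)
        rows.append({"forager_id": fid, "total_energy": m.total_energy,
                     "repertoire_quality": m.repertoire_quality,
                     "repertoire_diversity": m.repertoire_diversity,
                     "average_skill": m.average_skill})
    return pd.DataFrame(rows)


def population_mean_measure(run, year: float, measure: str) -> float:
    """Population mean of one measure at a snapshot year (foragers with
    empty repertoires are excluded)."""
    if measure not in MEASURE_NAMES:
        raise ValueError(f"unknown measure {measure!r}")
    df = snapshot_measures(run.snapshot_at(year))
    return float(df[measure].mean(skipna=True))


def cumulative_change(run, measure: str, y_early: float,
                      y_late: float) -> float:
    """(mean(y_late) - mean(y_early)) / mean(y_early) for one measure;
    undefined (NaN, with a warning) when the early mean is zero."""
    early = population_mean_measure(run, y_early, measure)
    late = population_mean_measure(run, y_late, measure)
    if early == 0 or not np.isfinite(early):
        warnings.warn(f"early mean of {measure} is zero/undefined; "
                      "cumulative change undefined", stacklevel=2)
        return np.nan
    return (late - early) / early


# -------------------------------------------------------------- significance

def significance_summary(scores_by_condition: dict[str, np.ndarray],
                         familywise_alpha: float = 0.05) -> pd.DataFrame:
    """One-sample Wilcoxon signed-rank tests (continuity-corrected normal
    approximation, one-sided 'greater than zero') per condition, with a
    Bonferroni-corrected per-test alpha of familywise / #conditions."""
    n_cond = len(scores_by_condition)
    if n_cond == 0:
        raise ValueError("no conditions to test")
    alpha = familywise_alpha / n_cond
    rows = []
    for name, scores in scores_by_condition.items():
        scores = np.asarray(scores, dtype=float)
        if len(scores) < 5:
            raise ValueError(f"condition {name!r} needs >= 5 replicate scores")
        if np.all(scores == 0):
            stat, p = np.nan, np.nan
        else:
            res = stats.wilcoxon(scores, alternative="greater",
                                 correction=True, method="approx")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"condition": name, "n": len(scores),
                     "median": float(np.median(scores)),
                     "statistic": stat, "p_value": p, "alpha": alpha,
                     "significant": bool(np.isfinite(p) and p < alpha)})
    return pd.DataFrame(rows)
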