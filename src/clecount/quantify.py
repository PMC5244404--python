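"""Video-level quantification and validation statistics.

Per-frame counts are aggregated into per-video means and totals, and
compared between experimental arms.  Two statistics carry the
scientific weight:

* **Lin's concordance correlation coefficient (CCC)** measures
  agreement between two count series (automatic vs. manual, or observer
  vs. observer).  Unlike Pearson's r it penalizes location and scale
  shifts:

      rho_c = 2*s_xy / (s_x^2 + s_y^2 + (m_x - m_y)^2)

  with population (1/n) moments.  rho_c = 1 only for exact agreement.

* **Mann-Whitney U** compares two independent groups of per-unit
  summaries.  For small tie-free designs (total n <= 12, which covers a
  5-vs-5 animal study) the two-sided p-value is exact, by full
  enumeration of all C(n_a + n_b, n_a) group assignments; otherwise a
  normal approximation with tie-corrected variance and continuity
  correction is used, and the result records which method produced it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .detection import FrameDetection

#: Largest pooled sample size for which the exact enumeration p-value
#: is used (tie-free data only).  C(12, 6) = 924 assignments.
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class VideoQuantification:
    """Counts of one video plus its study labels."""

    video_id: str
    counts_per_frame: np.ndarray
    rat_id: str = ""
    route: str = ""  # e.g. "ET" or "IV"
    condition: str = ""  # e.g. "Ctrl" or "RT"

    def __post_init__(self) -> None:
        self.counts_per_frame = np.asarray(self.counts_per_frame, dtype=float)
        if self.counts_per_frame.size == 0:
            raise ValueError("counts_per_frame must be nonempty")
        if np.any(self.counts_per_frame < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(self.counts_per_frame.size)

    @property
    def mean_count(self) -> float:
        return float(self.counts_per_frame.mean())

    @property
    def total_count(self) -> float:
        return float(self.counts_per_frame.sum())


@dataclass
class AgreementResult:
    """Lin's CCC between two paired count series."""

    n: int
    x_mean: float
    y_mean: float
    x_var: float
    y_var: float
    covariance: float
    ccc: float


@dataclass
class GroupComparisonResult:
    """Two-group Mann-Whitney comparison of per-unit summaries."""

    group_a: str
    group_b: str
    group_a_values: np.ndarray
    group_b_values: np.ndarray
    u_statistic: float
    p_value: float
    method: str  # "exact-enumeration" or "normal-approximation"
    unit: str = ""  # "rat" or "video"

    @property
    def group_a_mean(self) -> float:
        return float(np.mean(self.group_a_values))

    @property
    def group_b_mean(self) -> float:
        return float(np.mean(self.group_b_values))


def quantify_video(
    detections: Sequence[FrameDetection],
    video_id: str = "",
    rat_id: str = "",
    route: str = "",
    condition: str = "",
) -> VideoQuantification:
    """Collapse per-frame detections into a per-video quantification.

    Counts are kept in frame order; the mean and total are derived
    properties, so counts are conserved by construction.
    """
    if not detections:
        raise ValueError("need at least one frame detection")
    counts = np.array([d.count for d in detections], dtype=float)
    return VideoQuantification(
        video_id=video_id,
        counts_per_frame=counts,
        rat_id=rat_id,
        route=route,
        condition=condition,
    )


def concordance_correlation(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Lin's concordance correlation coefficient with population moments.

    Edge cases: two identical constant series agree perfectly
    (rho_c = 1); two different constant series do not agree at all
    (rho_c = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 2:
        raise ValueError("need at least two paired observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n) variances
    cov = float(((x - mx) * (y - my)).mean())
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        ccc = 1.0  # both series constant and equal
    else:
        ccc = 2.0 * cov / denom
    return AgreementResult(
        n=int(x.size), x_mean=float(mx), y_mean=float(my),
        x_var=float(vx), y_var=float(vy), covariance=cov, ccc=float(ccc),
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a via rank sums with mid-ranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """P(|U - n_a*n_b/2| >= observed) by enumeration of all assignments."""
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    mu = na * (n - na) / 2.0
    d_obs = abs(u_obs - mu) - 1e-12  # tolerate float fuzz in the rank sums
    ranks = stats.rankdata(pooled)
    extreme = 0
    total = 0
    for combo in itertools.combinations(range(n), na):
        ra = ranks[list(combo)].sum()
        u = ra - na * (na + 1) / 2.0
        total += 1
        if abs(u - mu) >= d_obs:
            extreme += 1
    return min(1.0, extreme / total)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for tie-free pooled samples of size <=
    :data:`EXACT_ENUMERATION_LIMIT`; otherwise the normal approximation
    with tie-corrected variance and a 0.5 continuity correction.  The
    two-sided exact p is P(|U - n_a*n_b/2| >= |observed|) under random
    assignment, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_ENUMERATION_LIMIT and not has_ties:
        p = _exact_two_sided_p(a, b, u)
        method = "exact-enumeration"
    else:
        na, nb = a.size, b.size
        mu = na * nb / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = pooled.size
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1.0)) if n > 1 else 0.0
        var = na * nb / 12.0 * (n + 1.0 - tie_term)
        if var <= 0:
            p = 1.0  # all pooled values identical
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * stats.norm.sf(z))
        method = "normal-approximation"
    return GroupComparisonResult(
        group_a="a", group_b="b",
        group_a_values=a, group_b_values=b,
        u_statistic=u, p_value=p, method=method,
    )


def compare_groups(
    videos: Sequence[VideoQuantification],
    factor: str = "route",
    unit: str = "rat",
    statistic: str = "mean",
) -> GroupComparisonResult:
    """Mann-Whitney comparison of two levels of a study factor.

    ``factor`` selects the grouping label (``route`` or ``condition``);
    ``unit`` chooses the statistical unit: per ``rat`` each animal
    contributes the mean of its videos' statistic (appropriate when the
    design nests consecutive acquisitions within animals), per ``video``
    each video contributes directly.  ``statistic`` is the per-video
    ``mean`` or ``total`` count.  Group levels are ordered
    alphabetically into (a, b).
    """
    if factor not in ("route", "condition"):
        raise ValueError(f"factor must be 'route' or 'condition', got {factor!r}")
    if unit not in ("rat", "video"):
        raise ValueError(f"unit must be 'rat' or 'video', got {unit!r}")
    if statistic not in ("mean", "total"):
        raise ValueError(f"statistic must be 'mean' or 'total', got {statistic!r}")
    value = {
        "mean": lambda v: v.mean_count,
        "total": lambda v: v.total_count,
    }[statistic]
    label = {"route": lambda v: v.route, "condition": lambda v: v.condition}[factor]
    levels = sorted({label(v) for v in videos})
    if len(levels) != 2:
        raise ValueError(f"need exactly two {factor} levels, got {levels}")
    per_level: dict[str, list[float]] = {lv: [] for lv in levels}
    if unit == "video":
        for v in videos:
            per_level[label(v)].append(value(v))
    else:
        by_rat: dict[tuple[str, str], list[float]] = {}
        for v in videos:
            if not v.rat_id:
                raise ValueError(f"video {v.video_id!r} lacks a rat_id")
            by_rat.setdefault((label(v), v.rat_id), []).append(value(v))
        for (lv, _rat), vals in sorted(by_rat.items()):
            per_level[lv].append(float(np.mean(vals)))
    for lv in levels:
        if not per_level[lv]:
            raise ValueError(f"{factor} level {lv!r} has no {unit}s")
    res = mann_whitney(per_level[levels[0]], per_level[levels[1]])
    res.group_a, res.group_b = levels[0], levels[1]
    res.unit = unit
    return res
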