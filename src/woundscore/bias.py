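"""Phenotypic-bias geometry, density-robustness testing, and grouping.

In the (migration, death) score plane the diagonal death = migration is the
no-bias line.  Each dose's deviation from it is summarized two ways:

  * magnitude: the signed perpendicular distance, which reduces to
    sin(pi/4) * (death - migration), positive on the cytotoxic side;
  * direction: the angular deviation arctan2(death, migration) - pi/4,
    in [-pi/4, +pi/4], positive toward the death axis.

Robustness of the scoring against seeding-density artifacts is quantified
by two-sample Kolmogorov-Smirnov tests between the per-dose bias samples of
two densities.  Drugs are classified from their lumped scores, and cell
lines are grouped by hierarchical clustering of their lumped-bias profiles
across drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ks_2samp

from .errors import CompletenessError, InsufficientDataError
from .landscape import DoseScores, LumpedScores

# above this product of sample sizes the asymptotic KS p-value is used
EXACT_KS_LIMIT = 10_000

MIGRASTATIC = "migrastatic"
CYTOTOXIC = "cytotoxic"
BALANCED = "balanced"
INACTIVE = "inactive"


@dataclass
class BiasPoint:
    """Phenotypic bias of one dose: raw difference, distance, and angle."""

    concentration: float
    bias: float
    distance: float
    angle: float


@dataclass
class RobustnessResult:
    """Two-sample KS comparison of bias profiles between two densities."""

    pair: tuple[int, int] | None
    ks_distance: float
    p_value: float
    significant: bool


def bias_profile(scores: Sequence[DoseScores]) -> list[BiasPoint]:
    """Per-dose bias points for an ordered score series."""
    if not scores:
        raise InsufficientDataError("bias_profile: empty score series")
    out = []
    for s in scores:
        b = s.death - s.migration
        if s.migration == 0 and s.death == 0:
            angle = 0.0
        else:
            angle = math.atan2(s.death, s.migration) - math.pi / 4
        out.append(
            BiasPoint(
                concentration=s.concentration,
                bias=b,
                distance=math.sin(math.pi / 4) * b,
                angle=angle,
            )
        )
    return out


def lumped_bias_distance(lumped: LumpedScores) -> float:
    """Signed perpendicular distance of the lumped scores from the no-bias line."""
    return math.sin(math.pi / 4) * lumped.bias


def ks_compare(
    bias_a: Sequence[float],
    bias_b: Sequence[float],
    alpha: float = 0.05,
    pair: tuple[int, int] | None = None,
) -> RobustnessResult:
    """Two-sample KS distance and p-value between two bias samples.

    The exact small-sample null distribution is used while
    n_a * n_b <= 10^4 (always true for the 8-dose design), otherwise the
    asymptotic Kolmogorov formula.
    """
    a = np.asarray(bias_a, dtype=float)
    b = np.asarray(bias_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("ks_compare: empty sample")
    method = "exact" if a.size * b.size <= EXACT_KS_LIMIT else "asymp"
    res = ks_2samp(a, b, method=method)
    return RobustnessResult(
        pair=pair,
        ks_distance=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


def classify_drug(
    lumped: LumpedScores,
    activity_floor: float = 0.05,
    bias_floor: float = 0.05,
) -> str:
    """Classify a series as migrastatic / cytotoxic / balanced / inactive.

    A series whose total lumped activity falls below ``activity_floor`` is
    inactive; otherwise the sign of the lumped bias (death - migration)
    decides, with a ``bias_floor`` dead band around zero labelled balanced.
    """
    if lumped.migration_lumped + lumped.death_lumped < activity_floor:
        return INACTIVE
    if lumped.bias < -bias_floor:
        return MIGRASTATIC
    if lumped.bias > bias_floor:
        return CYTOTOXIC
    return BALANCED


def cluster_cell_lines(bias_matrix: pd.DataFrame, n_groups: int) -> dict[str, int]:
    """Group cell lines by their lumped-bias profiles across drugs.

    Agglomerative hierarchical clustering (Euclidean distance, average
    linkage) on the rows of a complete cell-line x drug matrix, cut at
    ``n_groups``.  Rows are processed in lexicographic label order and
    group ids are renumbered by first appearance, so the assignment is
    deterministic.
    """
    if bias_matrix.isna().any().any():
        missing = bias_matrix.stack(future_stack=True)
        missing = missing[missing.isna()].index.tolist()
        raise CompletenessError(f"bias matrix has missing entries: {missing}")
    if len(bias_matrix) < 2:
        raise InsufficientDataError("clustering needs >= 2 cell lines")
    if not (1 <= n_groups <= len(bias_matrix)):
        raise InsufficientDataError(
            f"n_groups must lie in [1, {len(bias_matrix)}], got {n_groups}"
        )
    ordered = bias_matrix.sort_index()
    Z = linkage(ordered.to_numpy(dtype=float), method="average", metric="euclidean")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for cell_line, lab in zip(ordered.index, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[str(cell_line)] = remap[lab]
    return out
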