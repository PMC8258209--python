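"""Niche breadth, diversity and rank-sum group comparisons.

Levins' measure of niche breadth is the reciprocal Simpson
concentration, B = 1 / sum(p_j^2), where p_j is the proportion of prey
individuals in category j.  Standardizing by the category count n,

    B_st = (B - 1) / (n - 1)

rescales it to [0, 1]: values near 0 indicate a dietary specialist
(all mass on one category), values near 1 a perfect generalist
(uniform use).  Note that n counts the categories over which p is
defined, including any with p_j = 0, so B_st measures evenness over the
stated category universe.

Shannon-Wiener diversity H' = -sum(p_j * ln p_j) is computed per
specimen (natural log by default; the base is configurable) alongside
richness, and compared between groups with the Mann-Whitney-Wilcoxon
rank-sum test.  For small samples (n_a + n_b <= 20 by default) the
two-sided p-value is obtained by complete enumeration of all
C(n, n_a) assignments of the observed values to the two groups, using
mid-ranks so ties need no approximation; larger samples use the normal
approximation with tie-corrected variance and a continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from tepuidiet.diet_io import DietDataset, DietValidationError

__all__ = [
    "NicheBreadthResult",
    "DiversityResult",
    "GroupComparison",
    "levins_b",
    "standardized_niche_breadth",
    "shannon_index",
    "per_specimen_diversity",
    "mann_whitney",
    "compare_groups",
]

#: Largest combined sample size for which the exact enumeration p-value
#: is used; C(20, 10) = 184,756 assignments is still fast.
EXACT_ENUMERATION_MAX_N = 20


@dataclass
class NicheBreadthResult:
    """Levins B and its standardized form for one proportion vector."""

    B: float
    B_st: float
    n: int
    p: np.ndarray = field(repr=False)


@dataclass
class DiversityResult:
    """Richness and Shannon-Wiener H' for one specimen's gut contents."""

    specimen_id: str
    richness: int
    H: float


@dataclass
class GroupComparison:
    """Two-group Mann-Whitney-Wilcoxon comparison.

    ``W`` is the rank-sum of the first-named group (mid-ranks); ``U``
    the corresponding Mann-Whitney statistic W - n_a(n_a+1)/2.  Both are
    reported because the literature's "w" convention varies.
    ``group_summaries`` optionally carries per-group descriptive values
    (mean per-specimen H', pooled-counts H').
    """

    group_labels: tuple[str, str]
    n_a: int
    n_b: int
    W: float
    U: float
    p_value: float
    method: str  # "exact_enumeration" | "normal_approximation"
    group_summaries: dict = field(default_factory=dict)


def _as_proportions(p, tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DietValidationError("proportion vector must be 1-D and non-empty")
    if (p < 0).any():
        raise DietValidationError(f"proportions must be non-negative, got {p}")
    total = p.sum()
    if total <= 0:
        raise DietValidationError("proportion vector sums to zero")
    if abs(total - 1.0) > tol:
        raise DietValidationError(
            f"proportions sum to {total:.6f}, beyond the renormalization "
            f"tolerance {tol}; renormalize explicitly if intended"
        )
    return p / total


def levins_b(p) -> float:
    """Levins niche breadth B = 1 / sum(p_j^2).

    ``p`` must be non-negative and sum to 1 within 1e-6 (it is
    renormalized exactly within that tolerance).  B ranges from 1 (all
    mass in one category) to n (uniform over n categories).
    """
    p = _as_proportions(p)
    return 1.0 / float(np.sum(p**2))


def standardized_niche_breadth(p) -> NicheBreadthResult:
    """Standardized Levins breadth B_st = (B - 1) / (n - 1) in [0, 1].

    n is the length of the proportion vector (categories with p_j = 0
    included).  Requires n >= 2; B_st = 0 iff a single category holds
    all mass, B_st = 1 iff the distribution is uniform.
    """
    p = _as_proportions(p)
    n = len(p)
    if n < 2:
        raise DietValidationError("B_st is undefined for fewer than two categories")
    b = 1.0 / float(np.sum(p**2))
    return NicheBreadthResult(B=b, B_st=(b - 1.0) / (n - 1.0), n=n, p=p)


def shannon_index(counts, base: float = math.e) -> float:
    """Shannon-Wiener H' = -sum(p ln p) over categories with count > 0.

    ``counts`` are per-category prey counts (one specimen or a pooled
    group).  Natural log by default, so H' is in nats; pass ``base=2``
    or ``base=10`` for bits/bans.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise DietValidationError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise DietValidationError("Shannon index undefined for an all-zero count vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(base))


def per_specimen_diversity(
    dataset: DietDataset, base: float = math.e
) -> list[DiversityResult]:
    """Richness and H' for each analyzable specimen's identifiable items."""
    prey = dataset.prey[dataset.prey["identifiable"].astype(bool)]
    results = []
    analyzable = dataset.specimens[dataset.specimens["gut_status"] == "analyzable"]
    grouped = prey.groupby("specimen_id")["category"]
    for sid in analyzable["specimen_id"]:
        counts = grouped.get_group(sid).value_counts().to_numpy()
        results.append(
            DiversityResult(
                specimen_id=sid,
                richness=len(counts),
                H=shannon_index(counts, base=base),
            )
        )
    return results


def _exact_two_sided_p(values: np.ndarray, n_a: int) -> tuple[float, float]:
    """Enumerate every split of the observed values into groups of size
    (n_a, n - n_a) and return (W_observed, two-sided p) for the mid-rank
    sum of the first group.

    Because mid-ranks are a function of the pooled values, enumerating
    index subsets is exactly a permutation test on the observed values,
    which handles ties without approximation.  The mid-rank sum is
    symmetric about n_a (n + 1) / 2 under exchangeability, so the
    two-sided p counts splits at least as far from that center as the
    observed one.
    """
    n = len(values)
    ranks = stats.rankdata(values)
    w_obs = float(ranks[:n_a].sum())
    center = n_a * (n + 1) / 2.0
    d_obs = abs(w_obs - center)
    # enumerate the smaller side for speed; the statistic's distance from
    # center is invariant to which group is enumerated
    k = min(n_a, n - n_a)
    count = 0
    total = 0
    eps = 1e-9
    for idx in combinations(range(n), k):
        w = sum(ranks[i] for i in idx)
        c = k * (n + 1) / 2.0
        if abs(w - c) >= d_obs - eps:
            count += 1
        total += 1
    return w_obs, count / total


def _normal_approx_p(values: np.ndarray, n_a: int) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(values)
    n_b = n - n_a
    ranks = stats.rankdata(values)
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return w, min(1.0, 2.0 * stats.norm.sf(z))


def mann_whitney(
    a,
    b,
    *,
    labels: tuple[str, str] = ("a", "b"),
    exact_max_n: int = EXACT_ENUMERATION_MAX_N,
) -> GroupComparison:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Exact enumeration of all C(n, n_a) group assignments whenever
    n_a + n_b <= ``exact_max_n`` (mid-ranks, so ties are exact too);
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.  The method actually used is recorded on the
    result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DietValidationError("both groups must be non-empty")
    values = np.concatenate([a, b])
    n_a, n_b = len(a), len(b)
    if n_a + n_b <= exact_max_n:
        w, p = _exact_two_sided_p(values, n_a)
        method = "exact_enumeration"
    else:
        w, p = _normal_approx_p(values, n_a)
        method = "normal_approximation"
    u = w - n_a * (n_a + 1) / 2.0
    return GroupComparison(
        group_labels=labels, n_a=n_a, n_b=n_b, W=w, U=u, p_value=p, method=method
    )


def compare_groups(
    dataset: DietDataset,
    grouping: str,
    response: str = "H",
    base: float = math.e,
) -> GroupComparison:
    """Compare per-specimen diversity between exactly two groups.

    ``grouping`` is a specimen column ('sex' or 'species'); specimens
    with sex 'unknown' are dropped when grouping by sex.  ``response``
    is 'H' (Shannon-Wiener) or 'richness'.  The test always uses
    per-specimen values; each group's summary H' is additionally
    reported in two conventions (mean of per-specimen H' and
    pooled-counts H'), since group-level H' figures in the literature
    are ambiguous between the two.
    """
    if grouping not in ("sex", "species"):
        raise DietValidationError(f"grouping must be 'sex' or 'species', got {grouping!r}")
    if response not in ("H", "richness"):
        raise DietValidationError(f"response must be 'H' or 'richness', got {response!r}")
    specimens = dataset.specimens
    if grouping == "sex":
        specimens = specimens[specimens["sex"] != "unknown"]
    levels = sorted(specimens[grouping].dropna().unique())
    if len(levels) != 2:
        raise DietValidationError(
            f"grouping by {grouping!r} yields {len(levels)} non-empty group(s) "
            f"({levels}); exactly two are required"
        )
    diversity = {d.specimen_id: d for d in per_specimen_diversity(dataset, base=base)}
    prey = dataset.prey[dataset.prey["identifiable"].astype(bool)]

    group_values: dict[str, np.ndarray] = {}
    summaries: dict[str, dict] = {}
    for level in levels:
        ids = specimens.loc[
            (specimens[grouping] == level)
            & (specimens["gut_status"] == "analyzable"),
            "specimen_id",
        ]
        per_spec = [diversity[sid] for sid in ids if sid in diversity]
        if not per_spec:
            raise DietValidationError(f"group {level!r} has no analyzable specimens")
        vals = np.array(
            [d.H if response == "H" else d.richness for d in per_spec], dtype=float
        )
        group_values[level] = vals
        pooled_counts = (
            prey[prey["specimen_id"].isin(set(ids))]["category"].value_counts().to_numpy()
        )
        summaries[level] = {
            "n": len(per_spec),
            "mean_H": float(np.mean([d.H for d in per_spec])),
            "pooled_H": shannon_index(pooled_counts, base=base),
            "mean_richness": float(np.mean([d.richness for d in per_spec])),
        }

    result = mann_whitney(
        group_values[levels[0]], group_values[levels[1]], labels=(levels[0], levels[1])
    )
    result.group_summaries = summaries
    return result
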