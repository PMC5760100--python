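"""Sampling and group comparisons for per-photoreceptor summaries.

Implements the study's statistical workflow: random selection of a few
photoreceptors per animal from the pool of eligible cells (to avoid
sampling-error carryover), pairwise comparisons between genotypes
(Student's t-test for kinetic parameters, Mann-Whitney U for the
non-normal contact parameters), one-way ANOVA across the wild-type
condition groups, and the two-channel puncta colocalization fraction.

The exact Mann-Whitney p-value is computed by full enumeration of group
labelings for combined sample sizes up to 16 (tie-safe); larger samples
use the normal approximation with tie correction.  All p-values are
two-sided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_MWU_MAX_N = 16


@dataclass
class ComparisonResult:
    test_name: str  # student_t | welch_t | mann_whitney_u | one_way_anova
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def stars(self) -> str:
        """Significance stars at the 0.05 / 0.01 thresholds."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "n.s."


def select_photoreceptors(
    pool: Union[Sequence, dict],
    k: int = 3,
    seed: int = 0,
) -> list:
    """Randomly pick ``k`` cells per animal, uniformly without replacement.

    ``pool`` is either one animal's sequence of eligible cell ids or a
    mapping animal -> sequence of cell ids.  Pools smaller than ``k`` are
    taken whole.  Deterministic given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(pool, dict):
        selected: list = []
        for animal in pool:
            cells = list(pool[animal])
            if not cells:
                logger.warning("animal %s: empty pool, nothing selected", animal)
                continue
            n = min(k, len(cells))
            idx = rng.choice(len(cells), size=n, replace=False)
            selected.extend(cells[i] for i in sorted(idx))
        return selected
    cells = list(pool)
    if not cells:
        logger.warning("empty pool, nothing selected")
        return []
    n = min(k, len(cells))
    idx = rng.choice(len(cells), size=n, replace=False)
    return [cells[i] for i in sorted(idx)]


def _mwu_u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a vs b, with the midrank convention for ties."""
    u = 0.0
    for x in a:
        u += float(np.count_nonzero(b < x)) + 0.5 * float(np.count_nonzero(b == x))
    return u


def _exact_mwu_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of labelings.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to the two
    groups and doubles the smaller tail of the U distribution (capped at 1),
    mirroring the classical exact two-sided convention.  Correct under ties
    because U is recomputed per labeling with midranks.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = _mwu_u_statistic(a, b)
    n_total = 0
    n_le = 0
    n_ge = 0
    idx = np.arange(len(pooled))
    for comb in combinations(idx, n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        u = _mwu_u_statistic(pooled[sel], pooled[~sel])
        n_total += 1
        if u <= u_obs:
            n_le += 1
        if u >= u_obs:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / n_total
    return min(1.0, p)


def compare_two(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "student_t",
    welch: bool = False,
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided two-sample comparison.

    ``test='student_t'`` runs the classical equal-variance t-test (Welch
    via flag); ``test='mann_whitney_u'`` runs the Mann-Whitney U-test,
    exact by enumeration for combined n <= 16, normal approximation with
    tie correction otherwise.  Two t-test samples that are both constant
    with equal means yield p = 1 by convention.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if test == "student_t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test needs n >= 2 per group")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            if x[0] == y[0]:
                logger.warning("both samples constant and equal: p = 1 by convention")
                return ComparisonResult("student_t", 0.0, 1.0, (len(x), len(y)), labels)
        res = sps.ttest_ind(x, y, equal_var=not welch)
        name = "welch_t" if welch else "student_t"
        return ComparisonResult(name, float(res.statistic), float(res.pvalue), (len(x), len(y)), labels)
    if test == "mann_whitney_u":
        if len(x) < 1 or len(y) < 1:
            raise ValueError("Mann-Whitney needs n >= 1 per group")
        u = _mwu_u_statistic(x, y)
        if len(x) + len(y) <= EXACT_MWU_MAX_N:
            p = _exact_mwu_p(x, y)
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            p = float(res.pvalue)
        return ComparisonResult("mann_whitney_u", u, p, (len(x), len(y)), labels)
    raise ValueError(f"unknown test {test!r}")


def compare_many(groups: Sequence[Sequence[float]], labels: Sequence[str] = ()) -> ComparisonResult:
    """One-way fixed-effects ANOVA over two or more groups.

    All values identical across all groups yields F = 0, p = 1 (the test is
    vacuous with zero between- and within-group variance).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("ANOVA needs n >= 2 per group")
    pooled = np.concatenate(arrays)
    sizes = tuple(len(g) for g in arrays)
    lab = tuple(labels) if labels else tuple(f"g{i}" for i in range(len(arrays)))
    if np.ptp(pooled) == 0:
        return ComparisonResult("one_way_anova", 0.0, 1.0, sizes, lab)
    res = sps.f_oneway(*arrays)
    f = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(f):  # zero within-group variance, non-zero between
        f, p = math.inf, 0.0
    return ComparisonResult("one_way_anova", f, p, sizes, lab)


def colocalization_fraction(
    puncta_a: np.ndarray,
    puncta_b: Union[np.ndarray, Sequence],
    radius_nm: float = 630.0,
    mask_mode: bool = False,
    pixel_size_nm: float = 210.0,
) -> float:
    """Fraction of A puncta colocalizing with B.

    In centroid mode (default), an A punctum colocalizes when its centroid
    (nm) lies within ``radius_nm`` of any B centroid.  In mask mode,
    ``puncta_b`` is a boolean raster and an A punctum colocalizes when its
    centroid falls on a True pixel.
    """
    a = np.atleast_2d(np.asarray(puncta_a, dtype=float))
    if a.size == 0:
        raise ValueError("empty A puncta set: fraction undefined")
    if mask_mode:
        mask = np.asarray(puncta_b, dtype=bool)
        hits = 0
        for x, y in a:
            iy, ix = int(round(y / pixel_size_nm)), int(round(x / pixel_size_nm))
            if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]:
                hits += 1
        return hits / len(a)
    if radius_nm <= 0:
        raise ValueError("radius_nm must be positive in centroid mode")
    b = np.atleast_2d(np.asarray(puncta_b, dtype=float))
    if b.size == 0:
        return 0.0
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(np.count_nonzero(d.min(axis=1) <= radius_nm) / len(a))
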