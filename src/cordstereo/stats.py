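"""Segment-level statistics: mean +/- SE, Duncan's multiple range test with a
compact letter display, and a starred Pearson correlation matrix.

Duncan's test is a step-down range procedure on the ordered group means of a
balanced one-way layout.  A stretch of p consecutive ordered means is
homogeneous when its range does not exceed

    R_p = q(p, df; level = (1 - alpha)^(p-1)) * sqrt(MSE / n)

where q is the studentized-range quantile at Duncan's protection level and
MSE the one-way ANOVA error mean square with df = k(n-1).  The procedure
starts from the full range and recurses into subranges of stretches that
fail; two groups differ significantly iff no homogeneous stretch contains
both.  Letters are assigned to the maximal homogeneous stretches in
descending-mean order starting at "a", so sharing a letter is exactly
non-significance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "DuncanResult",
    "CorrelationTable",
    "mean_se",
    "duncan_mrt",
    "duncan_critical_range",
    "pearson_matrix",
    "ratio_percent",
    "relative_weight",
]

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and standard error (sample SD / sqrt(n)); needs n >= 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SE needs at least two observations")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


@lru_cache(maxsize=512)
def _duncan_q(p: int, df: int, alpha: float) -> float:
    # Duncan's protected level for a stretch of p means
    level = (1.0 - alpha) ** (p - 1)
    return float(sps.studentized_range.ppf(level, p, df))


def duncan_critical_range(p: int, df: int, alpha: float, mse: float, n: int) -> float:
    """Least significant range for a stretch of p ordered means."""
    return _duncan_q(p, df, alpha) * np.sqrt(mse / n)


@dataclass(frozen=True)
class DuncanResult:
    """Ordered means, homogeneous stretches, and the letter display."""

    order: tuple[str, ...]  # group labels, descending mean
    means: Mapping[str, float]
    letters: Mapping[str, str]
    stretches: tuple[tuple[int, int], ...]  # maximal homogeneous (i, j) in order
    mse: float
    df: int
    alpha: float
    n: int

    def significant(self, g1: str, g2: str) -> bool:
        """True iff the two groups differ under the protected range procedure."""
        i, j = sorted((self.order.index(g1), self.order.index(g2)))
        return not any(u <= i and j <= v for u, v in self.stretches)


def _letters_from_stretches(
    k: int, stretches: Sequence[tuple[int, int]]
) -> list[str]:
    """Compact letter display: one letter per maximal homogeneous stretch,
    singletons for uncovered groups, letters ordered by stretch start."""
    intervals = sorted(stretches)
    covered = set()
    for u, v in intervals:
        covered.update(range(u, v + 1))
    for i in range(k):
        if i not in covered:
            intervals.append((i, i))
    intervals.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for idx, (u, v) in enumerate(intervals):
        sym = alphabet[idx] if idx < len(alphabet) else f"z{idx}"
        for i in range(u, v + 1):
            letters[i] += sym
    return letters


def duncan_mrt(
    groups: Sequence[GroupSample] | Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> DuncanResult:
    """Duncan's multiple range test on a balanced one-way layout."""
    if isinstance(groups, Mapping):
        groups = [GroupSample(str(k), tuple(v)) for k, v in groups.items()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = {g.n for g in groups}
    if len(ns) > 1:
        raise ValueError("Duncan's test requires equal group sizes")
    n = ns.pop()
    if n < 2:
        raise ValueError("need n >= 2 replicates per group")
    k = len(groups)
    df = k * (n - 1)
    mse = float(np.mean([np.var(g.values, ddof=1) for g in groups]))

    order = sorted(groups, key=lambda g: -g.mean)
    m = [g.mean for g in order]
    ranges = {p: duncan_critical_range(p, df, alpha, mse, n) for p in range(2, k + 1)}

    homogeneous: set[tuple[int, int]] = set()
    seen: set[tuple[int, int]] = set()

    def step(i: int, j: int) -> None:
        if j <= i or (i, j) in seen:
            return
        seen.add((i, j))
        if m[i] - m[j] <= ranges[j - i + 1] + 1e-12:
            homogeneous.add((i, j))
            return
        step(i, j - 1)
        step(i + 1, j)

    step(0, k - 1)
    maximal = tuple(
        sorted(
            (u, v)
            for u, v in homogeneous
            if not any(
                (a <= u and v <= b) and (a, b) != (u, v) for a, b in homogeneous
            )
        )
    )
    letters = _letters_from_stretches(k, maximal)
    return DuncanResult(
        order=tuple(g.label for g in order),
        means={g.label: g.mean for g in order},
        letters={g.label: letters[i] for i, g in enumerate(order)},
        stretches=maximal,
        mse=mse,
        df=df,
        alpha=alpha,
        n=n,
    )


@dataclass(frozen=True)
class CorrelationTable:
    """Pairwise Pearson r with two-sided p and star codes."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "stars": self.stars.loc[a, b],
                        "n": self.n.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _stars(p: float) -> str:
    for level, sym in STAR_LEVELS:
        if p < level:
            return sym
    return ""


def pearson_matrix(table: pd.DataFrame, min_obs: int = 3) -> CorrelationTable:
    """Pairwise-complete Pearson correlations over the columns of ``table``.

    Zero-variance variables yield NaN r for their pairs (flagged by an empty
    star string); pairs with fewer than ``min_obs`` complete observations
    raise.
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    nn = pd.DataFrame(0, index=cols, columns=cols)
    stars = pd.DataFrame("", index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < min_obs:
            raise ValueError(f"pair ({a}, {b}) has fewer than {min_obs} observations")
        nn.loc[a, b] = nn.loc[b, a] = len(sub)
        if sub[a].std() == 0 or sub[b].std() == 0:
            continue  # r undefined; stays NaN
        res = sps.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
        stars.loc[a, b] = stars.loc[b, a] = _stars(res.pvalue)
    return CorrelationTable(r=r, p=p, stars=stars, n=nn)


def pool_for_correlation(
    table: pd.DataFrame, mode: str = "animal_segment"
) -> pd.DataFrame:
    """Choose the observation unit for pooled correlations.

    ``animal_segment`` keeps one row per animal x segment;
    ``segment_mean`` averages over animals first (one row per segment).
    The right unit for published correlation tables is often ambiguous, so
    both are offered and neither privileged.
    """
    if mode == "animal_segment":
        return table.drop(columns=["animal", "segment"], errors="ignore")
    if mode == "segment_mean":
        return (
            table.drop(columns=["animal"], errors="ignore")
            .groupby("segment")
            .mean(numeric_only=True)
            .reset_index(drop=True)
        )
    raise ValueError(f"unknown pooling mode {mode!r}")


def ratio_percent(part: float, whole: float) -> float:
    """100 x part / whole."""
    if whole <= 0:
        raise ValueError("denominator must be > 0")
    return 100.0 * part / whole


def relative_weight(organ_g: float, body_kg: float) -> float:
    """Organ weight as percent of body weight (grams over kilograms)."""
    if body_kg <= 0:
        raise ValueError("body weight must be > 0")
    return 100.0 * organ_g / (body_kg * 1000.0)
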