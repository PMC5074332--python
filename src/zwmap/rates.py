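"""Genome segmentation, cM/Mb recombination rates and the count-based
chi-square / expectation / rank tests used to compare them.

Map distance here is count-based: cM = 100 x events / meioses, so a
segment's rate is 100 x (events / n_offspring) / length_Mb.  All
chi-square statistics are Pearson without continuity correction; the
2x2 test on event counts requires this to match count-based arithmetic
(the Yates-corrected value differs noticeably at small counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MB = 1_000_000


@dataclass(frozen=True)
class Segment:
    """A rearrangement-free genomic piece with its event-based rate."""

    group_id: str
    start_bp: int
    end_bp: int
    n_events: int = 0
    n_offspring: int = 0

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / MB

    @property
    def rate_cm_per_mb(self) -> float:
        return rate(self.n_events, self.n_offspring, self.length_mb)


@dataclass(frozen=True)
class CountTest:
    """Chi-square comparison of observed event counts."""

    chi2: float
    df: int
    p: float
    observed: tuple
    expected: tuple


def rate(n_events: int, n_offspring: int, mb: float) -> float:
    """Recombination rate in cM/Mb: 100 x (events per meiosis) / Mb."""
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    if mb <= 0:
        raise ValueError("physical length must be positive (Mb)")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    return 100.0 * (n_events / n_offspring) / mb


def segment_map(
    group_id: str,
    length_bp: int,
    rearrangements: list[tuple[int, int]] | None = None,
    min_bp: int = 5 * MB,
    max_bp: int = 10 * MB,
) -> list[Segment]:
    """Tile a linkage group into 5-10 Mb segments free from rearrangements.

    Greedy tiling from the group start: full ``max_bp`` segments, with a
    single remainder segment kept only if it reaches ``min_bp``.  The
    tiling restarts after every flagged rearrangement interval, and no
    segment overlaps one.
    """
    if max_bp < min_bp:
        raise ValueError("max segment length below min")
    if length_bp <= 0:
        raise ValueError("group length must be positive")
    blocks: list[tuple[int, int]] = []
    cursor = 0
    for r_start, r_end in sorted(rearrangements or []):
        r_start, r_end = max(r_start, 0), min(r_end, length_bp)
        if r_start > cursor:
            blocks.append((cursor, r_start))
        cursor = max(cursor, r_end)
    if cursor < length_bp:
        blocks.append((cursor, length_bp))

    segments: list[Segment] = []
    for b_start, b_end in blocks:
        pos = b_start
        while b_end - pos >= max_bp:
            segments.append(Segment(group_id, pos, pos + max_bp))
            pos += max_bp
        if b_end - pos >= min_bp:
            segments.append(Segment(group_id, pos, b_end))
    return segments


def count_events_in_segments(
    segments: list[Segment],
    event_positions_bp: np.ndarray | list[float],
    n_offspring: int,
) -> list[Segment]:
    """Fill segment event counts from event midpoint positions (bp)."""
    pos = np.asarray(event_positions_bp, dtype=float)
    return [
        Segment(
            s.group_id,
            s.start_bp,
            s.end_bp,
            n_events=int(((pos >= s.start_bp) & (pos < s.end_bp)).sum()),
            n_offspring=n_offspring,
        )
        for s in segments
    ]


def chisq_gof(observed, expected) -> CountTest:
    """Pearson goodness-of-fit: sum (O-E)^2 / E with df = k-1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and expected must be equal-length vectors (k >= 2)")
    if (exp <= 0).any():
        raise ValueError("expected counts must be positive")
    if not np.isclose(obs.sum(), exp.sum(), rtol=0.05):
        raise ValueError("observed and expected totals disagree beyond rounding")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return CountTest(chi2, df, float(stats.chi2.sf(chi2, df)), tuple(obs), tuple(exp))


def chisq_2x2(table) -> CountTest:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all margins must be positive")
    expected = np.outer(rows, cols) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return CountTest(
        chi2, 1, float(stats.chi2.sf(chi2, 1)), tuple(t.ravel()), tuple(expected.ravel())
    )


def expected_events(total_events: float, genome_fraction: float) -> float:
    """Expected event count in a region under a constant genome-wide rate."""
    if not 0 <= genome_fraction <= 1:
        raise ValueError("genome_fraction must lie in [0, 1]")
    if total_events < 0:
        raise ValueError("total_events must be non-negative")
    return total_events * genome_fraction


def wilcoxon_rates(maternal, paternal) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of segment rates.

    Exact enumeration when both samples have n <= 10 and no ties; otherwise
    the normal approximation with tie correction (no continuity
    correction).  Returns (statistic, p) with the statistic being the
    Mann-Whitney U of the first sample.
    """
    x = np.asarray(maternal, dtype=float)
    y = np.asarray(paternal, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    tied = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not tied) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)
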