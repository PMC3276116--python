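"""Evaluation statistics: line-origin error and recombination-switch metrics.

The line-origin error of one haplotype at grid position i is
``e(i) = 1 - p1(i)`` when the true origin is line 1 and ``e(i) = p1(i)``
when it is line 2, where p1 is the inferred probability of line-1 origin.
Aggregates are the per-position mean and (sample) standard deviation over
all haplotypes of all individuals, and the grand mean over positions.

A *switch* is an inferred recombination: the p1 series crosses 0.5 and,
scanning outward from the crossing, reaches >= 0.975 on one side and
<= 0.025 on the other before any other 0.5-crossing.  Those threshold
positions are the switch end points; their distance is the switch's
*imprecision* (at least one grid step by construction).  The position where
the series crosses 0.5 — linearly interpolated between grid points, or the
central position of a run of exact 0.5 values — is compared with the true
crossover position to give the *inaccuracy*.  Detected switches are matched
to true crossovers greedily by distance, requiring the same haplotype and
the same direction of origin change, each matched at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TruthTrack

__all__ = [
    "ErrorSummary",
    "SwitchRecord",
    "line_origin_error",
    "summarize_error",
    "detect_switches",
    "detect_all_switches",
    "match_switches",
]


def line_origin_error(p1_series, truth_lines) -> np.ndarray:
    """Per-position error of one haplotype's line-1 probability series."""
    p1 = np.asarray(p1_series, dtype=float)
    truth = np.asarray(truth_lines)
    if p1.shape != truth.shape:
        raise ValueError(f"series lengths differ: {p1.shape} vs {truth.shape}")
    if p1.size and (p1.min() < 0 or p1.max() > 1):
        raise ValueError("p1 values must lie in [0, 1]")
    if not np.isin(truth, (1, 2)).all():
        raise ValueError("truth lines must be 1 or 2")
    return np.where(truth == 1, 1.0 - p1, p1)


@dataclass
class ErrorSummary:
    """Aggregated line-origin error over haplotypes x positions."""

    per_position_mean: np.ndarray
    per_position_sd: np.ndarray
    grand_mean: float
    n_haplotypes: int


def summarize_error(error_series) -> ErrorSummary:
    """Aggregate per-haplotype error series (rows) over a shared grid.

    Per-position statistics are taken over all haplotypes (both haplotypes
    of every individual pooled); the SD uses the n-1 denominator.  The
    grand mean averages every entry, equivalently the count-weighted mean
    of per-position means.
    """
    errors = np.asarray(error_series, dtype=float)
    if errors.ndim != 2 or errors.shape[0] < 1:
        raise ValueError("expected a (n_haplotypes, n_positions) array with >= 1 row")
    sd = errors.std(axis=0, ddof=1) if errors.shape[0] > 1 else np.zeros(errors.shape[1])
    return ErrorSummary(
        per_position_mean=errors.mean(axis=0),
        per_position_sd=sd,
        grand_mean=float(errors.mean()),
        n_haplotypes=errors.shape[0],
    )


@dataclass
class SwitchRecord:
    """One detected change of a haplotype's line origin."""

    individual: str
    haplotype: str  # 'maternal' or 'paternal'
    direction: str  # '1to2' or '2to1'
    start_cM: float
    end_cM: float
    cross_cM: float  # where p1 crosses 0.5
    matched_truth_cM: float | None = None
    inaccuracy_cM: float | None = None

    @property
    def imprecision_cM(self) -> float:
        return self.end_cM - self.start_cM


def _crossings(positions: np.ndarray, p1: np.ndarray):
    """All 0.5-crossings of a series.

    Yields ``(i, j, cross_position, falling)`` where ``i``/``j`` index the
    last/first strictly off-0.5 values flanking the crossing, ``falling``
    means p1 goes from above to below 0.5.  Runs of exactly 0.5 between the
    flanks use the central plateau position as the crossing.
    """
    s = p1 - 0.5
    nz = np.nonzero(s != 0)[0]
    for a, b in zip(nz[:-1], nz[1:]):
        if s[a] * s[b] >= 0:
            continue
        if b == a + 1:
            # linear interpolation of the 0.5 crossing inside (a, b)
            frac = (0.5 - p1[a]) / (p1[b] - p1[a])
            cross = positions[a] + frac * (positions[b] - positions[a])
        else:
            cross = 0.5 * (positions[a + 1] + positions[b - 1])
        yield int(a), int(b), float(cross), bool(s[a] > 0)


def detect_switches(
    positions,
    p1_series,
    upper: float = 0.975,
    lower: float = 0.025,
    individual: str = "0",
    haplotype: str = "maternal",
) -> list[SwitchRecord]:
    """Detect line-origin switches in one haplotype's p1 series on a grid.

    A switch is emitted for a 0.5-crossing only if, scanning outward on
    each side, the series attains ``>= upper`` on the high side and
    ``<= lower`` on the low side before running into another 0.5-crossing
    (switches truncated by a neighbouring crossing or the chromosome end
    are dropped: both end points are part of the definition).
    """
    positions = np.asarray(positions, dtype=float)
    p1 = np.asarray(p1_series, dtype=float)
    if positions.shape != p1.shape:
        raise ValueError("positions and p1 series must have the same length")
    events = list(_crossings(positions, p1))
    out: list[SwitchRecord] = []
    for k, (i, j, cross, falling) in enumerate(events):
        left_stop = events[k - 1][1] if k > 0 else 0  # first index after previous crossing
        right_stop = events[k + 1][0] if k + 1 < len(events) else p1.size - 1
        hi, lo = (upper, lower)
        left_thr, right_thr = (hi, lo) if falling else (lo, hi)
        left = None
        for idx in range(i, left_stop - 1, -1):
            if (p1[idx] >= left_thr) if falling else (p1[idx] <= left_thr):
                left = idx
                break
        right = None
        for idx in range(j, right_stop + 1):
            if (p1[idx] <= right_thr) if falling else (p1[idx] >= right_thr):
                right = idx
                break
        if left is None or right is None:
            continue
        out.append(
            SwitchRecord(
                individual=individual,
                haplotype=haplotype,
                direction="1to2" if falling else "2to1",
                start_cM=float(positions[left]),
                end_cM=float(positions[right]),
                cross_cM=cross,
            )
        )
    return out


def detect_all_switches(grid, upper: float = 0.975, lower: float = 0.025) -> list[SwitchRecord]:
    """Run :func:`detect_switches` on both haplotypes of every individual."""
    out: list[SwitchRecord] = []
    for iid in grid.individuals:
        for hap in ("maternal", "paternal"):
            out.extend(
                detect_switches(
                    grid.positions_cM, grid.p1(iid, hap), upper, lower, individual=iid, haplotype=hap
                )
            )
    return out


@dataclass
class MatchResult:
    switches: list[SwitchRecord]
    n_true: int
    n_matched: int
    unmatched_truth: list[tuple[str, str, float, str]]

    @property
    def detection_fraction(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")


def match_switches(
    switches: list[SwitchRecord],
    truth: TruthTrack,
    region: tuple[float, float] | None = None,
) -> MatchResult:
    """Match detected switches to true crossovers and fill inaccuracies.

    Greedy nearest-distance matching within (individual, haplotype,
    direction) groups; every truth and every switch is used at most once.
    ``region`` optionally restricts the true crossovers considered (e.g.
    the first 333 cM of a chromosome), by crossover position.
    """
    truths = list(truth.true_crossovers())
    if region is not None:
        lo, hi = region
        truths = [t for t in truths if lo <= t[2] <= hi]
    pairs = []
    for si, s in enumerate(switches):
        for ti, (ind, hap, pos, direction) in enumerate(truths):
            if s.individual == ind and s.haplotype == hap and s.direction == direction:
                pairs.append((abs(s.cross_cM - pos), si, ti))
    pairs.sort()
    used_s: set[int] = set()
    used_t: set[int] = set()
    for dist, si, ti in pairs:
        if si in used_s or ti in used_t:
            continue
        used_s.add(si)
        used_t.add(ti)
        switches[si].matched_truth_cM = truths[ti][2]
        switches[si].inaccuracy_cM = dist
    unmatched = [truths[ti] for ti in range(len(truths)) if ti not in used_t]
    return MatchResult(
        switches=switches,
        n_true=len(truths),
        n_matched=len(used_t),
        unmatched_truth=unmatched,
    )
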