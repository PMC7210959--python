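"""Chromothripsis scoring from segmented copy-number profiles.

The scorer counts switches between integer copy-number states along each
chromosome, finds the densest run of switches inside a sliding genomic
window (default 50 Mb), and assigns a confidence tier:

- high: >= 10 switches within the window,
- intermediate: 8-9,
- low: 6-7.

Within a called region the number of distinct copy-number states decides
canonical (<= 3 states, the classic oscillating pattern) versus
non-canonical (> 3), and telomere/centromere involvement is annotated from
the genome model. Thresholds are configurable but the defaults reproduce
the published tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, normalize_chrom
from .io import CALL_COLUMNS

__all__ = [
    "ScoringThresholds",
    "ChromothripsisCall",
    "SampleSummary",
    "count_switches",
    "best_window",
    "score_chromosome",
    "score_sample",
    "score_cohort",
    "calls_to_frame",
]

TIER_ORDER = {"low": 1, "intermediate": 2, "high": 3}


@dataclass(frozen=True)
class ScoringThresholds:
    """Tier thresholds for switch counts within the scoring window.

    ``high``/``intermediate``/``low`` are the minimum number of switches in
    a window (inclusive span between first and last switch <= ``window``)
    for each tier; ``telomere_margin`` is how close to a chromosome end a
    region must come to count as telomere-involved.
    """

    window: int = 50_000_000
    high: int = 10
    intermediate: int = 8
    low: int = 6
    telomere_margin: int = 1_000_000

    def tier(self, n_switches: int) -> str | None:
        if n_switches >= self.high:
            return "high"
        if n_switches >= self.intermediate:
            return "intermediate"
        if n_switches >= self.low:
            return "low"
        return None

    def tier_floor(self, tier: str) -> int:
        return {"high": self.high, "intermediate": self.intermediate,
                "low": self.low}[tier]


@dataclass(frozen=True)
class ChromothripsisCall:
    sample: str
    chrom: str
    start: int
    end: int
    n_switches: int
    confidence: str
    n_states: int
    canonical: bool
    telomere: bool
    centromere: bool


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample roll-up of chromothripsis calls.

    ``status`` maps each tier to whether the sample is positive at that
    tier or better; chromosome counts and flags are computed at
    ``summary_tier`` (default high confidence).
    """

    sample: str
    status: dict[str, bool]
    n_chromosomes: int
    any_telomere: bool
    any_centromere: bool
    multi_chromosome: bool
    heavy: bool
    summary_tier: str = "high"


def _check_profile(starts: np.ndarray, ends: np.ndarray) -> None:
    if len(starts) == 0:
        return
    if not (np.all(np.diff(starts) >= 0) and np.all(starts[1:] >= ends[:-1])):
        raise ValueError("segments must be sorted and non-overlapping")


def count_switches(segments: pd.DataFrame) -> np.ndarray:
    """Switch positions for one sample/chromosome profile.

    Runs of adjacent equal states are merged first; each boundary between
    unequal adjacent states contributes one switch at the boundary
    coordinate (the start of the later segment).
    """
    starts = segments["start"].to_numpy()
    ends = segments["end"].to_numpy()
    states = segments["state"].to_numpy()
    _check_profile(starts, ends)
    if len(states) < 2:
        return np.empty(0, dtype=np.int64)
    change = states[1:] != states[:-1]
    return starts[1:][change].astype(np.int64)


def best_window(
    positions: Sequence[int], window: int = 50_000_000
) -> tuple[int, tuple[int, int] | None]:
    """Largest number of switches whose span fits inside ``window``.

    The span is inclusive: switches at positions p_i..p_j fit iff
    p_j - p_i <= window. Returns the count and the (first, last) switch
    positions of the leftmost maximal window, or ``(0, None)`` for an
    empty list.
    """
    if window <= 0:
        raise ValueError("window span must be positive")
    pos = np.asarray(sorted(positions), dtype=np.int64)
    if len(pos) == 0:
        return 0, None
    best_count = 0
    best_iv: tuple[int, int] | None = None
    j = 0
    for i in range(len(pos)):
        if j < i:
            j = i
        while j + 1 < len(pos) and pos[j + 1] - pos[i] <= window:
            j += 1
        count = j - i + 1
        if count > best_count:
            best_count = count
            best_iv = (int(pos[i]), int(pos[j]))
    return best_count, best_iv


def _clusters(positions: np.ndarray, gap: int) -> list[np.ndarray]:
    """Split sorted switch positions where consecutive gaps exceed ``gap``."""
    if len(positions) == 0:
        return []
    breaks = np.where(np.diff(positions) > gap)[0]
    return np.split(positions, breaks + 1)


def _region_hull(pos: np.ndarray, thresholds: ScoringThresholds, tier: str) -> tuple[int, int, int]:
    """Minimal hull of switches lying in any window qualifying at ``tier``.

    Returns (start, end, n_switches_in_hull).
    """
    floor = thresholds.tier_floor(tier)
    w = thresholds.window
    n = len(pos)
    marked = np.zeros(n, dtype=bool)
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j + 1 < n and pos[j + 1] - pos[i] <= w:
            j += 1
        if j - i + 1 >= floor:
            marked[i : j + 1] = True
    idx = np.where(marked)[0]
    lo, hi = int(pos[idx[0]]), int(pos[idx[-1]])
    return lo, hi, int(idx[-1] - idx[0] + 1)


def score_chromosome(
    segments: pd.DataFrame,
    genome: GenomeModel,
    thresholds: ScoringThresholds = ScoringThresholds(),
) -> list[ChromothripsisCall]:
    """Score one sample/chromosome profile; returns 0+ calls.

    Switch clusters more than one window span apart are scored as separate
    calls. For each cluster the tier comes from the densest window, the
    region is the minimal hull of switches in qualifying windows, the
    distinct-state count is taken over segments overlapping the region and
    decides the canonical flag, and telomere/centromere involvement is
    annotated from the genome model.
    """
    if segments.empty:
        return []
    chroms = segments["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("score_chromosome expects a single chromosome")
    chrom = normalize_chrom(chroms[0])
    if chrom not in genome:
        raise ValueError(f"chromosome {chrom!r} absent from genome model")
    samples = segments["sample"].unique()
    if len(samples) != 1:
        raise ValueError("score_chromosome expects a single sample")
    sample = samples[0]
    segments = segments.sort_values("start", kind="stable")

    positions = count_switches(segments)
    calls: list[ChromothripsisCall] = []
    length = genome.length(chrom)
    cen = genome.centromere(chrom)
    for cluster in _clusters(positions, thresholds.window):
        m, _ = best_window(cluster, thresholds.window)
        tier = thresholds.tier(m)
        if tier is None:
            continue
        lo, hi, n_in_hull = _region_hull(cluster, thresholds, tier)
        overlapping = segments[(segments["end"] > lo) & (segments["start"] < hi)]
        if overlapping.empty:  # single-point region edge case
            overlapping = segments[(segments["end"] >= lo) & (segments["start"] <= hi)]
        n_states = int(overlapping["state"].nunique())
        telomere = lo <= thresholds.telomere_margin or hi >= length - thresholds.telomere_margin
        centromere = cen is not None and lo < cen[1] and hi > cen[0]
        calls.append(
            ChromothripsisCall(
                sample=str(sample),
                chrom=chrom,
                start=lo,
                end=hi,
                n_switches=n_in_hull,
                confidence=tier,
                n_states=n_states,
                canonical=n_states <= 3,
                telomere=bool(telomere),
                centromere=bool(centromere),
            )
        )
    return calls


def _status(calls: Iterable[ChromothripsisCall]) -> dict[str, bool]:
    best = max((TIER_ORDER[c.confidence] for c in calls), default=0)
    return {
        "high": best >= TIER_ORDER["high"],
        "intermediate": best >= TIER_ORDER["intermediate"],
        "low": best >= TIER_ORDER["low"],
    }


def score_sample(
    segments: pd.DataFrame,
    genome: GenomeModel,
    thresholds: ScoringThresholds = ScoringThresholds(),
    summary_tier: str = "high",
) -> tuple[list[ChromothripsisCall], SampleSummary]:
    """Score every chromosome of one sample and summarise."""
    samples = segments["sample"].unique()
    if len(samples) != 1:
        raise ValueError("score_sample expects a single sample")
    sample = str(samples[0])
    calls: list[ChromothripsisCall] = []
    for chrom, sub in segments.groupby("chrom", sort=False):
        calls.extend(score_chromosome(sub, genome, thresholds))
    floor = TIER_ORDER[summary_tier]
    at_tier = [c for c in calls if TIER_ORDER[c.confidence] >= floor]
    chroms = {c.chrom for c in at_tier}
    summary = SampleSummary(
        sample=sample,
        status=_status(calls),
        n_chromosomes=len(chroms),
        any_telomere=any(c.telomere for c in at_tier),
        any_centromere=any(c.centromere for c in at_tier),
        multi_chromosome=len(chroms) > 1,
        heavy=len(chroms) > 3,
        summary_tier=summary_tier,
    )
    return calls, summary


def score_cohort(
    segments: pd.DataFrame,
    genome: GenomeModel,
    thresholds: ScoringThresholds = ScoringThresholds(),
    summary_tier: str = "high",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every sample in a cohort segment table.

    Returns (calls table, per-sample summary table).
    """
    all_calls: list[ChromothripsisCall] = []
    rows = []
    for sample, sub in segments.groupby("sample", sort=True):
        calls, summary = score_sample(sub, genome, thresholds, summary_tier)
        all_calls.extend(calls)
        rows.append(
            {
                "sample": summary.sample,
                "status_high": summary.status["high"],
                "status_intermediate": summary.status["intermediate"],
                "status_low": summary.status["low"],
                "n_chromosomes": summary.n_chromosomes,
                "any_telomere": summary.any_telomere,
                "any_centromere": summary.any_centromere,
                "multi_chromosome": summary.multi_chromosome,
                "heavy": summary.heavy,
            }
        )
    return calls_to_frame(all_calls), pd.DataFrame(rows)


def calls_to_frame(calls: Iterable[ChromothripsisCall]) -> pd.DataFrame:
    rows = [
        {
            "sample": c.sample, "chrom": c.chrom, "start": c.start, "end": c.end,
            "n_switches": c.n_switches, "confidence": c.confidence,
            "n_states": c.n_states, "canonical": c.canonical,
            "telomere": c.telomere, "centromere": c.centromere,
        }
        for c in calls
    ]
    if not rows:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.DataFrame(rows)[CALL_COLUMNS]
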