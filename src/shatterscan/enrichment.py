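"""Per-chromosome enrichment of chromothriptic events by region permutation.

For each tumour entity with enough chromothripsis-positive cases, the
observed number of events per chromosome is compared against a null in
which every sample's chromothriptic regions are re-placed uniformly at
random (size-preserved, non-overlapping within the sample) across
autosomes + X. The default success rule ("peak") counts a permutation as a
success for chromosome c when the permutation's *maximum* per-chromosome
event count reaches the observed count on c; the alternative
("per-chromosome") compares the permuted count on c itself. Monte-Carlo
p-values use the add-one correction p = (1 + successes) / (1 + N) and are
Bonferroni-adjusted across chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = ["EnrichmentResult", "sample_null_regions", "enrichment_test"]


class PlacementError(RuntimeError):
    """Could not place all regions without overlap within the retry budget."""


@dataclass(frozen=True)
class EnrichmentResult:
    entity: str
    table: pd.DataFrame  # chrom, observed, successes, p, p_adj
    n_permutations: int
    mode: str
    correction: str = "bonferroni"


def sample_null_regions(
    sizes: list[int],
    genome: GenomeModel,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> list[tuple[str, int, int]]:
    """Place regions of the given sizes uniformly at random, non-overlapping.

    Each region lands fully inside one chromosome of the permutation pool
    (autosomes + X), with the chromosome chosen proportionally to its
    number of feasible start positions, and the start uniform among them.
    Regions of one call (one sample) must not overlap each other; placement
    of an overlapping draw is retried up to ``max_retries`` times.
    """
    pool = genome.permutation_pool()
    if not pool:
        raise ValueError("empty permutation pool")
    lengths = np.array([genome.length(c) for c in pool], dtype=np.int64)
    placed: list[tuple[str, int, int]] = []
    for size in sorted(sizes, reverse=True):
        size = int(size)
        feasible = np.maximum(lengths - size + 1, 0)
        if feasible.sum() == 0:
            raise PlacementError(
                f"region of size {size} does not fit on any chromosome"
            )
        ok = False
        for _ in range(max_retries):
            ci = rng.choice(len(pool), p=feasible / feasible.sum())
            start = int(rng.integers(0, feasible[ci]))
            end = start + size
            chrom = pool[ci]
            if all(
                not (chrom == c and start < e and end > s) for c, s, e in placed
            ):
                placed.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place region of size {size} after {max_retries} tries"
            )
    return placed


def _counts_by_chrom(regions: list[tuple[str, int, int]], pool: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(pool)}
    out = np.zeros(len(pool), dtype=np.int64)
    for chrom, _, _ in regions:
        if chrom in index:
            out[index[chrom]] += 1
    return out


def enrichment_test(
    calls: pd.DataFrame,
    genome: GenomeModel,
    entity: str = "all",
    n_permutations: int = 50_000,
    mode: str = "peak",
    rng: np.random.Generator | None = None,
    min_positive_cases: int = 10,
    tiers: tuple[str, ...] = ("high", "intermediate"),
) -> EnrichmentResult:
    """Permutation test for non-random chromosome usage of chromothripsis.

    ``calls`` is a call table for one entity (columns as written by
    :func:`shatterscan.io.write_calls`). Only calls at the given tiers are
    used (default high + intermediate). Requires more than
    ``min_positive_cases`` distinct positive samples; set it to 0 to force
    the test on small toy inputs.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if mode not in {"peak", "per-chromosome"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng() if rng is None else rng

    calls = calls[calls["confidence"].isin(tiers)]
    n_pos = calls["sample"].nunique()
    if n_pos <= min_positive_cases:
        raise ValueError(
            f"entity {entity!r} has {n_pos} positive cases; "
            f"needs more than {min_positive_cases}"
        )
    pool = genome.permutation_pool()
    observed = _counts_by_chrom(
        [(r.chrom, r.start, r.end) for r in calls.itertuples(index=False)], pool
    )
    sizes_per_sample = {
        sample: (sub["end"] - sub["start"]).astype(int).tolist()
        for sample, sub in calls.groupby("sample", sort=True)
    }

    successes = np.zeros(len(pool), dtype=np.int64)
    for _ in range(n_permutations):
        perm_regions: list[tuple[str, int, int]] = []
        for sample in sizes_per_sample:
            perm_regions.extend(
                sample_null_regions(sizes_per_sample[sample], genome, rng)
            )
        counts = _counts_by_chrom(perm_regions, pool)
        if mode == "peak":
            successes += counts.max() >= observed
        else:
            successes += counts >= observed
    p = (1 + successes) / (1 + n_permutations)
    p_adj = np.minimum(p * len(pool), 1.0)
    table = pd.DataFrame(
        {
            "chrom": pool,
            "observed": observed,
            "successes": successes,
            "p": p,
            "p_adj": p_adj,
        }
    )
    return EnrichmentResult(entity, table, n_permutations, mode)
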