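"""Genome walking over structural-variant adjacencies from a locus.

Used to ask whether the TERT locus (default GRCh37 chr5:1,253,282-1,295,184)
is connected to a chromothriptic region through at most two SV traversals
per direction within a total walked distance of 50 Mb.

Walking semantics: starting at the locus boundary, scan outward along the
chromosome. Any SV breakend encountered within the remaining distance
budget may be traversed ("hop"): the walk jumps to the partner breakend
and continues in the direction implied by the partner's orientation (a
head breakend continues toward decreasing coordinates, a tail breakend
toward increasing ones). Only intra-chromosomal scanned distance counts
against the budget; the jump itself is free. The walk links the locus to a
chromothriptic region as soon as any scanned interval overlaps one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel, normalize_chrom

__all__ = [
    "TERT_LOCUS_GRCH37",
    "WalkPath",
    "WalkResult",
    "walk_from_locus",
    "tert_linkage_contrast",
]

TERT_LOCUS_GRCH37 = ("5", 1_253_282, 1_295_184)

_ORIENT_DIR = {"head": -1, "tail": +1}


@dataclass(frozen=True)
class WalkPath:
    sv_ids: tuple[str, ...]
    distance: int
    terminal: tuple[str, int, int]  # chromosome, scan start, scan end
    direction: str  # 'upstream' | 'downstream'
    linked: bool


@dataclass(frozen=True)
class WalkResult:
    sample: str
    linked: bool
    paths: tuple[WalkPath, ...]


def _overlaps(chrom: str, lo: int, hi: int, regions) -> bool:
    # closed scan interval vs half-open regions
    return any(c == chrom and s <= hi and e > lo for c, s, e in regions)


def _breakends(svs: pd.DataFrame):
    """Flatten an SV table into breakend records with partner info."""
    out = []
    for row in svs.itertuples(index=False):
        o1 = "tail" if row.strand1 == "+" else "head"
        o2 = "tail" if row.strand2 == "+" else "head"
        out.append((row.sv_id, row.chrom1, int(row.pos1), row.chrom2, int(row.pos2), o2))
        out.append((row.sv_id, row.chrom2, int(row.pos2), row.chrom1, int(row.pos1), o1))
    return out


def walk_from_locus(
    locus: tuple[str, int, int],
    svs: pd.DataFrame,
    regions,
    genome: GenomeModel | None = None,
    max_hops: int = 2,
    max_distance: int = 50_000_000,
) -> WalkResult:
    """Walk outward from ``locus`` and test connectivity to ``regions``.

    ``regions`` is an iterable of (chrom, start, end) chromothriptic
    regions of the same sample; ``svs`` the sample's SV table. At most
    ``max_hops`` SVs are traversed per direction and the cumulative
    intra-chromosomal scanned distance never exceeds ``max_distance``.
    """
    chrom = normalize_chrom(locus[0])
    if genome is not None and chrom not in genome:
        raise ValueError(f"locus chromosome {chrom!r} absent from genome model")
    regions = [(normalize_chrom(c), int(s), int(e)) for c, s, e in regions]
    breakends = _breakends(svs) if len(svs) else []
    samples = svs["sample"].unique() if len(svs) else []
    sample = str(samples[0]) if len(samples) else ""

    paths: list[WalkPath] = []

    def clip(c: str, p: int) -> int:
        if genome is None or c not in genome:
            return p
        return min(max(p, 0), genome.length(c))

    def explore(c, pos, direction, budget, hops, path_ids, label):
        # scanned interval in this leg
        far = clip(c, pos + direction * budget)
        lo, hi = (far, pos) if direction < 0 else (pos, far)
        linked = _overlaps(c, lo, hi, regions)
        paths.append(
            WalkPath(tuple(path_ids), max_distance - budget, (c, lo, hi),
                     label, linked)
        )
        if hops >= max_hops:
            return
        for sv_id, bc, bpos, pc, ppos, porient in breakends:
            if sv_id in path_ids or bc != c:
                continue
            d = (bpos - pos) * direction
            if d < 0 or d > budget:
                continue
            explore(
                pc,
                ppos,
                _ORIENT_DIR[porient],
                budget - d,
                hops + 1,
                path_ids + [sv_id],
                label,
            )

    # locus itself overlapping a region counts as linked (zero-length walk)
    base_linked = _overlaps(chrom, int(locus[1]), int(locus[2]), regions)
    explore(chrom, int(locus[1]), -1, max_distance, 0, [], "upstream")
    explore(chrom, int(locus[2]), +1, max_distance, 0, [], "downstream")
    linked = base_linked or any(p.linked for p in paths)
    return WalkResult(sample=sample, linked=linked, paths=tuple(paths))


def tert_linkage_contrast(
    linked: pd.Series | np.ndarray,
    tert_gain: pd.Series | np.ndarray,
    correction: bool = False,
):
    """2x2 chi-square contrast of TERT gain vs locus-region linkage.

    Rows are TERT gain yes/no, columns linked yes/no. Returns a dict with
    the table, Pearson chi-square statistic (no continuity correction by
    default) and p-value; a degenerate table (an empty margin) yields
    p = NaN with a warning flag.
    """
    linked = np.asarray(linked, dtype=bool)
    tert_gain = np.asarray(tert_gain, dtype=bool)
    if linked.shape != tert_gain.shape:
        raise ValueError("linked and tert_gain must align")
    table = np.array(
        [
            [np.sum(tert_gain & linked), np.sum(tert_gain & ~linked)],
            [np.sum(~tert_gain & linked), np.sum(~tert_gain & ~linked)],
        ],
        dtype=np.int64,
    )
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        return {
            "table": table, "statistic": float("nan"), "p": float("nan"),
            "degenerate": True,
        }
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return {"table": table, "statistic": float(stat), "p": float(p),
            "degenerate": False}
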