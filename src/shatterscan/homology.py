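"""Breakpoint-microhomology binning and repair-pathway contrasts.

SvABA-style breakpoint homology lengths are binned into five
repair-pathway-informative classes:

====== ===========================
bin    typical repair process
====== ===========================
0-1 bp non-homologous end joining
2 bp   (transition)
3-5 bp alternative end joining
6-9 bp (transition)
>=10   homology-mediated repair
====== ===========================

Per-unit bin proportions (unit = sample for case-wise contrasts, or
sample x region-class for region-wise contrasts) are compared between
chromothripsis-positive and -negative groups with beta regression
(logit mean link, constant precision), after Smithson-Verkuilen shrinkage
of boundary proportions. P-values are Bonferroni-corrected across the five
bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "HOMOLOGY_BINS",
    "HomologyProfile",
    "assign_bin",
    "bin_homologies",
    "split_by_region",
    "homology_contrast",
    "eligible_entities",
]

# (label, lower, upper) with inclusive bounds; upper None = unbounded
HOMOLOGY_BINS = (
    ("0-1", 0, 1),
    ("2", 2, 2),
    ("3-5", 3, 5),
    ("6-9", 6, 9),
    (">=10", 10, None),
)
BIN_LABELS = tuple(b[0] for b in HOMOLOGY_BINS)


@dataclass(frozen=True)
class HomologyProfile:
    unit: str
    counts: tuple[int, ...]
    total: int

    @property
    def proportions(self) -> tuple[float, ...] | None:
        if self.total == 0:
            return None
        return tuple(c / self.total for c in self.counts)


def assign_bin(length: int) -> str:
    """Bin index label for a homology length in bp (total on ints >= 0)."""
    if length < 0:
        raise ValueError("homology length must be >= 0")
    for label, lo, hi in HOMOLOGY_BINS:
        if length >= lo and (hi is None or length <= hi):
            return label
    raise AssertionError("unreachable")


def bin_homologies(lengths, unit: str = "") -> HomologyProfile:
    """Count homology lengths into the five bins; unknowns (NaN) excluded."""
    arr = pd.array(lengths, dtype="Int64")
    arr = arr[~arr.isna()]
    counts = [0] * len(HOMOLOGY_BINS)
    index = {label: i for i, label in enumerate(BIN_LABELS)}
    for v in arr:
        counts[index[assign_bin(int(v))]] += 1
    return HomologyProfile(unit=unit, counts=tuple(counts), total=int(len(arr)))


def split_by_region(svs: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Flag each SV as on-chromothriptic-chromosome or not, per sample.

    An SV belongs to the chromothriptic unit iff either breakend lies on a
    chromosome with a chromothripsis call for that sample. Returns a copy
    of ``svs`` with a boolean ``chromothriptic`` column; no SV is dropped
    or duplicated.
    """
    ct_chroms: dict[str, set[str]] = {}
    for row in calls.itertuples(index=False):
        ct_chroms.setdefault(row.sample, set()).add(row.chrom)
    out = svs.copy()
    out["chromothriptic"] = [
        row.chrom1 in ct_chroms.get(row.sample, set())
        or row.chrom2 in ct_chroms.get(row.sample, set())
        for row in svs.itertuples(index=False)
    ]
    return out


def sample_profiles(svs: pd.DataFrame) -> pd.DataFrame:
    """Per-sample homology-bin proportions as a tidy table."""
    rows = []
    for sample, sub in svs.groupby("sample", sort=True):
        prof = bin_homologies(sub["homlen"], unit=str(sample))
        row = {"sample": sample, "total": prof.total}
        props = prof.proportions
        for i, label in enumerate(BIN_LABELS):
            row[label] = np.nan if props is None else props[i]
        rows.append(row)
    return pd.DataFrame(rows)


def eligible_entities(
    meta: pd.DataFrame,
    positive: pd.Series,
    min_total: int = 15,
    min_per_group: int = 5,
) -> list[str]:
    """Entities with >= min_total cases and >= min_per_group in each arm."""
    df = pd.DataFrame({"entity": meta["entity"].to_numpy(), "pos": np.asarray(positive)})
    keep = []
    for entity, sub in df.groupby("entity", sort=True):
        n_pos = int(sub["pos"].sum())
        if len(sub) >= min_total and n_pos >= min_per_group and len(sub) - n_pos >= min_per_group:
            keep.append(entity)
    return keep


def _shrink(y: np.ndarray) -> np.ndarray:
    """Smithson-Verkuilen transform pulling 0/1 off the boundary."""
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def homology_contrast(
    profiles: pd.DataFrame,
    group: pd.Series | np.ndarray,
    min_count: int = 1,
) -> pd.DataFrame:
    """Per-bin beta regression of homology proportion on a binary group.

    ``profiles`` as returned by :func:`sample_profiles` (bin-label columns
    + ``total``); ``group`` the chromothripsis indicator per row. Units
    with fewer than ``min_count`` informative SVs are dropped. Returns one
    row per bin with the group coefficient (log-odds of the mean
    proportion), raw and Bonferroni-adjusted p-values.
    """
    group = np.asarray(group, dtype=float)
    keep = profiles["total"].to_numpy() >= min_count
    profiles = profiles.loc[keep]
    group = group[keep]
    if len(np.unique(group)) < 2:
        raise ValueError("need both groups present for a contrast")
    exog = np.column_stack([np.ones(len(group)), group])
    rows = []
    for label in BIN_LABELS:
        y = _shrink(profiles[label].to_numpy(dtype=float))
        if np.allclose(y, y[0]):
            rows.append(
                {"bin": label, "coef": 0.0, "p": np.nan, "p_adj": np.nan,
                 "flag": "non-identifiable"}
            )
            continue
        fit = BetaModel(y, exog).fit(disp=False)
        rows.append(
            {"bin": label, "coef": float(fit.params[1]),
             "p": float(fit.pvalues[1]), "p_adj": np.nan, "flag": ""}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * len(BIN_LABELS), 1.0)
    return out
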