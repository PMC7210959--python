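"""Cohort-level chromothripsis tables and association tests.

Covers prevalence by tumour entity, the germline two-hit Fisher contrast,
the TERT-gain / ATRX-truncation chi-square contrast, genome-wide gain/loss
frequency profiles, signature-exposure rank-sum contrasts and the
classification of longitudinal (matched-pair) evolution scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel

__all__ = [
    "positive_samples",
    "prevalence",
    "two_hit_contrast",
    "tert_atrx_contrast",
    "gainloss_profiles",
    "signature_contrast",
    "classify_longitudinal",
    "classify_pairs",
]

TIER_SETS = {
    "high": {"high"},
    "himid": {"high", "intermediate"},
    "any": {"high", "intermediate", "low"},
}


def positive_samples(calls: pd.DataFrame, tier: str = "high") -> set[str]:
    """Samples with at least one call at the given tier or better."""
    tiers = TIER_SETS[tier]
    return set(calls.loc[calls["confidence"].isin(tiers), "sample"])


def prevalence(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    tier: str = "high",
    min_cases: int = 5,
) -> dict[str, pd.DataFrame | float]:
    """Chromothripsis prevalence per entity and cohort-wide.

    Entities with fewer than ``min_cases`` samples are reported in a
    separate ``small_entities`` table rather than the main one.
    """
    pos = positive_samples(calls, tier)
    df = meta[["sample", "entity"]].copy()
    df["positive"] = df["sample"].isin(pos)
    rows = []
    for entity, sub in df.groupby("entity", sort=True):
        rows.append(
            {
                "entity": entity,
                "n_cases": len(sub),
                "n_positive": int(sub["positive"].sum()),
                "prevalence_pct": 100.0 * sub["positive"].mean(),
            }
        )
    table = pd.DataFrame(rows)
    main = table[table["n_cases"] >= min_cases].reset_index(drop=True)
    small = table[table["n_cases"] < min_cases].reset_index(drop=True)
    overall = 100.0 * df["positive"].mean() if len(df) else float("nan")
    return {"table": main, "small_entities": small, "overall_pct": overall}


def _fisher_2x2(table: np.ndarray):
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def two_hit_contrast(
    meta: pd.DataFrame,
    calls: pd.DataFrame,
    tier: str = "high",
) -> dict:
    """Fisher exact contrast of chromothripsis by somatic second hit.

    Restricted to germline-variant carriers (non-null ``germline_gene``).
    Rows: second hit yes/no; columns: chromothripsis yes/no.
    """
    carriers = meta[meta["germline_gene"].notna() & (meta["germline_gene"] != "")]
    pos = positive_samples(calls, tier)
    hit = carriers["second_hit"].astype(bool).to_numpy()
    ct = carriers["sample"].isin(pos).to_numpy()
    table = np.array(
        [
            [np.sum(hit & ct), np.sum(hit & ~ct)],
            [np.sum(~hit & ct), np.sum(~hit & ~ct)],
        ],
        dtype=np.int64,
    )
    degenerate = (table.sum(axis=1) == 0).any()
    if degenerate:
        return {"table": table, "p": float("nan"), "odds_ratio": float("nan"),
                "proportions": (float("nan"), float("nan")), "degenerate": True}
    odds, p = _fisher_2x2(table)
    proportions = (
        table[0, 0] / table[0].sum(),
        table[1, 0] / table[1].sum(),
    )
    return {"table": table, "p": p, "odds_ratio": odds,
            "proportions": proportions, "degenerate": False}


def tert_atrx_contrast(
    meta: pd.DataFrame,
    calls: pd.DataFrame,
    tier: str = "himid",
    correction: bool = False,
) -> pd.DataFrame:
    """Chi-square contrasts of chromothripsis prevalence by telomere group.

    Groups: TERT gain, ATRX truncation, neither. Each of the first two is
    contrasted pairwise against "neither" on the high+intermediate tier
    (the convention for this analysis). Degenerate tables are flagged.
    """
    pos = positive_samples(calls, tier)
    gain = meta["tert_status"] == "gain"
    atrx = meta["atrx_trunc"].astype(bool)
    neither = ~gain & ~atrx
    ct = meta["sample"].isin(pos).to_numpy()
    rows = []
    ref_mask = neither.to_numpy()
    for name, mask in (("tert_gain", gain.to_numpy()), ("atrx_trunc", atrx.to_numpy())):
        table = np.array(
            [
                [np.sum(mask & ct), np.sum(mask & ~ct)],
                [np.sum(ref_mask & ct), np.sum(ref_mask & ~ct)],
            ],
            dtype=np.int64,
        )
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            stat = p = float("nan")
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
        rows.append(
            {
                "group": name,
                "n": int(mask.sum()),
                "prevalence_pct": 100.0 * ct[mask].mean() if mask.any() else np.nan,
                "reference_prevalence_pct": 100.0 * ct[ref_mask].mean()
                if ref_mask.any() else np.nan,
                "statistic": float(stat),
                "p": float(p),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)


def gainloss_profiles(
    segments: pd.DataFrame,
    calls: pd.DataFrame,
    genome: GenomeModel,
    bin_size: int = 1_000_000,
    tier: str = "high",
    baseline: int = 2,
) -> pd.DataFrame:
    """Per-bin gain/loss frequencies for chromothriptic vs other tumours.

    Gain: state > baseline; loss: state < baseline. Frequencies are the
    fraction of samples in each group carrying a gain (or loss) anywhere
    in the bin.
    """
    pos = positive_samples(calls, tier)
    samples = segments["sample"].unique()
    groups = {s: ("ct" if s in pos else "non_ct") for s in samples}
    n_group = {
        "ct": sum(1 for s in samples if groups[s] == "ct"),
        "non_ct": sum(1 for s in samples if groups[s] == "non_ct"),
    }
    rows = []
    for chrom in genome.chromosomes:
        length = genome.length(chrom)
        n_bins = int(np.ceil(length / bin_size))
        # per bin, per group: set of samples with a gain / loss
        gain_hits = {g: np.zeros(n_bins, dtype=object) for g in n_group}
        loss_hits = {g: np.zeros(n_bins, dtype=object) for g in n_group}
        for d in (gain_hits, loss_hits):
            for g in d:
                for i in range(n_bins):
                    d[g][i] = set()
        sub = segments[segments["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            if row.state == baseline:
                continue
            target = gain_hits if row.state > baseline else loss_hits
            g = groups[row.sample]
            first = row.start // bin_size
            last = (row.end - 1) // bin_size
            for i in range(first, last + 1):
                target[g][i].add(row.sample)
        for i in range(n_bins):
            entry = {
                "chrom": chrom,
                "start": i * bin_size,
                "end": min((i + 1) * bin_size, length),
            }
            for g in n_group:
                denom = n_group[g]
                entry[f"gain_{g}"] = len(gain_hits[g][i]) / denom if denom else np.nan
                entry[f"loss_{g}"] = len(loss_hits[g][i]) / denom if denom else np.nan
            rows.append(entry)
    return pd.DataFrame(rows)


def signature_contrast(
    meta: pd.DataFrame,
    calls: pd.DataFrame,
    tier: str = "high",
    pseudo_count: float = 1.0,
    signature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum contrasts of log2 signature exposures by status.

    Exposure columns are those prefixed ``sig_`` unless given explicitly.
    Tests are two-sided on log2(exposure + pseudo_count) and Bonferroni-
    corrected across the signatures tested.
    """
    if signature_columns is None:
        signature_columns = [c for c in meta.columns if c.startswith("sig_")]
    if not signature_columns:
        raise ValueError("no signature exposure columns found")
    pos = positive_samples(calls, tier)
    in_pos = meta["sample"].isin(pos).to_numpy()
    if not in_pos.any() or in_pos.all():
        raise ValueError("one of the chromothripsis groups is empty")
    rows = []
    for col in signature_columns:
        x = np.log2(meta.loc[in_pos, col].to_numpy(dtype=float) + pseudo_count)
        y = np.log2(meta.loc[~in_pos, col].to_numpy(dtype=float) + pseudo_count)
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append({"signature": col, "median_ct": float(np.median(x)),
                         "median_non_ct": float(np.median(y)),
                         "p": np.nan, "p_adj": np.nan, "flag": "constant"})
            continue
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"signature": col, "median_ct": float(np.median(x)),
                     "median_non_ct": float(np.median(y)),
                     "p": float(p), "p_adj": np.nan, "flag": ""})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * len(signature_columns), 1.0)
    return out


SCENARIOS = ("both-negative", "stable", "lost", "gained", "changed")


def classify_longitudinal(
    calls_t1: pd.DataFrame,
    calls_t2: pd.DataFrame,
    tier: str = "high",
    jaccard_threshold: float = 1.0,
) -> str:
    """Scenario of chromothriptic evolution between two timepoints.

    both negative -> both-negative; positive only at T1 -> lost; only at
    T2 -> gained; both positive with (Jaccard-) matching chromothriptic
    chromosome sets -> stable, otherwise changed. The default threshold
    1.0 requires exact set equality.
    """
    tiers = TIER_SETS[tier]
    s1 = set(calls_t1.loc[calls_t1["confidence"].isin(tiers), "chrom"])
    s2 = set(calls_t2.loc[calls_t2["confidence"].isin(tiers), "chrom"])
    if not s1 and not s2:
        return "both-negative"
    if s1 and not s2:
        return "lost"
    if s2 and not s1:
        return "gained"
    jaccard = len(s1 & s2) / len(s1 | s2)
    return "stable" if jaccard >= jaccard_threshold else "changed"


def classify_pairs(
    calls: pd.DataFrame,
    pairs: pd.DataFrame,
    tier: str = "high",
    jaccard_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify every (sample_t1, sample_t2) pair in a pairs table."""
    rows = []
    for row in pairs.itertuples(index=False):
        c1 = calls[calls["sample"] == row.sample_t1]
        c2 = calls[calls["sample"] == row.sample_t2]
        rows.append(
            {
                "patient": row.patient,
                "sample_t1": row.sample_t1,
                "sample_t2": row.sample_t2,
                "scenario": classify_longitudinal(c1, c2, tier, jaccard_threshold),
            }
        )
    return pd.DataFrame(rows)
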