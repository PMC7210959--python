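"""Fusion-call validation against genomic SV breakends and count regression.

A medium- or high-confidence fusion call is validated when both of its
genomic breakpoints have a structural-variant breakend of the same sample
within 200 kb on the same chromosome. The excess of fusions in
chromothripsis-positive tumours is quantified with a log-link count
regression of per-sample fusion counts on log(SV count) and the
chromothripsis indicator; exp(status coefficient) is the fusions-per-SV
rate ratio. Negative binomial by default (robust to overdispersion),
Poisson by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["FusionRegressionFit", "validate_fusions", "fit_fusion_regression"]

VALID_CONFIDENCE = {"medium", "high"}


@dataclass(frozen=True)
class FusionRegressionFit:
    intercept: float
    log_sv_slope: float
    status_effect: float
    rate_ratio: float
    rate_ratio_ci: tuple[float, float]
    family: str


def validate_fusions(
    fusions: pd.DataFrame,
    svs: pd.DataFrame,
    threshold: int = 200_000,
) -> pd.DataFrame:
    """Match both breakpoints of each fusion to nearby SV breakends.

    Low-confidence fusions are dropped before matching. Distance is the
    absolute position difference on the same chromosome (strand ignored);
    a fusion is validated iff both breakpoints are within ``threshold``
    (inclusive). Returns one row per retained fusion with nearest SV ids,
    distances and the validated flag.
    """
    fusions = fusions[fusions["confidence"].isin(VALID_CONFIDENCE)]
    # breakend lookup: sample -> chrom -> (positions, sv ids)
    lookup: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    if len(svs):
        ends = pd.concat(
            [
                svs[["sample", "chrom1", "pos1", "sv_id"]].rename(
                    columns={"chrom1": "chrom", "pos1": "pos"}
                ),
                svs[["sample", "chrom2", "pos2", "sv_id"]].rename(
                    columns={"chrom2": "chrom", "pos2": "pos"}
                ),
            ]
        )
        for (sample, chrom), sub in ends.groupby(["sample", "chrom"], sort=False):
            order = np.argsort(sub["pos"].to_numpy())
            lookup[(sample, chrom)] = (
                sub["pos"].to_numpy()[order],
                sub["sv_id"].to_numpy()[order],
            )

    def nearest(sample, chrom, pos):
        key = (sample, chrom)
        if key not in lookup:
            return None, np.inf
        positions, ids = lookup[key]
        i = int(np.argmin(np.abs(positions - pos)))
        return ids[i], int(abs(positions[i] - pos))

    rows = []
    for row in fusions.itertuples(index=False):
        id_a, d_a = nearest(row.sample, row.chrom_a, row.pos_a)
        id_b, d_b = nearest(row.sample, row.chrom_b, row.pos_b)
        rows.append(
            {
                "sample": row.sample,
                "fusion_id": row.fusion_id,
                "sv_a": id_a,
                "dist_a": d_a,
                "sv_b": id_b,
                "dist_b": d_b,
                "validated": bool(d_a <= threshold and d_b <= threshold),
            }
        )
    cols = ["sample", "fusion_id", "sv_a", "dist_a", "sv_b", "dist_b", "validated"]
    return pd.DataFrame(rows, columns=cols)


def fit_fusion_regression(
    fusion_counts,
    sv_counts,
    status,
    family: str = "nb",
    alpha: float = 0.05,
) -> FusionRegressionFit:
    """Count regression of fusions on log(SV count) and chromothripsis status.

    ``family`` is ``"nb"`` (negative binomial, maximum likelihood) or
    ``"poisson"``. Samples must have sv_count >= 1. Raises if the status
    indicator is constant (effect non-identifiable).
    """
    y = np.asarray(fusion_counts, dtype=float)
    sv = np.asarray(sv_counts, dtype=float)
    g = np.asarray(status, dtype=float)
    if (sv < 1).any():
        raise ValueError("all samples must have at least one structural variant")
    if len(np.unique(g)) < 2:
        raise ValueError("chromothripsis status is constant; effect non-identifiable")
    exog = np.column_stack([np.ones(len(y)), np.log(sv), g])
    if family == "nb":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = sm.NegativeBinomial(y, exog)
            fit = model.fit(disp=0, maxiter=200)
            params = fit.params[:3]
            ci = fit.conf_int(alpha=alpha)[2]
        if not np.all(np.isfinite(ci)) or not np.all(np.isfinite(params)):
            # dispersion collapsed to the Poisson boundary; the NB Hessian
            # is singular there, so take inference from the Poisson limit
            fit = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
            params = fit.params
            ci = fit.conf_int(alpha=alpha)[2]
    elif family == "poisson":
        model = sm.GLM(y, exog, family=sm.families.Poisson())
        fit = model.fit()
        params = fit.params
        ci = fit.conf_int(alpha=alpha)[2]
    else:
        raise ValueError(f"unknown family {family!r}")
    lo, hi = float(np.exp(ci[0])), float(np.exp(ci[1]))
    return FusionRegressionFit(
        intercept=float(params[0]),
        log_sv_slope=float(params[1]),
        status_effect=float(params[2]),
        rate_ratio=float(np.exp(params[2])),
        rate_ratio_ci=(lo, hi),
        family=family,
    )
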