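"""Cohort-level tables, contingency tests and longitudinal classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shatterscan.cohort import (
    classify_longitudinal,
    classify_pairs,
    gainloss_profiles,
    prevalence,
    signature_contrast,
    tert_atrx_contrast,
    two_hit_contrast,
)
from tests.conftest import make_profile


def call_rows(pairs, confidence="high"):
    return pd.DataFrame(
        [
            {"sample": s, "chrom": c, "start": 0, "end": 10_000_000,
             "n_switches": 12, "confidence": confidence, "n_states": 2,
             "canonical": True, "telomere": False, "centromere": False}
            for s, c in pairs
        ],
        columns=["sample", "chrom", "start", "end", "n_switches", "confidence",
                 "n_states", "canonical", "telomere", "centromere"],
    )


def meta_rows(samples, entity="e", **overrides):
    rows = []
    for s in samples:
        row = {"sample": s, "entity": entity, "patient": s,
               "tert_status": "none", "atrx_trunc": False,
               "germline_gene": "", "second_hit": False}
        row.update(overrides)
        rows.append(row)
    return pd.DataFrame(rows)


class TestPrevalence:
    def test_half_positive(self):
        calls = call_rows([("s1", "1"), ("s2", "2")])
        meta = meta_rows(["s1", "s2", "s3", "s4"])
        res = prevalence(calls, meta, min_cases=1)
        assert res["overall_pct"] == 50.0
        assert res["table"].loc[0, "prevalence_pct"] == 50.0

    def test_small_entities_separated(self):
        calls = call_rows([("s1", "1")])
        meta = pd.concat(
            [meta_rows([f"a{i}" for i in range(6)], entity="big"),
             meta_rows(["s1", "s2", "s3"], entity="tiny")]
        )
        res = prevalence(calls, meta)
        assert list(res["table"]["entity"]) == ["big"]
        assert list(res["small_entities"]["entity"]) == ["tiny"]

    def test_row_order_invariant(self):
        calls = call_rows([("s1", "1"), ("s3", "2")])
        meta = meta_rows(["s1", "s2", "s3", "s4", "s5"])
        a = prevalence(calls, meta)["overall_pct"]
        b = prevalence(calls, meta.iloc[::-1])["overall_pct"]
        assert a == b

    def test_recovers_planted_prevalence(self, small_cohort):
        cfg, cohort = small_cohort
        from shatterscan.scoring import score_cohort

        calls, _ = score_cohort(cohort.segments, cohort.genome)
        meta = cohort.metadata
        res = prevalence(calls, meta, min_cases=1)
        truth_rate = 100.0 * meta["ct_truth"].mean()
        assert abs(res["overall_pct"] - truth_rate) < 10.0


class TestTwoHit:
    def test_matches_hypergeometric_enumeration(self):
        # carriers: 10 with second hit (5 CT+), 10 without (2 CT+)
        samples = [f"s{i}" for i in range(20)]
        meta = meta_rows(samples, germline_gene="TP53")
        meta.loc[:9, "second_hit"] = True
        ct_samples = samples[:5] + samples[10:12]
        calls = call_rows([(s, "1") for s in ct_samples])
        res = two_hit_contrast(meta, calls)
        assert res["table"].tolist() == [[5, 5], [2, 8]]
        # independent oracle: exact hypergeometric enumeration
        M, n, N = 20, 7, 10  # total, total CT+, second-hit carriers
        rv = stats.hypergeom(M, n, N)
        p_obs = rv.pmf(5)
        p_exact = sum(rv.pmf(k) for k in range(0, N + 1) if rv.pmf(k) <= p_obs + 1e-12)
        assert res["p"] == pytest.approx(p_exact, rel=1e-9)

    def test_non_carriers_excluded(self):
        meta = pd.concat(
            [meta_rows(["c1", "c2"], germline_gene="ATM"),
             meta_rows(["x1", "x2"])]
        )
        meta.loc[meta["sample"] == "c1", "second_hit"] = True
        calls = call_rows([("c1", "1"), ("x1", "2")])
        res = two_hit_contrast(meta, calls)
        assert res["table"].sum() == 2

    def test_degenerate_flagged(self):
        meta = meta_rows(["s1", "s2"], germline_gene="TP53")  # nobody with hit
        res = two_hit_contrast(meta, call_rows([("s1", "1")]))
        assert res["degenerate"]


class TestTertAtrx:
    def test_matches_closed_form(self):
        samples = [f"s{i}" for i in range(100)]
        meta = meta_rows(samples)
        meta.loc[:29, "tert_status"] = "gain"
        ct = samples[:18] + samples[30:50]  # 18/30 gain, 20/70 neither
        calls = call_rows([(s, "1") for s in ct])
        res = tert_atrx_contrast(meta, calls).set_index("group")
        row = res.loc["tert_gain"]
        a, b, c, d = 18, 12, 20, 50
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert row["statistic"] == pytest.approx(expected, rel=1e-12)
        assert row["p"] == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)

    def test_uses_high_plus_intermediate_tier(self):
        samples = ["s1", "s2", "s3", "s4"]
        meta = meta_rows(samples)
        meta.loc[:1, "tert_status"] = "gain"
        calls = call_rows([("s1", "1")], confidence="intermediate")
        res = tert_atrx_contrast(meta, calls).set_index("group")
        assert res.loc["tert_gain", "prevalence_pct"] == 50.0

    def test_empty_group_flagged(self):
        meta = meta_rows(["s1", "s2"])  # nobody with TERT gain or ATRX
        res = tert_atrx_contrast(meta, call_rows([("s1", "1")]))
        assert res["degenerate"].all()

    def test_type_one_error_controlled(self):
        """Under a common positive rate the test rejects at ~nominal rate."""
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 120
            samples = [f"s{i}" for i in range(n)]
            meta = meta_rows(samples)
            gain = rng.random(n) < 0.3
            meta.loc[gain, "tert_status"] = "gain"
            ct = rng.random(n) < 0.5
            calls = call_rows([(s, "1") for s, c in zip(samples, ct) if c])
            res = tert_atrx_contrast(meta, calls).set_index("group")
            p = res.loc["tert_gain", "p"]
            rejections += (p < 0.05)
        assert rejections / reps <= 0.08  # <= 1.6x nominal


class TestGainLoss:
    def test_all_diploid_zero(self, toy_genome):
        seg = pd.concat(
            [make_profile([0, 100_000_000], [2], sample=s) for s in ("a", "b")]
        )
        prof = gainloss_profiles(seg, call_rows([]), toy_genome,
                                 bin_size=10_000_000)
        value_cols = [c for c in prof.columns if c.startswith(("gain", "loss"))]
        assert (prof[value_cols].fillna(0) == 0).all().all()

    def test_single_gain_sample(self, toy_genome):
        seg = pd.concat(
            [
                make_profile([0, 100_000_000], [3], sample="a"),
                make_profile([0, 100_000_000], [2], sample="b"),
            ]
        )
        # sample "b" carries a call so the groups are {a}=non-CT, {b}=CT
        prof = gainloss_profiles(seg, call_rows([("b", "3")]), toy_genome,
                                 bin_size=50_000_000)
        chr1 = prof[prof["chrom"] == "1"]
        assert (chr1["gain_non_ct"] == 1.0).all()
        assert (chr1["loss_non_ct"] == 0.0).all()
        assert (chr1["gain_ct"] == 0.0).all()

    def test_frequencies_bounded(self, small_cohort):
        _, cohort = small_cohort
        from shatterscan.scoring import score_cohort

        calls, _ = score_cohort(cohort.segments, cohort.genome)
        prof = gainloss_profiles(
            cohort.segments, calls, cohort.genome, bin_size=25_000_000
        )
        value_cols = [c for c in prof.columns if c.startswith(("gain", "loss"))]
        vals = prof[value_cols].to_numpy(dtype=float)
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1


class TestSignatures:
    def _meta(self, n, rng, shift=1.0):
        samples = [f"s{i}" for i in range(2 * n)]
        meta = meta_rows(samples)
        for sig in ("sig_A", "sig_B"):
            meta[sig] = rng.lognormal(6, 1, size=2 * n)
        meta.loc[: n - 1, "sig_A"] *= shift
        return meta, samples[:n]

    def test_identical_groups_not_rejected(self):
        samples = [f"s{i}" for i in range(8)]
        meta = meta_rows(samples)
        meta["sig_A"] = [1, 2, 3, 4, 1, 2, 3, 4]
        calls = call_rows([(s, "1") for s in samples[:4]])
        res = signature_contrast(meta, calls)
        assert (res["p_adj"] == 1.0).all()

    def test_planted_shift_flagged_selectively(self):
        rng = np.random.default_rng(23)
        meta, positives = self._meta(60, rng, shift=4.0)
        calls = call_rows([(s, "1") for s in positives])
        res = signature_contrast(meta, calls).set_index("signature")
        assert res.loc["sig_A", "p_adj"] < 0.05
        assert res.loc["sig_B", "p_adj"] > 0.05

    def test_empty_group_rejected(self):
        meta = meta_rows(["s1", "s2"])
        meta["sig_A"] = [1.0, 2.0]
        with pytest.raises(ValueError, match="empty"):
            signature_contrast(meta, call_rows([]))


class TestLongitudinal:
    def test_scenario_rules(self):
        c5 = call_rows([("t", "5")])
        c5b = call_rows([("t", "5")])
        c7 = call_rows([("t", "7")])
        empty = call_rows([])
        assert classify_longitudinal(c5, c5b) == "stable"
        assert classify_longitudinal(c5, empty) == "lost"
        assert classify_longitudinal(empty, c5) == "gained"
        assert classify_longitudinal(c5, c7) == "changed"
        assert classify_longitudinal(empty, empty) == "both-negative"

    def test_jaccard_relaxation(self):
        c12 = call_rows([("t", "1"), ("t", "2")])
        c1 = call_rows([("t", "1")])
        assert classify_longitudinal(c12, c1) == "changed"
        assert classify_longitudinal(c12, c1, jaccard_threshold=0.5) == "stable"

    def test_tier_filter(self):
        low = call_rows([("t", "5")], confidence="low")
        empty = call_rows([])
        assert classify_longitudinal(low, empty, tier="high") == "both-negative"
        assert classify_longitudinal(low, empty, tier="any") == "lost"

    def test_planted_scenarios_recovered(self, small_cohort):
        _, cohort = small_cohort
        from shatterscan.scoring import score_cohort

        calls, _ = score_cohort(cohort.segments, cohort.genome)
        verdicts = classify_pairs(calls, cohort.pairs)
        merged = verdicts.merge(cohort.pairs, on=["patient", "sample_t1", "sample_t2"])
        agree = (merged["scenario_x"] == merged["scenario_y"]).mean()
        assert agree >= 0.9
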