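"""Seeded synthetic cohorts with planted chromothripsis.

The generator emulates the statistical structure the downstream analyses
assume: clustered breakpoints with oscillating integer copy-number states
(k <= 3 states canonical, > 3 non-canonical), fragment joins drawn
uniformly over the four orientation classes, sparse long background CNVs
and sporadic SVs, group-dependent breakpoint-homology distributions,
TERT-gain status correlated with chromothripsis, fusion counts with a
planted rate ratio, and matched longitudinal pairs under stable / lost /
gained evolution scenarios. A truth table records every planted event.

It is a test harness for the pipeline, not a mechanistic model of
micronucleation or bridge resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, grch37_model
from . import io as sio
from .walking import TERT_LOCUS_GRCH37

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "plant_chromothripsis",
    "simulate_longitudinal_pair",
]

_HOMOLOGY_BIN_RANGES = ((0, 1), (2, 2), (3, 5), (6, 9), (10, 50))
_GERMLINE_GENES = ("TP53", "ATM", "BRCA1", "BRCA2", "MSH2", "NBN")


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; defaults mirror the cohort
    structure of a pan-cancer WGS study (~49% overall planted prevalence,
    ~25% TERT gains, multi-chromosome events in ~78% of positives)."""

    seed: int = 0
    n_samples: int = 200
    genome: str = "GRCh37-like"
    # entity label -> (sampling weight, chromothripsis probability)
    entities: dict = field(
        default_factory=lambda: {
            "sarcoma": {"weight": 0.5, "ct_prob": 0.62},
            "carcinoma": {"weight": 0.5, "ct_prob": 0.36},
        }
    )
    # planted events
    bp_offset: int = 10
    bp_mean: float = 25.0  # breakpoints = bp_offset + Poisson(bp_mean)
    span_range: tuple = (20_000_000, 50_000_000)
    k_probs: dict = field(
        default_factory=lambda: {2: 0.35, 3: 0.35, 4: 0.15, 5: 0.10, 6: 0.05}
    )
    p_telomere: float = 0.36
    p_centromere: float = 0.55
    extra_event_mean: float = 1.5  # events per positive = 1 + Poisson(...)
    max_events: int = 6
    baseline_state: int = 2
    cn_noise: float = 0.3  # uniform +- jitter on copy numbers, < 0.5
    # background
    background_cnv_mean: float = 3.0
    background_cnv_span: tuple = (5_000_000, 30_000_000)
    background_sv_mean: float = 15.0
    # homology bin probabilities: {0-1, 2, 3-5, 6-9, >=10}
    homology_probs_ct: tuple = (0.40, 0.12, 0.28, 0.12, 0.08)
    homology_probs_bg: tuple = (0.28, 0.12, 0.22, 0.16, 0.22)
    # fusions
    fusion_rate_per_sv: float = 0.05
    fusion_rate_ratio: float = 5.0
    fusion_offset_max: int = 50_000
    # TERT / telomere maintenance
    p_gain_ct: float = 0.32
    p_gain_noct: float = 0.20
    p_promoter_mutation: float = 0.05
    p_link_gain: float = 0.30
    p_link_nogain: float = 0.05
    p_atrx: float = 0.08
    # germline two-hit model
    germline_carrier_prob: float = 0.12
    second_hit_prob: float = 0.40
    ct_prob_hit: float = 0.50
    ct_prob_nohit: float = 0.256
    # signatures (log-normal absolute exposures; CT+ shifted where noted)
    signature_names: tuple = ("sig_AC1", "sig_AC2", "sig_AC3", "sig_AC13")
    signature_shift: dict = field(
        default_factory=lambda: {"sig_AC2": 2.0, "sig_AC13": 2.0}
    )
    # longitudinal pairs (added on top of n_samples)
    n_pairs: int = 30
    scenario_mix: tuple = (1 / 3, 1 / 3, 1 / 3)  # stable, lost, gained
    tcc_range: tuple = (0.4, 1.0)

    def genome_model(self) -> GenomeModel:
        if isinstance(self.genome, GenomeModel):
            return self.genome
        if self.genome == "GRCh37-like":
            return grch37_model()
        raise ValueError(f"unknown genome spec {self.genome!r}")


@dataclass
class Cohort:
    genome: GenomeModel
    segments: pd.DataFrame
    svs: pd.DataFrame
    fusions: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    pairs: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_genome_model(
            self.genome, outdir / "genome.sizes", outdir / "centromeres.bed"
        )
        sio.write_segments(self.segments, outdir / "segments.seg")
        sio.write_svs(self.svs, outdir / "svs.bedpe")
        sio.write_fusions(self.fusions, outdir / "fusions.tsv")
        sio.write_metadata(self.metadata, outdir / "metadata.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# event planting


def _state_sequence(n: int, k: int, baseline: int, rng: np.random.Generator) -> list[int]:
    """States s0..sn with s0=sn=baseline, adjacent unequal, exactly k distinct."""
    others = [baseline + 1, baseline - 1, baseline + 2, baseline + 3, baseline + 4]
    others = [s for s in others if s >= 0][: k - 1]
    pool = [baseline] + others
    for _ in range(200):
        seq = [baseline]
        ok = True
        for i in range(1, n):
            choices = [s for s in pool if s != seq[-1]]
            if i == n - 1:
                choices = [s for s in choices if s != baseline] or choices
            seq.append(int(rng.choice(choices)))
        if seq[-1] == baseline:
            continue
        seq.append(baseline)
        if len(set(seq)) == k:
            return seq
    # deterministic fallback: visit each non-baseline state between baselines
    if n < 2 * (k - 1):
        raise ValueError(f"cannot realise {k} states with {n} switches")
    if (n + 1) % 2 == (2 * k - 1) % 2:
        seq = [baseline]
        for o in others:
            seq += [o, baseline]
    else:  # parity mismatch (odd n, k >= 3): fuse the first two visits
        seq = [baseline, others[0], others[1], baseline]
        for o in others[2:]:
            seq += [o, baseline]
    while len(seq) < n + 1:
        seq.insert(1, baseline)
        seq.insert(1, others[0])
    return seq


def plant_chromothripsis(
    chrom_length: int,
    region: tuple[int, int],
    n_breakpoints: int,
    k_states: int,
    rng: np.random.Generator,
    baseline: int = 2,
    telomere_margin: int = 1_000_000,
    force_telomere: bool = False,
):
    """Plant a chromothriptic event inside ``region``.

    Returns ``(breakpoints, pieces, junctions)`` where ``pieces`` is a
    list of (start, end, state) tiling the region, every breakpoint
    boundary is a state switch, exactly ``k_states`` distinct states are
    used, and ``junctions`` couples adjacent breakpoints with uniformly
    random join orientations (one SV per internal junction).

    The state sequence opens and closes at the baseline so the planted
    switch count is exactly ``n_breakpoints``; with ``k_states == 2`` this
    requires an even count, so an odd one is bumped by one.
    """
    start, end = int(region[0]), int(region[1])
    if not (0 <= start < end <= chrom_length):
        raise ValueError("region outside chromosome")
    n = int(n_breakpoints)
    k = int(k_states)
    if n < 2 or k < 2:
        raise ValueError("need at least 2 breakpoints and 2 states")
    if k > n:
        raise ValueError("more states than breakpoints")
    if k == 2 and n % 2:
        n += 1
    chosen: set[int] = set()
    if force_telomere:
        # pin a breakpoint close to the chromosome end the region touches
        if end >= chrom_length - telomere_margin:
            chosen.add(chrom_length - max(telomere_margin // 2, 1))
        elif start <= telomere_margin:
            chosen.add(start + max(telomere_margin // 2, 1))
    while len(chosen) < n:
        draws = rng.integers(start + 1, end - 1, size=n - len(chosen))
        chosen.update(int(d) for d in draws)
    positions = np.sort(np.fromiter(chosen, dtype=np.int64, count=n))
    states = _state_sequence(n, k, baseline, rng)
    bounds = [start, *positions.tolist(), end]
    pieces = [
        (bounds[i], bounds[i + 1], states[i]) for i in range(n + 1)
        if bounds[i] < bounds[i + 1]
    ]
    junctions = []
    for i in range(n - 1):
        s1 = "+" if rng.random() < 0.5 else "-"
        s2 = "+" if rng.random() < 0.5 else "-"
        junctions.append((int(positions[i]), s1, int(positions[i + 1]), s2))
    return positions, pieces, junctions


def _homlen(rng: np.random.Generator, probs) -> int:
    b = rng.choice(len(_HOMOLOGY_BIN_RANGES), p=np.asarray(probs) / np.sum(probs))
    lo, hi = _HOMOLOGY_BIN_RANGES[b]
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# per-sample simulation


class _SampleBundle:
    def __init__(self):
        self.segments: list[dict] = []
        self.svs: list[dict] = []
        self.fusions: list[dict] = []
        self.truth: list[dict] = []
        self.meta: dict = {}


def _place_event_region(cfg, genome, chrom, rng):
    length = genome.length(chrom)
    span = int(rng.uniform(*cfg.span_range))
    span = min(span, int(0.8 * length))
    telomere = rng.random() < cfg.p_telomere
    want_cen = rng.random() < cfg.p_centromere
    cen = genome.centromere(chrom)
    if telomere:
        if rng.random() < 0.5:
            region = (0, span)
        else:
            region = (length - span, length)
    elif want_cen and cen is not None:
        mid = (cen[0] + cen[1]) // 2
        lo = max(0, min(mid - int(span * 0.75), length - span))
        hi = max(lo, min(length - span, mid - int(span * 0.25)))
        start = int(rng.integers(lo, hi + 1))
        region = (start, start + span)
    else:
        start = int(rng.integers(0, length - span + 1))
        region = (start, start + span)
    return region, telomere


def _simulate_sample(
    cfg: SimulationConfig,
    genome: GenomeModel,
    rng: np.random.Generator,
    sample: str,
    patient: str,
    entity: str,
    timepoint: str,
    ct_positive: bool,
    forced_chroms=None,
    meta_overrides=None,
) -> _SampleBundle:
    bundle = _SampleBundle()
    baseline = cfg.baseline_state
    pool = genome.permutation_pool()
    lengths = np.array([genome.length(c) for c in pool], dtype=float)
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    sv_serial = 0
    k_values = np.array(sorted(cfg.k_probs))
    k_weights = np.array([cfg.k_probs[k] for k in k_values], dtype=float)
    k_weights = k_weights / k_weights.sum()
    margin = 1_000_000

    event_regions: list[tuple[str, int, int]] = []
    if ct_positive:
        if forced_chroms is not None:
            chroms = list(forced_chroms)
        else:
            n_events = min(1 + int(rng.poisson(cfg.extra_event_mean)),
                           cfg.max_events, len(pool))
            chroms = list(
                rng.choice(pool, size=n_events, replace=False, p=lengths / lengths.sum())
            )
        for chrom in chroms:
            region, telomere = _place_event_region(cfg, genome, chrom, rng)
            n_bp = cfg.bp_offset + int(rng.poisson(cfg.bp_mean))
            k = int(rng.choice(k_values, p=k_weights))
            k = min(k, n_bp)
            positions, pieces, junctions = plant_chromothripsis(
                genome.length(chrom), region, n_bp, k, rng,
                baseline=baseline, telomere_margin=margin, force_telomere=telomere,
            )
            used[chrom].append(region)
            event_regions.append((chrom, int(region[0]), int(region[1])))
            for s, e, st in pieces:
                bundle.segments.append(
                    {"sample": sample, "chrom": chrom, "start": s, "end": e,
                     "state": st, "planted": True}
                )
            for p1, s1, p2, s2 in junctions:
                sv_serial += 1
                bundle.svs.append(
                    {"sample": sample, "sv_id": f"{sample}_sv{sv_serial}",
                     "chrom1": chrom, "pos1": p1, "strand1": s1,
                     "chrom2": chrom, "pos2": p2, "strand2": s2,
                     "homlen": _homlen(rng, cfg.homology_probs_ct)}
                )
            hull_lo, hull_hi = int(positions[0]), int(positions[-1])
            cen = genome.centromere(chrom)
            length = genome.length(chrom)
            bundle.truth.append(
                {
                    "sample": sample, "chrom": chrom,
                    "start": int(region[0]), "end": int(region[1]),
                    "n_switches": int(len(positions)), "k_states": k,
                    "telomere": bool(
                        hull_lo <= margin or hull_hi >= length - margin
                    ),
                    "centromere": bool(
                        cen is not None and hull_lo < cen[1] and hull_hi > cen[0]
                    ),
                    "canonical": k <= 3,
                }
            )

    # sparse long background CNVs
    n_cnv = int(rng.poisson(cfg.background_cnv_mean))
    for _ in range(n_cnv):
        for _attempt in range(50):
            chrom = pool[int(rng.integers(0, len(pool)))]
            length = genome.length(chrom)
            span = int(rng.uniform(*cfg.background_cnv_span))
            if span >= length:
                continue
            start = int(rng.integers(0, length - span + 1))
            end = start + span
            if all(not (start < e and end > s) for s, e in used[chrom]):
                used[chrom].append((start, end))
                state = baseline + 1 if rng.random() < 0.5 else baseline - 1
                bundle.segments.append(
                    {"sample": sample, "chrom": chrom, "start": start,
                     "end": end, "state": state, "planted": False}
                )
                break

    # sporadic background SVs
    n_bg_sv = int(rng.poisson(cfg.background_sv_mean))
    for _ in range(n_bg_sv):
        sv_serial += 1
        if rng.random() < 0.6:
            chrom = pool[int(rng.integers(0, len(pool)))]
            length = genome.length(chrom)
            p1, p2 = sorted(int(rng.integers(0, length)) for _ in range(2))
            c1 = c2 = chrom
        else:
            i, j = rng.choice(len(pool), size=2, replace=False)
            c1, c2 = pool[int(i)], pool[int(j)]
            p1 = int(rng.integers(0, genome.length(c1)))
            p2 = int(rng.integers(0, genome.length(c2)))
        bundle.svs.append(
            {"sample": sample, "sv_id": f"{sample}_sv{sv_serial}",
             "chrom1": c1, "pos1": p1, "strand1": "+" if rng.random() < 0.5 else "-",
             "chrom2": c2, "pos2": p2, "strand2": "+" if rng.random() < 0.5 else "-",
             "homlen": _homlen(rng, cfg.homology_probs_bg)}
        )

    # telomere maintenance + planted TERT-region link
    if ct_positive:
        tert_gain = rng.random() < cfg.p_gain_ct
    else:
        tert_gain = rng.random() < cfg.p_gain_noct
    if tert_gain:
        tert_status = "gain"
    elif rng.random() < cfg.p_promoter_mutation:
        tert_status = "promoter-mutation"
    else:
        tert_status = "none"
    tert_chrom = TERT_LOCUS_GRCH37[0]
    if ct_positive and event_regions and tert_chrom in genome:
        p_link = cfg.p_link_gain if tert_gain else cfg.p_link_nogain
        if rng.random() < p_link:
            chrom, rs, re_ = event_regions[int(rng.integers(0, len(event_regions)))]
            sv_serial += 1
            pos_a = TERT_LOCUS_GRCH37[2] + int(rng.uniform(100_000, 5_000_000))
            pos_b = int(rng.integers(rs, re_))
            bundle.svs.append(
                {"sample": sample, "sv_id": f"{sample}_sv{sv_serial}",
                 "chrom1": tert_chrom, "pos1": pos_a,
                 "strand1": "+" if rng.random() < 0.5 else "-",
                 "chrom2": chrom, "pos2": pos_b,
                 "strand2": "+" if rng.random() < 0.5 else "-",
                 "homlen": _homlen(rng, cfg.homology_probs_ct)}
            )

    # fusions with the planted fusions-per-SV rate ratio
    n_sv = len(bundle.svs)
    rate = cfg.fusion_rate_per_sv * n_sv * (
        cfg.fusion_rate_ratio if ct_positive else 1.0
    )
    n_fusions = int(rng.poisson(rate)) if n_sv else 0
    for fi in range(n_fusions):
        sv = bundle.svs[int(rng.integers(0, n_sv))]
        off_a = int(rng.integers(0, cfg.fusion_offset_max + 1))
        off_b = int(rng.integers(0, cfg.fusion_offset_max + 1))
        pos_a = min(max(sv["pos1"] + off_a * (1 if rng.random() < 0.5 else -1), 0),
                    genome.length(sv["chrom1"]))
        pos_b = min(max(sv["pos2"] + off_b * (1 if rng.random() < 0.5 else -1), 0),
                    genome.length(sv["chrom2"]))
        conf = rng.choice(["high", "medium", "low"], p=[0.5, 0.3, 0.2])
        bundle.fusions.append(
            {"sample": sample, "fusion_id": f"{sample}_fus{fi + 1}",
             "gene_a": f"GENE{rng.integers(1, 5000)}",
             "gene_b": f"GENE{rng.integers(5000, 10000)}",
             "chrom_a": sv["chrom1"], "pos_a": int(pos_a),
             "chrom_b": sv["chrom2"], "pos_b": int(pos_b),
             "confidence": str(conf)}
        )

    # germline two-hit status was decided by the caller (drives ct_prob)
    meta = {
        "sample": sample, "patient": patient, "entity": entity,
        "cohort_arm": "WGS", "timepoint": timepoint,
        "tert_status": tert_status,
        "atrx_trunc": bool(rng.random() < cfg.p_atrx),
        "germline_gene": "", "second_hit": False,
        "tumor_cell_content": round(float(rng.uniform(*cfg.tcc_range)), 3),
        "n_sv": n_sv, "ct_truth": ct_positive,
    }
    for sig in cfg.signature_names:
        val = float(rng.lognormal(mean=np.log(500.0), sigma=1.0))
        if ct_positive and sig in cfg.signature_shift:
            val *= cfg.signature_shift[sig]
        meta[sig] = round(val, 3)
    if meta_overrides:
        meta.update(meta_overrides)
    bundle.meta = meta

    # assemble full-chromosome segment tables (baseline fill between features)
    rows = []
    for chrom in genome.chromosomes:
        length = genome.length(chrom)
        feats = sorted(
            (s for s in bundle.segments if s["chrom"] == chrom),
            key=lambda s: s["start"],
        )
        cursor = 0
        for f in feats:
            if f["start"] > cursor:
                rows.append({"sample": sample, "chrom": chrom, "start": cursor,
                             "end": f["start"], "state": baseline})
            rows.append({"sample": sample, "chrom": chrom, "start": f["start"],
                         "end": f["end"], "state": f["state"]})
            cursor = f["end"]
        if cursor < length:
            rows.append({"sample": sample, "chrom": chrom, "start": cursor,
                         "end": length, "state": baseline})
    for r in rows:
        noise = float(rng.uniform(-cfg.cn_noise, cfg.cn_noise))
        r["copy_number"] = round(max(r["state"] + noise, 0.0), 4)
    bundle.segments = rows
    return bundle


def simulate_longitudinal_pair(
    scenario: str,
    cfg: SimulationConfig,
    genome: GenomeModel,
    rng: np.random.Generator,
    patient: str,
    entity: str,
    sample_prefix: str,
) -> tuple[_SampleBundle, _SampleBundle]:
    """Matched timepoint pair under a planted evolution scenario.

    stable: same chromothriptic chromosome set at both timepoints;
    lost: events at T1 only; gained: events at T2 only.
    """
    if scenario not in {"stable", "lost", "gained"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    pool = genome.permutation_pool()
    lengths = np.array([genome.length(c) for c in pool], dtype=float)
    n_events = min(1 + int(rng.poisson(cfg.extra_event_mean)), cfg.max_events, len(pool))
    chroms = list(
        rng.choice(pool, size=n_events, replace=False, p=lengths / lengths.sum())
    )
    ct1 = scenario in {"stable", "lost"}
    ct2 = scenario in {"stable", "gained"}
    t1 = _simulate_sample(
        cfg, genome, rng, f"{sample_prefix}_T1", patient, entity, "primary",
        ct1, forced_chroms=chroms if ct1 else None,
    )
    t2 = _simulate_sample(
        cfg, genome, rng, f"{sample_prefix}_T2", patient, entity, "relapse",
        ct2, forced_chroms=chroms if ct2 else None,
    )
    return t1, t2


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort described by ``cfg``.

    Deterministic: the same config (including seed) yields byte-identical
    output files. Longitudinal pair samples are appended after the
    ``n_samples`` independent samples.
    """
    genome = cfg.genome_model()
    rng = np.random.default_rng(cfg.seed)
    entity_names = sorted(cfg.entities)
    weights = np.array([cfg.entities[e]["weight"] for e in entity_names], dtype=float)
    weights = weights / weights.sum()

    bundles: list[_SampleBundle] = []
    pair_rows: list[dict] = []

    for i in range(cfg.n_samples):
        sample = f"S{i + 1:04d}"
        entity = str(rng.choice(entity_names, p=weights))
        carrier = rng.random() < cfg.germline_carrier_prob
        second_hit = bool(carrier and rng.random() < cfg.second_hit_prob)
        if carrier:
            ct_prob = cfg.ct_prob_hit if second_hit else cfg.ct_prob_nohit
        else:
            ct_prob = cfg.entities[entity]["ct_prob"]
        ct_positive = rng.random() < ct_prob
        overrides = {}
        if carrier:
            overrides = {
                "germline_gene": str(
                    _GERMLINE_GENES[int(rng.integers(0, len(_GERMLINE_GENES)))]
                ),
                "second_hit": second_hit,
            }
        bundles.append(
            _simulate_sample(
                cfg, genome, rng, sample, sample, entity, "primary",
                ct_positive, meta_overrides=overrides,
            )
        )

    scenarios = ("stable", "lost", "gained")
    mix = np.asarray(cfg.scenario_mix, dtype=float)
    mix = mix / mix.sum()
    for j in range(cfg.n_pairs):
        scenario = str(rng.choice(scenarios, p=mix))
        patient = f"P{j + 1:03d}"
        entity = str(rng.choice(entity_names, p=weights))
        t1, t2 = simulate_longitudinal_pair(
            scenario, cfg, genome, rng, patient, entity, f"L{j + 1:03d}"
        )
        bundles.extend([t1, t2])
        pair_rows.append(
            {"patient": patient, "sample_t1": t1.meta["sample"],
             "sample_t2": t2.meta["sample"], "scenario": scenario}
        )

    seg = pd.DataFrame([r for b in bundles for r in b.segments])
    seg["state"] = seg["state"].astype(int)
    seg = seg[["sample", "chrom", "start", "end", "copy_number", "state"]]
    svs = pd.DataFrame(
        [r for b in bundles for r in b.svs],
        columns=["sample", "sv_id", "chrom1", "pos1", "strand1",
                 "chrom2", "pos2", "strand2", "homlen"],
    )
    svs["homlen"] = svs["homlen"].astype("Int64")
    if len(svs):
        svs["join_class"] = [
            sio.derive_join_class(a, b) for a, b in zip(svs["strand1"], svs["strand2"])
        ]
        svs["sv_type"] = [
            sio.sv_type_from_join(c1, c2, j)
            for c1, c2, j in zip(svs["chrom1"], svs["chrom2"], svs["join_class"])
        ]
    else:
        svs["join_class"] = []
        svs["sv_type"] = []
    svs = svs[sio.SV_COLUMNS]
    fusions = pd.DataFrame(
        [r for b in bundles for r in b.fusions], columns=sio.FUSION_COLUMNS
    )
    meta = pd.DataFrame([b.meta for b in bundles])
    truth = pd.DataFrame(
        [r for b in bundles for r in b.truth],
        columns=["sample", "chrom", "start", "end", "n_switches", "k_states",
                 "telomere", "centromere", "canonical"],
    )
    pairs = pd.DataFrame(
        pair_rows, columns=["patient", "sample_t1", "sample_t2", "scenario"]
    )
    return Cohort(genome, seg, svs, fusions, meta, truth, pairs)
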