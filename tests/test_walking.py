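"""Genome walking from the TERT locus and the linkage contrast."""

import numpy as np
import pandas as pd
import pytest

from shatterscan.genome import GenomeModel
from shatterscan.walking import TERT_LOCUS_GRCH37, tert_linkage_contrast, walk_from_locus

LOCUS = TERT_LOCUS_GRCH37


def sv_frame(rows):
    out = []
    for i, (c1, p1, s1, c2, p2, s2) in enumerate(rows):
        out.append(
            {"sample": "s", "sv_id": f"sv{i}", "chrom1": c1, "pos1": p1,
             "strand1": s1, "chrom2": c2, "pos2": p2, "strand2": s2,
             "sv_type": "translocation", "join_class": "tail-tail", "homlen": 0}
        )
    return pd.DataFrame(
        out, columns=["sample", "sv_id", "chrom1", "pos1", "strand1", "chrom2",
                      "pos2", "strand2", "sv_type", "join_class", "homlen"]
    )


@pytest.fixture
def walk_genome():
    names = ("5", "7", "9")
    return GenomeModel(names, {c: 250_000_000 for c in names})


class TestWalkFromLocus:
    def test_no_svs_not_linked(self, walk_genome):
        res = walk_from_locus(
            LOCUS, sv_frame([]), [("9", 0, 10_000_000)], genome=walk_genome
        )
        assert not res.linked

    def test_single_hop_into_region(self, walk_genome):
        svs = sv_frame([("5", LOCUS[2] + 100_000, "+", "9", 5_000_000, "+")])
        res = walk_from_locus(
            LOCUS, svs, [("9", 4_000_000, 8_000_000)], genome=walk_genome
        )
        assert res.linked
        linked_paths = [p for p in res.paths if p.linked]
        assert linked_paths and len(linked_paths[0].sv_ids) == 1

    def test_direct_scan_overlap_without_sv(self, walk_genome):
        res = walk_from_locus(
            LOCUS, sv_frame([]), [("5", 10_000_000, 12_000_000)],
            genome=walk_genome,
        )
        assert res.linked  # region within 50 Mb downstream scan

    def test_three_hop_chain_not_linked(self, walk_genome):
        svs = sv_frame(
            [
                ("5", LOCUS[2] + 1_000_000, "+", "7", 1_000_000, "+"),
                ("7", 2_000_000, "+", "9", 1_000_000, "+"),
                ("9", 2_000_000, "+", "5", 200_000_000, "+"),
            ]
        )
        region = ("5", 200_500_000, 201_000_000)
        assert not walk_from_locus(LOCUS, svs, [region], genome=walk_genome).linked
        assert walk_from_locus(
            LOCUS, svs, [region], genome=walk_genome, max_hops=3
        ).linked

    def test_orientation_controls_direction_after_jump(self, walk_genome):
        # partner breakend with head orientation walks toward 0, missing a
        # region placed above it
        svs_head = sv_frame([("5", LOCUS[2] + 100_000, "+", "9", 100_000_000, "-")])
        svs_tail = sv_frame([("5", LOCUS[2] + 100_000, "+", "9", 100_000_000, "+")])
        region_above = ("9", 110_000_000, 115_000_000)
        assert not walk_from_locus(
            LOCUS, svs_head, [region_above], genome=walk_genome
        ).linked
        assert walk_from_locus(
            LOCUS, svs_tail, [region_above], genome=walk_genome
        ).linked

    def test_distance_budget_enforced(self, walk_genome):
        svs = sv_frame([("5", LOCUS[2] + 49_000_000, "+", "9", 5_000_000, "+")])
        near = ("9", 5_500_000, 6_000_000)  # 0.5 Mb past the jump: within budget
        far = ("9", 7_000_000, 8_000_000)  # 2 Mb past the jump: beyond budget
        assert walk_from_locus(LOCUS, svs, [near], genome=walk_genome).linked
        assert not walk_from_locus(LOCUS, svs, [far], genome=walk_genome).linked

    def test_monotone_in_caps(self, walk_genome):
        rng = np.random.default_rng(21)
        names = walk_genome.chromosomes
        for _ in range(40):
            rows = []
            for _i in range(5):
                c1, c2 = rng.choice(names, size=2)
                rows.append(
                    (c1, int(rng.integers(0, 250_000_000)),
                     "+" if rng.random() < 0.5 else "-",
                     c2, int(rng.integers(0, 250_000_000)),
                     "+" if rng.random() < 0.5 else "-")
                )
            svs = sv_frame(rows)
            c = str(rng.choice(names))
            s = int(rng.integers(0, 240_000_000))
            regions = [(c, s, s + 10_000_000)]
            base = walk_from_locus(LOCUS, svs, regions, genome=walk_genome).linked
            more_hops = walk_from_locus(
                LOCUS, svs, regions, genome=walk_genome, max_hops=4
            ).linked
            more_dist = walk_from_locus(
                LOCUS, svs, regions, genome=walk_genome, max_distance=80_000_000
            ).linked
            assert more_hops >= base and more_dist >= base

    def test_mirror_symmetry(self, walk_genome):
        """Mirroring every coordinate (and flipping orientations) preserves
        the linkage verdict."""
        L = 250_000_000
        rng = np.random.default_rng(33)
        flip = {"+": "-", "-": "+"}
        for _ in range(40):
            rows = []
            for _i in range(4):
                c1, c2 = rng.choice(walk_genome.chromosomes, size=2)
                rows.append(
                    (c1, int(rng.integers(0, L)), "+" if rng.random() < 0.5 else "-",
                     c2, int(rng.integers(0, L)), "+" if rng.random() < 0.5 else "-")
                )
            c = str(rng.choice(walk_genome.chromosomes))
            s = int(rng.integers(0, L - 10_000_000))
            regions = [(c, s, s + 10_000_000)]
            fwd = walk_from_locus(LOCUS, sv_frame(rows), regions,
                                  genome=walk_genome).linked
            mirrored_rows = [
                (c1, L - p1, flip[s1], c2, L - p2, flip[s2])
                for c1, p1, s1, c2, p2, s2 in rows
            ]
            mirrored_regions = [(c, L - e, L - s) for c, s, e in regions]
            mirrored_locus = (LOCUS[0], L - LOCUS[2], L - LOCUS[1])
            rev = walk_from_locus(
                mirrored_locus, sv_frame(mirrored_rows), mirrored_regions,
                genome=walk_genome,
            ).linked
            assert fwd == rev

    def test_matches_brute_force_enumeration(self, walk_genome):
        """Independent oracle: exhaustively enumerate all <=2-hop chains."""

        def oracle_linked(locus, svs, regions, max_hops=2, budget=50_000_000):
            ends = []
            for r in svs.itertuples(index=False):
                ends.append((r.sv_id, r.chrom1, r.pos1, r.chrom2, r.pos2,
                             "tail" if r.strand2 == "+" else "head"))
                ends.append((r.sv_id, r.chrom2, r.pos2, r.chrom1, r.pos1,
                             "tail" if r.strand1 == "+" else "head"))

            def hit(chrom, lo, hi):
                return any(c == chrom and s <= hi and e > lo for c, s, e in regions)

            def go(chrom, pos, direction, left, hops, seen):
                far = pos + direction * left
                lo, hi = min(pos, far), max(pos, far)
                lo, hi = max(lo, 0), min(hi, 250_000_000)
                if hit(chrom, lo, hi):
                    return True
                if hops == max_hops:
                    return False
                for sv_id, bc, bp, pc, pp, orient in ends:
                    if sv_id in seen or bc != chrom:
                        continue
                    d = (bp - pos) * direction
                    if 0 <= d <= left and go(
                        pc, pp, 1 if orient == "tail" else -1,
                        left - d, hops + 1, seen | {sv_id},
                    ):
                        return True
                return False

            if hit(locus[0], locus[1], locus[2]):
                return True
            return go(locus[0], locus[1], -1, budget, 0, frozenset()) or go(
                locus[0], locus[2], +1, budget, 0, frozenset()
            )

        rng = np.random.default_rng(55)
        for _ in range(60):
            rows = []
            for _i in range(int(rng.integers(0, 6))):
                c1, c2 = rng.choice(walk_genome.chromosomes, size=2)
                rows.append(
                    (c1, int(rng.integers(0, 250_000_000)),
                     "+" if rng.random() < 0.5 else "-",
                     c2, int(rng.integers(0, 250_000_000)),
                     "+" if rng.random() < 0.5 else "-")
                )
            svs = sv_frame(rows)
            c = str(rng.choice(walk_genome.chromosomes))
            s = int(rng.integers(0, 230_000_000))
            regions = [(c, s, s + 15_000_000)]
            got = walk_from_locus(LOCUS, svs, regions, genome=walk_genome).linked
            assert got == oracle_linked(LOCUS, svs, regions)


class TestLinkageContrast:
    def test_matches_closed_form_pearson(self):
        linked = np.r_[np.ones(10), np.zeros(40), np.ones(3), np.zeros(47)] > 0
        gain = np.r_[np.ones(50), np.zeros(50)] > 0
        res = tert_linkage_contrast(linked, gain)
        a, b = res["table"][0]
        c, d = res["table"][1]
        n = a + b + c + d
        expected = (
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        assert res["statistic"] == pytest.approx(expected, rel=1e-12)
        assert res["statistic"] == pytest.approx(4.33245, abs=1e-4)

    def test_degenerate_table_flagged(self):
        res = tert_linkage_contrast(np.ones(10, dtype=bool), np.r_[np.ones(5), np.zeros(5)] > 0)
        assert res["degenerate"] and np.isnan(res["p"])

    def test_power_at_planted_effect(self):
        """P(link|gain)=0.3 vs 0.05 at n=400 is detected nearly always."""
        rng = np.random.default_rng(2)
        hits = 0
        reps = 40
        for _ in range(reps):
            gain = rng.random(400) < 0.3
            p_link = np.where(gain, 0.3, 0.05)
            linked = rng.random(400) < p_link
            res = tert_linkage_contrast(linked, gain)
            hits += res["p"] < 0.01
        assert hits / reps >= 0.95
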