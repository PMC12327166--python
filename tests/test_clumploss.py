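"""Greedy LD clumping, index tagging and lost-loci accounting."""

import numpy as np
import pandas as pd
import pytest

from inflation_audit import (
    TableLD,
    VariantKey,
    clump_bounds,
    greedy_clump,
    lost_loci_report,
    map_index_to_clumps,
    percent_lost_loci,
)
from inflation_audit.clumploss import Clump, Tagging

from conftest import make_stats


def table_ld(pairs, variants):
    """TableLD from {(pos_a, pos_b): r2} on chromosome 1."""
    df = pd.DataFrame(
        [{"chrom": "1", "pos_a": a, "pos_b": b, "r2": r} for (a, b), r in pairs.items()],
        columns=["chrom", "pos_a", "pos_b", "r2"],
    )
    return TableLD(df, variants=[("1", p) for p in variants])


def reference_clump(stats, ld, p_index=5e-8, p_secondary=5e-6,
                    r2_min=0.20, window_kb=500.0):
    """Independent re-statement of the greedy rule: full exhaustive scan at
    every step, no indexing shortcuts."""
    df = stats.df.reset_index(drop=True)
    nlp = df["neg_log10_p"].to_numpy()
    thr_i = -np.log10(p_index) - 1e-9
    thr_s = -np.log10(p_secondary) - 1e-9
    window = window_kb * 1000.0
    chrom_rank = {str(c): i for i, c in enumerate(list(range(1, 23)) + ["X"])}
    unassigned = set(range(len(df)))
    clumps = []
    while True:
        candidates = [i for i in unassigned if nlp[i] >= thr_i]
        if not candidates:
            break
        i = min(candidates, key=lambda i: (-nlp[i], chrom_rank[df["chrom"][i]],
                                           df["pos"][i]))
        chrom, pos_i = df["chrom"][i], int(df["pos"][i])
        if not ld.has(chrom, pos_i):
            clumps.append((frozenset([i]), i, True))
            unassigned.discard(i)
            continue
        members = set()
        for j in sorted(unassigned):
            if df["chrom"][j] != chrom or nlp[j] < thr_s:
                continue
            if abs(int(df["pos"][j]) - pos_i) > window:
                continue
            r2 = ld.r2_many(chrom, pos_i, [int(df["pos"][j])])[0]
            if np.isnan(r2) or r2 < r2_min:
                continue
            members.add(j)
        members.add(i)
        unassigned -= members
        clumps.append((frozenset(members), i, False))
    return clumps


def as_comparable(stats, clump_set):
    df = stats.df.reset_index(drop=True)
    row_of = {(df["chrom"][i], int(df["pos"][i])): i for i in range(len(df))}
    out = []
    for c in clump_set.clumps:
        members = frozenset(row_of[(k.chrom, k.pos)] for k in c.members)
        out.append((members, row_of[(c.index.chrom, c.index.pos)], c.ld_absent))
    return out


class TestGreedyClump:
    def test_single_isolated_significant(self):
        stats = make_stats([{"pos": 1000, "nlp": 9.0}, {"pos": 5_000_000, "nlp": 2.0}])
        ld = table_ld({}, [1000, 5_000_000])
        clumps = greedy_clump(stats, ld)
        assert len(clumps) == 1
        assert clumps.clumps[0].n_members == 1
        assert clumps.clumps[0].index.pos == 1000
        assert not clumps.clumps[0].ld_absent

    def test_no_index_candidates_gives_empty(self):
        stats = make_stats([{"pos": 1000, "nlp": 7.0}])
        assert len(greedy_clump(stats, table_ld({}, [1000]))) == 0

    def test_five_variant_toy_hand_run(self):
        """Printed r^2 matrix; hand-run of the greedy rule.

        A (p=1e-10) indexes first and absorbs B (r2 0.5) and C (r2 0.3);
        D has r2 0.1 with A and p above the index threshold, so it stays
        out; E is below the secondary threshold.
        """
        stats = make_stats([
            {"pos": 10_000, "id": "A", "nlp": 10.0},
            {"pos": 20_000, "id": "B", "nlp": 9.0},
            {"pos": 30_000, "id": "C", "nlp": 6.5},
            {"pos": 40_000, "id": "D", "nlp": 6.8},
            {"pos": 50_000, "id": "E", "nlp": 4.0},
        ])
        ld = table_ld(
            {(10_000, 20_000): 0.5, (10_000, 30_000): 0.3, (10_000, 40_000): 0.1,
             (20_000, 40_000): 0.25, (10_000, 50_000): 0.9},
            [10_000, 20_000, 30_000, 40_000, 50_000],
        )
        clumps = greedy_clump(stats, ld)
        assert len(clumps) == 1
        c = clumps.clumps[0]
        assert c.index_id == "A"
        assert sorted(c.member_ids) == ["A", "B", "C"]
        assert (c.bound_lo, c.bound_hi) == (10_000, 30_000)

    def test_ld_absent_index_becomes_flagged_single(self):
        stats = make_stats([{"pos": 1000, "nlp": 9.0}])
        clumps = greedy_clump(stats, table_ld({}, []))
        assert clumps.clumps[0].ld_absent
        assert clumps.clumps[0].n_members == 1

    def test_row_order_invariance(self, rng):
        stats, ld = _random_instance(rng, n=25)
        base = sorted(as_comparable(stats, greedy_clump(stats, ld)))
        shuffled = stats.replace(
            stats.df.sample(frac=1, random_state=7).reset_index(drop=True)
        )
        # comparable form maps back to (chrom, pos) row ids of the original
        got = greedy_clump(shuffled, ld)
        df = stats.df.reset_index(drop=True)
        row_of = {(df["chrom"][i], int(df["pos"][i])): i for i in range(len(df))}
        out = sorted(
            (frozenset(row_of[(k.chrom, k.pos)] for k in c.members),
             row_of[(c.index.chrom, c.index.pos)], c.ld_absent)
            for c in got.clumps
        )
        assert out == base

    def test_partition_and_threshold_invariants(self, rng):
        for _ in range(10):
            stats, ld = _random_instance(rng, n=30)
            clumps = greedy_clump(stats, ld)
            seen = set()
            for c in clumps.clumps:
                for k in c.members:
                    assert (k.chrom, k.pos) not in seen
                    seen.add((k.chrom, k.pos))
                nlp = stats.df.set_index("pos")["neg_log10_p"]
                assert nlp[c.index.pos] >= -np.log10(5e-8) - 1e-9
                for k in c.members:
                    assert nlp[k.pos] >= -np.log10(5e-6) - 1e-9
                lo, hi = clump_bounds(c)
                assert lo <= c.index.pos <= hi

    def test_matches_reference_on_random_instances(self, rng):
        for _ in range(25):
            stats, ld = _random_instance(rng, n=int(rng.integers(5, 31)))
            got = sorted(as_comparable(stats, greedy_clump(stats, ld)))
            want = sorted(reference_clump(stats, ld))
            assert got == want


def _random_instance(rng, n=20):
    """Random clumping instance: clustered positions, random r2 table,
    some variants absent from the LD provider."""
    positions = np.sort(rng.choice(np.arange(1000, 3_000_000, 1000), size=n,
                                   replace=False))
    nlp = rng.uniform(3.0, 12.0, size=n)
    stats = make_stats([
        {"pos": int(p), "id": f"v{i}", "nlp": float(v)}
        for i, (p, v) in enumerate(zip(positions, nlp))
    ])
    known = [int(p) for p in positions if rng.random() > 0.15]
    pairs = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                pairs[(int(positions[i]), int(positions[j]))] = float(rng.uniform(0, 1))
    return stats, table_ld(pairs, known)


class TestBounds:
    def test_examples(self):
        key = VariantKey("1", 1000, "A", "G")
        c = Clump("1", key, "x", [key], ["x"], 1000, 1000)
        assert clump_bounds(c) == (1000, 1000)
        members = [VariantKey("1", p, "A", "G") for p in (500, 900, 700)]
        c2 = Clump("1", members[0], "x", members, ["a", "b", "c"], 500, 900)
        assert clump_bounds(c2) == (500, 900)

    def test_bounds_contain_members(self, rng):
        for _ in range(20):
            positions = rng.integers(1, 10**6, size=int(rng.integers(1, 8)))
            members = [VariantKey("2", int(p), "A", "G") for p in positions]
            c = Clump("2", members[0], "x", members, ["y"] * len(members),
                      int(positions.min()), int(positions.max()))
            lo, hi = clump_bounds(c)
            assert all(lo <= k.pos <= hi for k in c.members)


class TestTagging:
    def _clumps(self):
        stats = make_stats([
            {"pos": 10_000, "nlp": 10.0}, {"pos": 20_000, "nlp": 8.0},
            {"pos": 5_000_000, "nlp": 9.0},
        ])
        ld = table_ld({(10_000, 20_000): 0.8}, [10_000, 20_000, 5_000_000])
        return greedy_clump(stats, ld)

    def test_index_variant_tags_its_clump(self):
        clumps = self._clumps()
        tagging = map_index_to_clumps([VariantKey("1", 10_000, "A", "G")], clumps)
        assert tagging.tagged == {0}
        assert tagging.unplaced == []

    def test_unplaced_index_variant(self):
        clumps = self._clumps()
        tagging = map_index_to_clumps([VariantKey("1", 999_999, "A", "G")], clumps)
        assert tagging.tagged == set()
        assert len(tagging.unplaced) == 1

    def test_two_index_variants_one_clump(self):
        clumps = self._clumps()
        tagging = map_index_to_clumps(
            [VariantKey("1", 10_000, "A", "G"), VariantKey("1", 20_000, "A", "G")],
            clumps,
        )
        assert tagging.tagged == {0}


class TestLostLoci:
    def _setup(self):
        stats = make_stats([
            {"pos": 10_000, "nlp": 10.0}, {"pos": 20_000, "nlp": 8.5},
            {"pos": 5_000_000, "nlp": 9.0}, {"pos": 5_010_000, "nlp": 8.2},
            {"pos": 5_020_000, "nlp": 8.1},
        ])
        ld = table_ld(
            {(10_000, 20_000): 0.9, (5_000_000, 5_010_000): 0.8,
             (5_000_000, 5_020_000): 0.5},
            [10_000, 20_000, 5_000_000, 5_010_000, 5_020_000],
        )
        clumps = greedy_clump(stats, ld)
        assert len(clumps) == 2
        return clumps

    def test_all_lost_in_tagged_clumps(self):
        clumps = self._setup()
        tagged = Tagging(tagged={0, 1}, unplaced=[])
        report = lost_loci_report(
            [VariantKey("1", 20_000, "A", "G")], clumps, tagged, n_loci_identified=2,
        )
        assert report.n_lost_loci == 0
        assert report.pct_lost == 0.0

    def test_three_lost_in_one_untagged_clump(self):
        clumps = self._setup()
        tagged = Tagging(tagged={0}, unplaced=[])
        lost = [VariantKey("1", p, "A", "G") for p in (5_000_000, 5_010_000, 5_020_000)]
        report = lost_loci_report(lost, clumps, tagged, n_loci_identified=1)
        assert report.n_lost_robust_untagged == 3
        assert report.n_lost_loci == 1
        assert report.pct_lost == pytest.approx(50.0)

    def test_mhc_exclusion(self):
        clumps = self._setup()
        tagged = Tagging(tagged=set(), unplaced=[])
        lost = [VariantKey("6", 30_000_000, "A", "G")]
        report = lost_loci_report(lost, clumps, tagged, n_loci_identified=3)
        assert report.n_mhc_excluded == 1
        assert report.n_lost_loci == 0

    def test_clumpless_lost_variant_counts_single_excluded(self):
        clumps = self._setup()
        tagged = Tagging(tagged=set(), unplaced=[])
        lost = [VariantKey("1", 777_777, "A", "G")]
        report = lost_loci_report(lost, clumps, tagged, n_loci_identified=1)
        assert report.n_single_excluded == 1
        assert report.n_lost_loci == 0

    def test_undefined_percentage_flagged(self):
        clumps = self._setup()
        tagged = Tagging(tagged={0, 1}, unplaced=[])
        report = lost_loci_report([], clumps, tagged, n_loci_identified=0)
        assert np.isnan(report.pct_lost)


class TestPercentLostLoci:
    def test_printed_counts(self):
        assert round(percent_lost_loci(149, 231), 1) == 39.2
        assert round(percent_lost_loci(170, 277), 1) == 38.0
        assert percent_lost_loci(0, 231) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            percent_lost_loci(0, 0)
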