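"""Greedy LD clumping and the lost-independent-loci accounting.

Clumping groups correlated genome-wide significant variants into loci the
way PLINK does: repeatedly take the smallest-p unassigned variant with
p <= 5e-8 as an index, and assign to its clump every unassigned variant with
p <= 5e-6 lying within +/-500 kb of the index and correlated with it at
r^2 >= 0.20.  A clump's genomic bounds are the min/max member positions.

The loci-loss accounting then asks whether robust associations lost to an
inflation correction fall outside every clump containing a study-defined
index variant: each *untagged* clump holding at least one lost robust
association is a candidate lost independent locus.  Lost associations in
the MHC region (chr6:28,477,797-33,448,354, GRCh37) are removed first —
its extreme LD defeats clump-based independence — and variants absent from
the LD reference (single-variant clumps) are excluded.  The headline
percentage divides lost loci by (lost loci + loci identified in the smaller
study).

Pairwise r^2 comes from an LD provider: either a haplotype panel
(:class:`PanelLD`) or a precomputed table (:class:`TableLD`) so toy
fixtures can state exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import SummaryStats, VariantKey

__all__ = [
    "Clump",
    "ClumpSet",
    "Tagging",
    "LociLossReport",
    "PanelLD",
    "TableLD",
    "MHC_GRCH37",
    "greedy_clump",
    "clump_bounds",
    "map_index_to_clumps",
    "lost_loci_report",
    "percent_lost_loci",
]

#: Major histocompatibility complex region, GRCh37, 1-based inclusive.
MHC_GRCH37 = ("6", 28_477_797, 33_448_354)

_NLP_EPS = 1e-9


class PanelLD:
    """Pairwise r^2 provider backed by a haplotype panel."""

    def __init__(self, panel):
        self._panel = panel
        hap = panel.haplotypes.astype(np.float64)
        sd = hap.std(axis=0)
        sd[sd == 0] = 1.0
        self._x = (hap - hap.mean(axis=0)) / sd
        self._col = {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(panel.chrom, panel.pos))
        }

    def has(self, chrom: str, pos: int) -> bool:
        return (chrom, int(pos)) in self._col

    def r2_many(self, chrom: str, pos_index: int, positions: Sequence[int]) -> np.ndarray:
        """r^2 between the index variant and each listed same-chromosome
        position; NaN for positions absent from the panel."""
        i = self._col.get((chrom, int(pos_index)))
        out = np.full(len(positions), np.nan)
        if i is None:
            return out
        xi = self._x[:, i]
        n = xi.size
        for k, p in enumerate(positions):
            j = self._col.get((chrom, int(p)))
            if j is not None:
                r = float(xi @ self._x[:, j]) / n
                out[k] = r * r
        return out


class TableLD:
    """Pairwise r^2 provider from an explicit table (chrom, pos_a, pos_b, r2).

    The table is treated as symmetric; r^2 of a variant with itself is 1.
    The provider knows exactly the variants listed in ``variants`` (or, by
    default, every position appearing in the table) — anything else is
    "absent from the LD reference".  Unlisted pairs of known variants have
    r^2 = 0.
    """

    def __init__(self, table: pd.DataFrame, variants: Optional[Iterable[tuple]] = None):
        self._r2: dict[tuple, float] = {}
        known = set()
        for row in table.itertuples(index=False):
            chrom = str(row.chrom)
            a, b = int(row.pos_a), int(row.pos_b)
            self._r2[(chrom, a, b)] = float(row.r2)
            self._r2[(chrom, b, a)] = float(row.r2)
            known.add((chrom, a))
            known.add((chrom, b))
        if variants is not None:
            known = {(str(c), int(p)) for c, p in variants}
        self._known = known

    def has(self, chrom: str, pos: int) -> bool:
        return (str(chrom), int(pos)) in self._known

    def r2_many(self, chrom: str, pos_index: int, positions: Sequence[int]) -> np.ndarray:
        chrom = str(chrom)
        out = np.full(len(positions), np.nan)
        for k, p in enumerate(positions):
            p = int(p)
            if (chrom, p) not in self._known:
                continue
            if p == int(pos_index):
                out[k] = 1.0
            else:
                out[k] = self._r2.get((chrom, int(pos_index), p), 0.0)
        return out


@dataclass
class Clump:
    """One LD clump: its index variant (smallest p) and members."""

    chrom: str
    index: VariantKey
    index_id: str
    members: list
    member_ids: list
    bound_lo: int
    bound_hi: int
    ld_absent: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class ClumpSet:
    """All clumps of one study plus the clumping parameters used."""

    clumps: list
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clumps)

    def membership(self) -> dict:
        """(chrom, pos) -> clump position in ``clumps``."""
        out = {}
        for i, c in enumerate(self.clumps):
            for key in c.members:
                out[(key.chrom, key.pos)] = i
        return out


def greedy_clump(
    stats: SummaryStats,
    ld,
    p_index: float = 5e-8,
    p_secondary: float = 5e-6,
    r2_min: float = 0.20,
    window_kb: float = 500.0,
) -> ClumpSet:
    """PLINK-style greedy LD clumping.

    Iteratively picks the unassigned variant with the smallest p among those
    with p <= ``p_index`` (ties broken by chromosome then position
    ascending), and assigns every unassigned variant with p <=
    ``p_secondary`` within +/-``window_kb`` of it and r^2 >= ``r2_min``.
    Index candidates absent from the LD provider become single-variant
    clumps flagged ``ld_absent``.  The result is invariant to input row
    order.
    """
    df = stats.df
    nlp = df["neg_log10_p"].to_numpy()
    thr_index = -np.log10(p_index) - _NLP_EPS
    thr_sec = -np.log10(p_secondary) - _NLP_EPS
    window = window_kb * 1000.0

    chrom_order = {str(c): c_i for c_i, c in enumerate(
        [str(i) for i in range(1, 23)] + ["X"])}
    order = sorted(
        range(len(df)),
        key=lambda i: (
            -nlp[i],
            chrom_order.get(df["chrom"].iat[i], 99),
            int(df["pos"].iat[i]),
        ),
    )

    # per-chromosome position-sorted row lookup for window queries
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in df["chrom"].unique():
        rows = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        rows = rows[np.argsort(df["pos"].to_numpy()[rows], kind="stable")]
        by_chrom[chrom] = (df["pos"].to_numpy()[rows], rows)

    assigned = np.zeros(len(df), dtype=bool)
    clumps: list[Clump] = []
    for i in order:
        if nlp[i] < thr_index:
            break
        if assigned[i]:
            continue
        chrom = df["chrom"].iat[i]
        pos_i = int(df["pos"].iat[i])
        key_i = VariantKey(chrom, pos_i, df["ea"].iat[i], df["oa"].iat[i])
        if not ld.has(chrom, pos_i):
            assigned[i] = True
            clumps.append(
                Clump(chrom, key_i, df["id"].iat[i], [key_i], [df["id"].iat[i]],
                      pos_i, pos_i, ld_absent=True)
            )
            continue
        pos_arr, rows = by_chrom[chrom]
        lo = int(np.searchsorted(pos_arr, pos_i - window, side="left"))
        hi = int(np.searchsorted(pos_arr, pos_i + window, side="right"))
        cand = rows[lo:hi]
        cand = cand[(~assigned[cand]) & (nlp[cand] >= thr_sec)]
        r2 = ld.r2_many(chrom, pos_i, df["pos"].to_numpy()[cand])
        members_rows = cand[np.nan_to_num(r2, nan=-1.0) >= r2_min]
        if i not in members_rows:
            members_rows = np.append(members_rows, i)
        assigned[members_rows] = True
        members_rows = members_rows[np.argsort(df["pos"].to_numpy()[members_rows])]
        keys = [
            VariantKey(chrom, int(df["pos"].iat[r]), df["ea"].iat[r], df["oa"].iat[r])
            for r in members_rows
        ]
        clumps.append(
            Clump(
                chrom=chrom,
                index=key_i,
                index_id=df["id"].iat[i],
                members=keys,
                member_ids=[df["id"].iat[r] for r in members_rows],
                bound_lo=int(min(k.pos for k in keys)),
                bound_hi=int(max(k.pos for k in keys)),
            )
        )
    return ClumpSet(
        clumps=clumps,
        params={
            "p_index": p_index,
            "p_secondary": p_secondary,
            "r2_min": r2_min,
            "window_kb": window_kb,
        },
    )


def clump_bounds(c: Clump) -> tuple[int, int]:
    """Genomic bounds of a clump: min and max member position."""
    if not c.members:
        raise ValueError("clump has no members")
    positions = [k.pos for k in c.members]
    return min(positions), max(positions)


@dataclass
class Tagging:
    """Which clumps contain a study-defined index variant."""

    tagged: set
    unplaced: list


def map_index_to_clumps(index_variants: Sequence, clumps: ClumpSet) -> Tagging:
    """Tag every clump containing a study-defined index variant.

    Membership is by (chrom, pos); an index variant belonging to no clump is
    reported in ``unplaced`` and tags nothing (no proximity fallback).
    Tagging is idempotent: two index variants in one clump tag it once.
    """
    membership = clumps.membership()
    tagged: set[int] = set()
    unplaced = []
    for key in index_variants:
        i = membership.get((key.chrom, key.pos))
        if i is None:
            unplaced.append(key)
        else:
            tagged.add(i)
    return Tagging(tagged=tagged, unplaced=unplaced)


@dataclass(frozen=True)
class LociLossReport:
    """Accounting of independent loci lost to a correction."""

    n_loci_identified: int
    n_lost_robust_untagged: int
    n_lost_loci: int
    n_single_excluded: int
    n_mhc_excluded: int
    pct_lost: float


def lost_loci_report(
    lost_robust: Sequence,
    clumps: ClumpSet,
    tagged: Tagging,
    n_loci_identified: int,
    mhc: tuple = MHC_GRCH37,
) -> LociLossReport:
    """Count unique untagged clumps holding lost robust associations.

    ``lost_robust`` lists the variants (VariantKey, or anything with chrom
    and pos) that were robust before correcting the earlier study and not
    after.  Lost associations inside the MHC interval are removed; those in
    LD-absent single-variant clumps (or in no clump at all, which with
    clumping run on the uncorrected study means LD-absent) are excluded.
    The percentage uses the denominator (lost loci + loci identified in the
    smaller study); it is NaN when both terms are zero.
    """
    mhc_chrom, mhc_lo, mhc_hi = mhc
    membership = clumps.membership()
    n_mhc = 0
    n_single = 0
    untagged_variants = 0
    lost_clumps: set[int] = set()
    for key in lost_robust:
        chrom, pos = str(key.chrom), int(key.pos)
        if chrom == str(mhc_chrom) and mhc_lo <= pos <= mhc_hi:
            n_mhc += 1
            continue
        i = membership.get((chrom, pos))
        if i is None or clumps.clumps[i].ld_absent:
            n_single += 1
            continue
        if i in tagged.tagged:
            continue
        untagged_variants += 1
        lost_clumps.add(i)
    n_lost_loci = len(lost_clumps)
    if n_lost_loci + n_loci_identified > 0:
        pct = percent_lost_loci(n_lost_loci, n_loci_identified)
    else:
        pct = float("nan")
    return LociLossReport(
        n_loci_identified=int(n_loci_identified),
        n_lost_robust_untagged=untagged_variants,
        n_lost_loci=n_lost_loci,
        n_single_excluded=n_single,
        n_mhc_excluded=n_mhc,
        pct_lost=pct,
    )


def percent_lost_loci(n_lost: int, n_identified: int) -> float:
    """100 * lost / (lost + identified): the share of pre-correction loci lost."""
    if n_lost + n_identified <= 0:
        raise ValueError("no loci to account for (both counts zero)")
    return 100.0 * n_lost / (n_lost + n_identified)
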