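"""Pairwise confirmation of associations between successive meta-analyses.

An earlier (smaller) and a later (larger) study of the same trait are
harmonized on shared variants, and every variant is classified against the
genome-wide significance threshold (p <= 5e-8):

* robust / true positive (TP): significant in both studies with a
  consistent direction of effect;
* false positive (FP): significant in the earlier study only, or in both
  with opposite effect directions;
* false negative (FN): significant in the later study only;
* true negative (TN): significant in neither.

From these, %robust = 100 * TP / (earlier-significant), the loss of robust
associations under a correction of the earlier study, and

    FPR = FP / (FP + TN),    TPR = TP / (TP + FN).

Only the earlier study is ever corrected; the later study serves as the
uncorrected confirmation reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats_io import SummaryStats

__all__ = [
    "HarmonizedPair",
    "Confusion",
    "harmonize_pair",
    "classify_pair",
    "percent_robust",
    "percent_lost",
    "confusion_rates",
]

logger = logging.getLogger(__name__)

NLP_GWS = -np.log10(5e-8)
_NLP_EPS = 1e-9  # boundary equality counts as significant


@dataclass
class HarmonizedPair:
    """Shared variants of an earlier/later study pair, allele-aligned.

    ``df`` columns: chrom, pos, id, ea, oa (earlier orientation), eaf_e,
    eaf_l, beta_e, beta_l, nlp_e, nlp_l, chisq_e, chisq_l, flipped.  Where
    ``flipped`` is set the later study's beta was negated and its EAF
    complemented to match the earlier study's effect allele.
    """

    df: pd.DataFrame
    n_dropped_allele_mismatch: int = 0
    n_dropped_multiallelic: int = 0

    @property
    def n_variants(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class Confusion:
    """Confusion counts of a classified pair at one significance threshold."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = 5e-8

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_significant_earlier(self) -> int:
        """Earlier-significant variants: every TP and every FP."""
        return self.tp + self.fp


def _drop_multiallelic(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    dup = df.duplicated(subset=["chrom", "pos"], keep=False)
    return df.loc[~dup], int(dup.sum())


def harmonize_pair(earlier: SummaryStats, later: SummaryStats) -> HarmonizedPair:
    """Inner-join two studies on (chrom, pos) and align alleles.

    Positions carrying more than one variant in either study (multi-allelic
    sites) are dropped before the join; variants whose allele pairs differ
    between the studies are dropped after it, both with tallies.  A swapped
    effect/other allele order in the later study is resolved by negating its
    beta and complementing its EAF (``flipped``).
    """
    if earlier.n_variants == 0 or later.n_variants == 0:
        raise ValueError("both studies must be non-empty")
    e, n_multi_e = _drop_multiallelic(earlier.df)
    l, n_multi_l = _drop_multiallelic(later.df)
    merged = e.merge(l, on=["chrom", "pos"], suffixes=("_e", "_l"), how="inner")
    if len(merged) == 0:
        raise ValueError("the two studies share no variants")

    same = (merged["ea_e"] == merged["ea_l"]) & (merged["oa_e"] == merged["oa_l"])
    swapped = (merged["ea_e"] == merged["oa_l"]) & (merged["oa_e"] == merged["ea_l"])
    mismatch = ~(same | swapped)
    n_mismatch = int(mismatch.sum())
    merged = merged.loc[~mismatch]
    if len(merged) == 0:
        raise ValueError("no variants with matching allele pairs")
    flipped = swapped.loc[merged.index].to_numpy()

    df = pd.DataFrame(
        {
            "chrom": merged["chrom"].to_numpy(),
            "pos": merged["pos"].to_numpy(),
            "id": merged["id_e"].to_numpy(),
            "ea": merged["ea_e"].to_numpy(),
            "oa": merged["oa_e"].to_numpy(),
            "eaf_e": merged["eaf_e"].to_numpy(),
            "eaf_l": np.where(flipped, 1.0 - merged["eaf_l"], merged["eaf_l"]),
            "beta_e": merged["beta_e"].to_numpy(),
            "beta_l": np.where(flipped, -merged["beta_l"], merged["beta_l"]),
            "nlp_e": merged["neg_log10_p_e"].to_numpy(),
            "nlp_l": merged["neg_log10_p_l"].to_numpy(),
            "chisq_e": merged["chisq_e"].to_numpy(),
            "chisq_l": merged["chisq_l"].to_numpy(),
            "flipped": flipped,
        }
    ).reset_index(drop=True)
    if n_mismatch or n_multi_e or n_multi_l:
        logger.info(
            "harmonize_pair dropped %d allele-mismatched and %d+%d multi-allelic variants",
            n_mismatch, n_multi_e, n_multi_l,
        )
    return HarmonizedPair(
        df=df,
        n_dropped_allele_mismatch=n_mismatch,
        n_dropped_multiallelic=n_multi_e + n_multi_l,
    )


def classify_pair(
    pair: HarmonizedPair,
    threshold: float = 5e-8,
    *,
    zero_beta_consistent: bool = False,
) -> tuple[Confusion, pd.DataFrame]:
    """Label every harmonized variant TP/FP/FN/TN at ``threshold``.

    Direction consistency is sign(beta_e) * sign(beta_l) > 0 on the
    harmonized (log-odds) scale.  A beta of exactly 0 on a doubly
    significant variant counts as inconsistent by default
    (``zero_beta_consistent`` flips that policy); occurrences are logged.

    Returns the confusion counts and a per-variant labels table (the
    harmonized columns plus ``label``).
    """
    nlp_thr = -np.log10(threshold)
    df = pair.df
    sig_e = df["nlp_e"].to_numpy() >= nlp_thr - _NLP_EPS
    sig_l = df["nlp_l"].to_numpy() >= nlp_thr - _NLP_EPS
    prod = np.sign(df["beta_e"].to_numpy()) * np.sign(df["beta_l"].to_numpy())
    consistent = (prod > 0) | (zero_beta_consistent & (prod == 0))

    n_zero_sig = int(((prod == 0) & sig_e & sig_l).sum())
    if n_zero_sig:
        logger.warning(
            "%d doubly-significant variants carry a zero beta; counted as %s",
            n_zero_sig, "consistent" if zero_beta_consistent else "inconsistent",
        )

    labels = np.full(len(df), "TN", dtype=object)
    labels[sig_l & ~sig_e] = "FN"
    labels[sig_e & ~sig_l] = "FP"
    labels[sig_e & sig_l & ~consistent] = "FP"
    labels[sig_e & sig_l & consistent] = "TP"

    out = df.copy()
    out["label"] = labels
    counts = pd.Series(labels).value_counts()
    confusion = Confusion(
        tp=int(counts.get("TP", 0)),
        fp=int(counts.get("FP", 0)),
        fn=int(counts.get("FN", 0)),
        tn=int(counts.get("TN", 0)),
        threshold=threshold,
    )
    return confusion, out


def percent_robust(n_robust: int, n_significant_earlier: int) -> float:
    """%robust = 100 * robust / earlier-significant."""
    if n_significant_earlier <= 0:
        raise ValueError("earlier study has no significant associations")
    return 100.0 * n_robust / n_significant_earlier


def percent_lost(n_before: int, n_after: int) -> tuple[int, float]:
    """Robust associations lost to a correction, as (count, percentage).

    ``n_before``/``n_after`` are robust counts before/after correcting the
    earlier study; correction can only remove earlier-study significance, so
    ``n_after`` may not exceed ``n_before``.
    """
    if n_after > n_before:
        raise ValueError(
            f"robust count after correction ({n_after}) exceeds before ({n_before})"
        )
    if n_before <= 0:
        raise ValueError("no robust associations before correction")
    n_lost = n_before - n_after
    return n_lost, 100.0 * n_lost / n_before


def confusion_rates(c: Confusion) -> tuple[float, float]:
    """(FPR, TPR) of a confusion table; NaN where a denominator is zero."""
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else float("nan")
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    return fpr, tpr
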