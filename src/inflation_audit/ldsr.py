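"""LD scores, LD-score regression, intercept correction and polygenicity.

LD-score regression separates confounding from polygenicity by regressing
per-variant association chi^2 statistics on LD scores:

    E[chi^2_j] = intercept + (N * h2 / M) * l_j

where l_j = sum over nearby variants k of r^2_jk (self term included).  Under
pure polygenicity the intercept is 1; an intercept above 1 measures
confounding and can divide the chi^2 statistics exactly like the genomic
inflation factor in GC correction, but is typically smaller, making
intercept correction less conservative.

The fit mirrors the reference procedure: chi^2 values above max(80, 0.001*N)
are removed first; a two-step weighted least squares follows, the second step
weighting each variant by 1 / [2 * (expected chi^2)^2 * max(l, 1)] — the
heteroskedasticity of a scaled chi^2_1 response times the overcounting of
correlated variants; the intercept SE comes from a delete-a-block jackknife
over 200 contiguous blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .inflation import gc_correct
from .sumstats_io import LDScores, SummaryStats

__all__ = [
    "LDSRFit",
    "compute_ld_scores",
    "ldsr_fit",
    "intercept_correct",
    "polygenicity_proxy",
    "effective_sample_size",
]


@dataclass(frozen=True)
class LDSRFit:
    """Result of the chi^2-on-LD-score regression."""

    intercept: float
    slope: float
    h2_est: float
    n_used: int
    n_filtered: int
    jackknife_se_intercept: Optional[float] = None


def compute_ld_scores(panel, window_kb: float = 1000.0, adjust_bias: bool = True) -> LDScores:
    """LD scores from a haplotype panel: l_j = sum_{|pos_k - pos_j| <= w} r^2_jk.

    The self term is included (an isolated variant has l = 1).  With
    ``adjust_bias`` each r^2 is replaced by the approximately unbiased
    r^2 - (1 - r^2)/(n_hap - 2), which removes the 1/n_hap sampling
    inflation of squared correlations (the self term, r^2 = 1, is unchanged).
    """
    n_hap = panel.n_haplotypes
    if n_hap < 2:
        raise ValueError("panel must have at least 2 haplotypes")
    if adjust_bias and n_hap < 3:
        raise ValueError("bias adjustment requires at least 3 haplotypes")
    window = window_kb * 1000.0

    hap = panel.haplotypes.astype(np.float64)
    sd = hap.std(axis=0)
    sd[sd == 0] = 1.0  # monomorphic guard; correlation treated as 0
    x = (hap - hap.mean(axis=0)) / sd

    l2 = np.empty(panel.m_variants)
    for chrom in np.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == chrom)
        idx = idx[np.argsort(panel.pos[idx], kind="stable")]
        pos = panel.pos[idx].astype(float)
        xc = x[:, idx]
        m_c = idx.size
        chunk = 512
        for start in range(0, m_c, chunk):
            stop = min(start + chunk, m_c)
            lo = int(np.searchsorted(pos, pos[start] - window, side="left"))
            hi = int(np.searchsorted(pos, pos[stop - 1] + window, side="right"))
            r = xc[:, start:stop].T @ xc[:, lo:hi] / n_hap
            r2 = r * r
            if adjust_bias:
                r2 = r2 - (1.0 - r2) / (n_hap - 2)
            in_window = (
                np.abs(pos[lo:hi][None, :] - pos[start:stop][:, None]) <= window
            )
            l2[idx[start:stop]] = np.where(in_window, r2, 0.0).sum(axis=1)
    df = pd.DataFrame(
        {"chrom": panel.chrom, "snp": panel.ids, "bp": panel.pos, "l2": l2}
    )
    return LDScores(df=df)


def ldsr_fit(
    stats: SummaryStats,
    scores: LDScores,
    n: float,
    m: Optional[int] = None,
    *,
    jackknife: bool = False,
    n_blocks: int = 200,
) -> LDSRFit:
    """Fit the LD-score regression and estimate intercept, slope and h2.

    Joins summary statistics and LD scores on variant id, removes variants
    with chi^2 > max(80, 0.001*N), then runs the two-step WLS described in
    the module docstring.  ``m`` (the variant count entering h2 = slope*M/N)
    defaults to the number of LD scores supplied.
    """
    merged = stats.df[["id", "chisq", "chrom", "pos"]].merge(
        scores.df[["snp", "l2"]], left_on="id", right_on="snp", how="inner"
    )
    n_input = stats.n_variants
    if len(merged) < 50:
        raise ValueError(
            f"only {len(merged)} variants join the LD scores; need >= 50"
        )
    merged = merged.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    cap = max(80.0, 0.001 * n)
    kept = merged[merged["chisq"] <= cap]
    n_used = len(kept)
    n_filtered = n_input - n_used
    if n_used < 50:
        raise ValueError(f"only {n_used} variants remain after the chi^2 cap")
    l2 = kept["l2"].to_numpy()
    chisq = kept["chisq"].to_numpy()
    if np.ptp(l2) == 0:
        raise ValueError("LD scores have zero variance; slope unidentifiable")

    if m is None:
        m = scores.n_variants

    intercept, slope = _two_step_wls(chisq, l2)
    se = None
    if jackknife:
        blocks = np.array_split(np.arange(n_used), min(n_blocks, n_used))
        est = []
        for b in blocks:
            mask = np.ones(n_used, dtype=bool)
            mask[b] = False
            est.append(_two_step_wls(chisq[mask], l2[mask])[0])
        est = np.asarray(est)
        nb = len(blocks)
        se = float(np.sqrt((nb - 1) / nb * np.sum((est - est.mean()) ** 2)))

    return LDSRFit(
        intercept=float(intercept),
        slope=float(slope),
        h2_est=float(slope * m / n),
        n_used=n_used,
        n_filtered=int(n_filtered),
        jackknife_se_intercept=se,
    )


def _two_step_wls(chisq: np.ndarray, l2: np.ndarray) -> tuple[float, float]:
    """Initial overcounting-weighted fit, then the full LDSR weights."""
    x = sm.add_constant(l2)
    l_adj = np.maximum(l2, 1.0)
    fit0 = sm.WLS(chisq, x, weights=1.0 / l_adj).fit()
    expected = np.maximum(fit0.predict(x), 1e-6)
    w = 1.0 / (2.0 * expected**2 * l_adj)
    fit1 = sm.WLS(chisq, x, weights=w).fit()
    return float(fit1.params[0]), float(fit1.params[1])


def intercept_correct(stats: SummaryStats, intercept: float, *, always: bool = False) -> SummaryStats:
    """Divide chi^2 by the LDSR intercept, exactly as GC correction uses lambda.

    Applied only when the intercept exceeds 1 unless ``always`` is set.
    """
    if intercept <= 0:
        raise ValueError(f"intercept must be > 0, got {intercept}")
    return gc_correct(stats, intercept, always=always)


def polygenicity_proxy(stats: SummaryStats, scores: LDScores) -> float:
    """Pearson correlation of chi^2 with LD score — the polygenicity proxy.

    Rises with effective sample size as more of the polygenic signal is
    captured.  Returns NaN when either side has zero variance.
    """
    merged = stats.df[["id", "chisq"]].merge(
        scores.df[["snp", "l2"]], left_on="id", right_on="snp", how="inner"
    )
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} variants join the LD scores; need >= 3")
    chisq = merged["chisq"].to_numpy()
    l2 = merged["l2"].to_numpy()
    if chisq.std() == 0 or l2.std() == 0:
        return float("nan")
    return float(np.corrcoef(chisq, l2)[0, 1])


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Effective sample size of a case-control study: 4/(1/Ncases + 1/Ncontrols)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be > 0")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
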