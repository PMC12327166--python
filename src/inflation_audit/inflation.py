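"""Genomic inflation factor (lambda) and genomic-control correction.

The genomic inflation factor is

    lambda = median(observed chi^2) / median(chi^2_1)

where the chi-square statistics come from 1-df association tests and the
theoretical median of the chi^2 distribution with one degree of freedom is
~0.45494 (often printed as 0.454).  Genomic control (GC) divides every chi^2
statistic by lambda and recomputes p-values, deflating the whole distribution
to median 1.

All p-value arithmetic here runs on the -log10(p) / chi^2 scale: meta-analyses
routinely contain p ~ 1e-300, far below where a double can represent p
directly, so conversions go through the log survival function of the normal
distribution (chi^2_1 is the square of a standard normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "CHI2_1_MEDIAN",
    "LambdaResult",
    "MafLambdaProfile",
    "p_to_chisq",
    "chisq_to_p",
    "compute_lambda",
    "gc_correct",
    "gc_uncorrect",
    "lambda_maf_profile",
]

#: Median of the chi-square distribution with one degree of freedom, at full
#: double precision.  The commonly printed value 0.454 is this rounded down.
CHI2_1_MEDIAN: float = float(sps.chi2.ppf(0.5, df=1))

_LN10 = np.log(10.0)
_LN2 = np.log(2.0)


@dataclass(frozen=True)
class LambdaResult:
    """Genomic inflation factor together with the statistics behind it."""

    lam: float
    n_variants: int
    median_chisq: float


@dataclass(frozen=True)
class MafLambdaProfile:
    """Lambda recomputed after removing variants below successive MAF cutoffs.

    ``lam_at`` holds ``None`` where a cutoff left no variants.
    """

    thresholds: tuple
    lam_at: tuple
    n_at: tuple


def p_to_chisq(neg_log10_p):
    """Convert -log10(p) to the matching 1-df chi-square statistic.

    Evaluated on the log scale through the inverse of the normal log-CDF
    (``ndtri_exp``), so it stays exact far beyond the underflow point of a
    double (p < 1e-308, i.e. neg_log10_p > 308).

    Parameters
    ----------
    neg_log10_p : float or array-like
        -log10 of the p-value(s); must be finite and >= 0.

    Returns
    -------
    float or ndarray
        chi-square statistic(s) with sf_chi2_1(chisq) = p.
    """
    nlp = np.asarray(neg_log10_p, dtype=float)
    if not np.all(np.isfinite(nlp)):
        raise ValueError("neg_log10_p must be finite")
    if np.any(nlp < 0):
        raise ValueError("neg_log10_p must be >= 0")
    # sf(chisq) = p  <=>  2 * Phi(-z) = p with z = sqrt(chisq)
    log_half_p = -nlp * _LN10 - _LN2
    z = -special.ndtri_exp(log_half_p)
    out = z * z
    return out if out.ndim else float(out)


def chisq_to_p(chisq):
    """Convert a 1-df chi-square statistic to -log10(p), underflow-safe.

    Inverse of :func:`p_to_chisq`; the round trip is exact to ~1e-9 relative
    over -log10(p) in [0, 320].
    """
    x = np.asarray(chisq, dtype=float)
    if np.any(x < 0):
        raise ValueError("chisq must be >= 0")
    log_p = special.log_ndtr(-np.sqrt(x)) + _LN2
    out = -log_p / _LN10
    return out if out.ndim else float(out)


def compute_lambda(stats) -> LambdaResult:
    """Genomic inflation factor of a summary-statistics table.

    lambda = median(chi^2) / median(chi^2_1), with the theoretical median at
    full precision and the sample median using midpoint interpolation for
    even counts.
    """
    chisq = np.asarray(stats.df["chisq"], dtype=float)
    if chisq.size == 0:
        raise ValueError("cannot compute lambda on empty summary statistics")
    med = float(np.median(chisq))
    return LambdaResult(lam=med / CHI2_1_MEDIAN, n_variants=int(chisq.size), median_chisq=med)


def _rescale(stats, factor: float):
    """Return a copy of ``stats`` with chi^2 multiplied by ``factor``."""
    df = stats.df.copy()
    df["chisq"] = df["chisq"] * factor
    df["neg_log10_p"] = chisq_to_p(df["chisq"].to_numpy())
    return stats.replace(df)


def gc_correct(stats, lam: float, *, always: bool = False):
    """Apply genomic-control correction: chi^2 -> chi^2 / lambda.

    By default the division is applied only when ``lam > 1`` (standard GC
    practice: no deflation correction); pass ``always=True`` to force it, as
    needed for an exact un-correct/re-correct round trip.  Effect sizes and
    standard errors are left untouched — GC operates on test statistics only.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    if lam <= 1 and not always:
        return stats.replace(stats.df.copy())
    return _rescale(stats, 1.0 / lam)


def gc_uncorrect(stats, lam: float):
    """Undo a GC correction: chi^2 -> chi^2 * lambda, p recomputed.

    Used to recover uncorrected statistics from studies that report only
    GC-corrected p-values alongside their lambda.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    return _rescale(stats, lam)


def lambda_maf_profile(stats, thresholds: Sequence[float]) -> MafLambdaProfile:
    """Lambda over the subsets {MAF >= t} for each cutoff t.

    Cutoffs that leave no variants yield ``None`` in ``lam_at`` (and 0 in
    ``n_at``) rather than failing the whole profile.
    """
    maf = stats.maf.to_numpy()
    chisq = stats.df["chisq"].to_numpy()
    lam_at, n_at = [], []
    for t in thresholds:
        keep = maf >= t
        n = int(keep.sum())
        n_at.append(n)
        lam_at.append(float(np.median(chisq[keep]) / CHI2_1_MEDIAN) if n else None)
    return MafLambdaProfile(tuple(thresholds), tuple(lam_at), tuple(n_at))
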