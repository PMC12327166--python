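"""Synthetic LD panels and GWAS summary statistics with known truth.

The generator emulates the statistical structure that both inflation
estimators assume:

* a haplotype reference panel with block-diagonal LD — within a block,
  adjacent variants correlate at a target rho (AR(1)-like decay); across
  blocks, independence; blocks are separated by >1 Mb so LD windows never
  bridge them;
* per-variant z-scores drawn from the LD-score-regression variance model,
  Var(z_j) = c + N * h2 * l_j / M, where c >= 1 is the confounding intercept,
  N the effective sample size, h2 the heritability, l_j the LD score and M
  the variant count;
* a pair of overlapping studies sharing the variant set and the true genetic
  signal, with study-specific confounding and noise — the earlier/later
  design used to define robust associations.

Haplotypes are binary Markov chains: each variant's carriers are drawn so the
correlation with the previous variant matches rho given both marginal
frequencies (joint frequency clipped to the feasible Frechet range).  MAFs
follow a symmetric beta spectrum with a 0.5% floor, mirroring common
meta-analysis frequency filters.  Statistical power's dependence on allele
frequency can be emulated (``maf_power=True``) by scaling each variant's
polygenic variance share with 2*maf*(1-maf) (the additive-coding genotype
variance), normalised to mean 1.  It is off by default: allele frequency
bounds attainable r^2 in a binary panel, so the scaling correlates with the
LD score and bends E[chi^2 | l] away from the straight line the LD-score
regression assumes — it is a deliberate model violation for studying
MAF-threshold effects, not part of the calibrated generative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .inflation import chisq_to_p
from .sumstats_io import SummaryStats, SUMSTATS_COLUMNS, VariantKey

__all__ = [
    "SynthConfig",
    "Panel",
    "SyntheticTruth",
    "simulate_panel",
    "simulate_sumstats",
    "simulate_study_pair",
    "make_index_variants",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Generating parameters for a synthetic study pair.

    Defaults describe a polygenic case-control trait measured in two
    overlapping meta-analyses: a confounded earlier study (c = 1.2) of
    effective size 50,000 and a clean later study four times larger, with
    h2 = 0.4 spread over every variant (infinitesimal model), blocks of 50
    variants at adjacent-correlation 0.7, and a beta(0.8, 0.8) MAF spectrum
    floored at 0.5%.
    """

    m_variants: int = 20_000
    n_chromosomes: int = 10
    block_size: int = 50
    rho: float = 0.7
    rho_block_sd: float = 0.15
    maf_beta: tuple = (0.8, 0.8)
    maf_floor: float = 0.005
    h2: float = 0.4
    prop_causal: float = 1.0
    c_earlier: float = 1.2
    c_later: float = 1.0
    n_earlier: float = 50_000.0
    n_later: float = 200_000.0
    n_haplotypes: int = 400
    sample_overlap: float = 0.0
    maf_power: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not 0 <= self.h2 < 1:
            raise ValueError(f"h2 must be in [0, 1), got {self.h2}")
        if not 0 < self.prop_causal <= 1:
            raise ValueError(f"prop_causal must be in (0, 1], got {self.prop_causal}")
        for name in ("c_earlier", "c_later"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (confounding intercept)")
        if not 0 <= self.sample_overlap <= 1:
            raise ValueError("sample_overlap must be in [0, 1]")
        if self.m_variants < 1 or self.n_chromosomes < 1 or self.block_size < 1:
            raise ValueError("m_variants, n_chromosomes, block_size must be >= 1")


@dataclass
class Panel:
    """Haplotype reference panel with block LD structure.

    haplotypes: (n_hap, m) 0/1 matrix; one column per variant, sorted by
    (chrom, pos).  ``eaf`` is the realised panel frequency of the allele
    coded 1 (the effect allele).
    """

    haplotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    eaf: np.ndarray
    block_id: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def m_variants(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated study (pair)."""

    causal: np.ndarray
    effects: np.ndarray
    h2: float
    c: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    ld_scores: Optional[np.ndarray] = None
    panel: Optional[Panel] = None


# --- panel ------------------------------------------------------------------

_BLOCK_SPACING_BP = 4_000       # within-block inter-variant distance
_BLOCK_GAP_BP = 1_500_000      # gap between consecutive blocks (>1 Mb window)


def simulate_panel(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> Panel:
    """Draw a haplotype panel with AR(1)-like LD inside blocks.

    Within a block, each variant's joint frequency with its predecessor is
    set so their correlation equals the block's LD strength (so variants k
    apart correlate at ~rho**k); blocks and chromosomes are independent.
    Block LD strengths are normal around ``config.rho`` with spread
    ``config.rho_block_sd`` (clipped to [0, 0.98]) — heterogeneous LD across
    the genome is what gives the LD-score distribution its spread; set the
    spread to 0 for a homogeneous panel.  A block of 50 variants spans
    ~200 kb and consecutive blocks are 1.5 Mb apart.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m, n_hap = config.m_variants, config.n_haplotypes

    a, b = config.maf_beta
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1

    chrom = np.repeat([str(i + 1) for i in range(config.n_chromosomes)], per_chrom)
    pos = np.empty(m, dtype=np.int64)
    block_id = np.empty(m, dtype=np.int64)
    hap = np.empty((n_hap, m), dtype=np.int8)

    # MAF is drawn per LD block with mild per-variant jitter: variants of a
    # block share haplotype backgrounds, so their frequencies are similar —
    # which also keeps the target adjacent correlation inside the Frechet
    # bounds of the binary joint distribution for any rho < 1.  Haplotypes
    # code the minor allele as 1; a random half of the columns are recoded
    # to the major allele afterwards (r^2 is invariant to the coding).
    j = 0
    next_block = 0
    for n_c in per_chrom:
        p = 1_000_000
        for start in range(0, n_c, config.block_size):
            size = min(config.block_size, n_c - start)
            cols = slice(j, j + size)
            block_id[cols] = next_block
            pos[cols] = p + _BLOCK_SPACING_BP * np.arange(size)
            block_maf = config.maf_floor + (0.5 - config.maf_floor) * rng.beta(a, b)
            freq = np.clip(
                block_maf * (1.0 + 0.05 * rng.standard_normal(size)),
                config.maf_floor,
                0.5,
            )
            # per-block LD strength: genomic blocks differ widely in LD,
            # which is what spreads the LD-score distribution.  The ceiling
            # keeps extreme-LD blocks' chi^2 well below the LDSR fit's cap
            # at the sample sizes this generator emulates.
            rho_b = float(np.clip(
                config.rho + config.rho_block_sd * rng.standard_normal(), 0.0, 0.92
            ))
            _fill_block(hap[:, cols], freq, rho_b, rng)
            p += _BLOCK_SPACING_BP * size + _BLOCK_GAP_BP
            next_block += 1
            j += size
    flip = rng.random(m) < 0.5
    hap[:, flip] = 1 - hap[:, flip]

    # guard against monomorphic columns (possible at floor MAF with a finite
    # panel): give them a single carrier so r^2 is defined
    counts = hap.sum(axis=0)
    for col in np.flatnonzero(counts == 0):
        hap[rng.integers(n_hap), col] = 1
    for col in np.flatnonzero(counts == n_hap):
        hap[rng.integers(n_hap), col] = 0

    pair_idx = rng.integers(0, 4, size=m)
    offset = rng.integers(1, 4, size=m)
    ea = _BASES[pair_idx]
    oa = _BASES[(pair_idx + offset) % 4]
    ids = np.array([f"snp{i}" for i in range(m)])
    return Panel(
        haplotypes=hap,
        chrom=np.asarray(chrom),
        pos=pos,
        ids=ids,
        ea=ea,
        oa=oa,
        eaf=hap.mean(axis=0),
        block_id=block_id,
    )


def _fill_block(out: np.ndarray, freq: np.ndarray, rho: float, rng: np.random.Generator) -> None:
    """Markov-chain haplotype block with adjacent correlation ~rho."""
    n_hap, size = out.shape
    prev = (rng.random(n_hap) < freq[0]).astype(np.int8)
    out[:, 0] = prev
    for k in range(1, size):
        f_prev, f_k = freq[k - 1], freq[k]
        p11 = f_prev * f_k + rho * np.sqrt(f_prev * (1 - f_prev) * f_k * (1 - f_k))
        p11 = min(max(p11, max(0.0, f_prev + f_k - 1.0)), min(f_prev, f_k))
        p_given1 = p11 / f_prev
        p_given0 = (f_k - p11) / (1.0 - f_prev)
        u = rng.random(n_hap)
        cur = np.where(prev == 1, u < p_given1, u < p_given0).astype(np.int8)
        out[:, k] = cur
        prev = cur


# --- summary statistics -----------------------------------------------------


def _polygenic_variance(config: SynthConfig, n: float, ld_scores: np.ndarray,
                        eaf: np.ndarray, causal: np.ndarray) -> np.ndarray:
    """Per-variant polygenic variance share N*h2*l_j/M, with optional
    MAF-power and sparse-causal modulation (both mean-one, independent of l)."""
    m = ld_scores.size
    v = n * config.h2 * ld_scores / m
    if config.maf_power:
        s = 2.0 * eaf * (1.0 - eaf)
        v = v * (s / s.mean())
    v = v * causal / config.prop_causal
    return v


def simulate_sumstats(
    panel: Panel,
    config: SynthConfig,
    n: float,
    c: float,
    rng: Optional[np.random.Generator] = None,
    *,
    seed: Optional[int] = None,
    ld_scores: Optional[np.ndarray] = None,
    shared: Optional[tuple] = None,
) -> tuple[SummaryStats, SyntheticTruth]:
    """Draw one study's summary statistics under the LDSR variance model.

    z_j = sqrt(v_j) * u_j + sqrt(c) * e_j with v_j the polygenic variance
    share (mean N*h2*l_j/M) and u_j the genetic component; chi^2 = z^2, the
    beta carries the sign of z, SE = 1/sqrt(2*eaf*(1-eaf)*N).  Passing
    ``shared=(causal, u)`` reuses the genetic component so several studies
    observe the same true effects.
    """
    if c < 1:
        raise ValueError(f"confounding intercept c must be >= 1, got {c}")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if ld_scores is None:
        from .ldsr import compute_ld_scores

        ld_scores = compute_ld_scores(panel).df["l2"].to_numpy()
    m = panel.m_variants

    if shared is None:
        causal = rng.random(m) < config.prop_causal
        u = np.where(causal, rng.standard_normal(m), 0.0)
    else:
        causal, u = shared
    v = _polygenic_variance(config, n, ld_scores, panel.eaf, causal)
    z = np.sqrt(v) * u + np.sqrt(c) * rng.standard_normal(m)

    stats = _stats_from_z(panel, z, n)
    truth = SyntheticTruth(
        causal=causal,
        effects=np.sqrt(v / max(n, 1.0)) * u,
        h2=config.h2,
        c={"study": c},
        n={"study": n},
        ld_scores=ld_scores,
        panel=panel,
    )
    return stats, truth


def _stats_from_z(panel: Panel, z: np.ndarray, n: float) -> SummaryStats:
    chisq = z * z
    eaf = panel.eaf
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
    df = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "id": panel.ids,
            "ea": panel.ea,
            "oa": panel.oa,
            "eaf": eaf,
            "beta": z * se,
            "se": se,
            "neg_log10_p": chisq_to_p(chisq),
            "chisq": chisq,
            "n": float(n),
        }
    )[SUMSTATS_COLUMNS]
    return SummaryStats(df=df)


def simulate_study_pair(
    config: SynthConfig,
) -> tuple[SummaryStats, SummaryStats, SyntheticTruth]:
    """Simulate an earlier/later study pair over one shared panel.

    Both studies see the same causal variants and genetic components u_j —
    only the scale sqrt(N*h2*l/M) and the confounding/noise differ — so a
    well-powered later study confirms the earlier study's true signals.
    ``config.sample_overlap`` correlates the noise components (0 = disjoint
    samples).  Fully deterministic given the config (seed included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    from .ldsr import compute_ld_scores

    ld_scores = compute_ld_scores(panel).df["l2"].to_numpy()
    m = panel.m_variants

    causal = rng.random(m) < config.prop_causal
    u = np.where(causal, rng.standard_normal(m), 0.0)

    eps_e = rng.standard_normal(m)
    eps_fresh = rng.standard_normal(m)
    r = config.sample_overlap
    eps_l = r * eps_e + np.sqrt(1.0 - r * r) * eps_fresh

    v_e = _polygenic_variance(config, config.n_earlier, ld_scores, panel.eaf, causal)
    v_l = _polygenic_variance(config, config.n_later, ld_scores, panel.eaf, causal)
    z_e = np.sqrt(v_e) * u + np.sqrt(config.c_earlier) * eps_e
    z_l = np.sqrt(v_l) * u + np.sqrt(config.c_later) * eps_l

    earlier = _stats_from_z(panel, z_e, config.n_earlier)
    later = _stats_from_z(panel, z_l, config.n_later)
    truth = SyntheticTruth(
        causal=causal,
        effects=np.sqrt(v_e / max(config.n_earlier, 1.0)) * u,
        h2=config.h2,
        c={"earlier": config.c_earlier, "later": config.c_later},
        n={"earlier": config.n_earlier, "later": config.n_later},
        ld_scores=ld_scores,
        panel=panel,
    )
    return earlier, later, truth


def make_index_variants(stats: SummaryStats, panel: Panel) -> list[VariantKey]:
    """Synthetic stand-in for a study's published index-variant list.

    Returns the index variants of greedy LD clumping at the default
    thresholds (p <= 5e-8 index, 5e-6 secondary, r^2 >= 0.20, +/-500 kb).
    """
    from .clumploss import PanelLD, greedy_clump

    clumps = greedy_clump(stats, PanelLD(panel))
    return [c.index for c in clumps.clumps]
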