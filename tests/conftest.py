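"""Shared fixtures: hand-built summary statistics and small simulated pairs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from inflation_audit import SynthConfig, SummaryStats, simulate_study_pair
from inflation_audit.inflation import chisq_to_p, p_to_chisq
from inflation_audit.ldsr import compute_ld_scores
from inflation_audit.sumstats_io import SUMSTATS_COLUMNS


def make_stats(rows) -> SummaryStats:
    """Build validated SummaryStats from terse row dicts.

    Each row needs chrom and pos; alleles default to A/G, eaf to 0.3,
    beta to 0.1, se to 0.02, n to 10_000.  The association statistic is
    given as ``nlp`` (-log10 p) or ``chisq`` (the other is derived).
    """
    records = []
    for i, r in enumerate(rows):
        nlp = r.get("nlp")
        chisq = r.get("chisq")
        if nlp is None and chisq is None:
            nlp = 1.0
        if nlp is None:
            nlp = chisq_to_p(chisq)
        if chisq is None:
            chisq = p_to_chisq(nlp)
        records.append(
            {
                "chrom": str(r.get("chrom", "1")),
                "pos": int(r["pos"]),
                "id": r.get("id", f"v{i}"),
                "ea": r.get("ea", "A"),
                "oa": r.get("oa", "G"),
                "eaf": float(r.get("eaf", 0.3)),
                "beta": float(r.get("beta", 0.1)),
                "se": float(r.get("se", 0.02)),
                "neg_log10_p": float(nlp),
                "chisq": float(chisq),
                "n": float(r.get("n", 10_000)),
            }
        )
    return SummaryStats(df=pd.DataFrame(records, columns=SUMSTATS_COLUMNS))


@pytest.fixture(scope="session")
def small_pair():
    """A modest simulated study pair with LD scores (shared, read-only)."""
    config = SynthConfig(m_variants=4_000, n_chromosomes=4, seed=42)
    earlier, later, truth = simulate_study_pair(config)
    scores = compute_ld_scores(truth.panel)
    return config, earlier, later, truth, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
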