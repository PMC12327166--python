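"""Reading, validating and writing GWAS summary statistics and LD scores.

A summary-statistics table has one row per variant with chromosome, 1-based
position (GRCh37 convention), variant id, effect/other allele, effect-allele
frequency, beta (log-odds scale), SE, and the association statistic stored
simultaneously as -log10(p) and chi^2 (1 df).  Keeping both lets every
downstream correction run on the chi^2 / log scale where p-values below the
double underflow limit (~1e-308) remain exact.

Variant identity is (chrom, pos, unordered allele pair): rsIDs differ across
releases and the unordered pair is what allele-swap harmonization preserves.
Duplicated identities and rows outside the valid domain are dropped, with the
drop reasons tallied on the returned object.

LD-score files follow the LDSC tabular convention (CHR, SNP, BP, L2),
optionally gzip-compressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .inflation import chisq_to_p, p_to_chisq

__all__ = [
    "VariantKey",
    "SummaryStats",
    "LDScores",
    "SUMSTATS_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "read_ldscores",
    "write_ldscores",
]

ALLOWED_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])
_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: Canonical column order of the in-memory table and the on-disk TSV.
SUMSTATS_COLUMNS = [
    "chrom", "pos", "id", "ea", "oa", "eaf", "beta", "se",
    "neg_log10_p", "chisq", "n",
]

_HEADER = {
    "chrom": "CHR", "pos": "POS", "id": "ID", "ea": "EA", "oa": "OA",
    "eaf": "EAF", "beta": "BETA", "se": "SE",
    "neg_log10_p": "NEG_LOG10_P", "chisq": "CHISQ", "n": "N",
}


class VariantKey(NamedTuple):
    """Identity of a biallelic variant: chromosome, position, allele pair."""

    chrom: str
    pos: int
    ea: str
    oa: str


@dataclass
class SummaryStats:
    """Validated per-variant association table for one study.

    ``df`` holds the canonical columns (:data:`SUMSTATS_COLUMNS`);
    ``drop_tally`` records how many input rows each validation rule removed.
    """

    df: pd.DataFrame
    drop_tally: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def maf(self) -> pd.Series:
        """Minor allele frequency, min(eaf, 1 - eaf)."""
        eaf = self.df["eaf"]
        return np.minimum(eaf, 1.0 - eaf)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.chrom, int(r.pos), r.ea, r.oa)
            for r in self.df.itertuples(index=False)
        ]

    def replace(self, df: pd.DataFrame) -> "SummaryStats":
        """New SummaryStats with the same provenance but a different table."""
        return SummaryStats(df=df, drop_tally=dict(self.drop_tally))

    def significant(self, threshold: float = 5e-8) -> pd.Series:
        """Boolean mask of genome-wide significance at ``threshold``.

        Compared on the -log10 scale; boundary equality counts as significant
        (a tiny epsilon absorbs float noise in the threshold conversion).
        """
        nlp_thr = -np.log10(threshold)
        return self.df["neg_log10_p"] >= nlp_thr - 1e-9


@dataclass
class LDScores:
    """Per-variant LD scores in the LDSC layout (chrom, snp, bp, l2)."""

    df: pd.DataFrame
    drop_tally: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.df)


def _unordered_pair(ea: pd.Series, oa: pd.Series) -> pd.Series:
    lo = np.minimum(ea, oa)
    hi = np.maximum(ea, oa)
    return lo.astype(str) + "|" + hi.astype(str)


def normalize_chrom(c) -> str:
    s = str(c).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s in ("23", "x"):
        s = "X"
    return s


def validate_sumstats(df: pd.DataFrame) -> SummaryStats:
    """Validate a raw table into :class:`SummaryStats`, dropping bad rows.

    Drop rules (each tallied separately): chromosome outside 1-22/X;
    position < 1; non-ACGT or identical alleles; EAF outside (0, 1);
    SE <= 0 or non-finite beta; p outside (0, 1] (p = 0 cannot be placed on
    the -log10 scale); duplicate (chrom, pos, unordered alleles) beyond the
    first occurrence.  Validation is idempotent: re-validating drops nothing.
    """
    tally: dict[str, int] = {}
    df = df.copy()

    def drop(mask: np.ndarray, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            tally[reason] = tally.get(reason, 0) + n
            df = df.loc[~mask]

    df["chrom"] = df["chrom"].map(normalize_chrom)
    drop(~df["chrom"].isin(ALLOWED_CHROMS).to_numpy(), "bad_chrom")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    drop((~np.isfinite(df["pos"])) | (df["pos"] < 1), "bad_pos")
    df["pos"] = df["pos"].astype(np.int64)

    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    ok = df["ea"].str.match(_ALLELE_RE) & df["oa"].str.match(_ALLELE_RE)
    drop((~ok | (df["ea"] == df["oa"])).to_numpy(), "bad_alleles")

    for col in ("eaf", "beta", "se"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    drop((~np.isfinite(df["eaf"]) | (df["eaf"] <= 0) | (df["eaf"] >= 1)).to_numpy(), "bad_eaf")
    drop((~np.isfinite(df["beta"]) | ~np.isfinite(df["se"]) | (df["se"] <= 0)).to_numpy(), "bad_beta_se")

    # Association statistic: accept neg_log10_p, p, or chisq; keep the pair
    # (neg_log10_p, chisq) mutually consistent.
    if "neg_log10_p" in df.columns:
        df["neg_log10_p"] = pd.to_numeric(df["neg_log10_p"], errors="coerce")
    elif "p" in df.columns:
        p = pd.to_numeric(df["p"], errors="coerce")
        bad = (~np.isfinite(p)) | (p <= 0) | (p > 1)
        drop(bad.to_numpy(), "bad_p")
        p = pd.to_numeric(df["p"], errors="coerce")
        df["neg_log10_p"] = -np.log10(p)
    elif "chisq" in df.columns:
        df["chisq"] = pd.to_numeric(df["chisq"], errors="coerce")
        drop((~np.isfinite(df["chisq"]) | (df["chisq"] < 0)).to_numpy(), "bad_chisq")
        df["neg_log10_p"] = chisq_to_p(df["chisq"].to_numpy())
    else:
        raise ValueError("missing mandatory association column: P, NEG_LOG10_P or CHISQ")
    drop((~np.isfinite(df["neg_log10_p"]) | (df["neg_log10_p"] < 0)).to_numpy(), "bad_p")

    if "chisq" in df.columns:
        df["chisq"] = pd.to_numeric(df["chisq"], errors="coerce")
        nlp_from_chisq = chisq_to_p(np.clip(df["chisq"].to_numpy(), 0, None))
        inconsistent = ~np.isclose(
            nlp_from_chisq, df["neg_log10_p"].to_numpy(), rtol=1e-6, atol=1e-9
        ) | ~np.isfinite(df["chisq"]) | (df["chisq"] < 0)
        if inconsistent.any():
            df.loc[inconsistent, "chisq"] = p_to_chisq(
                df.loc[inconsistent, "neg_log10_p"].to_numpy()
            )
    else:
        df["chisq"] = p_to_chisq(df["neg_log10_p"].to_numpy())

    if "n" in df.columns:
        df["n"] = pd.to_numeric(df["n"], errors="coerce").astype(float)
    else:
        df["n"] = np.nan

    if "id" not in df.columns:
        df["id"] = (
            df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["ea"] + ":" + df["oa"]
        )
    df["id"] = df["id"].astype(str)

    pair = pd.Series(_unordered_pair(df["ea"], df["oa"]).to_numpy(), index=df.index)
    key = df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + pair
    drop(key.duplicated(keep="first").to_numpy(), "duplicate_key")

    df = df[SUMSTATS_COLUMNS].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no variants left after validation")
    return SummaryStats(df=df, drop_tally=tally)


DEFAULT_COLUMN_MAP = {
    "chrom": "CHR", "pos": "POS", "id": "ID", "ea": "EA", "oa": "OA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "p": "P",
    "neg_log10_p": "NEG_LOG10_P", "chisq": "CHISQ", "n": "N",
}

_MANDATORY = ("chrom", "pos", "ea", "oa", "eaf", "beta", "se")


def read_sumstats(path, column_map: Optional[Mapping[str, str]] = None) -> SummaryStats:
    """Read a delimited summary-statistics table into :class:`SummaryStats`.

    ``column_map`` maps logical names (chrom, pos, id, ea, oa, eaf, beta, se,
    p | neg_log10_p | chisq, n) to the file's actual headers; unmapped logical
    names fall back to the canonical headers (CHR, POS, ...).  The dialect is
    tab- or whitespace-delimited, auto-detected from the header line.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = _read_table(path)
    missing = [cmap[k] for k in _MANDATORY if cmap[k] not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    if not any(cmap[k] in raw.columns for k in ("p", "neg_log10_p", "chisq")):
        raise ValueError(
            f"missing mandatory association column: one of "
            f"{cmap['p']}, {cmap['neg_log10_p']}, {cmap['chisq']}"
        )
    rename = {v: k for k, v in cmap.items() if v in raw.columns}
    return validate_sumstats(raw.rename(columns=rename)[list(rename.values())])


def _read_table(path) -> pd.DataFrame:
    with pd.io.common.get_handle(str(path), "r", compression="infer") as handle:
        header = handle.handle.readline()
    sep = "\t" if "\t" in header else r"\s+"
    return pd.read_csv(path, sep=sep, dtype={"CHR": str})


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write a canonical tab-delimited summary-statistics file.

    Floats are written with 17 significant digits so that
    ``read_sumstats(write_sumstats(x))`` round-trips every field exactly,
    including -log10(p) values far beyond 308 (sub-double p).
    """
    out = stats.df.rename(columns=_HEADER)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ldscores(path) -> LDScores:
    """Read an LDSC-layout LD-score table (CHR, SNP, BP, L2).

    Rows with negative L2 and duplicate SNP ids (beyond the first) are
    dropped with a tally.
    """
    df = _read_table(path)
    if "L2" not in df.columns:
        raise ValueError("missing mandatory column: L2")
    df = df.rename(columns={"CHR": "chrom", "SNP": "snp", "BP": "bp", "L2": "l2"})
    tally: dict[str, int] = {}
    df["l2"] = pd.to_numeric(df["l2"], errors="coerce")
    bad = (~np.isfinite(df["l2"]) | (df["l2"] < 0)).to_numpy()
    if bad.any():
        tally["bad_l2"] = int(bad.sum())
        df = df.loc[~bad]
    dup = df["snp"].duplicated(keep="first").to_numpy()
    if dup.any():
        tally["duplicate_snp"] = int(dup.sum())
        df = df.loc[~dup]
    keep = [c for c in ("chrom", "snp", "bp", "l2") if c in df.columns]
    return LDScores(df=df[keep].reset_index(drop=True), drop_tally=tally)


def write_ldscores(scores: LDScores, path) -> None:
    out = scores.df.rename(columns={"chrom": "CHR", "snp": "SNP", "bp": "BP", "l2": "L2"})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
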