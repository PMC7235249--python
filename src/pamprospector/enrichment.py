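"""Reporter-sort enrichment analysis of a randomized PAM library.

In a PAM-binding reporter screen (PAM-SCANR-style), cells carrying functional
PAMs turn on GFP and are collected by sorting. Sanger traces over the
randomized PAM region are summarized as per-position base fractions, before
and after sorting; bases enriched in the sorted population mark the
recognized PAM. Traces enter as base-fraction tables — peak quantification
is upstream of this package.

Positions are 1-based in tables and files to match how PAM positions are
spoken of at the bench.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .iupac import DNA_BASES, iupac_for

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_CALL_THRESHOLD = 1.0  # log2 units = 2-fold


@dataclass
class TraceProfile:
    """Per-position base fractions over the randomized PAM region.

    ``fractions``: positions (1-based index) x A/C/G/T; rows sum to 1.
    """

    fractions: pd.DataFrame

    def __post_init__(self):
        f = self.fractions
        if list(f.columns) != list(DNA_BASES):
            raise InputError(f"columns must be {DNA_BASES}, got {list(f.columns)}")
        arr = f.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 1 + 1e-9).any():
            raise InputError("fractions must lie in [0, 1]")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = f.index[np.abs(sums - 1.0) > 1e-6].tolist()
            raise InputError(f"fractions do not sum to 1 at positions {bad}")

    @property
    def region_length(self) -> int:
        return len(self.fractions)


@dataclass
class EnrichmentResult:
    """Log2 post/pre ratios per position and base, with the pseudocount used."""

    log2_ratio: pd.DataFrame
    pseudocount: float


def normalize_trace(raw: pd.DataFrame) -> TraceProfile:
    """Row-normalize nonnegative peak heights into base fractions.

    Raises InputError naming the first all-zero position.
    """
    raw = raw[list(DNA_BASES)]
    arr = raw.to_numpy(dtype=float)
    if (arr < 0).any():
        raise InputError("peak heights must be nonnegative")
    totals = arr.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise InputError(f"position {raw.index[zero[0]]} has zero total height")
    return TraceProfile(fractions=raw.div(raw.sum(axis=1), axis=0))


def compute_enrichment(pre: TraceProfile, post: TraceProfile,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> EnrichmentResult:
    """log2((post + eps) / (pre + eps)) per position and base.

    The pseudocount is applied to both proportions, so identical profiles
    give exactly zero everywhere and missing bases stay finite.
    """
    if pre.region_length != post.region_length:
        raise InputError(
            f"region lengths differ: pre {pre.region_length}, post {post.region_length}")
    p = pre.fractions.to_numpy(dtype=float)
    q = post.fractions.to_numpy(dtype=float)
    ratio = np.log2((q + pseudocount) / (p + pseudocount))
    return EnrichmentResult(
        log2_ratio=pd.DataFrame(ratio, index=pre.fractions.index,
                                columns=list(DNA_BASES)),
        pseudocount=pseudocount)


def call_pam_preference(e: EnrichmentResult,
                        call_threshold: float = DEFAULT_CALL_THRESHOLD) -> str:
    """Per-position preference string: the IUPAC code of all bases enriched by
    at least ``call_threshold`` log2 units; N where no base clears it."""
    letters = []
    for _, row in e.log2_ratio.iterrows():
        enriched = {b for b in DNA_BASES if row[b] >= call_threshold}
        letters.append(iupac_for(enriched) if enriched else "N")
    return "".join(letters)


def read_trace_tsv(path: str | Path) -> TraceProfile:
    """Read a trace table (columns: position, A, C, G, T; fractions or raw
    heights — raw heights are normalized)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"position", *DNA_BASES} - set(df.columns)
    if missing:
        raise InputError(f"trace TSV missing columns: {sorted(missing)}")
    df = df.set_index("position")
    return normalize_trace(df)


def write_trace_tsv(profile: TraceProfile, path: str | Path) -> None:
    out = profile.fractions.copy()
    out.insert(0, "position", out.index)
    out.to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(e: EnrichmentResult, path: str | Path) -> None:
    out = e.log2_ratio.copy()
    out.insert(0, "position", out.index)
    out.to_csv(path, sep="\t", index=False)
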