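"""Genome PAM-landscape statistics.

Enumerates PAM sites (any IUPAC motif, both strands) with their candidate
protospacers, and computes dinucleotide abundances and PAM density — the
fraction of motif-length windows matching the motif on either strand. An
adenine-dinucleotide PAM is attractive precisely because AA/TT windows are
the most abundant dinucleotide class in AT-rich genomes; these statistics
quantify that targetable space.

Density convention: the denominator is the number of motif-length windows
(L - |motif| + 1 per record, no bridging across records); windows containing
N are excluded from numerator and denominator. A window counts as a match if
it matches the motif on the forward strand or its reverse complement does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .iupac import DNA_BASES, bases_for, reverse_complement, validate_motif
from .records import DnaRecord

DEFAULT_SPACER_LEN = 20


@dataclass(frozen=True)
class PamSite:
    """A motif occurrence with its candidate protospacer.

    ``pam_start`` is 0-based on the forward strand; the protospacer lies 5'
    of the PAM on the PAM's strand (type II-A geometry), so on the minus
    strand its forward-strand interval sits 3' of the motif window.
    """

    genome_id: str
    pam_start: int
    strand: str
    pam_sequence: str
    protospacer_start: int
    protospacer_end: int


@dataclass
class ScanResult:
    """PAM sites plus the count of motif matches whose protospacer fell
    outside the sequence bounds."""

    sites: list[PamSite]
    n_excluded: int


@dataclass
class DinucStats:
    """Overlapping dinucleotide counts and frequencies (N windows excluded)."""

    counts: dict[str, int]
    frequencies: dict[str, float]
    total_windows: int


@dataclass
class PamDensity:
    """Fraction of motif-length windows matching a motif (strand union)."""

    motif: str
    window_count: int
    match_count: int
    density: float
    both_strands: bool


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_windows(arr: np.ndarray, motif: str) -> np.ndarray:
    """Boolean array over all motif-length windows: forward-strand match."""
    m = len(motif)
    n_win = len(arr) - m + 1
    ok = np.ones(n_win, dtype=bool)
    for j, code in enumerate(motif):
        table = np.zeros(256, dtype=bool)
        for b in bases_for(code):
            table[ord(b)] = True
        ok &= table[arr[j:j + n_win]]
    return ok


def _n_windows(arr: np.ndarray, m: int) -> np.ndarray:
    """Boolean array: window contains at least one N."""
    is_n = arr == ord("N")
    n_win = len(arr) - m + 1
    has_n = np.zeros(n_win, dtype=bool)
    for j in range(m):
        has_n |= is_n[j:j + n_win]
    return has_n


def scan_pam_sites(seq: DnaRecord, motif: str,
                   spacer_len: int = DEFAULT_SPACER_LEN,
                   both_strands: bool = True) -> ScanResult:
    """Enumerate motif matches and their protospacers on one or both strands.

    Matches whose ``spacer_len``-nt protospacer would run outside the
    sequence are excluded from ``sites`` and counted in ``n_excluded``.
    N-containing windows never match.
    """
    motif = validate_motif(motif)
    m = len(motif)
    if len(seq) < m:
        raise InputError(f"sequence {seq.id!r} shorter than motif")
    arr = _encode(seq.sequence)
    fwd = _match_windows(arr, motif)
    sites: list[PamSite] = []
    excluded = 0

    for start in np.nonzero(fwd)[0]:
        start = int(start)
        ps_start, ps_end = start - spacer_len, start
        if ps_start < 0:
            excluded += 1
            continue
        sites.append(PamSite(
            genome_id=seq.id, pam_start=start, strand="+",
            pam_sequence=seq.sequence[start:start + m],
            protospacer_start=ps_start, protospacer_end=ps_end))

    if both_strands:
        rev = _match_windows(arr, validate_motif(reverse_complement(motif)))
        for start in np.nonzero(rev)[0]:
            start = int(start)
            ps_start, ps_end = start + m, start + m + spacer_len
            if ps_end > len(seq):
                excluded += 1
                continue
            sites.append(PamSite(
                genome_id=seq.id, pam_start=start, strand="-",
                pam_sequence=reverse_complement(seq.sequence[start:start + m]),
                protospacer_start=ps_start, protospacer_end=ps_end))
    sites.sort(key=lambda s: (s.pam_start, s.strand))
    return ScanResult(sites=sites, n_excluded=excluded)


def dinucleotide_frequencies(seq: DnaRecord) -> DinucStats:
    """Overlapping dinucleotide counts at step 1; windows containing N are
    excluded from both numerator and denominator."""
    if len(seq) < 2:
        raise InputError(f"sequence {seq.id!r} shorter than 2 nt")
    arr = _encode(seq.sequence)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(DNA_BASES):
        code[ord(b)] = i
    c1, c2 = code[arr[:-1]], code[arr[1:]]
    valid = (c1 >= 0) & (c2 >= 0)
    idx = c1[valid] * 4 + c2[valid]
    tallies = np.bincount(idx, minlength=16)
    total = int(valid.sum())
    counts = {a + b: int(tallies[i * 4 + j])
              for i, a in enumerate(DNA_BASES) for j, b in enumerate(DNA_BASES)}
    freqs = {d: (c / total if total else 0.0) for d, c in counts.items()}
    return DinucStats(counts=counts, frequencies=freqs, total_windows=total)


def pam_density(seqs: DnaRecord | Sequence[DnaRecord], motif: str,
                both_strands: bool = True) -> PamDensity:
    """Fraction of valid motif-length windows matching the motif.

    With ``both_strands`` a window matches if the forward window matches the
    motif or its reverse complement does (strand union, indexed by
    forward-strand start). Multi-record input aggregates counts across
    records without bridging windows between them.
    """
    motif = validate_motif(motif)
    if isinstance(seqs, DnaRecord):
        seqs = [seqs]
    m = len(motif)
    window_count = match_count = 0
    rc_motif = validate_motif(reverse_complement(motif))
    for seq in seqs:
        if len(seq) < m:
            continue
        arr = _encode(seq.sequence)
        valid = ~_n_windows(arr, m)
        hit = _match_windows(arr, motif)
        if both_strands:
            hit |= _match_windows(arr, rc_motif)
        window_count += int(valid.sum())
        match_count += int((hit & valid).sum())
    density = match_count / window_count if window_count else 0.0
    return PamDensity(motif=motif, window_count=window_count,
                      match_count=match_count, density=density,
                      both_strands=both_strands)


def write_sites_bed(result: ScanResult, path, motif_len: int | None = None) -> None:
    """BED-like TSV: chrom, start, end, name=pam_sequence, score=0, strand.

    Intervals cover the PAM window itself on forward coordinates.
    """
    rows = [{
        "chrom": s.genome_id, "start": s.pam_start,
        "end": s.pam_start + len(s.pam_sequence),
        "name": s.pam_sequence, "score": 0, "strand": s.strand,
    } for s in result.sites]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                "strand"]).to_csv(path, sep="\t", index=False,
                                                  header=False)
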