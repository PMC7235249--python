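"""PAM inference from CRISPR spacer-to-phage mapping.

Spacers from CRISPR arrays are matched against phage genomes by exact
sliding-window Hamming comparison on both strands (no indels). The flank
immediately 3' of each protospacer on the spacer-matching strand — the
candidate PAM — is collected into a position frequency matrix, from which
per-position information content and an IUPAC consensus are derived. This is
how a nuclease's natural PAM preference is read off the phages its host has
defended against.

Coordinates are 0-based half-open on the forward strand; minus-strand hits
still report forward coordinates (BED-like convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, InputError
from .iupac import DNA_BASES, bases_for, iupac_for, reverse_complement
from .records import DnaRecord, SpacerRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProtospacerHit:
    """A spacer match on a genome; forward-strand coordinates regardless of strand."""

    spacer_id: str
    genome_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mismatches: int
    pam_flank: str | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise InputError(f"bad coordinates [{self.start}, {self.end})")


@dataclass
class PamMatrix:
    """Position frequency matrix over A/C/G/T.

    ``counts`` is positions x bases; rows sum to ``n_observations``. Counts
    are integers unless multi-hit down-weighting produced fractional weights.
    """

    counts: pd.DataFrame
    n_observations: float

    @property
    def length(self) -> int:
        return len(self.counts)

    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)


@dataclass
class ConsensusCall:
    """IUPAC consensus string with per-position information content (bits)."""

    iupac: str
    ic_bits: np.ndarray
    low_confidence: bool = False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_protospacers(spacer: SpacerRecord, genome: DnaRecord,
                      max_mismatches: int = 2) -> list[ProtospacerHit]:
    """All positions on either strand where the spacer matches within the
    mismatch budget (Hamming distance; no indels).

    Genome N bases never match. Hits are sorted by (start, strand).
    """
    if max_mismatches >= len(spacer) / 2:
        raise ConfigError(
            f"max_mismatches={max_mismatches} is too permissive for a "
            f"{len(spacer)}-nt spacer (must be < length/2)")
    if len(spacer) > len(genome):
        raise InputError(
            f"spacer {spacer.id!r} ({len(spacer)} nt) longer than genome "
            f"{genome.id!r} ({len(genome)} nt)")

    garr = _encode(genome.sequence)
    windows = sliding_window_view(garr, len(spacer))
    hits: list[ProtospacerHit] = []
    for strand, query in (("+", spacer.sequence),
                          ("-", reverse_complement(spacer.sequence))):
        qarr = _encode(query)
        mism = (windows != qarr).sum(axis=1)
        for start in np.nonzero(mism <= max_mismatches)[0]:
            hits.append(ProtospacerHit(
                spacer_id=spacer.id, genome_id=genome.id,
                start=int(start), end=int(start) + len(spacer),
                strand=strand, mismatches=int(mism[start])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def extract_pam_flank(hit: ProtospacerHit, genome: DnaRecord,
                      flank_len: int = 8) -> str | None:
    """Sequence immediately 3' of the protospacer on the spacer-matching strand.

    Plus strand: ``genome[end:end+flank_len]``. Minus strand: reverse
    complement of ``genome[start-flank_len:start]``. Returns None (and logs)
    when the flank would run past the genome boundary.
    """
    if hit.end > len(genome):
        raise InputError(f"hit [{hit.start},{hit.end}) outside genome "
                         f"{genome.id!r} (len {len(genome)})")
    if hit.strand == "+":
        if hit.end + flank_len > len(genome):
            logger.info("flank past genome end for %s at %d; hit excluded",
                        hit.spacer_id, hit.start)
            return None
        return genome.sequence[hit.end:hit.end + flank_len]
    if hit.start - flank_len < 0:
        logger.info("flank past genome start for %s at %d; hit excluded",
                    hit.spacer_id, hit.start)
        return None
    return reverse_complement(genome.sequence[hit.start - flank_len:hit.start])


def build_pam_matrix(flanks: Sequence[str],
                     weights: Sequence[float] | None = None) -> PamMatrix:
    """Tally equal-length flank strings into a position frequency matrix.

    Optional per-flank weights (used to down-weight multi-mapping spacers)
    make the counts fractional; rows still sum to the total weight.
    """
    if not flanks:
        raise InputError("no flanks to tally")
    length = len(flanks[0])
    if any(len(f) != length for f in flanks):
        raise InputError("flanks have ragged lengths")
    if weights is None:
        weights = [1.0] * len(flanks)
    elif len(weights) != len(flanks):
        raise InputError("weights and flanks differ in length")

    counts = pd.DataFrame(0.0, index=range(length), columns=list(DNA_BASES))
    for flank, w in zip(flanks, weights):
        for j, base in enumerate(flank):
            if base in DNA_BASES:
                counts.loc[j, base] += w
    total = float(sum(weights))
    if np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
        counts = counts.round().astype(int)
    return PamMatrix(counts=counts, n_observations=total)


def information_content(m: PamMatrix) -> np.ndarray:
    """Per-position information content ``2 - H_j`` bits against a uniform
    DNA background; no small-sample correction."""
    if m.n_observations <= 0:
        raise InputError("matrix has zero observations")
    freqs = m.frequencies().to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logs).sum(axis=1)
    return 2.0 - entropy


def call_consensus(m: PamMatrix, include_threshold: float = 0.25,
                   min_observations: int = 10,
                   ic_floor: float = 0.2) -> ConsensusCall:
    """IUPAC consensus: per position, the code covering every base whose
    frequency is at least ``include_threshold`` times the top base's
    frequency; positions with information content below ``ic_floor`` bits
    are forced to N.

    Below ``min_observations`` flanks the call is still emitted but flagged
    low-confidence (and a warning is logged).
    """
    ic = information_content(m)
    freqs = m.frequencies()
    letters = []
    for j in range(m.length):
        if ic[j] < ic_floor:
            letters.append("N")
            continue
        row = freqs.iloc[j]
        cutoff = include_threshold * row.max()
        included = {b for b in DNA_BASES if row[b] >= cutoff and row[b] > 0}
        letters.append(iupac_for(included) if included else "N")
    low = m.n_observations < min_observations
    if low:
        logger.warning("consensus from only %.0f observations (< %d); "
                       "low confidence", m.n_observations, min_observations)
    return ConsensusCall(iupac="".join(letters), ic_bits=ic, low_confidence=low)


@dataclass
class PamInferenceResult:
    """End-to-end product of the spacer-to-phage PAM inference stage."""

    hits: list[ProtospacerHit]
    flanks: list[str]
    matrix: PamMatrix
    consensus: ConsensusCall


def infer_pam(spacers: Iterable[SpacerRecord], genomes: Sequence[DnaRecord],
              max_mismatches: int = 2, flank_len: int = 8,
              weight_multi_hits: bool = False,
              include_threshold: float = 0.25,
              min_observations: int = 10) -> PamInferenceResult:
    """Map every spacer to every genome, collect PAM-side flanks, and call
    the consensus motif.

    With ``weight_multi_hits`` each spacer's flanks are weighted by the
    reciprocal of its number of flank-bearing hits, so repetitive phage
    regions cannot dominate the logo.
    """
    all_hits: list[ProtospacerHit] = []
    flanks: list[str] = []
    weights: list[float] = []
    for spacer in spacers:
        spacer_flanked: list[tuple[ProtospacerHit, str]] = []
        for genome in genomes:
            for hit in find_protospacers(spacer, genome, max_mismatches):
                flank = extract_pam_flank(hit, genome, flank_len)
                hit = replace(hit, pam_flank=flank)
                all_hits.append(hit)
                if flank is not None:
                    spacer_flanked.append((hit, flank))
        w = 1.0 / len(spacer_flanked) if (weight_multi_hits and spacer_flanked) else 1.0
        for _, flank in spacer_flanked:
            flanks.append(flank)
            weights.append(w)
    if not flanks:
        raise InputError("no protospacer hits with complete flanks; "
                         "cannot infer a PAM")
    matrix = build_pam_matrix(flanks, weights if weight_multi_hits else None)
    consensus = call_consensus(matrix, include_threshold=include_threshold,
                               min_observations=min_observations)
    return PamInferenceResult(all_hits, flanks, matrix, consensus)


def write_hits_tsv(hits: Sequence[ProtospacerHit], path) -> None:
    pd.DataFrame([{
        "spacer_id": h.spacer_id, "genome_id": h.genome_id,
        "start": h.start, "end": h.end, "strand": h.strand,
        "mismatches": h.mismatches, "flank": h.pam_flank or "",
    } for h in hits]).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(m: PamMatrix, path) -> None:
    out = m.counts.copy()
    out.insert(0, "position", [i + 1 for i in range(m.length)])
    out.to_csv(path, sep="\t", index=False)
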