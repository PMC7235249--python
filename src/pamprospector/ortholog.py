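"""Ortholog mining for PAM-specificity divergence.

A reference nuclease (e.g. SpyCas9) is globally aligned to a set of ortholog
protein sequences under a substitution matrix with affine gap costs. Orthologs
scoring below a percent-of-self-score threshold are discarded; positions
aligned to the reference's PAM-contacting residues (R1333/R1335 in SpyCas9
numbering) are read out across the family to spot candidates whose contacts
have diverged — the signature by which an adenine-preferring Cas9 is found
among guanine-preferring relatives. The module also records hybrid designs
(scaffold + PAM-interacting-domain donor, plus point mutations) such as the
SpyMac/iSpyMac series.

Conventions
-----------
* Residue positions are 1-based, matching the field's R1333/R1335 naming.
* A gap of length L costs ``gap_open + L * gap_extend`` (EMBOSS needle
  convention); terminal gaps are penalized like internal ones.
* Percent score is ``100 * score(ref, query) / score(ref, ref)``, clamped
  below at zero, so self-alignment is exactly 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigError, InputError, ValidationError
from .records import AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)

GAP = None  # marker for reference positions deleted in the query

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise protein alignment with affine-gap scoring."""

    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    raw_score: float
    percent_score: float

    def __post_init__(self):
        if len(self.aligned_ref) != len(self.aligned_query):
            raise InputError("aligned strings differ in length")

    @property
    def columns(self):
        return zip(self.aligned_ref, self.aligned_query)


@dataclass
class DivergenceProfile:
    """Residues, counts and information content over a window of reference positions."""

    window_positions: list[int]
    residue_table: pd.DataFrame        # rows: ortholog ids, cols: ref positions
    frequency_table: pd.DataFrame      # rows: ref positions, cols: residues
    information_content: pd.Series     # bits per position, in [0, log2 20]


@dataclass(frozen=True)
class HybridDesign:
    """A scaffold/donor chimera with verified point mutations."""

    name: str
    scaffold_id: str
    pid_donor_id: str
    junction_ref_pos: int
    point_mutations: tuple[tuple[str, int, str], ...]
    product_sequence: str

    def to_record(self) -> ProteinRecord:
        muts = ",".join(f"{e}{p}{n}" for e, p, n in self.point_mutations)
        desc = (f"scaffold={self.scaffold_id} donor={self.pid_donor_id} "
                f"junction={self.junction_ref_pos}" + (f" mutations={muts}" if muts else ""))
        return ProteinRecord(id=self.name, sequence=self.product_sequence,
                             description=desc)


def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except Exception as exc:
        raise ConfigError(f"unknown substitution matrix {name!r}") from exc


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(matrix)
    # engine charges "open" on the first gapped column, "extend" on the rest;
    # shift so that a length-L gap costs open + L*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def self_score(record: ProteinRecord, matrix: str = DEFAULT_MATRIX) -> float:
    """Score of aligning a sequence to itself (sum of diagonal substitution scores)."""
    m = _load_matrix(matrix)
    return float(sum(m[aa, aa] for aa in record.sequence))


def global_align(ref: ProteinRecord, query: ProteinRecord,
                 matrix: str = DEFAULT_MATRIX,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``ref``.

    Affine gap costs (a length-L gap costs ``gap_open + L * gap_extend``);
    the reported alignment is the engine's first traceback, which is
    deterministic for fixed inputs. ``percent_score`` normalizes the raw
    score by the reference self-score and clamps at zero.
    """
    if not ref.sequence or not query.sequence:
        raise InputError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(ref.sequence, query.sequence)
    best = alignments[0]
    raw = float(best.score)
    pct = percent_blosum_score(raw, self_score(ref, matrix))
    return PairwiseAlignment(
        ref_id=ref.id, query_id=query.id,
        aligned_ref=str(best[0]), aligned_query=str(best[1]),
        raw_score=raw, percent_score=pct,
    )


def percent_blosum_score(raw_score: float, ref_self_score: float) -> float:
    """100 * raw / self, clamped below at 0 (self-alignment scores exactly 100)."""
    if ref_self_score <= 0:
        raise InputError(f"reference self-score must be positive, got {ref_self_score}")
    return max(0.0, 100.0 * raw_score / ref_self_score)


@dataclass
class OrthologFilterResult:
    """Partition of an ortholog set by percent score against the reference."""

    kept: list[ProteinRecord]
    discarded: list[ProteinRecord]
    scores: dict[str, float]  # record id -> percent score
    threshold: float


def filter_orthologs(records: Sequence[ProteinRecord], reference: ProteinRecord,
                     threshold: float = 70.0,
                     matrix: str = DEFAULT_MATRIX,
                     gap_open: float = DEFAULT_GAP_OPEN,
                     gap_extend: float = DEFAULT_GAP_EXTEND) -> OrthologFilterResult:
    """Keep orthologs whose percent score against the reference is >= threshold.

    The boundary is inclusive; input order is preserved in both partitions.
    """
    if not records:
        logger.warning("filter_orthologs called with an empty record list")
        return OrthologFilterResult([], [], {}, threshold)
    kept, discarded, scores = [], [], {}
    for rec in records:
        aln = global_align(reference, rec, matrix, gap_open, gap_extend)
        scores[rec.id] = aln.percent_score
        (kept if aln.percent_score >= threshold else discarded).append(rec)
    return OrthologFilterResult(kept, discarded, scores, threshold)


def residue_map(aln: PairwiseAlignment) -> dict[int, int | None]:
    """Map every 1-based reference position to its query position (or GAP).

    Strictly increasing over mapped positions; the domain covers all
    reference positions present in the alignment.
    """
    mapping: dict[int, int | None] = {}
    rpos = qpos = 0
    for rchar, qchar in aln.columns:
        if rchar != "-":
            rpos += 1
        if qchar != "-":
            qpos += 1
        if rchar != "-":
            mapping[rpos] = qpos if qchar != "-" else GAP
    return mapping


def map_reference_positions(aln: PairwiseAlignment,
                            positions: Sequence[int]) -> list[tuple[int | None, str | None]]:
    """Transfer reference positions through the alignment.

    Returns, per position, the 1-based query position and the query residue
    there, or ``(None, None)`` where the query carries a deletion.
    """
    mapping = residue_map(aln)
    ref_len = max(mapping) if mapping else 0
    out = []
    query = aln.aligned_query.replace("-", "")
    for pos in positions:
        if not 1 <= pos <= ref_len:
            raise InputError(f"reference position {pos} out of range 1..{ref_len}")
        q = mapping[pos]
        out.append((q, query[q - 1]) if q is not GAP else (None, None))
    return out


def _window_around(center_positions: Sequence[int], window: int,
                   ref_len: int) -> list[int]:
    """A single odd-length window of reference positions spanning all centers."""
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 1, got {window}")
    lo, hi = min(center_positions), max(center_positions)
    if hi - lo + 1 > window:
        raise ConfigError(
            f"centers {center_positions} span more than the {window}-position window")
    mid = (lo + hi) // 2
    start = mid - window // 2
    start = max(1, min(start, ref_len - window + 1))
    return list(range(start, start + window))


def build_residue_logo(records: Sequence[ProteinRecord], reference: ProteinRecord,
                       center_positions: Sequence[int], window: int = 11,
                       matrix: str = DEFAULT_MATRIX,
                       gap_open: float = DEFAULT_GAP_OPEN,
                       gap_extend: float = DEFAULT_GAP_EXTEND) -> DivergenceProfile:
    """Residue conservation profile over a window around the contact positions.

    Each ortholog is aligned to the reference and its residues at the window's
    reference positions are collected. Gaps (and unknown X residues) are
    excluded from frequency denominators; the information content of column j
    is ``log2(20) - H_j`` with H_j the Shannon entropy of the residue
    distribution there. Columns covered by fewer than half the orthologs are
    flagged in the log.
    """
    for pos in center_positions:
        if not 1 <= pos <= len(reference):
            raise ConfigError(f"contact position {pos} outside reference (len "
                              f"{len(reference)})")
    positions = _window_around(center_positions, window, len(reference))
    aas = sorted(AMINO_ACIDS)
    rows = {}
    for rec in records:
        aln = global_align(reference, rec, matrix, gap_open, gap_extend)
        mapped = map_reference_positions(aln, positions)
        rows[rec.id] = [res if res is not None else "-" for _, res in mapped]
    residue_table = pd.DataFrame.from_dict(rows, orient="index", columns=positions)

    counts = pd.DataFrame(0, index=positions, columns=aas, dtype=int)
    for pos in positions:
        col = residue_table[pos]
        vc = col[col.isin(aas)].value_counts()
        counts.loc[pos, vc.index] = vc.values
        coverage = vc.sum() / len(records) if records else 0.0
        if coverage < 0.5:
            logger.warning("logo column %d covered by only %.0f%% of orthologs",
                           pos, 100 * coverage)

    n = counts.sum(axis=1)
    ic = pd.Series(0.0, index=positions)
    for pos in positions:
        if n[pos] == 0:
            continue
        p = counts.loc[pos] / n[pos]
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        ic[pos] = np.log2(20) - entropy
    return DivergenceProfile(positions, residue_table, counts, ic)


def design_hybrid(scaffold: ProteinRecord, donor: ProteinRecord,
                  junction_ref_pos: int,
                  mutations: Sequence[tuple[str, int, str]] = (),
                  name: str = "hybrid",
                  matrix: str = DEFAULT_MATRIX,
                  gap_open: float = DEFAULT_GAP_OPEN,
                  gap_extend: float = DEFAULT_GAP_EXTEND) -> HybridDesign:
    """Join a scaffold prefix to a donor tail and apply verified point mutations.

    The product keeps scaffold residues 1..junction and continues with the
    donor from the position its alignment places opposite scaffold position
    junction+1 (the classic PAM-interacting-domain graft). Each mutation
    ``(expected, pos, new)`` is applied at 1-based product position ``pos``
    only after checking the pre-mutation product carries ``expected`` there.
    """
    if not 1 <= junction_ref_pos <= len(scaffold):
        raise InputError(f"junction {junction_ref_pos} outside scaffold "
                         f"(len {len(scaffold)})")
    if junction_ref_pos == len(scaffold):
        product = scaffold.sequence
    else:
        aln = global_align(scaffold, donor, matrix, gap_open, gap_extend)
        mapping = residue_map(aln)
        q = mapping[junction_ref_pos + 1]
        if q is GAP:
            raise ValidationError(
                f"scaffold position {junction_ref_pos + 1} aligns to a donor gap; "
                "choose a different junction")
        product = scaffold.sequence[:junction_ref_pos] + donor.sequence[q - 1:]

    prod = list(product)
    for expected, pos, new in mutations:
        if not 1 <= pos <= len(prod):
            raise InputError(f"mutation position {pos} outside product (len {len(prod)})")
        if prod[pos - 1] != expected:
            raise ValidationError(
                f"expected {expected} at position {pos} but product has {prod[pos - 1]}")
        prod[pos - 1] = new
    return HybridDesign(
        name=name, scaffold_id=scaffold.id, pid_donor_id=donor.id,
        junction_ref_pos=junction_ref_pos,
        point_mutations=tuple((e, p, n) for e, p, n in mutations),
        product_sequence="".join(prod),
    )


def write_divergence_tsv(profile: DivergenceProfile, path) -> None:
    """Long-format TSV (ref_pos, residue, count, frequency, IC) for logo plotting."""
    rows = []
    for pos in profile.window_positions:
        total = profile.frequency_table.loc[pos].sum()
        for residue, count in profile.frequency_table.loc[pos].items():
            if count == 0:
                continue
            rows.append({
                "ref_pos": pos, "residue": residue, "count": int(count),
                "frequency": count / total if total else 0.0,
                "IC": profile.information_content[pos],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
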