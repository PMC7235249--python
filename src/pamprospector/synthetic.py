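"""Seeded synthetic data with known ground truth for every pipeline stage.

Each generator draws from its own ``numpy.random.default_rng(seed)`` stream
(no global state), returns in-memory objects in the same shapes the pipeline
consumes, and ships a :class:`TruthRecord` carrying the planted parameters —
enough to compute the expected downstream result without rerunning the
generator. Identical seed and parameters reproduce byte-identical output.

What is emulated, and what is not: ortholog families are i.i.d. point
substitutions on a reference (no phylogenetic correlation, no domain
structure); phage genomes are uniform-composition background with planted
protospacers (no genome grammar); sort traces are fraction tables with
multiplicative peak noise (no chromatogram artifacts); gel lanes carry
multiplicative densitometry noise (no image effects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cleavage import GelLane, TimeCourse
from .enrichment import TraceProfile
from .errors import ConfigError
from .iupac import DNA_BASES, bases_for, reverse_complement
from .records import DnaRecord, ProteinRecord, SpacerRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class TruthRecord:
    """Generator provenance: name, seed, and the planted parameters."""

    generator: str
    seed: int
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "seed": self.seed, "params": self.params},
            sort_keys=True, indent=2, default=str)


def random_protein(length: int, seed: int, id: str = "ref") -> ProteinRecord:
    """A uniformly random protein sequence over the 20 canonical residues."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AA20), size=length))
    return ProteinRecord(id=id, sequence=seq)


def random_dna(length: int, seed: int, id: str = "seq",
               gc_content: float = 0.5) -> DnaRecord:
    """Random DNA with a tunable GC fraction (AT split evenly, GC split evenly)."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    seq = "".join(rng.choice(list(DNA_BASES), size=length, p=p))
    return DnaRecord(id=id, sequence=seq)


def gen_ortholog_family(reference: ProteinRecord, n: int, divergence: float,
                        contact_positions: Sequence[int] = (),
                        planted_residues: Mapping[int, str] | None = None,
                        seed: int = 0,
                        indel_rate: float = 0.0) -> tuple[list[ProteinRecord], TruthRecord]:
    """Mutated copies of a reference protein with optionally planted contact residues.

    Every site substitutes to a uniformly chosen different residue with
    probability ``divergence``; orthologs listed in ``planted_residues``
    (index -> one residue per contact position) then receive those residues
    at the contact positions. Deletions occur only if ``indel_rate`` > 0.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ConfigError(f"divergence must be in [0, 0.5], got {divergence}")
    for pos in contact_positions:
        if not 1 <= pos <= len(reference):
            raise ConfigError(f"contact position {pos} outside reference "
                              f"(len {len(reference)})")
    planted_residues = dict(planted_residues or {})
    for idx, residues in planted_residues.items():
        if len(residues) != len(contact_positions):
            raise ConfigError(
                f"ortholog {idx}: need {len(contact_positions)} planted residues, "
                f"got {len(residues)}")

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        seq = list(reference.sequence)
        for j in range(len(seq)):
            if rng.random() < divergence:
                choices = [a for a in _AA20 if a != seq[j]]
                seq[j] = choices[rng.integers(len(choices))]
        if i in planted_residues:
            for pos, res in zip(contact_positions, planted_residues[i]):
                seq[pos - 1] = res
        if indel_rate > 0:
            seq = [a for a in seq if rng.random() >= indel_rate]
        records.append(ProteinRecord(
            id=f"ortholog_{i:03d}", sequence="".join(seq),
            description=f"synthetic divergence={divergence}"))
    truth = TruthRecord("gen_ortholog_family", seed, {
        "reference_id": reference.id, "n": n, "divergence": divergence,
        "contact_positions": list(contact_positions),
        "planted_residues": {str(k): v for k, v in planted_residues.items()},
        "indel_rate": indel_rate,
    })
    return records, truth


def pam_profile_from_consensus(consensus: str, strength: float = 0.9,
                               length: int = 8) -> list[dict[str, float]]:
    """Per-position base distributions: concrete letters get ``strength``
    (remainder spread over the other bases); N positions are uniform.
    The profile is padded with uniform positions out to ``length``."""
    profile = []
    for code in consensus.upper():
        allowed = bases_for(code)
        if allowed == frozenset(DNA_BASES):
            profile.append({b: 0.25 for b in DNA_BASES})
        else:
            per = strength / len(allowed)
            rest = (1 - strength) / (4 - len(allowed))
            profile.append({b: (per if b in allowed else rest) for b in DNA_BASES})
    while len(profile) < length:
        profile.append({b: 0.25 for b in DNA_BASES})
    return profile


def gen_phage_cohort(n_genomes: int = 5, genome_len: int = 20_000,
                     n_protospacers: int = 40, spacer_len: int = 20,
                     pam_profile: Sequence[Mapping[str, float]] | None = None,
                     mismatch_rate: float = 0.0, seed: int = 0,
                     flank_len: int = 8,
                     ) -> tuple[list[DnaRecord], list[SpacerRecord], TruthRecord]:
    """Phage genomes with planted protospacers whose 3' flanks follow a PAM profile.

    Each protospacer is placed on a random genome and strand without overlap
    (including its flank); the emitted spacer copies the protospacer with
    per-base errors at ``mismatch_rate``. The default profile plants a
    NAAN-style motif (A at flank positions 2-3 at 90%).
    """
    if pam_profile is None:
        pam_profile = pam_profile_from_consensus("NAAN", 0.9, flank_len)
    if len(pam_profile) != flank_len:
        raise ConfigError(f"pam_profile must have {flank_len} positions")
    footprint = spacer_len + 2 * flank_len
    if n_protospacers * footprint > 0.5 * n_genomes * genome_len:
        raise ConfigError("planted protospacers would overcrowd the genomes")

    rng = np.random.default_rng(seed)
    genomes = [rng.choice(list(DNA_BASES), size=genome_len)
               for _ in range(n_genomes)]
    reserved: list[list[tuple[int, int]]] = [[] for _ in range(n_genomes)]
    spacers: list[SpacerRecord] = []
    plants = []

    for i in range(n_protospacers):
        for _attempt in range(1000):
            g = int(rng.integers(n_genomes))
            start = int(rng.integers(flank_len, genome_len - spacer_len - flank_len))
            end = start + spacer_len
            lo, hi = start - flank_len, end + flank_len
            if all(hi <= a or lo >= b for a, b in reserved[g]):
                break
        else:
            raise ConfigError("could not place protospacer without overlap")
        reserved[g].append((lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        proto = "".join(rng.choice(list(DNA_BASES), size=spacer_len))
        flank = "".join(
            rng.choice(list(DNA_BASES), p=[dist[b] for b in DNA_BASES])
            for dist in pam_profile)
        if strand == "+":
            genomes[g][start:end] = list(proto)
            genomes[g][end:end + flank_len] = list(flank)
        else:
            genomes[g][start:end] = list(reverse_complement(proto))
            genomes[g][start - flank_len:start] = list(reverse_complement(flank))
        spacer_seq = list(proto)
        n_err = 0
        for j in range(spacer_len):
            if rng.random() < mismatch_rate:
                others = [b for b in DNA_BASES if b != spacer_seq[j]]
                spacer_seq[j] = others[rng.integers(3)]
                n_err += 1
        sid = f"spacer_{i:03d}"
        spacers.append(SpacerRecord(id=sid, sequence="".join(spacer_seq),
                                    array_id="synthetic_array"))
        plants.append({"spacer_id": sid, "genome_id": f"phage_{g:02d}",
                       "start": start, "end": end, "strand": strand,
                       "flank": flank, "spacer_errors": n_err})

    genome_records = [DnaRecord(id=f"phage_{g:02d}", sequence="".join(genomes[g]),
                                description="synthetic phage genome")
                      for g in range(n_genomes)]
    truth = TruthRecord("gen_phage_cohort", seed, {
        "n_genomes": n_genomes, "genome_len": genome_len,
        "n_protospacers": n_protospacers, "spacer_len": spacer_len,
        "flank_len": flank_len, "mismatch_rate": mismatch_rate,
        "pam_profile": [dict(d) for d in pam_profile],
        "plants": plants,
    })
    return genome_records, spacers, truth


def _noisy_profile(fractions: np.ndarray, noise_sd: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Multiplicative peak noise (coefficient of variation ``noise_sd``),
    floored at zero, then renormalized per position."""
    noisy = fractions * (1.0 + rng.normal(0.0, noise_sd, fractions.shape))
    noisy = np.clip(noisy, 1e-9, None)
    noisy /= noisy.sum(axis=1, keepdims=True)
    return pd.DataFrame(noisy, index=range(1, len(noisy) + 1),
                        columns=list(DNA_BASES))


def gen_trace_pair(region_len: int = 8, true_calls: str = "NAANNNNN",
                   fold_enrichment: float = 4.0, noise_sd: float = 0.05,
                   seed: int = 0) -> tuple[TraceProfile, TraceProfile, TruthRecord]:
    """Pre/post-sort base-fraction traces with a planted PAM preference.

    The pre-sort library is uniform; in the post-sort profile the bases named
    by ``true_calls`` (IUPAC; N = no selection) are reweighted by
    ``fold_enrichment`` and renormalized. Both profiles then receive
    multiplicative peak noise with coefficient of variation ``noise_sd``.
    """
    if fold_enrichment <= 0:
        raise ConfigError(f"fold_enrichment must be positive, got {fold_enrichment}")
    if len(true_calls) != region_len:
        raise ConfigError(f"true_calls length {len(true_calls)} != region_len "
                          f"{region_len}")
    rng = np.random.default_rng(seed)
    pre = np.full((region_len, 4), 0.25)
    post = np.empty_like(pre)
    for j, code in enumerate(true_calls.upper()):
        allowed = bases_for(code)
        if allowed == frozenset(DNA_BASES):
            post[j] = 0.25
        else:
            w = np.array([fold_enrichment if b in allowed else 1.0
                          for b in DNA_BASES])
            post[j] = w / w.sum()
    pre_profile = TraceProfile(_noisy_profile(pre, noise_sd, rng))
    post_profile = TraceProfile(_noisy_profile(post, noise_sd, rng))
    truth = TruthRecord("gen_trace_pair", seed, {
        "region_len": region_len, "true_calls": true_calls.upper(),
        "fold_enrichment": fold_enrichment, "noise_sd": noise_sd,
    })
    return pre_profile, post_profile, truth


def gen_gel_data(true_fractions: Mapping[str, float],
                 total_intensity: float = 10_000.0, noise_cv: float = 0.0,
                 seed: int = 0) -> tuple[list[GelLane], TruthRecord]:
    """Gel lanes with known cleaved fractions.

    Substrate band = total * (1 - f), single product band = total * f; each
    band perturbed by multiplicative Gaussian noise with coefficient of
    variation ``noise_cv`` and floored at zero.
    """
    if noise_cv < 0:
        raise ConfigError(f"noise_cv must be nonnegative, got {noise_cv}")
    for lane_id, f in true_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ConfigError(f"lane {lane_id!r}: fraction {f} outside [0, 1]")
    rng = np.random.default_rng(seed)
    lanes = []
    for lane_id, f in true_fractions.items():
        substrate = total_intensity * (1.0 - f)
        product = total_intensity * f
        if noise_cv > 0:
            substrate = max(0.0, substrate * (1.0 + rng.normal(0.0, noise_cv)))
            product = max(0.0, product * (1.0 + rng.normal(0.0, noise_cv)))
        lanes.append(GelLane(lane_id=lane_id, substrate_intensity=substrate,
                             product_intensities=[product]))
    truth = TruthRecord("gen_gel_data", seed, {
        "true_fractions": dict(true_fractions),
        "total_intensity": total_intensity, "noise_cv": noise_cv,
    })
    return lanes, truth


def gen_timecourse(k: float, plateau: float, timepoints: Sequence[float],
                   noise_sd: float = 0.0, seed: int = 0,
                   ) -> tuple[TimeCourse, TruthRecord]:
    """A first-order digestion time course f(t) = plateau * (1 - exp(-k t))
    with additive Gaussian noise, clipped to [0, 1]."""
    if len(timepoints) == 0:
        raise ConfigError("timepoints must be non-empty")
    if k < 0:
        raise ConfigError(f"rate k must be nonnegative, got {k}")
    if not 0.0 <= plateau <= 1.0:
        raise ConfigError(f"plateau must be in [0, 1], got {plateau}")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    f = plateau * (1.0 - np.exp(-k * t))
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0.0, noise_sd, size=len(t)), 0.0, 1.0)
    tc = TimeCourse(points=list(zip(t.tolist(), f.tolist())))
    truth = TruthRecord("gen_timecourse", seed, {
        "k": k, "plateau": plateau, "timepoints": list(map(float, timepoints)),
        "noise_sd": noise_sd,
    })
    return tc, truth
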