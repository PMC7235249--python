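"""Nucleotide alphabet helpers: complements and IUPAC degeneracy codes.

The degenerate alphabet maps each one-letter code to the set of concrete
bases it covers (``R`` = A/G, ``N`` = any, ...). The inverse mapping turns a
non-empty base set back into its canonical code, which is how consensus
strings are spelled from position frequency matrices.
"""

from __future__ import annotations

from .errors import ConfigError

DNA_BASES = ("A", "C", "G", "T")

#: one-letter IUPAC code -> set of concrete bases covered
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC codes are complemented too)."""
    return seq.translate(_COMPLEMENT)[::-1]


def bases_for(code: str) -> frozenset[str]:
    """Concrete bases covered by a single IUPAC letter."""
    try:
        return IUPAC_TO_BASES[code]
    except KeyError:
        raise ConfigError(f"invalid IUPAC nucleotide code: {code!r}") from None


def iupac_for(bases) -> str:
    """Canonical IUPAC letter for a non-empty set of concrete bases."""
    key = frozenset(bases)
    if not key:
        raise ConfigError("cannot encode an empty base set as IUPAC")
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise ConfigError(f"not a set of concrete DNA bases: {sorted(key)}") from None


def validate_motif(motif: str) -> str:
    """Uppercase and validate an IUPAC motif string; raise ConfigError otherwise."""
    motif = motif.upper()
    if not motif:
        raise ConfigError("empty IUPAC motif")
    for ch in motif:
        bases_for(ch)
    return motif
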