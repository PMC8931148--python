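"""DNA alphabet and IUPAC degeneracy utilities.

Sequences handled by pamscape are uppercase DNA over ``{A, C, G, T, N}``;
motifs may use the full IUPAC nucleotide code. ``U`` is rejected everywhere
(DNA only). These are the shared primitives every other module builds on.
"""

from __future__ import annotations

from .errors import AlphabetError

DNA_BASES = "ACGT"

#: Degeneracy sets of the IUPAC nucleotide codes (N = any, R = purine, ...).
IUPAC_SETS: dict[str, frozenset[str]] = {
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

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

# code whose degeneracy set is the base-wise complement of each code's set
_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}
IUPAC_COMPLEMENT: dict[str, str] = {
    code: _SET_TO_CODE[frozenset(_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


def validate_dna(seq: str, *, context: str = "sequence") -> None:
    """Raise :class:`AlphabetError` unless *seq* is uppercase over ACGTN."""
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise AlphabetError(
            f"{context} contains non-DNA characters {sorted(invalid)!r}; "
            "expected uppercase A/C/G/T/N"
        )


def complement(base: str) -> str:
    """Watson-Crick complement of a single A/C/G/T/N base."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(f"cannot complement non-DNA base {base!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    validate_dna(seq)
    return seq.translate(_RC_TABLE)[::-1]


def iupac_matches(base: str, code: str) -> bool:
    """True iff *base* (A/C/G/T) lies in the degeneracy set of IUPAC *code*."""
    if base not in IUPAC_SETS or len(base) != 1 or base not in "ACGT":
        raise AlphabetError(f"base must be one of A/C/G/T, got {base!r}")
    try:
        return base in IUPAC_SETS[code]
    except KeyError:
        raise AlphabetError(f"invalid IUPAC code {code!r}") from None


def iupac_reverse_complement(motif: str) -> str:
    """Reverse complement of an IUPAC motif (R -> Y, N -> N, ...)."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(motif))
    except KeyError as exc:
        raise AlphabetError(f"invalid IUPAC code in motif {motif!r}") from exc
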