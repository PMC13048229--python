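"""DNA IUPAC alphabet algebra.

Every one of the 15 IUPAC codes stands for a non-empty subset of {A, C, G, T};
the mapping is a bijection.  Two codes *match* when their nucleotide sets
intersect: ``Y`` (C/T) and ``S`` (C/G) match because both can represent C,
while ``R`` (A/G) and ``Y`` do not.  The gap character ``-`` is not an IUPAC
code; it matches only another gap.

Input is case-insensitive and ``U`` is treated as ``T``; canonical output is
uppercase DNA.
"""

from __future__ import annotations

GAP = "-"

#: code -> nucleotide set, over the 15 DNA IUPAC codes.
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

#: nucleotide set -> code (inverse of :data:`IUPAC_SETS`).
SET_TO_IUPAC: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}

IUPAC_CODES: str = "".join(IUPAC_SETS)
AMBIGUOUS_CODES: frozenset[str] = frozenset(IUPAC_SETS) - frozenset("ACGT")


def canonicalize(char: str) -> str:
    """Normalise one character: uppercase, ``U`` -> ``T``.

    Raises ``ValueError`` for anything that is not an IUPAC code or a gap.
    """
    c = char.upper()
    if c == "U":
        c = "T"
    if c != GAP and c not in IUPAC_SETS:
        raise ValueError(f"unknown IUPAC character: {char!r}")
    return c


def canonicalize_seq(seq: str, allow_gap: bool = False) -> str:
    """Normalise a whole sequence, validating every character."""
    out = seq.upper().replace("U", "T")
    allowed = IUPAC_SETS.keys() | {GAP} if allow_gap else IUPAC_SETS.keys()
    for i, c in enumerate(out):
        if c not in allowed:
            raise ValueError(f"unknown IUPAC character {seq[i]!r} at position {i}")
    return out


def nucleotide_set(code: str) -> frozenset[str]:
    """Return the set of nucleotides a code can represent."""
    c = canonicalize(code)
    if c == GAP:
        raise ValueError("the gap character has no nucleotide set")
    return IUPAC_SETS[c]


def symbol_for_set(nucleotides) -> str:
    """Return the unique IUPAC code whose nucleotide set equals the input.

    >>> symbol_for_set({"C", "T"})
    'Y'
    """
    nucs = frozenset(canonicalize(n) for n in nucleotides)
    if not nucs:
        raise ValueError("no IUPAC code for empty set")
    try:
        return SET_TO_IUPAC[nucs]
    except KeyError:  # a member outside ACGT (e.g. an ambiguity code)
        bad = sorted(nucs - frozenset("ACGT"))
        raise ValueError(f"not a set of nucleotides: {bad}") from None


def codes_match(a: str, b: str) -> bool:
    """True iff the two codes share a potential nucleotide.

    Gaps only match gaps; a gap never matches a code.
    """
    ca, cb = canonicalize(a), canonicalize(b)
    if ca == GAP or cb == GAP:
        return ca == cb
    return bool(IUPAC_SETS[ca] & IUPAC_SETS[cb])
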