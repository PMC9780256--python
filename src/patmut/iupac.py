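"""The IUPAC nucleotide ambiguity alphabet and its elementary refinements.

A pattern partition is built by recursively splitting one position's
ambiguity code into two disjoint, covering sub-codes (a *two-partition*).
``TWO_PARTITIONS`` lists, for each ambiguity code, every way its base set
can be split into two sets that are themselves IUPAC-codable; the listed
order is the canonical enumeration order used for deterministic
tie-breaking in the optimizers.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .dna import BASES

#: code -> set of matched bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

CODES = "ACGTSWRYKMBDHVN"
CODE_INDEX = {c: i for i, c in enumerate(CODES)}

SET_TO_CODE = {s: c for c, s in IUPAC_SETS.items()}

#: every way to split a code's base set into two disjoint IUPAC-codable
#: subsets whose union is the full set, in canonical order
TWO_PARTITIONS: dict[str, list[tuple[str, str]]] = {
    "S": [("C", "G")],
    "W": [("A", "T")],
    "R": [("A", "G")],
    "Y": [("C", "T")],
    "K": [("G", "T")],
    "M": [("A", "C")],
    "B": [("C", "K"), ("G", "Y"), ("T", "S")],
    "D": [("A", "K"), ("G", "W"), ("T", "R")],
    "H": [("A", "Y"), ("C", "W"), ("T", "M")],
    "V": [("A", "S"), ("C", "R"), ("G", "M")],
    "N": [("A", "B"), ("C", "D"), ("G", "H"), ("T", "V"),
          ("R", "Y"), ("S", "W"), ("K", "M")],
}

#: membership matrix: MEMBER[code_index, base_code] == base in code's set
MEMBER = np.zeros((len(CODES), 4), dtype=bool)
for _c, _s in IUPAC_SETS.items():
    for _b in _s:
        MEMBER[CODE_INDEX[_c], BASES.index(_b)] = True


def two_partitions(code: str) -> list[tuple[str, str]]:
    """All two-partitions of an ambiguity code; empty for A/C/G/T."""
    if code not in IUPAC_SETS:
        raise ValueError(f"not an IUPAC code: {code!r}")
    return list(TWO_PARTITIONS.get(code, []))


def matches(pattern: str, kmer: str) -> bool:
    """True iff every base of ``kmer`` is in the set of its pattern position."""
    if len(pattern) != len(kmer):
        return False
    return all(b in IUPAC_SETS[p] for p, b in zip(pattern, kmer))


def pattern_size(pattern: str) -> int:
    """Number of k-mers a pattern matches (product of its set sizes)."""
    n = 1
    for p in pattern:
        n *= len(IUPAC_SETS[p])
    return n


def expand(pattern: str) -> list[str]:
    """All k-mers a pattern matches, lexicographic."""
    out = [""]
    for p in pattern:
        out = [pre + b for pre in out for b in sorted(IUPAC_SETS[p])]
    return out


@lru_cache(maxsize=None)
def subset_codes(code: str) -> tuple[str, ...]:
    """Codes whose base sets are subsets of ``code``'s (the codes reachable
    from ``code`` by recursive two-partition splits, plus ``code`` itself)."""
    s = IUPAC_SETS[code]
    return tuple(c for c in CODES if IUPAC_SETS[c] <= s)


def pattern_match_mask(pattern: str, k: int) -> np.ndarray:
    """Boolean mask over all 4**k k-mer indices matched by ``pattern``."""
    from .dna import position_digits

    if len(pattern) != k:
        raise ValueError("pattern length != k")
    mask = np.ones(4 ** k, dtype=bool)
    for pos, code in enumerate(pattern):
        mask &= MEMBER[CODE_INDEX[code], position_digits(k, pos)]
    return mask
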