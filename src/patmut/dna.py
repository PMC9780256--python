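"""Low-level DNA encodings shared by the counting and model code.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N and IUPAC
ambiguity letters in the input genome) maps to code 4 and invalidates
every k-mer window that contains it.  k-mers are addressed by their
base-4 integer index with the 5'-most base most significant.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
N_CODE = 4

_COMP = str.maketrans("ACGTN", "TGCAN")

_ENC = np.full(256, N_CODE, dtype=np.uint8)
for _b, _i in BASE_CODE.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def encode(seq: str) -> np.ndarray:
    """Encode a string into base codes (uint8; non-ACGT -> 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_index(kmer: str) -> int:
    idx = 0
    for b in kmer:
        idx = idx * 4 + BASE_CODE[b]
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def all_kmers(k: int):
    """All 4**k k-mers in index order."""
    return [index_to_kmer(i, k) for i in range(4 ** k)]


def window_indices(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k-mer index and validity for every window of an encoded sequence.

    Returns ``(idx, valid)`` of length ``len(codes) - k + 1``; window ``i``
    covers ``codes[i:i+k]`` and is valid iff it contains no N.
    """
    if len(codes) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = np.minimum(win, 3).astype(np.int64) @ powers
    return idx, valid


def revcomp_index_table(k: int) -> np.ndarray:
    """Lookup table mapping each k-mer index to its reverse complement's index."""
    idx = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(idx)
    rest = idx.copy()
    for j in range(k):  # j-th digit from the 3' end
        digit = rest % 4
        rest //= 4
        rc = rc * 4 + (3 - digit)
    return rc


def position_digits(k: int, pos: int) -> np.ndarray:
    """Base code at ``pos`` (0 = 5'-most) for every k-mer index."""
    idx = np.arange(4 ** k, dtype=np.int64)
    return (idx // 4 ** (k - 1 - pos)) % 4
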