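"""Shared nucleotide/codon encodings.

Nucleotides are encoded A=0, C=1, G=2, T=3; a codon (a, b, c) gets the
integer index 16*a + 4*b + c, so the 64 codons enumerate AAA..TTT in
alphabetical order.
"""

from __future__ import annotations

import numpy as np

NT_ORDER = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT_ORDER)}

# complement in index space: A<->T, C<->G
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)

CODONS = tuple(a + b + c for a in NT_ORDER for b in NT_ORDER for c in NT_ORDER)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG", "CTG"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
MOLLICUTE_STOP_CODONS = frozenset({"TAA", "TAG"})

# lookup tables built once at import
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _c, _i in NT_INDEX.items():
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i

_DECODE_LUT = np.frombuffer(NT_ORDER.encode(), dtype=np.uint8)

# (64, 3) array of nucleotide indices per codon
CODON_NT = np.array(
    [[i >> 4, (i >> 2) & 3, i & 3] for i in range(64)], dtype=np.int8
)


def reverse_complement_index(codon_idx: int) -> int:
    """Index of the reverse complement of the codon with index ``codon_idx``."""
    a, b, c = codon_idx >> 4, (codon_idx >> 2) & 3, codon_idx & 3
    return ((3 - c) << 4) | ((3 - b) << 2) | (3 - a)


RC_PERMUTATION = np.array([reverse_complement_index(i) for i in range(64)])


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T string to an int8 index array.

    Raises ``ValueError`` on any character outside {A, C, G, T} (case
    insensitive).
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="strict"), dtype=np.uint8)
    enc = _ENCODE_LUT[raw]
    if (enc < 0).any():
        bad = chr(raw[int(np.argmax(enc < 0))])
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return enc


def decode_sequence(encoded: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    return _DECODE_LUT[np.asarray(encoded, dtype=np.int8)].tobytes().decode()


def reverse_complement(sequence: str) -> str:
    return decode_sequence(COMPLEMENT[encode_sequence(sequence)][::-1])


def codon_indices(encoded: np.ndarray, offset: int = 0) -> np.ndarray:
    """Triplet indices of a frame starting at ``offset`` (0, 1 or 2).

    Trailing nucleotides that do not complete a triplet are dropped.
    """
    n = (len(encoded) - offset) // 3
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    trimmed = encoded[offset : offset + 3 * n].reshape(n, 3).astype(np.int64)
    return 16 * trimmed[:, 0] + 4 * trimmed[:, 1] + trimmed[:, 2]


def codon_set_mask(codons: frozenset[str] | set[str]) -> np.ndarray:
    """Boolean length-64 mask for a set of codon strings."""
    mask = np.zeros(64, dtype=bool)
    for c in codons:
        mask[CODON_INDEX[c.upper()]] = True
    return mask
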