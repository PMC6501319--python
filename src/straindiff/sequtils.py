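"""Low-level nucleotide helpers: 2-bit encoding, random sequences, codons.

The 2-bit packing (A=0, C=1, G=2, T=3) lets k-mers up to k=31 be encoded as
exact uint64 codes, so k-mer identity is collision-free.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i

STOP_CODONS = ("TAA", "TAG", "TGA")


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 array of base indices (A=0..T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = int(np.argmax(arr == 255))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    return BASES[arr].tobytes().decode()


def complement_codes(arr: np.ndarray) -> np.ndarray:
    return 3 - arr


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """uint64 2-bit packed codes of all k-mers (length len(arr)-k+1)."""
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    if len(arr) < k:
        return np.empty(0, dtype=np.uint64)
    w = np.lib.stride_tricks.sliding_window_view(arr, k).astype(np.uint64)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    return w @ weights


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. base indices with the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


_CODON_TABLE = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            _CODON_TABLE[_c1 + _c2 + _c3] = None
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _idx, _codon in enumerate(
    [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
):
    _CODON_TABLE[_codon] = _AA[_idx]


def translate(seq: str) -> str:
    """Translate a nucleotide CDS; trailing stop omitted, internal stop -> '*'."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def is_stop(codon_arr: np.ndarray) -> bool:
    return decode(codon_arr) in STOP_CODONS
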