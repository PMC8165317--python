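"""Low-level DNA helpers shared across modules.

Sequences are handled in two forms: Python strings over {A,C,G,T} at the API
surface, and uint8 code arrays (A=0, C=1, G=2, T=3) internally where speed
matters (read simulation and mapping). Both forms round-trip losslessly.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def validate_dna(seq: str, *, name: str = "sequence") -> None:
    """Raise ValueError unless *seq* is a non-empty string over {A,C,G,T}."""
    if not isinstance(seq, str) or not seq:
        raise ValueError(f"{name} must be a non-empty DNA string")
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({c for c in seq if c.upper() not in ALPHABET})
        raise ValueError(f"{name} contains non-ACGT characters: {bad}")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("cannot encode non-ACGT sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGT string."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[..., ::-1]


def random_codes(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. background sequence with the given GC fraction, as codes."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers of a 1-D code array (base-4 packing).

    Requires k <= 31 so the packed value fits in int64.
    """
    codes = np.asarray(codes, dtype=np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = np.empty(n, dtype=np.int64)
    out[0] = codes[:k] @ powers
    if n > 1:
        # rolling update: drop leading base, shift, append trailing base
        top = powers[0]
        lead = codes[: n - 1] * top
        trail = codes[k:]
        for i in range(1, n):
            out[i] = (out[i - 1] - lead[i - 1]) * 4 + trail[i - 1]
    return out


def kmer_codes_matrix(codes: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k-mer codes for a 2-D (n_reads, read_length) code matrix."""
    codes = np.asarray(codes, dtype=np.int64)
    n, L = codes.shape
    w = L - k + 1
    if w <= 0:
        return np.empty((n, 0), dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = np.empty((n, w), dtype=np.int64)
    out[:, 0] = codes[:, :k] @ powers
    top = powers[0]
    for i in range(1, w):
        out[:, i] = (out[:, i - 1] - codes[:, i - 1] * top) * 4 + codes[:, i + k - 1]
    return out
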