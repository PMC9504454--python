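"""Base alphabet, integer encoding, one-hot encoding and reverse complement.

Bases are encoded as small integers: A=0, C=1, G=2, T=3, N=4.  Every array
that holds encoded sequence uses dtype uint8.  N is a first-class symbol at
parse time but is never a prediction target: positions whose context (or
focus base) contains an N are "disqualified" and excluded from model
estimation and scoring.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

#: index of each base letter; lowercase maps like uppercase
_LETTER_TO_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LETTER_TO_CODE[ord(_b)] = _i
    _LETTER_TO_CODE[ord(_b.lower())] = _i

#: complement of each code (A<->T, C<->G, N->N)
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(bases: str) -> np.ndarray:
    """Encode a base string to a uint8 code array (unknown letters -> N)."""
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return _LETTER_TO_CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case base string."""
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def one_hot_encode(bases) -> np.ndarray:
    """One-hot encode a sequence over {A,C,G,T}.

    Parameters
    ----------
    bases : str or uint8 code array
        Sequence to encode.  N (or any non-ACGT letter) is rejected:
        callers must mask disqualified positions first.

    Returns
    -------
    (len, 4) float64 matrix with rows A=(1,0,0,0) ... T=(0,0,0,1).
    """
    codes = encode(bases) if isinstance(bases, str) else np.asarray(bases, dtype=np.uint8)
    if codes.size and codes.max(initial=0) >= 4:
        raise ValueError("cannot one-hot encode N or unknown symbols; mask first")
    out = np.zeros((codes.size, 4))
    out[np.arange(codes.size), codes] = 1.0
    return out


def reverse_complement(bases):
    """Reverse complement; accepts and returns either str or code array.

    An involution: applying it twice returns the input.  N maps to N.
    """
    if isinstance(bases, str):
        return decode(COMPLEMENT[encode(bases)][::-1])
    return COMPLEMENT[np.asarray(bases, dtype=np.uint8)][::-1]
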