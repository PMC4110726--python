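"""Nucleotide <-> integer encoding shared by the index, mapper and simulator.

Sequences are handled case-insensitively and stored lowercase. The integer
code is a, c, g, t -> 0, 1, 2, 3; any other character (N, IUPAC ambiguity
codes, ...) maps to INVALID and is rejected or masked by callers.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "acgt"
INVALID = np.uint8(255)

_ENC = np.full(256, INVALID, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.upper())] = _i

# decode table: codes 0..3 -> acgt, anything else (INVALID) -> 'n'
_DEC = np.full(256, ord("n"), dtype=np.uint8)
_DEC[:4] = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# complement under the 2-bit code: a<->t is 0<->3, c<->g is 1<->2;
# invalid codes complement to themselves
_COMP = np.arange(256, dtype=np.uint8)
_COMP[:4] = [3, 2, 1, 0]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 array (255 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def encode_strict(seq: str) -> np.ndarray:
    """Encode, raising ValueError on any non-ACGT character."""
    enc = encode(seq)
    if (enc == INVALID).any():
        bad = seq[int(np.argmax(enc == INVALID))]
        raise ValueError(f"non-nucleotide character {bad!r} in sequence")
    return enc


def decode(enc: np.ndarray) -> str:
    return _DEC[enc].tobytes().decode("ascii")


def revcomp_encoded(enc: np.ndarray) -> np.ndarray:
    return _COMP[enc[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_encoded(encode_strict(seq)))
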