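"""Nucleotide alphabet helpers shared across modules.

Sequences are handled either as upper-case strings over ``ACGTN`` or as
``int8`` code arrays (A=0, C=1, G=2, T=3, N=4).  ``N`` marks masked or
ambiguous positions and never matches anything, including another ``N``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T, N = 0, 1, 2, 3, 4
ALPHABET = "ACGTN"
GAP_CODE = 5  # used by alignment rows only

_ENCODE = np.full(256, N, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("n")] = N
_ENCODE[ord("N")] = N

_COMPLEMENT = np.array([T, G, C, A, N, GAP_CODE], dtype=np.int8)
_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into int8 codes (non-ACGT -> N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN-"[c] for c in codes)


def normalize(seq: str) -> tuple[str, int]:
    """Upper-case and map non-ACGTN characters to N.

    Returns the normalized string and the number of substituted characters
    (characters that were neither an IUPAC ACGT base nor N, in any case).
    """
    up = seq.upper()
    out = []
    n_sub = 0
    for ch in up:
        if ch in "ACGTN":
            out.append(ch)
        else:
            out.append("N")
            n_sub += 1
    return "".join(out), n_sub


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1].copy()
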