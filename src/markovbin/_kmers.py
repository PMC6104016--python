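"""Shared (k+1)-mer window machinery.

Bases are coded A=0, C=1, G=2, T=3; anything else codes to -1 and any window
containing it is skipped. A (k+1)-mer window represents one k-mer -> k-mer
transition step, indexed as prefix_index * 4 + successor_base.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to base codes; non-ACGT becomes -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transition_counts(seq: str, k: int) -> np.ndarray:
    """Count (k+1)-mer windows of ``seq``, skipping windows with non-ACGT bases.

    Returns a float vector of length 4**(k+1).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    width = k + 1
    n_states = 4 ** width
    counts = np.zeros(n_states, dtype=np.float64)
    if len(seq) < width:
        return counts
    codes = encode_sequence(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, width)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return counts
    powers = 4 ** np.arange(width - 1, -1, -1, dtype=np.int64)
    idx = windows[valid].astype(np.int64) @ powers
    counts += np.bincount(idx, minlength=n_states)
    return counts
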