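"""Vectorised k-mer encoding and counting primitives.

Sequences are encoded base-per-byte (A=0, C=1, G=2, T=3; anything else -1)
and k-mer windows are reduced to integer codes in [0, 4**k).  Codes are
ordered so that decoding enumerates motifs alphabetically.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to int8 codes; non-ACGT characters become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_block(seqs: Sequence[str], length: int) -> np.ndarray:
    """Encode equal-length sequences into an (n, length) int8 array."""
    joined = "".join(seqs)
    arr = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    return arr.reshape(len(seqs), length)


def decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    """All 4**k motifs in alphabetical (== code) order."""
    return [decode(c, k) for c in range(4**k)]


def motif_code(motif: str) -> int:
    arr = encode(motif)
    if (arr < 0).any():
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    code = 0
    for v in arr:
        code = (code << 2) | int(v)
    return code


def window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes for each row of an (n, L) encoded array.

    Returns ``(codes, valid)`` of shape (n, L-k+1); windows touching a
    negative (non-ACGT) position are flagged invalid.
    """
    n, length = arr.shape
    if length < k:
        return (np.zeros((n, 0), dtype=np.int64), np.zeros((n, 0), dtype=bool))
    w = length - k + 1
    codes = np.zeros((n, w), dtype=np.int64)
    valid = np.ones((n, w), dtype=bool)
    for j in range(k):
        col = arr[:, j : j + w]
        codes = (codes << 2) | np.where(col < 0, 0, col).astype(np.int64)
        valid &= col >= 0
    return codes, valid


def presence_counts(tags: Iterable[str], k: int) -> np.ndarray:
    """Number of tags containing each motif at least once (length-4**k array)."""
    nmotif = 4**k
    counts = np.zeros(nmotif, dtype=np.int64)
    by_len: dict[int, list[str]] = defaultdict(list)
    for t in tags:
        by_len[len(t)].append(t)
    row_base = 0
    for length, group in sorted(by_len.items()):
        if length < k:
            row_base += len(group)
            continue
        arr = encode_block(group, length)
        codes, valid = window_codes(arr, k)
        rows = np.repeat(np.arange(len(group), dtype=np.int64), codes.shape[1])
        flat = rows * nmotif + codes.ravel()
        flat = flat[valid.ravel()]
        uniq = np.unique(flat)
        counts += np.bincount(uniq % nmotif, minlength=nmotif)
        row_base += len(group)
    return counts


def occurrence_count(
    seq: str, motif_codes: Sequence[int], k: int, overlapping: bool = True
) -> tuple[int, bool]:
    """Total occurrences of any motif in ``seq``.

    Returns ``(count, had_invalid)`` where ``had_invalid`` reports whether
    any window was skipped due to non-ACGT characters.
    """
    arr = encode(seq).reshape(1, -1)
    codes, valid = window_codes(arr, k)
    hits = np.isin(codes[0], np.asarray(motif_codes, dtype=np.int64)) & valid[0]
    had_invalid = bool((~valid[0]).any())
    if overlapping:
        return int(hits.sum()), had_invalid
    count = 0
    i = 0
    n = hits.shape[0]
    while i < n:
        if hits[i]:
            count += 1
            i += k
        else:
            i += 1
    return count, had_invalid


def weighted_scores(arr: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Per-row sum of ``weights[code]`` over all k-mer windows of ``arr``."""
    codes, valid = window_codes(arr, k)
    w = weights[codes]
    w[~valid] = 0.0
    return w.sum(axis=1)
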