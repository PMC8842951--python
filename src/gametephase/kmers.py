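"""Exact canonical k-mer counting on 2-bit encoded sequences.

k is restricted to odd values <= 31 so every k-mer fits in a uint64 and
forward/reverse-complement encodings can never tie (strand-unambiguous
canonicalization).
"""
from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .datatypes import ConfigError

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def check_k(k: int) -> None:
    if k < 1 or k > 31 or k % 2 == 0:
        raise ConfigError(f"k must be odd and in [1, 31], got {k}")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 255)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    if np.any(codes > 3):
        raise ValueError("cannot decode non-ACGT codes")
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def canonical_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """All canonical k-mers of one code sequence, one per start position.

    k-mers containing a non-ACGT code are dropped.
    """
    check_k(k)
    codes = np.asarray(codes, dtype=np.uint8)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    bad = codes > 3
    safe = np.where(bad, 0, codes).astype(np.uint64)
    for t in range(k):
        c = safe[t:t + n]
        fwd |= c << np.uint64(2 * (k - 1 - t))
        rev |= (np.uint64(3) - c) << np.uint64(2 * t)
    out = np.minimum(fwd, rev)
    if bad.any():
        cum = np.concatenate(([0], np.cumsum(bad)))
        out = out[(cum[k:] - cum[:-k]) == 0]
    return out


def canonical_kmers_2d(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mers of a (n_seqs, L) code matrix -> (n_seqs, L-k+1)."""
    check_k(k)
    mat = np.asarray(mat, dtype=np.uint8)
    n = mat.shape[1] - k + 1
    if n <= 0:
        raise ConfigError("k exceeds sequence length")
    fwd = np.zeros((mat.shape[0], n), dtype=np.uint64)
    rev = np.zeros_like(fwd)
    safe = np.where(mat > 3, 0, mat).astype(np.uint64)
    for t in range(k):
        c = safe[:, t:t + n]
        fwd |= c << np.uint64(2 * (k - 1 - t))
        rev |= (np.uint64(3) - c) << np.uint64(2 * t)
    return np.minimum(fwd, rev)


def count_kmers(arrays: Iterable[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate canonical k-mer counts over many arrays.

    Returns (sorted unique k-mers, counts); merges incrementally so peak
    memory stays proportional to the distinct-k-mer count plus one chunk.
    """
    uniq = np.empty(0, dtype=np.uint64)
    counts = np.empty(0, dtype=np.int64)
    buf: list[np.ndarray] = []
    size = 0

    def flush() -> None:
        nonlocal uniq, counts, buf, size
        if not buf:
            return
        u, c = np.unique(np.concatenate(buf), return_counts=True)
        merged = np.concatenate([uniq, u])
        order = np.argsort(merged, kind="mergesort")
        merged = merged[order]
        mcounts = np.concatenate([counts, c])[order]
        keep = np.concatenate(([True], merged[1:] != merged[:-1]))
        grp = np.cumsum(keep) - 1
        out = np.zeros(int(grp[-1]) + 1 if grp.size else 0, dtype=np.int64)
        np.add.at(out, grp, mcounts)
        uniq, counts = merged[keep], out
        buf, size = [], 0

    for arr in arrays:
        arr = np.ravel(arr)
        if arr.size == 0:
            continue
        buf.append(arr)
        size += arr.size
        if size >= 8_000_000:
            flush()
    flush()
    return uniq, counts


def lookup_counts(uniq: np.ndarray, counts: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Counts of each query k-mer in a (sorted unique, counts) profile; 0 if absent."""
    idx = np.searchsorted(uniq, query)
    idx = np.clip(idx, 0, max(uniq.size - 1, 0))
    if uniq.size == 0:
        return np.zeros(query.shape, dtype=np.int64)
    hit = uniq[idx] == query
    return np.where(hit, counts[idx], 0)


def member(sorted_set: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Boolean membership of query k-mers in a sorted k-mer set."""
    if sorted_set.size == 0:
        return np.zeros(query.shape, dtype=bool)
    idx = np.clip(np.searchsorted(sorted_set, query), 0, sorted_set.size - 1)
    return sorted_set[idx] == query


def iter_seq_kmers(seqs: Iterable[str], k: int, batch: int = 10_000) -> Iterator[np.ndarray]:
    """Yield one canonical k-mer array per sequence, preserving input order.

    Contiguous runs of equal-length sequences are processed as one matrix.
    """
    check_k(k)
    rows: list[np.ndarray] = []
    cur_len = -1

    def drain() -> Iterator[np.ndarray]:
        nonlocal rows
        if not rows:
            return
        if cur_len >= k:
            for row in canonical_kmers_2d(np.vstack(rows), k):
                yield row
        else:
            for _ in rows:
                yield np.empty(0, dtype=np.uint64)
        rows = []

    for s in seqs:
        if len(s) != cur_len or len(rows) >= batch:
            yield from drain()
            cur_len = len(s)
        rows.append(encode(s))
    yield from drain()
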