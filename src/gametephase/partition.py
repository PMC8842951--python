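"""Haplotype-block-based read partitioning and k-mer depth normalization.

A read is assigned to a parental pool only when its mapped interval is
fully contained in a haplotype block *of its own cell* (containment, not
overlap-majority: boundary reads are exactly the ones whose wrong-haplotype
k-mers would contaminate downstream binning, and the pipeline can afford
discarding them).  Pools are merged across cells before normalization.

Normalization is a two-pass scheme: pass 1 counts canonical k-mers over
the pool, pass 2 keeps each read with probability
``min(1, target_depth / median k-mer count)`` from a seeded generator.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Iterable

import numpy as np

from . import kmers
from .blocks import CellBlockSet
from .datatypes import ConfigError, ReadSet

UNASSIGNED = -1


@dataclasses.dataclass
class ReadPartition:
    """Assignment of every input read to pool A, pool B or unassigned."""

    reads: ReadSet
    assignment: np.ndarray  # int8 per read: 0=A, 1=B, -1=unassigned

    @property
    def n_pool_a(self) -> int:
        return int(np.sum(self.assignment == 0))

    @property
    def n_pool_b(self) -> int:
        return int(np.sum(self.assignment == 1))

    @property
    def n_unassigned(self) -> int:
        return int(np.sum(self.assignment == UNASSIGNED))

    def pool(self, origin: int) -> ReadSet:
        return self.reads.subset(self.assignment == origin)

    def per_cell_counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for ci, cell in enumerate(self.reads.cells):
            mask = self.reads.cell_idx == ci
            a = self.assignment[mask]
            out[cell] = {"A": int(np.sum(a == 0)), "B": int(np.sum(a == 1)),
                         "unassigned": int(np.sum(a == UNASSIGNED))}
        return out


def partition_reads(reads: ReadSet, blockset: CellBlockSet) -> ReadPartition:
    """Assign reads to parental pools by containment in their cell's blocks."""
    if reads.n_reads and (reads.cell_idx.min() < 0
                          or reads.cell_idx.max() >= len(reads.cells)):
        raise ValueError("placement references an unknown cell index")
    assignment = np.full(reads.n_reads, UNASSIGNED, dtype=np.int8)
    index = blockset.by_cell_chrom()
    for ci, cell in enumerate(reads.cells):
        for hi, chrom in enumerate(reads.chroms):
            key = (cell, chrom)
            if key not in index:
                continue
            starts, ends, origins = index[key]
            mask = (reads.cell_idx == ci) & (reads.chrom_idx == hi)
            if not mask.any():
                continue
            rs, re = reads.start[mask], reads.end[mask]
            bi = np.searchsorted(starts, rs, side="right") - 1
            ok = bi >= 0
            contained = ok & (re <= ends[np.clip(bi, 0, None)])
            vals = np.full(rs.size, UNASSIGNED, dtype=np.int8)
            vals[contained] = origins[bi[contained]]
            assignment[mask] = vals
    if reads.mate is not None:
        assignment = _reconcile_mates(assignment, reads.mate)
    return ReadPartition(reads, assignment)


def _reconcile_mates(assignment: np.ndarray, mate: np.ndarray) -> np.ndarray:
    """Pair rule: disagreeing mates -> both unassigned; one assigned -> both."""
    out = assignment.copy()
    for i in range(assignment.size):
        j = mate[i]
        if j < 0 or j <= i:
            continue
        a, b = assignment[i], assignment[j]
        if a == UNASSIGNED and b != UNASSIGNED:
            out[i] = b
        elif b == UNASSIGNED and a != UNASSIGNED:
            out[j] = a
        elif a != UNASSIGNED and b != UNASSIGNED and a != b:
            out[i] = out[j] = UNASSIGNED
    return out


def kmer_depth_profile(read_kmers: Iterable[np.ndarray], k: int,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact canonical k-mer counts over a read pool.

    ``read_kmers`` yields one canonical k-mer array per read (see
    :func:`gametephase.kmers.iter_seq_kmers`).
    """
    kmers.check_k(k)
    return kmers.count_kmers(read_kmers)


def normalize_by_kmer_depth(read_kmers_factory: Callable[[], Iterable[np.ndarray]],
                            k: int, target_depth: float, seed: int,
                            ) -> np.ndarray:
    """Two-pass k-mer depth normalization; returns a boolean keep mask.

    Reads whose median k-mer count is at most ``target_depth`` are always
    retained; deeper reads are downsampled with probability
    ``target_depth / median``.  Median (not mean) resists repeat-induced
    outliers.  The seeded generator makes the retained set deterministic.
    """
    if target_depth < 1:
        raise ConfigError("target_depth must be >= 1")
    uniq, counts = kmer_depth_profile(read_kmers_factory(), k)

    medians: list[np.ndarray] = []
    buf: list[np.ndarray] = []
    size = 0

    def flush() -> None:
        nonlocal buf, size
        if not buf:
            return
        lens = np.array([a.size for a in buf])
        vals = kmers.lookup_counts(uniq, counts, np.concatenate(buf))
        med = np.array([np.median(v) if v.size else 0.0
                        for v in np.split(vals, np.cumsum(lens)[:-1])])
        medians.append(med)
        buf, size = [], 0

    for arr in read_kmers_factory():
        if arr.ndim == 2:  # chunk of equal-length reads, one row per read
            flush()
            if arr.shape[1] == 0:
                medians.append(np.zeros(arr.shape[0]))
            else:
                vals = kmers.lookup_counts(uniq, counts, arr)
                medians.append(np.median(vals, axis=1))
            continue
        buf.append(arr)
        size += max(arr.size, 1)
        if size >= 4_000_000:
            flush()
    flush()
    med = np.concatenate(medians) if medians else np.empty(0)
    rng = np.random.default_rng(seed)
    draws = rng.random(med.size)
    with np.errstate(divide="ignore"):
        prob = np.minimum(1.0, np.where(med > 0, target_depth / med, np.inf))
    return draws < prob


def genome_backed_kmers(truth, reads: ReadSet, k: int,
                        mask: np.ndarray | None = None) -> Callable[[], Iterable[np.ndarray]]:
    """k-mer iterator factory for simulated reads, sliced from gamete genomes.

    Avoids materializing read strings: the canonical k-mer array of each
    gamete chromosome is computed once and reads index into it.  Yields 2D
    chunks (one row per read) for contiguous runs of equal-length reads on
    the same gamete chromosome, 1D arrays otherwise.
    """
    kmers.check_k(k)
    idx = np.flatnonzero(mask) if mask is not None else np.arange(reads.n_reads)
    keys = reads.cell_idx[idx].astype(np.int64) * len(reads.chroms) + reads.chrom_idx[idx]
    lengths = reads.end[idx] - reads.start[idx]
    run_end = np.flatnonzero(np.diff(keys) | np.diff(lengths)) + 1
    bounds = np.concatenate(([0], run_end, [idx.size])) if idx.size else np.array([0])

    def factory() -> Iterable[np.ndarray]:
        # reads from the simulator arrive grouped by (cell, chrom), so only
        # one chromosome's k-mer array is held at a time
        for b in range(bounds.size - 1):
            lo, hi = int(bounds[b]), int(bounds[b + 1])
            if hi <= lo:
                continue
            sel = idx[lo:hi]
            key = (int(reads.cell_idx[sel[0]]), int(reads.chrom_idx[sel[0]]))
            arr = kmers.canonical_kmers(truth.gamete_codes(*key), k)
            m = int(lengths[lo]) - k + 1
            if m <= 0:
                yield np.empty((hi - lo, 0), dtype=np.uint64)
                continue
            for c0 in range(lo, hi, 50_000):
                c1 = min(c0 + 50_000, hi)
                starts = reads.start[idx[c0:c1]]
                yield arr[starts[:, None] + np.arange(m)]
    return factory


def per_window_depth(reads: ReadSet, chrom_lengths: dict[str, int],
                     window: int = 10_000,
                     mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Mean per-window base coverage per chromosome, pooled over cells."""
    out = {}
    sel = mask if mask is not None else np.ones(reads.n_reads, dtype=bool)
    for hi, chrom in enumerate(reads.chroms):
        L = chrom_lengths[chrom]
        n_win = -(-L // window)
        depth = np.zeros(n_win)
        m = sel & (reads.chrom_idx == hi)
        # attribute each read's bases to the window of its start (toy scale)
        np.add.at(depth, reads.start[m] // window,
                  (reads.end[m] - reads.start[m]).astype(float))
        widths = np.minimum(np.arange(1, n_win + 1) * window, L) - \
            np.arange(n_win) * window
        out[chrom] = depth / widths
    return out
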