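"""Scoring of phasing outputs against ground truth.

Implements hapmer-based positive predictive value (PPV) for read pools or
contigs, switch-error / Hamming accuracy for consensus haplotypes, and
precision/recall of crossover calls.  PPV for a pool with marker counts
(n1, n2) is ``max(n1, n2) / (n1 + n2)`` — invariant to haplotype label
swap, NA when no markers are present.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from . import kmers
from .blocks import CrossoverEvent
from .phasing import ConsensusHaplotypes


@dataclasses.dataclass
class HapmerSets:
    """Canonical k-mers occurring in exactly one of the two truth haplotypes."""

    k: int
    hap1_only: np.ndarray  # sorted uint64
    hap2_only: np.ndarray


@dataclasses.dataclass
class PoolScore:
    name: str
    n_hap1_markers: int
    n_hap2_markers: int

    @property
    def ppv(self) -> float:
        tot = self.n_hap1_markers + self.n_hap2_markers
        if tot == 0:
            return float("nan")
        return max(self.n_hap1_markers, self.n_hap2_markers) / tot


@dataclasses.dataclass
class PhasingScore:
    switch_error_rate: float
    hamming_accuracy: float
    n_pairs: int
    n_loci: int


def compute_hapmers(hap1_seqs: Iterable[str | np.ndarray],
                    hap2_seqs: Iterable[str | np.ndarray],
                    k: int = 21) -> HapmerSets:
    """Haplotype-specific canonical k-mer sets (symmetric in its two inputs)."""
    kmers.check_k(k)

    def kmer_set(seqs: Iterable[str | np.ndarray]) -> np.ndarray:
        arrays = []
        for s in seqs:
            codes = kmers.encode(s) if isinstance(s, (str, bytes)) else np.asarray(s, np.uint8)
            arrays.append(kmers.canonical_kmers(codes, k))
        if not arrays:
            return np.empty(0, dtype=np.uint64)
        return np.unique(np.concatenate(arrays))

    s1, s2 = kmer_set(hap1_seqs), kmer_set(hap2_seqs)
    return HapmerSets(k, np.setdiff1d(s1, s2, assume_unique=True),
                      np.setdiff1d(s2, s1, assume_unique=True))


def score_pool(read_kmers: Iterable[np.ndarray], hapmers: HapmerSets,
               name: str = "pool") -> PoolScore:
    """Count haplotype-specific markers in a pool of reads or contigs."""
    n1 = n2 = 0
    buf: list[np.ndarray] = []
    size = 0

    def flush() -> tuple[int, int]:
        nonlocal buf, size
        if not buf:
            return 0, 0
        cat = np.concatenate(buf)
        buf, size = [], 0
        return (int(kmers.member(hapmers.hap1_only, cat).sum()),
                int(kmers.member(hapmers.hap2_only, cat).sum()))

    for arr in read_kmers:
        if arr.size:
            buf.append(np.ravel(arr))
            size += arr.size
        if size >= 4_000_000:
            d1, d2 = flush()
            n1 += d1; n2 += d2
    d1, d2 = flush()
    return PoolScore(name, n1 + d1, n2 + d2)


def aggregate_ppv(scores: Sequence[PoolScore]) -> float:
    """Marker-count-weighted PPV over pools; dominant counts summed per pool."""
    dom = sum(max(s.n_hap1_markers, s.n_hap2_markers) for s in scores)
    tot = sum(s.n_hap1_markers + s.n_hap2_markers for s in scores)
    return float("nan") if tot == 0 else dom / tot


def is_chimeric(score: PoolScore, min_fraction: float = 0.1) -> bool:
    """Flag pools carrying a non-trivial marker fraction from both haplotypes."""
    tot = score.n_hap1_markers + score.n_hap2_markers
    if tot == 0:
        return False
    return min(score.n_hap1_markers, score.n_hap2_markers) / tot >= min_fraction


def switch_error(consensus: ConsensusHaplotypes, truth_hap: np.ndarray,
                 ) -> PhasingScore:
    """Switch error and Hamming accuracy versus a truth haplotype code vector.

    ``truth_hap`` gives the 0/1 (REF/ALT) allele of one truth haplotype at
    every panel locus.  Within each phase set the globally better of the
    two orientations is chosen before scoring (label-swap invariance).
    """
    truth_hap = np.asarray(truth_hap, dtype=np.int8)
    if truth_hap.shape != (consensus.panel.n_loci,):
        raise ValueError("truth vector does not match consensus locus order")
    n_switch = n_pairs = n_match = 0
    for chrom, sl in consensus.panel.iter_chroms():
        hap = consensus.hap_a[sl]
        ps = consensus.phase_set[sl]
        tr = truth_hap[sl]
        for pid in np.unique(ps):
            idx = np.flatnonzero(ps == pid)
            mism = hap[idx] != tr[idx]
            flip = int(mism.sum() * 2 > idx.size)
            n_match += int(np.sum(mism == flip))
            if idx.size > 1:
                rel_c = hap[idx[1:]] ^ hap[idx[:-1]]
                rel_t = tr[idx[1:]] ^ tr[idx[:-1]]
                n_switch += int(np.sum(rel_c != rel_t))
                n_pairs += idx.size - 1
    n_loci = consensus.panel.n_loci
    return PhasingScore(
        switch_error_rate=0.0 if n_pairs == 0 else n_switch / n_pairs,
        hamming_accuracy=1.0 if n_loci == 0 else n_match / n_loci,
        n_pairs=n_pairs, n_loci=n_loci)


def crossover_recovery(detected: Sequence[CrossoverEvent], truth,
                       tolerance: int | None = None) -> dict:
    """Greedy one-to-one matching of detected crossovers to truth breakpoints.

    A detected event matches a truth breakpoint of the same cell-chromosome
    when the breakpoint lies inside the event's flanking-locus interval
    (optionally widened by ``tolerance`` bases on each side).  Returns
    precision, recall, false calls per cell-chromosome and localization
    error quantiles (|midpoint - truth|).
    """
    tol = 0 if tolerance is None else int(tolerance)
    cfg = truth.config
    by_key: dict[tuple[str, str], list[CrossoverEvent]] = {}
    for ev in detected:
        by_key.setdefault((ev.cell, ev.chrom), []).append(ev)
    n_truth = n_matched = 0
    loc_errors: list[float] = []
    cells = [f"cell{i:03d}" for i in range(cfg.n_cells)]
    for ci, cell in enumerate(cells):
        for hi, chrom in enumerate(truth.chrom_names):
            bps = truth.cell_breaks[ci][hi]
            n_truth += bps.size
            events = sorted(by_key.get((cell, chrom), []), key=lambda e: e.midpoint)
            used = np.zeros(len(events), dtype=bool)
            for p in bps:
                best, best_d = -1, np.inf
                for ei, ev in enumerate(events):
                    if used[ei]:
                        continue
                    if ev.left_snp_pos - tol <= p <= ev.right_snp_pos + tol:
                        d = abs(ev.midpoint - p)
                        if d < best_d:
                            best, best_d = ei, d
                if best >= 0:
                    used[best] = True
                    n_matched += 1
                    loc_errors.append(best_d)
    n_detected = len(detected)
    n_cell_chrom = cfg.n_cells * cfg.n_chromosomes
    q = {}
    if loc_errors:
        arr = np.array(loc_errors)
        q = {"q50": float(np.quantile(arr, 0.5)),
             "q90": float(np.quantile(arr, 0.9)),
             "q100": float(arr.max())}
    return {
        "n_truth": int(n_truth),
        "n_detected": int(n_detected),
        "n_matched": int(n_matched),
        "recall": float("nan") if n_truth == 0 else n_matched / n_truth,
        "precision": float("nan") if n_detected == 0 else n_matched / n_detected,
        "false_per_cell_chrom": (n_detected - n_matched) / n_cell_chrom,
        "localization_quantiles": q,
    }


def truth_hap_codes(truth) -> np.ndarray:
    """Truth haplotype-A allele codes over the panel (REF=hapA convention -> 0)."""
    return np.zeros(truth.panel.n_loci, dtype=np.int8)
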