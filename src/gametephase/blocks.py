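"""Per-cell haplotype blocks and crossover intervals via a two-state HMM.

Each cell's non-missing genotypes are compared with the consensus
haplotypes, giving a MATCH_A / MATCH_B observation track.  A two-state HMM
(state = parental origin) with a per-SNP error rate ``epsilon`` and
distance-scaled transition probability ``tau(d) = 1 - exp(-rate * d)`` is
decoded by Viterbi within each phase set; phase-set boundaries force block
breaks and never emit a crossover.

Block boundaries are placed at the midpoint between the flanking
informative loci of adjacent blocks — the true breakpoint is unidentifiable
inside that interval, which :class:`CrossoverEvent` preserves in full.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .datatypes import (MATCH_A, MATCH_B, NO_CALL, ConfigError,
                        GenotypeMatrix)
from .phasing import ConsensusHaplotypes


@dataclasses.dataclass
class HaplotypeBlock:
    cell: str
    chrom: str
    start: int          # 0-based half-open reference coordinates
    end: int
    origin: str         # "A" | "B"
    n_snps: int         # informative loci inside
    mean_match: float   # fraction of those matching the assigned origin


@dataclasses.dataclass
class CrossoverEvent:
    cell: str
    chrom: str
    left_snp_pos: int
    right_snp_pos: int

    @property
    def midpoint(self) -> float:
        return (self.left_snp_pos + self.right_snp_pos) / 2


@dataclasses.dataclass
class CellBlockSet:
    """All blocks of one run, with a fast per-(cell, chrom) interval index."""

    blocks: list[HaplotypeBlock]

    def by_cell_chrom(self) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]:
        grouped: dict[tuple[str, str], list[HaplotypeBlock]] = {}
        for b in self.blocks:
            grouped.setdefault((b.cell, b.chrom), []).append(b)
        out = {}
        for key, bs in grouped.items():
            bs.sort(key=lambda b: b.start)
            out[key] = (np.array([b.start for b in bs], dtype=np.int64),
                        np.array([b.end for b in bs], dtype=np.int64),
                        np.array([0 if b.origin == "A" else 1 for b in bs], dtype=np.int8))
        return out


def genotype_match_profile(genotypes: np.ndarray, consensus: ConsensusHaplotypes,
                           ) -> np.ndarray:
    """Per-locus track: MATCH_A, MATCH_B or NO_CALL for one cell.

    By biallelic complementarity every non-missing genotype matches exactly
    one haplotype.
    """
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if genotypes.shape != (consensus.panel.n_loci,):
        raise ValueError("genotype vector does not match consensus locus order")
    out = np.full(genotypes.size, NO_CALL, dtype=np.int8)
    called = genotypes >= 0
    out[called & (genotypes == consensus.hap_a)] = MATCH_A
    out[called & (genotypes == consensus.hap_b)] = MATCH_B
    return out


def _log_trans(dist: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """(log stay, log switch) per junction for distance-scaled transitions."""
    tau = 1.0 - np.exp(-rate * dist.astype(float))
    tau = np.clip(tau, 1e-300, 1.0 - 1e-12)
    return np.log1p(-tau), np.log(tau)


def viterbi_path(obs: np.ndarray, pos: np.ndarray, epsilon: float,
                 rate: float) -> np.ndarray:
    """Most probable origin path (0=A, 1=B) over informative loci.

    ``obs`` in {0, 1} (MATCH_A / MATCH_B), ``pos`` the reference positions
    of those loci.  Uniform initial state; ties broken toward state A.
    """
    if not 0.0 < epsilon < 0.5:
        raise ConfigError(f"epsilon must be in (0, 0.5), got {epsilon}")
    n = obs.size
    if n == 0:
        return np.empty(0, dtype=np.int8)
    le, lm = math.log(epsilon), math.log1p(-epsilon)
    # log emission for states (A, B) given each observation
    emit = np.where(obs[:, None] == np.array([0, 1]), lm, le)
    lstay, lswitch = _log_trans(np.diff(pos), rate)
    score = emit[0].astype(float)
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        # from-state k to to-state s
        cand = score[:, None] + np.array([[0.0, 0.0], [0.0, 0.0]])
        cand[0, 0] = score[0] + lstay[t - 1]
        cand[1, 0] = score[1] + lswitch[t - 1]
        cand[0, 1] = score[0] + lswitch[t - 1]
        cand[1, 1] = score[1] + lstay[t - 1]
        back[t] = np.argmax(cand, axis=0)  # ties -> lower index (state A)
        score = np.max(cand, axis=0) + emit[t]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_log_prob(path: np.ndarray, obs: np.ndarray, pos: np.ndarray,
                  epsilon: float, rate: float) -> float:
    """Log probability score of an explicit state path (uniform prior)."""
    le, lm = math.log(epsilon), math.log1p(-epsilon)
    lp = float(np.sum(np.where(path == obs, lm, le)))
    if path.size > 1:
        lstay, lswitch = _log_trans(np.diff(pos), rate)
        sw = path[1:] != path[:-1]
        lp += float(np.sum(np.where(sw, lswitch, lstay)))
    return lp


def exhaustive_best_path(obs: np.ndarray, pos: np.ndarray, epsilon: float,
                         rate: float) -> tuple[float, np.ndarray]:
    """Brute-force best path over all 2^n assignments (test oracle, n <= 15)."""
    n = obs.size
    if n > 15:
        raise ConfigError("exhaustive path oracle limited to <= 15 loci")
    best_lp, best = -np.inf, np.empty(0, dtype=np.int8)
    for code in range(2 ** n):
        path = np.array([(code >> t) & 1 for t in range(n)], dtype=np.int8)
        lp = path_log_prob(path, obs, pos, epsilon, rate)
        if lp > best_lp:
            best_lp, best = lp, path
    return best_lp, best


def _absorb_short_runs(states: np.ndarray, min_len: int) -> np.ndarray:
    """Merge same-state runs shorter than ``min_len`` into their neighbours.

    Deterministic: repeatedly absorbs the leftmost shortest offending run.
    A lone run is kept regardless of length.
    """
    runs = _runs(states)
    while len(runs) > 1:
        lens = [r[1] - r[0] for r in runs]
        short = [(l, i) for i, l in enumerate(lens) if l < min_len]
        if not short:
            break
        _, i = min(short)
        lo, hi, _ = runs[i]
        if i == 0:
            states[lo:hi] = states[hi]
        elif i == len(runs) - 1:
            states[lo:hi] = states[lo - 1]
        else:
            states[lo:hi] = states[lo - 1]  # flanks share a state by alternation
        runs = _runs(states)
    return states


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, state) runs of a state vector."""
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate(([0], change, [states.size]))
    return [(int(bounds[i]), int(bounds[i + 1]), int(states[bounds[i]]))
            for i in range(bounds.size - 1)]


def viterbi_blocks(genotypes: np.ndarray, consensus: ConsensusHaplotypes,
                   cell: str, chrom: str, chrom_length: int,
                   epsilon: float = 0.02, crossover_rate_per_bp: float = 1e-8,
                   min_block_snps: int = 5,
                   ) -> tuple[list[HaplotypeBlock], list[CrossoverEvent]]:
    """Call haplotype blocks and crossovers for one cell on one chromosome."""
    sl = consensus.panel.chrom_slice(chrom)
    profile = genotype_match_profile(genotypes, consensus)[sl]
    pos = consensus.panel.pos[sl]
    ps = consensus.phase_set[sl]
    informative = profile != NO_CALL

    # phase-set segments (over all loci, informative or not) define the
    # reference intervals between forced block breaks
    seg_ids = np.unique(ps)
    seg_bounds = []
    prev_end = 0
    for si, pid in enumerate(seg_ids):
        idx = np.flatnonzero(ps == pid)
        if si + 1 < seg_ids.size:
            nxt = np.flatnonzero(ps == seg_ids[si + 1])
            end = int((pos[idx[-1]] + pos[nxt[0]] + 1) // 2)
        else:
            end = chrom_length
        seg_bounds.append((prev_end, end, idx))
        prev_end = end

    blocks: list[HaplotypeBlock] = []
    events: list[CrossoverEvent] = []
    for seg_start, seg_end, idx in seg_bounds:
        obs_idx = idx[informative[idx]]
        if obs_idx.size == 0:
            continue
        obs = profile[obs_idx]
        p = pos[obs_idx]
        states = viterbi_path(obs, p, epsilon, crossover_rate_per_bp)
        states = _absorb_short_runs(states, min_block_snps)
        runs = _runs(states)
        for ri, (lo, hi, st) in enumerate(runs):
            b_start = seg_start if ri == 0 else int((p[lo - 1] + p[lo] + 1) // 2)
            b_end = seg_end if ri == len(runs) - 1 else int((p[hi - 1] + p[hi] + 1) // 2)
            inside = obs[lo:hi]
            blocks.append(HaplotypeBlock(
                cell=cell, chrom=chrom, start=b_start, end=b_end,
                origin="A" if st == 0 else "B", n_snps=int(hi - lo),
                mean_match=float(np.mean(inside == st))))
            if ri > 0:
                events.append(CrossoverEvent(
                    cell=cell, chrom=chrom,
                    left_snp_pos=int(p[lo - 1]), right_snp_pos=int(p[lo])))
    return blocks, events


def call_blocks(matrix: GenotypeMatrix, consensus: ConsensusHaplotypes,
                chrom_lengths: dict[str, int], epsilon: float = 0.02,
                crossover_rate_per_bp: float = 1e-8, min_block_snps: int = 5,
                ) -> tuple[CellBlockSet, list[CrossoverEvent]]:
    """Call blocks and crossovers for every cell in a genotype matrix."""
    if not matrix.panel.equals(consensus.panel):
        raise ValueError("matrix and consensus are indexed on different panels")
    all_blocks: list[HaplotypeBlock] = []
    all_events: list[CrossoverEvent] = []
    for ci, cell in enumerate(matrix.cells):
        for chrom, _ in matrix.panel.iter_chroms():
            b, e = viterbi_blocks(
                matrix.data[ci], consensus, cell, chrom, chrom_lengths[chrom],
                epsilon=epsilon, crossover_rate_per_bp=crossover_rate_per_bp,
                min_block_snps=min_block_snps)
            all_blocks.extend(b)
            all_events.extend(e)
    return CellBlockSet(all_blocks), all_events
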