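"""Consensus reconstruction of the two parental haplotypes from gamete genotypes.

Each gamete cell is haploid, so equal genotypes at two loci in one cell are
evidence that the same parental haplotype carries those alleles (a *cis*
link) and unequal genotypes are evidence for *trans*.  Votes from all
qualified cells are chained left-to-right along each chromosome; junctions
with no informative cell or an exactly tied vote open a new phase set
rather than guessing (a wrong guess would silently propagate switch
errors).

Orientation bookkeeping: ``hap_a[j] = 0`` means haplotype A carries the REF
allele at locus j.  The first locus of every phase set is anchored at 0 —
a pure labeling convention removed by swap-aware evaluation.
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .datatypes import GT_MISSING, ConfigError, GenotypeMatrix, SnpPanel


@dataclasses.dataclass
class LinkEdges:
    """Per-cell linkage edges between consecutive non-missing loci.

    Indices are locus positions within one chromosome slice.  ``trans`` is 1
    when the cell's genotypes at the two loci differ.  ``span == j - i``;
    edges with span > 1 arise from missing intermediate observations.
    """

    i: np.ndarray
    j: np.ndarray
    trans: np.ndarray
    cell: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(self.i.size)


@dataclasses.dataclass
class JunctionVotes:
    """Direct-adjacency vote counts per junction (locus i, locus i+1)."""

    cis: np.ndarray    # length n_loci - 1
    trans: np.ndarray

    @property
    def n_informative(self) -> np.ndarray:
        return self.cis + self.trans


@dataclasses.dataclass
class ConsensusHaplotypes:
    """Phased parental haplotypes over a SNP panel.

    ``hap_a`` is the 0/1 (REF/ALT) allele code of haplotype A per locus;
    haplotype B is its complement.  ``phase_set`` is non-decreasing along
    each chromosome and increments exactly where evidence was absent or
    tied.  ``assign_margin`` records the winning-vote margin that placed
    each locus (0 for phase-set anchors).
    """

    panel: SnpPanel
    hap_a: np.ndarray
    phase_set: np.ndarray
    assign_margin: np.ndarray
    junction_votes: dict[str, JunctionVotes] = dataclasses.field(default_factory=dict)

    @property
    def hap_b(self) -> np.ndarray:
        return (1 - self.hap_a).astype(np.int8)

    def n_phase_sets(self) -> int:
        return int(np.unique(self.phase_set).size)

    def alleles(self) -> tuple[np.ndarray, np.ndarray]:
        """(hapA, hapB) as nucleotide strings per locus."""
        a = np.where(self.hap_a == 0, self.panel.ref, self.panel.alt)
        b = np.where(self.hap_a == 0, self.panel.alt, self.panel.ref)
        return a, b


def collect_link_votes(matrix: GenotypeMatrix, max_span: int | None = None,
                       ) -> tuple[dict[str, LinkEdges], dict[str, JunctionVotes]]:
    """Emit per-cell linkage edges and aggregate direct-adjacency votes.

    For every cell and every consecutive pair of non-missing loci in that
    cell, one edge is emitted; only span-1 edges contribute to
    ``JunctionVotes``.  ``max_span`` optionally drops long-range edges.
    """
    edges: dict[str, LinkEdges] = {}
    votes: dict[str, JunctionVotes] = {}
    for chrom, sl in matrix.panel.iter_chroms():
        sub = matrix.data[:, sl]
        n = sub.shape[1]
        ii, jj, tt, cc = [], [], [], []
        for c in range(sub.shape[0]):
            obs = np.flatnonzero(sub[c] != GT_MISSING)
            if obs.size < 2:
                continue
            i, j = obs[:-1], obs[1:]
            tr = (sub[c, i] != sub[c, j]).astype(np.int8)
            if max_span is not None:
                keep = (j - i) <= max_span
                i, j, tr = i[keep], j[keep], tr[keep]
            ii.append(i); jj.append(j); tt.append(tr)
            cc.append(np.full(i.size, c, dtype=np.int32))
        cat = (lambda xs, dt: np.concatenate(xs) if xs else np.empty(0, dt))
        e = LinkEdges(cat(ii, np.int64), cat(jj, np.int64),
                      cat(tt, np.int8), cat(cc, np.int32))
        edges[chrom] = e
        cis = np.zeros(max(n - 1, 0), dtype=np.int64)
        trans = np.zeros(max(n - 1, 0), dtype=np.int64)
        direct = e.j - e.i == 1
        np.add.at(cis, e.i[direct & (e.trans == 0)], 1)
        np.add.at(trans, e.i[direct & (e.trans == 1)], 1)
        votes[chrom] = JunctionVotes(cis, trans)
    return edges, votes


def _phase_chrom(edges: LinkEdges, n_loci: int, first_set_id: int,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Greedy left-to-right vote chaining plus suffix-flip refinement."""
    orient = np.zeros(n_loci, dtype=np.int8)
    ps = np.zeros(n_loci, dtype=np.int64)
    order = np.argsort(edges.j, kind="stable")
    ei, ej, et = edges.i[order], edges.j[order], edges.trans[order]
    bounds = np.searchsorted(ej, np.arange(n_loci + 1))
    set_id = first_set_id
    ps[0] = set_id
    for j in range(1, n_loci):
        lo, hi = bounds[j], bounds[j + 1]
        votes = np.zeros(2, dtype=np.int64)
        for idx in range(lo, hi):
            i = ei[idx]
            if ps[i] == set_id:
                votes[orient[i] ^ et[idx]] += 1
        if votes[0] == votes[1]:
            set_id += 1  # no evidence or exact tie: open a new phase set
            orient[j] = 0
        else:
            orient[j] = int(votes[1] > votes[0])
        ps[j] = set_id
    _refine_suffix_flips(orient, ps, ei, ej, et)
    margin = _assignment_margins(orient, ps, ei, ej, et, bounds)
    return orient, ps, margin, set_id + 1


def _refine_suffix_flips(orient: np.ndarray, ps: np.ndarray, ei: np.ndarray,
                         ej: np.ndarray, et: np.ndarray,
                         max_sweeps: int = 20) -> None:
    """Hill-climb on total satisfied edges by flipping phase-set suffixes.

    Greedy chaining can commit to a locally-winning orientation that a
    later long-span edge contradicts; flipping every locus from a junction
    to the end of its phase set is the minimal move that revisits such a
    decision.  Flips are accepted only when strictly improving, so
    noise-free inputs are never altered.
    """
    in_set = np.flatnonzero(ps[ei] == ps[ej])
    # edges crossing junction j (i < j <= ej), grouped per junction
    crossing: dict[int, list[int]] = {}
    for e in in_set:
        for j in range(int(ei[e]) + 1, int(ej[e]) + 1):
            crossing.setdefault(j, []).append(int(e))
    sat = ((orient[ei] ^ orient[ej]) == et)
    set_end = {}
    for j in range(ps.size - 1, -1, -1):
        set_end.setdefault(int(ps[j]), j + 1)

    def flip(j: int) -> None:
        orient[j:set_end[int(ps[j])]] ^= 1
        for e in crossing.get(j, ()):
            sat[e] = not sat[e]

    def gain(j: int) -> int:
        return sum(1 if not sat[e] else -1 for e in crossing.get(j, ()))

    valid = [j for j in range(1, ps.size) if ps[j] == ps[j - 1]]
    for _ in range(max_sweeps):
        improved = False
        for j in valid:
            if gain(j) > 0:
                flip(j)
                improved = True
        if not improved:
            # single flips converged; try junction pairs that share an edge
            # (the pair leaves the shared edge intact, so it can escape
            # local optima a single suffix flip cannot)
            for e in in_set:
                lo, hi = int(ei[e]) + 1, int(ej[e]) + 1
                if hi - lo < 2:
                    continue
                done = False
                for a in range(lo, hi):
                    if ps[a] != ps[a - 1]:
                        continue
                    for b in range(a + 1, hi):
                        if ps[b] != ps[b - 1]:
                            continue
                        shared = set(crossing.get(a, ())) & set(crossing.get(b, ()))
                        both = sum(2 if sat[x] else -2 for x in shared)
                        if gain(a) + gain(b) + both > 0:
                            flip(a)
                            flip(b)
                            improved = True
                            done = True
                            break
                    if done:
                        break
        if not improved:
            break


def _assignment_margins(orient: np.ndarray, ps: np.ndarray, ei: np.ndarray,
                        ej: np.ndarray, et: np.ndarray, bounds: np.ndarray,
                        ) -> np.ndarray:
    """Signed vote margin backing each locus's final orientation.

    Positive: the chosen orientation won the local vote; negative can occur
    when refinement preferred global consistency over a local majority.
    Phase-set anchors carry margin 0.
    """
    margin = np.zeros(ps.size, dtype=np.int64)
    for j in range(1, ps.size):
        if ps[j] != ps[j - 1]:
            continue
        pro = con = 0
        for idx in range(bounds[j], bounds[j + 1]):
            i = ei[idx]
            if ps[i] == ps[j]:
                if (orient[i] ^ et[idx]) == orient[j]:
                    pro += 1
                else:
                    con += 1
        margin[j] = pro - con
    return margin


def majority_vote_phase(matrix: GenotypeMatrix, max_span: int | None = None,
                        ) -> ConsensusHaplotypes:
    """Reconstruct consensus haplotypes by majority voting over linkage edges."""
    panel = matrix.panel
    edges, votes = collect_link_votes(matrix, max_span=max_span)
    hap = np.zeros(panel.n_loci, dtype=np.int8)
    ps = np.zeros(panel.n_loci, dtype=np.int64)
    margin = np.zeros(panel.n_loci, dtype=np.int64)
    next_id = 0
    for chrom, sl in panel.iter_chroms():
        n = sl.stop - sl.start
        o, p, m, next_id = _phase_chrom(edges[chrom], n, next_id)
        hap[sl], ps[sl], margin[sl] = o, p, m
    return ConsensusHaplotypes(panel, hap, ps, margin, votes)


def exhaustive_phase_oracle(matrix: GenotypeMatrix,
                            ) -> dict[str, tuple[int, list[np.ndarray]]]:
    """Enumerate all orientation assignments; return the max-agreement optima.

    Test oracle only.  For each chromosome returns
    ``(best_score, [optimal assignments with orientation[0] fixed to 0])``
    where score is the number of satisfied cell linkage edges.  Refuses
    more than 12 loci per chromosome.
    """
    edges, _ = collect_link_votes(matrix)
    out: dict[str, tuple[int, list[np.ndarray]]] = {}
    for chrom, sl in matrix.panel.iter_chroms():
        n = sl.stop - sl.start
        if n > 12:
            raise ConfigError("exhaustive oracle limited to <= 12 loci")
        e = edges[chrom]
        best_score, best = -1, []
        for bits in itertools.product((0, 1), repeat=max(n - 1, 0)):
            o = np.array((0,) + bits, dtype=np.int8)
            score = int(np.sum((o[e.i] ^ o[e.j]) == e.trans))
            if score > best_score:
                best_score, best = score, [o]
            elif score == best_score:
                best.append(o)
        out[chrom] = (best_score, best)
    return out
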