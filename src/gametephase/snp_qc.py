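"""SNP-level filtering of gamete-cell variant calls and cell-level QC.

Filtering defaults (all configurable): biallelic SNPs only, QUAL >= 20,
pooled alternate-allele fraction in [0.3, 0.7], distance to the nearest
InDel >= 5 bp.  Per-cell genotypes with supporting depth < 5 are demoted
to missing, as are raw heterozygous calls (a haploid cell cannot truly be
heterozygous; the raw het count feeds cell QC).  Cells with het rate > 5%
or missing rate outside [30%, 70%] are excluded.

Boundary semantics follow the printed comparators: ``>= 20`` inclusive,
``[0.3, 0.7]`` inclusive, ``< 5 bp`` strict (exactly 5 bp away is kept),
``> 5%`` strict, ``< 30% or > 70%`` strict.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datatypes import (GT_ALT, GT_MISSING, GT_REF, GenotypeMatrix,
                        SnpPanel)


@dataclasses.dataclass
class VcfRecord:
    """One parsed variant record (coordinates 0-based internally)."""

    chrom: str
    pos: int            # 0-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    depth: int | None = None       # per-sample DP
    allele_depths: tuple[int, ...] | None = None  # per-sample AD (ref, alt, ...)
    genotype: tuple[int, ...] | None = None       # GT allele indices

    @property
    def is_snp(self) -> bool:
        return (len(self.alts) == 1 and len(self.ref) == 1
                and len(self.alts[0]) == 1)

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref) for a in self.alts) or len(self.ref) > 1


@dataclasses.dataclass
class CellQCReport:
    cell: str
    het_rate: float
    missing_rate: float
    passed: bool
    reason: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def indel_exclusion_positions(records: Iterable[VcfRecord]) -> dict[str, np.ndarray]:
    """Sorted start/end coordinates of InDel records per chromosome."""
    out: dict[str, list[int]] = {}
    for rec in records:
        if rec.is_indel:
            end = rec.pos + len(rec.ref)
            out.setdefault(rec.chrom, []).extend((rec.pos, end))
    return {c: np.unique(np.array(v, dtype=np.int64)) for c, v in out.items()}


def _min_indel_distance(chrom: str, pos: np.ndarray,
                        indels: Mapping[str, np.ndarray]) -> np.ndarray:
    pts = indels.get(chrom)
    if pts is None or pts.size == 0:
        return np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
    idx = np.searchsorted(pts, pos)
    left = np.where(idx > 0, np.abs(pos - pts[np.maximum(idx - 1, 0)]),
                    np.iinfo(np.int64).max)
    right = np.where(idx < pts.size, np.abs(pts[np.minimum(idx, pts.size - 1)] - pos),
                     np.iinfo(np.int64).max)
    return np.minimum(left, right)


def filter_snps(records: Sequence[VcfRecord] | Mapping[str, Sequence[VcfRecord]],
                indels: Mapping[str, np.ndarray] | None = None,
                min_qual: float = 20.0,
                af_lo: float = 0.3, af_hi: float = 0.7,
                indel_distance: int = 5,
                chrom_order: Sequence[str] | None = None) -> SnpPanel:
    """Build the filtered biallelic SNP panel from pooled variant records.

    Records of the same site from several cells are pooled: QUAL is the
    maximum observed and the alternate-allele fraction is computed from
    summed allelic depths.  Multi-allelic records are excluded (not an
    error).  Input must be position-sorted within each chromosome.
    """
    streams: list[Sequence[VcfRecord]]
    if isinstance(records, Mapping):
        streams = list(records.values())
    else:
        streams = [records]
    if indels is None:
        merged: dict[str, np.ndarray] = {}
        for st in streams:
            for c, v in indel_exclusion_positions(st).items():
                merged[c] = np.union1d(merged.get(c, np.empty(0, np.int64)), v)
        indels = merged

    pooled: dict[tuple[str, int, str, str], dict] = {}
    order: list[str] = list(chrom_order) if chrom_order else []
    for stream in streams:
        last: dict[str, int] = {}
        for rec in stream:
            if rec.chrom in last and rec.pos < last[rec.chrom]:
                raise ValueError(f"unsorted input at {rec.chrom}:{rec.pos + 1}")
            last[rec.chrom] = rec.pos
            if rec.chrom not in order:
                order.append(rec.chrom)
            if not rec.is_snp:
                continue
            key = (rec.chrom, rec.pos, rec.ref, rec.alts[0])
            slot = pooled.setdefault(key, {"qual": 0.0, "ref_ad": 0, "alt_ad": 0})
            slot["qual"] = max(slot["qual"], rec.qual)
            if rec.allele_depths is not None and len(rec.allele_depths) >= 2:
                slot["ref_ad"] += rec.allele_depths[0]
                slot["alt_ad"] += rec.allele_depths[1]

    chrom_index, pos, ref, alt, qual = [], [], [], [], []
    for ci, chrom in enumerate(order):
        keys = sorted(k for k in pooled if k[0] == chrom)
        if not keys:
            continue
        p = np.array([k[1] for k in keys], dtype=np.int64)
        q = np.array([pooled[k]["qual"] for k in keys])
        ref_ad = np.array([pooled[k]["ref_ad"] for k in keys], dtype=float)
        alt_ad = np.array([pooled[k]["alt_ad"] for k in keys], dtype=float)
        tot = ref_ad + alt_ad
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(tot > 0, alt_ad / tot, np.nan)
        dist = _min_indel_distance(chrom, p, indels)
        keep = (q >= min_qual) & (dist >= indel_distance)
        keep &= np.where(np.isnan(af), False, (af >= af_lo) & (af <= af_hi))
        # duplicate positions (same site, different alt) are multi-allelic
        dup = np.concatenate(([False], p[1:] == p[:-1])) | \
            np.concatenate((p[:-1] == p[1:], [False]))
        keep &= ~dup
        sel = np.flatnonzero(keep)
        chrom_index.append(np.full(sel.size, ci, dtype=np.int32))
        pos.append(p[sel])
        ref.append(np.array([keys[i][2] for i in sel], dtype="<U1"))
        alt.append(np.array([keys[i][3] for i in sel], dtype="<U1"))
        qual.append(q[sel])

    cat = (lambda xs, dt: np.concatenate(xs) if xs else np.empty(0, dt))
    return SnpPanel(order, cat(chrom_index, np.int32), cat(pos, np.int64),
                    cat(ref, "<U1"), cat(alt, "<U1"), cat(qual, float))


def _call_allele(rec: VcfRecord) -> int | None:
    """REF/ALT/het classification of a per-cell call.

    Uses GT when present; falls back to allelic depths (majority allele)
    otherwise.  Returns GT_REF, GT_ALT or None for heterozygous.
    """
    if rec.genotype is not None and len(rec.genotype) > 0:
        alleles = {a for a in rec.genotype if a is not None}
        if alleles == {0}:
            return GT_REF
        if alleles == {1}:
            return GT_ALT
        return None  # heterozygous (or uncallable mixed)
    if rec.allele_depths is not None and len(rec.allele_depths) >= 2:
        r, a = rec.allele_depths[0], rec.allele_depths[1]
        if r > 0 and a > 0:
            return None
        return GT_ALT if a > r else GT_REF
    return GT_REF


def build_genotype_matrix(cell_records: Mapping[str, Sequence[VcfRecord]],
                          panel: SnpPanel, min_depth: int = 5) -> GenotypeMatrix:
    """Project per-cell calls onto the panel with depth and het demotions."""
    if panel.n_loci == 0:
        raise ValueError("cannot build a genotype matrix on an empty panel")
    contigs = set(panel.chroms)
    locus_of = {(panel.chroms[panel.chrom_index[i]], int(panel.pos[i])): i
                for i in range(panel.n_loci)}
    cells = list(cell_records)
    data = np.full((len(cells), panel.n_loci), GT_MISSING, dtype=np.int8)
    n_called = np.zeros(len(cells), dtype=np.int64)
    n_het = np.zeros(len(cells), dtype=np.int64)
    n_low = np.zeros(len(cells), dtype=np.int64)
    for ci, cell in enumerate(cells):
        for rec in cell_records[cell]:
            if rec.chrom not in contigs:
                raise ValueError(
                    f"cell {cell}: contig {rec.chrom!r} is not in the panel's contig set")
            li = locus_of.get((rec.chrom, rec.pos))
            if li is None:
                continue
            n_called[ci] += 1
            allele = _call_allele(rec)
            if allele is None:
                n_het[ci] += 1
                continue  # demoted to MISSING, counted as raw het
            depth = rec.depth
            if depth is None and rec.allele_depths is not None:
                depth = int(sum(rec.allele_depths))
            if depth is not None and depth < min_depth:
                n_low[ci] += 1
                continue
            data[ci, li] = allele
    return GenotypeMatrix(cells, panel, data, n_called, n_het, n_low)


def qc_cells(matrix: GenotypeMatrix, het_max: float = 0.05,
             miss_lo: float = 0.30, miss_hi: float = 0.70,
             ) -> tuple[list[CellQCReport], GenotypeMatrix]:
    """Exclude cells with abnormal heterozygous or missing-call rates."""
    het = matrix.het_rate()
    miss = matrix.missing_rate()
    reports: list[CellQCReport] = []
    keep = np.ones(matrix.n_cells, dtype=bool)
    for i, cell in enumerate(matrix.cells):
        reasons = []
        if het[i] > het_max:
            reasons.append(f"heterozygous rate > {het_max:.0%}")
        if miss[i] < miss_lo:
            reasons.append(f"missing rate < {miss_lo:.0%}")
        elif miss[i] > miss_hi:
            reasons.append(f"missing rate > {miss_hi:.0%}")
        passed = not reasons
        keep[i] = passed
        reports.append(CellQCReport(cell, float(het[i]), float(miss[i]),
                                    passed, "; ".join(reasons) or "pass"))
    if not keep.any():
        raise ValueError(
            "all cells failed QC; review het/missing thresholds "
            "(downstream phasing is impossible with zero cells)")
    return reports, matrix.subset_cells(keep)
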