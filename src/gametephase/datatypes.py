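"""Shared data containers used across pipeline stages.

Coordinates are 0-based half-open everywhere inside the package and are
converted to 1-based only when writing/reading VCF.
"""
from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np

#: genotype codes used in :class:`GenotypeMatrix`
GT_REF: int = 0
GT_ALT: int = 1
GT_MISSING: int = -1

#: match-profile codes (see :mod:`gametephase.blocks`)
MATCH_A: int = 0
MATCH_B: int = 1
NO_CALL: int = -1


class ConfigError(ValueError):
    """Raised for invalid user-supplied parameters."""


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclasses.dataclass
class SnpPanel:
    """Ordered biallelic SNP loci on which all downstream stages are indexed.

    Loci are grouped by chromosome (in ``chroms`` order) and strictly
    increasing in position within each chromosome.
    """

    chroms: list[str]
    chrom_index: np.ndarray  # int32, per-locus index into ``chroms``
    pos: np.ndarray          # int64, 0-based positions
    ref: np.ndarray          # single-character unicode
    alt: np.ndarray
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom_index = np.asarray(self.chrom_index, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="<U1")
        self.alt = np.asarray(self.alt, dtype="<U1")
        if not (len(self.chrom_index) == len(self.pos) == len(self.ref) == len(self.alt)):
            raise ValueError("panel arrays must have equal length")
        if np.any(np.diff(self.chrom_index) < 0):
            raise ValueError("loci must be grouped by chromosome in panel order")
        for _, sl in self.iter_chroms():
            if np.any(np.diff(self.pos[sl]) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")
        if np.any(self.ref == self.alt):
            raise ValueError("ref and alt alleles must differ at every locus")

    @property
    def n_loci(self) -> int:
        return int(self.pos.size)

    def chrom_slice(self, chrom: str) -> slice:
        ci = self.chroms.index(chrom)
        lo, hi = np.searchsorted(self.chrom_index, [ci, ci + 1])
        return slice(int(lo), int(hi))

    def iter_chroms(self) -> Iterator[tuple[str, slice]]:
        for ci, name in enumerate(self.chroms):
            lo, hi = np.searchsorted(self.chrom_index, [ci, ci + 1])
            if hi > lo:
                yield name, slice(int(lo), int(hi))

    def subset(self, mask: np.ndarray) -> "SnpPanel":
        qual = self.qual[mask] if self.qual is not None else None
        return SnpPanel(self.chroms, self.chrom_index[mask], self.pos[mask],
                        self.ref[mask], self.alt[mask], qual)

    def equals(self, other: "SnpPanel") -> bool:
        return (self.chroms == other.chroms
                and np.array_equal(self.chrom_index, other.chrom_index)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.ref, other.ref)
                and np.array_equal(self.alt, other.alt))


@dataclasses.dataclass
class GenotypeMatrix:
    """Cells x loci genotype observations in {REF, ALT, MISSING}.

    ``n_called`` counts raw non-missing calls per cell (before heterozygous
    and low-depth demotions); ``n_het_raw`` counts raw calls that were
    heterozygous in the haploid cell and were demoted to MISSING;
    ``n_low_depth`` counts calls demoted for insufficient read depth.
    """

    cells: list[str]
    panel: SnpPanel
    data: np.ndarray  # int8, shape (n_cells, n_loci)
    n_called: np.ndarray
    n_het_raw: np.ndarray
    n_low_depth: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.cells), self.panel.n_loci):
            raise ValueError("matrix shape must be (n_cells, n_loci)")
        for name in ("n_called", "n_het_raw", "n_low_depth"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (len(self.cells),):
                raise ValueError(f"{name} must have one entry per cell")
            setattr(self, name, arr)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def missing_rate(self) -> np.ndarray:
        """Fraction of MISSING entries per cell over panel loci."""
        if self.panel.n_loci == 0:
            return np.zeros(self.n_cells)
        return (self.data == GT_MISSING).mean(axis=1)

    def het_rate(self) -> np.ndarray:
        """Raw heterozygous-call rate per cell (het calls / raw calls)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.n_het_raw / self.n_called
        return np.where(self.n_called > 0, r, 0.0)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Restrict to a subset of panel loci (raw-call counters recomputed)."""
        mask = np.asarray(mask, dtype=bool)
        data = self.data[:, mask]
        return GenotypeMatrix(
            list(self.cells), self.panel.subset(mask), data,
            (data != GT_MISSING).sum(axis=1),
            np.zeros(len(self.cells), dtype=np.int64),
            np.zeros(len(self.cells), dtype=np.int64))

    def subset_cells(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            [self.cells[i] for i in idx], self.panel, self.data[idx],
            self.n_called[idx], self.n_het_raw[idx], self.n_low_depth[idx])


@dataclasses.dataclass
class ReadSet:
    """Mapped placements of fixed-coordinate reads, optionally with truth origin.

    ``origin`` holds the simulated parental origin (0=A, 1=B, -1 unknown);
    ``mate`` holds the index of the paired mate or -1 for single-end reads.
    """

    cells: list[str]
    chroms: list[str]
    cell_idx: np.ndarray
    chrom_idx: np.ndarray
    start: np.ndarray
    end: np.ndarray
    origin: np.ndarray | None = None
    mate: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_idx = np.asarray(self.cell_idx, dtype=np.int32)
        self.chrom_idx = np.asarray(self.chrom_idx, dtype=np.int32)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        n = self.cell_idx.size
        if not (self.chrom_idx.size == self.start.size == self.end.size == n):
            raise ValueError("placement arrays must have equal length")
        if n and np.any(self.start >= self.end):
            raise ValueError("placements require start < end")
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=np.int8)
        if self.mate is not None:
            self.mate = np.asarray(self.mate, dtype=np.int64)

    @property
    def n_reads(self) -> int:
        return int(self.cell_idx.size)

    def read_ids(self) -> np.ndarray:
        if self.ids is not None:
            return self.ids
        return np.array([f"read{i:08d}" for i in range(self.n_reads)])

    def subset(self, mask: np.ndarray) -> "ReadSet":
        mask = np.asarray(mask)
        return ReadSet(
            self.cells, self.chroms,
            self.cell_idx[mask], self.chrom_idx[mask],
            self.start[mask], self.end[mask],
            None if self.origin is None else self.origin[mask],
            None,  # mate links are not preserved across subsetting
            None if self.ids is None else self.ids[mask])
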