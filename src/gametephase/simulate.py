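"""Synthetic diploid genomes, meiosis, and amplification-biased gamete observations.

The simulator produces a complete truth record (haplotypes, per-cell
crossover positions, per-read origins) so that every downstream stage can
be scored exactly.  All randomness derives from ``SimConfig.seed`` through
named child streams, so each operation is reproducible independently of
call order.

Model choices (deliberate simplifications):

* crossovers: Poisson count per chromosome, uniform positions, no
  interference and no obligate crossover; cells are independent gametes
  (tetrad structure is not modelled);
* amplification bias: per-cell multiplicative Gamma factor per genomic
  window (mean 1); windows in the lowest quantile of the factor are
  dropped entirely, which realizes the target missing-call fraction;
* reads are error-free; genotype error is injected at the genotype level
  since downstream stages consume genotypes, not base calls.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .datatypes import (GT_MISSING, ConfigError, GenotypeMatrix, ReadSet,
                        SnpPanel)

_STREAMS = ("genome", "meiosis", "mda", "observations", "reads")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameter envelope for one simulation run."""

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    snp_rate: float = 0.002
    n_cells: int = 30
    crossover_lambda: float = 2.0
    genotype_error: float = 0.01
    missing_rate_target: float = 0.40
    het_call_rate: float = 0.0
    mda_window: int = 10_000
    mda_gamma_shape: float = 0.8
    read_length: int = 100
    mean_depth: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1 or self.n_cells < 1:
            raise ConfigError("counts and lengths must be positive")
        for name in ("snp_rate", "genotype_error", "missing_rate_target", "het_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.snp_rate > 0 and self.snp_rate * self.chrom_length < 2:
            raise ConfigError("snp_rate * chrom_length must be >= 2 (or snp_rate == 0)")
        if self.crossover_lambda < 0 or self.mda_gamma_shape <= 0:
            raise ConfigError("crossover_lambda must be >= 0 and mda_gamma_shape > 0")
        if self.mda_window < 1 or self.read_length < 1 or self.mean_depth < 0:
            raise ConfigError("mda_window, read_length, mean_depth must be positive")

    def n_windows(self) -> int:
        return -(-self.chrom_length // self.mda_window)


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclasses.dataclass
class SimTruth:
    """Ground truth for one simulation: genome, meiosis paths and reads."""

    config: SimConfig
    chrom_names: list[str]
    hap_a: list[np.ndarray]  # uint8 base codes per chromosome
    hap_b: list[np.ndarray]
    panel: SnpPanel          # REF = hapA allele, ALT = hapB allele
    # meiosis: filled by simulate_meiosis
    cell_breaks: list[list[np.ndarray]] | None = None   # [cell][chrom] sorted breakpoints
    cell_start_origin: np.ndarray | None = None          # (n_cells, n_chrom), 0=A 1=B
    # reads: filled by simulate_cell_reads
    reads: ReadSet | None = None

    def origin_at(self, cell: int, chrom: int, positions: np.ndarray) -> np.ndarray:
        """Parental origin (0=A, 1=B) of a cell's gamete at reference positions."""
        if self.cell_breaks is None:
            raise ValueError("meiosis has not been simulated")
        breaks = self.cell_breaks[cell][chrom]
        parity = np.searchsorted(breaks, np.asarray(positions), side="right") & 1
        return (self.cell_start_origin[cell, chrom] ^ parity).astype(np.int8)

    def gamete_codes(self, cell: int, chrom: int) -> np.ndarray:
        """2-bit encoded gamete chromosome sequence (mosaic of hapA/hapB)."""
        sl = self.panel.chrom_slice(self.chrom_names[chrom])
        pos = self.panel.pos[sl]
        seq = self.hap_a[chrom].copy()
        from_b = self.origin_at(cell, chrom, pos) == 1
        seq[pos[from_b]] = self.hap_b[chrom][pos[from_b]]
        return seq

    def snp_origin(self, cell: int, chrom: int) -> np.ndarray:
        sl = self.panel.chrom_slice(self.chrom_names[chrom])
        return self.origin_at(cell, chrom, self.panel.pos[sl])

    def n_crossovers(self) -> np.ndarray:
        """Crossover counts per (cell, chromosome)."""
        cfg = self.config
        out = np.zeros((cfg.n_cells, cfg.n_chromosomes), dtype=np.int64)
        for c in range(cfg.n_cells):
            for ch in range(cfg.n_chromosomes):
                out[c, ch] = self.cell_breaks[c][ch].size
        return out


def simulate_diploid_genome(cfg: SimConfig) -> SimTruth:
    """Draw the two parental haplotype sequences and the heterozygous SNP panel."""
    cfg.validate()
    rng = _rng(cfg, "genome")
    names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    hap_a, hap_b = [], []
    chrom_index, pos, ref, alt = [], [], [], []
    for ci in range(cfg.n_chromosomes):
        seq = rng.integers(0, 4, size=cfg.chrom_length, dtype=np.uint8)
        n_snp = rng.binomial(cfg.chrom_length, cfg.snp_rate)
        loci = np.sort(rng.choice(cfg.chrom_length, size=n_snp, replace=False))
        alt_codes = (seq[loci] + rng.integers(1, 4, size=n_snp, dtype=np.uint8)) % 4
        other = seq.copy()
        other[loci] = alt_codes
        hap_a.append(seq)
        hap_b.append(other)
        chrom_index.append(np.full(n_snp, ci, dtype=np.int32))
        pos.append(loci.astype(np.int64))
        ref.append(seq[loci])
        alt.append(alt_codes)
    bases = np.array(list("ACGT"))
    panel = SnpPanel(
        names,
        np.concatenate(chrom_index) if chrom_index else np.empty(0, np.int32),
        np.concatenate(pos) if pos else np.empty(0, np.int64),
        bases[np.concatenate(ref).astype(int)] if ref and sum(r.size for r in ref) else np.empty(0, "<U1"),
        bases[np.concatenate(alt).astype(int)] if alt and sum(a.size for a in alt) else np.empty(0, "<U1"),
    )
    return SimTruth(cfg, names, hap_a, hap_b, panel)


def simulate_meiosis(truth: SimTruth) -> SimTruth:
    """Draw per-cell crossover breakpoints and starting parental origins in place."""
    cfg = truth.config
    rng = _rng(cfg, "meiosis")
    breaks: list[list[np.ndarray]] = []
    start = np.zeros((cfg.n_cells, cfg.n_chromosomes), dtype=np.int8)
    for c in range(cfg.n_cells):
        per_chrom = []
        for ch in range(cfg.n_chromosomes):
            n = rng.poisson(cfg.crossover_lambda)
            bp = np.unique(rng.integers(1, cfg.chrom_length, size=n))
            per_chrom.append(bp.astype(np.int64))
            start[c, ch] = rng.integers(0, 2)
        breaks.append(per_chrom)
    truth.cell_breaks = breaks
    truth.cell_start_origin = start
    return truth


def mda_amplification_factors(cfg: SimConfig) -> np.ndarray:
    """Per-window amplification factors ~ Gamma(shape, 1/shape), mean 1.

    Shape: (n_cells, n_chromosomes, n_windows).  Shared by the genotype
    dropout model and the read-depth model so low-amplification windows are
    simultaneously read-poor and call-missing.
    """
    rng = _rng(cfg, "mda")
    shape = cfg.mda_gamma_shape
    return rng.gamma(shape, 1.0 / shape,
                     size=(cfg.n_cells, cfg.n_chromosomes, cfg.n_windows()))


def simulate_cell_observations(truth: SimTruth) -> GenotypeMatrix:
    """Project each cell's gamete onto the SNP panel with error, het and dropout."""
    cfg = truth.config
    if truth.cell_breaks is None:
        raise ValueError("run simulate_meiosis first")
    factors = mda_amplification_factors(cfg)
    rng = _rng(cfg, "observations")
    n_loci = truth.panel.n_loci
    data = np.full((cfg.n_cells, n_loci), GT_MISSING, dtype=np.int8)
    n_called = np.zeros(cfg.n_cells, dtype=np.int64)
    n_het = np.zeros(cfg.n_cells, dtype=np.int64)
    for c in range(cfg.n_cells):
        for ch, name in enumerate(truth.chrom_names):
            sl = truth.panel.chrom_slice(name)
            pos = truth.panel.pos[sl]
            if pos.size == 0:
                continue
            gt = truth.origin_at(c, ch, pos).astype(np.int8)  # REF=hapA convention
            if cfg.genotype_error > 0:
                flip = rng.random(pos.size) < cfg.genotype_error
                gt = np.where(flip, 1 - gt, gt)
            het = (rng.random(pos.size) < cfg.het_call_rate) if cfg.het_call_rate > 0 \
                else np.zeros(pos.size, dtype=bool)
            f = factors[c, ch]
            if cfg.missing_rate_target > 0:
                thr = np.quantile(f, cfg.missing_rate_target)
                dropped = f[pos // cfg.mda_window] < thr
            else:
                dropped = np.zeros(pos.size, dtype=bool)
            called = ~dropped
            n_called[c] += int(called.sum())
            n_het[c] += int((called & het).sum())
            out = np.where(called & ~het, gt, GT_MISSING).astype(np.int8)
            data[c, sl] = out
    return GenotypeMatrix([f"cell{i:03d}" for i in range(cfg.n_cells)],
                          truth.panel, data, n_called, n_het,
                          np.zeros(cfg.n_cells, dtype=np.int64))


def simulate_cell_reads(truth: SimTruth) -> ReadSet:
    """Sample error-free fixed-length reads with window-level depth bias.

    Each read records its placement on the reference coordinate system and
    the parental origin of the segment covering its midpoint.
    """
    cfg = truth.config
    if truth.cell_breaks is None:
        raise ValueError("run simulate_meiosis first")
    if cfg.read_length > cfg.chrom_length:
        raise ConfigError("read_length exceeds chrom_length")
    factors = mda_amplification_factors(cfg)
    rng = _rng(cfg, "reads")
    L, rl, w = cfg.chrom_length, cfg.read_length, cfg.mda_window
    n_win = cfg.n_windows()
    win_start = np.arange(n_win, dtype=np.int64) * w
    win_end = np.minimum(win_start + w, L - rl + 1)
    valid = win_end > win_start
    width = np.where(valid, win_end - win_start, 0)
    span = np.minimum(win_start + w, L) - win_start  # bases covered by window

    cell_idx, chrom_idx, starts, origins = [], [], [], []
    for c in range(cfg.n_cells):
        for ch in range(cfg.n_chromosomes):
            lam = cfg.mean_depth * span / rl * factors[c, ch] * valid
            n_per = rng.poisson(lam)
            total = int(n_per.sum())
            if total == 0:
                continue
            base = np.repeat(win_start, n_per)
            wid = np.repeat(width, n_per)
            s = base + np.floor(rng.random(total) * wid).astype(np.int64)
            cell_idx.append(np.full(total, c, dtype=np.int32))
            chrom_idx.append(np.full(total, ch, dtype=np.int32))
            starts.append(s)
            origins.append(truth.origin_at(c, ch, s + rl // 2))
    cat = (lambda xs, dt: np.concatenate(xs) if xs else np.empty(0, dt))
    s = cat(starts, np.int64)
    reads = ReadSet(
        cells=[f"cell{i:03d}" for i in range(cfg.n_cells)],
        chroms=list(truth.chrom_names),
        cell_idx=cat(cell_idx, np.int32), chrom_idx=cat(chrom_idx, np.int32),
        start=s, end=s + rl, origin=cat(origins, np.int8))
    truth.reads = reads
    return reads


def read_sequences(truth: SimTruth, reads: ReadSet) -> list[str]:
    """Materialize read nucleotide strings from the gamete mosaic sequences."""
    from .kmers import decode
    cache: dict[tuple[int, int], np.ndarray] = {}
    out = []
    for i in range(reads.n_reads):
        key = (int(reads.cell_idx[i]), int(reads.chrom_idx[i]))
        if key not in cache:
            cache[key] = truth.gamete_codes(*key)
        out.append(decode(cache[key][reads.start[i]:reads.end[i]]))
    return out


def simulate_all(cfg: SimConfig) -> tuple[SimTruth, GenotypeMatrix, ReadSet]:
    """Convenience wrapper: genome + meiosis + observations + reads."""
    truth = simulate_meiosis(simulate_diploid_genome(cfg))
    matrix = simulate_cell_observations(truth)
    reads = simulate_cell_reads(truth)
    return truth, matrix, reads
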