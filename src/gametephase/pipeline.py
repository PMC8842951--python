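"""End-to-end pipeline driver: simulate/ingest -> QC -> phase -> blocks ->
partition -> normalize -> evaluate, with a JSON run report.

All stage randomness flows from a single seed.  The report echoes every
parameter (full provenance) and per-stage counts that reconcile with the
conservation invariants of the individual modules.
"""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Any

import numpy as np

from . import io as gio
from .blocks import call_blocks
from .datatypes import ConfigError
from .evaluation import (aggregate_ppv, compute_hapmers, crossover_recovery,
                         score_pool, switch_error, truth_hap_codes)
from .partition import (genome_backed_kmers, normalize_by_kmer_depth,
                        partition_reads, per_window_depth)
from .phasing import majority_vote_phase
from .simulate import SimConfig, read_sequences, simulate_all
from .snp_qc import qc_cells

_PIPELINE_FIELDS = {
    "het_max": 0.05, "miss_lo": 0.30, "miss_hi": 0.70, "min_depth": 5,
    "epsilon": 0.02, "crossover_rate_per_bp": 1e-8, "min_block_snps": 5,
    "kmer_size": 21, "normalize_k": 31, "target_depth": None,
    "write_fastq": False, "log_level": "INFO",
}


@dataclasses.dataclass
class PipelineConfig:
    """Stage parameters for a full run.  Unknown keys are rejected."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    het_max: float = 0.05
    miss_lo: float = 0.30
    miss_hi: float = 0.70
    min_depth: int = 5
    epsilon: float = 0.02
    crossover_rate_per_bp: float = 1e-8
    min_block_snps: int = 5
    kmer_size: int = 21
    normalize_k: int = 31
    target_depth: float | None = None
    write_fastq: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim_keys = {f.name for f in dataclasses.fields(SimConfig)}
        sim_args = {k: d.pop(k) for k in list(d) if k in sim_keys}
        unknown = set(d) - set(_PIPELINE_FIELDS)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(sim=SimConfig(**sim_args), **d)

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self.sim)
        d.update({k: getattr(self, k) for k in _PIPELINE_FIELDS})
        return d


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 evaluate: bool = True) -> dict[str, Any]:
    """Run the simulated end-to-end pipeline and write all stage outputs.

    Returns the run report (also written to ``outdir/run_report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"parameters": cfg.as_dict(), "seed": cfg.sim.seed,
                              "stages": {}}

    def stage(name: str):
        t0 = time.time()

        def done(**counts: Any) -> None:
            report["stages"][name] = {"wall_time_s": round(time.time() - t0, 3),
                                      **counts}
        return done

    # ---- simulate
    done = stage("simulate")
    truth, matrix, reads = simulate_all(cfg.sim)
    done(n_loci=truth.panel.n_loci, n_cells=cfg.sim.n_cells,
         n_reads=reads.n_reads,
         n_true_crossovers=int(truth.n_crossovers().sum()))
    gio.write_panel_vcf(outdir / "panel.vcf", truth.panel)
    gio.write_placements_tsv(outdir / "placements.tsv", reads)
    gio.write_genotype_matrix(outdir / "genotype_matrix.tsv", matrix)
    if cfg.write_fastq:
        seqs = read_sequences(truth, reads)
        ids = reads.read_ids()
        for ci, cell in enumerate(reads.cells):
            mask = reads.cell_idx == ci
            gio.write_fastq(outdir / f"{cell}.fastq",
                            ((ids[i], seqs[i]) for i in np.flatnonzero(mask)))

    # ---- cell QC
    done = stage("qc_cells")
    reports, qmatrix = qc_cells(matrix, cfg.het_max, cfg.miss_lo, cfg.miss_hi)
    gio.write_qc_report(outdir / "cell_qc", reports)
    done(cells_in=matrix.n_cells, cells_passed=qmatrix.n_cells)

    # ---- consensus phasing
    done = stage("phase")
    consensus = majority_vote_phase(qmatrix)
    gio.write_phased_vcf(outdir / "haplotypes.vcf", consensus)
    gio.write_haplotypes_tsv(outdir / "haplotypes.tsv", consensus)
    gio.write_junction_votes_tsv(outdir / "junction_votes.tsv", consensus)
    done(n_phased_loci=truth.panel.n_loci, n_phase_sets=consensus.n_phase_sets())

    # ---- block / crossover calling
    done = stage("call_blocks")
    chrom_lengths = {c: cfg.sim.chrom_length for c in truth.chrom_names}
    blockset, events = call_blocks(
        qmatrix, consensus, chrom_lengths, epsilon=cfg.epsilon,
        crossover_rate_per_bp=cfg.crossover_rate_per_bp,
        min_block_snps=cfg.min_block_snps)
    gio.write_blocks_tsv(outdir / "blocks.tsv", blockset.blocks)
    gio.write_crossovers_tsv(outdir / "crossovers.tsv", events)
    done(n_blocks=len(blockset.blocks), n_crossovers=len(events))

    # ---- read partition (reads of QC-failed cells are left unassigned)
    done = stage("partition")
    part = partition_reads(reads, blockset)
    done(reads_in=reads.n_reads, pool_a=part.n_pool_a, pool_b=part.n_pool_b,
         unassigned=part.n_unassigned)
    assert part.n_pool_a + part.n_pool_b + part.n_unassigned == reads.n_reads

    # ---- k-mer depth normalization (per pool, merged across cells)
    norm_masks = {}
    if cfg.target_depth is not None:
        done = stage("normalize")
        counts = {}
        for label, origin in (("A", 0), ("B", 1)):
            mask = part.assignment == origin
            factory = genome_backed_kmers(truth, reads, cfg.normalize_k, mask)
            keep = normalize_by_kmer_depth(
                factory, cfg.normalize_k, cfg.target_depth, cfg.sim.seed)
            full = np.zeros(reads.n_reads, dtype=bool)
            full[np.flatnonzero(mask)] = keep
            norm_masks[label] = full
            counts[f"pool_{label}_in"] = int(mask.sum())
            counts[f"pool_{label}_kept"] = int(keep.sum())
        done(**counts)

    # ---- evaluation against simulation truth
    if evaluate:
        done = stage("evaluate")
        score = switch_error(consensus, truth_hap_codes(truth))
        recovery = crossover_recovery(events, truth)
        hapmers = compute_hapmers(
            (truth.hap_a[i] for i in range(cfg.sim.n_chromosomes)),
            (truth.hap_b[i] for i in range(cfg.sim.n_chromosomes)),
            k=cfg.kmer_size)
        pool_scores = []
        for label, origin in (("A", 0), ("B", 1)):
            mask = norm_masks.get(label)
            if mask is None:
                mask = part.assignment == origin
            factory = genome_backed_kmers(truth, reads, cfg.kmer_size, mask)
            pool_scores.append(score_pool(factory(), hapmers, name=f"pool_{label}"))
        assigned = part.assignment >= 0
        purity = float("nan")
        if assigned.any() and reads.origin is not None:
            purity = float(np.mean(
                part.assignment[assigned] == reads.origin[assigned]))
        done(switch_error_rate=score.switch_error_rate,
             hamming_accuracy=score.hamming_accuracy,
             crossover_recall=recovery["recall"],
             crossover_precision=recovery["precision"],
             false_crossovers_per_cell_chrom=recovery["false_per_cell_chrom"],
             assigned_purity=purity,
             pool_ppv={s.name: s.ppv for s in pool_scores},
             aggregate_ppv=aggregate_ppv(pool_scores))

    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report


def depth_cv(reads, chrom_lengths: dict[str, int], window: int = 10_000,
             mask=None) -> float:
    """Coefficient of variation of pooled per-window depth (evenness metric)."""
    depths = per_window_depth(reads, chrom_lengths, window, mask)
    allw = np.concatenate(list(depths.values()))
    return float(allw.std() / allw.mean()) if allw.mean() > 0 else float("nan")
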