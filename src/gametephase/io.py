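"""File-format adapters.

Conventions, stated in every header we write: VCF POS is 1-based; all
BED-like TSV intervals are 0-based half-open.  Plain and gzip-compressed
text are accepted everywhere.
"""
from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .blocks import CrossoverEvent, HaplotypeBlock
from .datatypes import (GT_MISSING, FormatError, GenotypeMatrix, ReadSet,
                        SnpPanel)
from .phasing import ConsensusHaplotypes
from .snp_qc import CellQCReport, VcfRecord


def _open_text(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------- VCF

def read_vcf(path: str | Path, sample: str | None = None) -> list[VcfRecord]:
    """Parse a VCF into :class:`VcfRecord` (positions converted to 0-based).

    Accepts plain text, BGZF and ordinary gzip (decompressed to a temporary
    file first, since htslib only reads BGZF).
    """
    path = Path(path)
    if path.suffix == ".gz":
        with open(path, "rb") as fh:
            head = fh.read(18)
        is_bgzf = head[:4] == b"\x1f\x8b\x08\x04" and b"BC" in head[10:18]
        if not is_bgzf:  # ordinary gzip: re-inflate for pysam/htslib
            import tempfile
            with gzip.open(path, "rb") as fh, \
                    tempfile.NamedTemporaryFile("wb", suffix=".vcf",
                                                delete=False) as tmp:
                tmp.write(fh.read())
                tmp_path = tmp.name
            try:
                return read_vcf(tmp_path, sample)
            finally:
                Path(tmp_path).unlink(missing_ok=True)
    out: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if sample is None and samples:
            sample = samples[0]
        for rec in vf:
            depth = ad = gt = None
            if sample is not None and sample in rec.samples:
                fmt = rec.samples[sample]
                if "DP" in fmt and fmt["DP"] is not None:
                    depth = int(fmt["DP"])
                if "AD" in fmt and fmt["AD"] is not None and fmt["AD"][0] is not None:
                    ad = tuple(int(x) for x in fmt["AD"])
                if "GT" in fmt and fmt["GT"] is not None and fmt["GT"][0] is not None:
                    gt = tuple(fmt["GT"])
            out.append(VcfRecord(
                chrom=rec.chrom, pos=rec.start, ref=rec.ref,
                alts=tuple(rec.alts or ()),
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                depth=depth, allele_depths=ad, genotype=gt))
    return out


def write_panel_vcf(path: str | Path, panel: SnpPanel) -> None:
    """Write the SNP panel as a minimal sites-only VCF."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in panel.chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        qual = panel.qual if panel.qual is not None else np.full(panel.n_loci, 60.0)
        for i in range(panel.n_loci):
            fh.write(f"{panel.chroms[panel.chrom_index[i]]}\t{panel.pos[i] + 1}\t.\t"
                     f"{panel.ref[i]}\t{panel.alt[i]}\t{qual[i]:g}\tPASS\t.\n")


def write_cell_vcf(path: str | Path, records: Sequence[VcfRecord],
                   sample: str, contigs: Sequence[str]) -> None:
    """Write one cell's calls with DP/AD/GT FORMAT fields."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for rec in records:
            alts = ",".join(rec.alts) if rec.alts else "."
            gt = "./." if rec.genotype is None else "/".join(str(a) for a in rec.genotype)
            dp = "." if rec.depth is None else str(rec.depth)
            ad = "." if rec.allele_depths is None else ",".join(map(str, rec.allele_depths))
            fh.write(f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t{alts}\t"
                     f"{rec.qual:g}\tPASS\t.\tGT:DP:AD\t{gt}:{dp}:{ad}\n")


def write_phased_vcf(path: str | Path, consensus: ConsensusHaplotypes) -> None:
    """Write consensus haplotypes as a 1-sample phased VCF with PS tags."""
    panel = consensus.panel
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in panel.chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tconsensus\n")
        for i in range(panel.n_loci):
            gt = "0|1" if consensus.hap_a[i] == 0 else "1|0"
            fh.write(f"{panel.chroms[panel.chrom_index[i]]}\t{panel.pos[i] + 1}\t.\t"
                     f"{panel.ref[i]}\t{panel.alt[i]}\t.\tPASS\t.\tGT:PS\t"
                     f"{gt}:{consensus.phase_set[i]}\n")


# -------------------------------------------------------------- FASTA/FASTQ

def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs with uniform maximal quality (reads are
    simulated error-free; plain writer is used for speed at scale)."""
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]


# ---------------------------------------------------------------- TSV forms

def write_genotype_matrix(path: str | Path, matrix: GenotypeMatrix) -> None:
    """Rows = loci, columns = cells, values 0/1/NA."""
    panel = matrix.panel
    df = pd.DataFrame({
        "chrom": [panel.chroms[i] for i in panel.chrom_index],
        "pos": panel.pos, "ref": panel.ref, "alt": panel.alt})
    body = pd.DataFrame(matrix.data.T, columns=matrix.cells).astype("object")
    body[matrix.data.T == GT_MISSING] = "NA"
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False)
    meta = Path(str(path) + ".counts.json")
    meta.write_text(json.dumps({
        "cells": matrix.cells,
        "n_called": matrix.n_called.tolist(),
        "n_het_raw": matrix.n_het_raw.tolist(),
        "n_low_depth": matrix.n_low_depth.tolist()}, indent=1))


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     keep_default_na=False)
    cells = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    chroms = list(dict.fromkeys(df["chrom"]))
    panel = SnpPanel(chroms, [chroms.index(c) for c in df["chrom"]],
                     df["pos"].to_numpy(), df["ref"].to_numpy(), df["alt"].to_numpy())
    body = df[cells].replace("NA", GT_MISSING).apply(pd.to_numeric)
    data = body.to_numpy(dtype=np.int8).T
    meta_path = Path(str(path) + ".counts.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        n_called = np.array(meta["n_called"])
        n_het = np.array(meta["n_het_raw"])
        n_low = np.array(meta["n_low_depth"])
    else:
        n_called = (data != GT_MISSING).sum(axis=1)
        n_het = np.zeros(len(cells), dtype=np.int64)
        n_low = np.zeros(len(cells), dtype=np.int64)
    return GenotypeMatrix(cells, panel, data, n_called, n_het, n_low)


def write_blocks_tsv(path: str | Path, blocks: Sequence[HaplotypeBlock]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        fh.write("chrom\tstart\tend\tcell\torigin\tn_snps\tmean_match\n")
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.cell}\t{b.origin}\t"
                     f"{b.n_snps}\t{b.mean_match:.4f}\n")


def read_blocks_tsv(path: str | Path) -> list[HaplotypeBlock]:
    out = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 7:
                raise FormatError(f"{path}:{ln}: expected 7 columns, got {len(f)}")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise FormatError(f"{path}:{ln}: start >= end")
            out.append(HaplotypeBlock(cell=f[3], chrom=f[0], start=start, end=end,
                                      origin=f[4], n_snps=int(f[5]),
                                      mean_match=float(f[6])))
    return out


def write_crossovers_tsv(path: str | Path, events: Sequence[CrossoverEvent]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("# positions are 0-based\n")
        fh.write("cell\tchrom\tleft_snp_pos\tright_snp_pos\tmidpoint\n")
        for e in events:
            fh.write(f"{e.cell}\t{e.chrom}\t{e.left_snp_pos}\t{e.right_snp_pos}\t"
                     f"{e.midpoint:.1f}\n")


def write_placements_tsv(path: str | Path, reads: ReadSet) -> None:
    """6-column placement table: read_id, cell, chrom, start, end, truth_origin."""
    ids = reads.read_ids()
    with _open_text(path, "wt") as fh:
        fh.write("# intervals are 0-based half-open; origin -1 = unknown\n")
        fh.write("read_id\tcell\tchrom\tstart\tend\ttruth_origin\n")
        origin = reads.origin if reads.origin is not None \
            else np.full(reads.n_reads, -1, dtype=np.int8)
        for i in range(reads.n_reads):
            fh.write(f"{ids[i]}\t{reads.cells[reads.cell_idx[i]]}\t"
                     f"{reads.chroms[reads.chrom_idx[i]]}\t{reads.start[i]}\t"
                     f"{reads.end[i]}\t{origin[i]}\n")


def read_placements_tsv(path: str | Path) -> ReadSet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"cell": str, "chrom": str})
    cells = list(dict.fromkeys(df["cell"]))
    chroms = list(dict.fromkeys(df["chrom"]))
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise FormatError(f"{path}: start >= end at data row {bad[0] + 1}")
    return ReadSet(
        cells, chroms,
        np.array([cells.index(c) for c in df["cell"]], dtype=np.int32),
        np.array([chroms.index(c) for c in df["chrom"]], dtype=np.int32),
        df["start"].to_numpy(), df["end"].to_numpy(),
        df["truth_origin"].to_numpy(np.int8) if "truth_origin" in df else None,
        ids=df["read_id"].to_numpy())


def write_qc_report(prefix: str | Path, reports: Sequence[CellQCReport]) -> None:
    rows = [r.as_dict() for r in reports]
    pd.DataFrame(rows).to_csv(f"{prefix}.tsv", sep="\t", index=False)
    Path(f"{prefix}.json").write_text(json.dumps(rows, indent=1))


def write_junction_votes_tsv(path: str | Path, consensus: ConsensusHaplotypes) -> None:
    panel = consensus.panel
    with _open_text(path, "wt") as fh:
        fh.write("chrom\tpos_i\tpos_j\tcis\ttrans\tmargin\n")
        for chrom, sl in panel.iter_chroms():
            votes = consensus.junction_votes.get(chrom)
            if votes is None:
                continue
            pos = panel.pos[sl]
            margin = consensus.assign_margin[sl]
            for i in range(pos.size - 1):
                fh.write(f"{chrom}\t{pos[i]}\t{pos[i + 1]}\t{votes.cis[i]}\t"
                         f"{votes.trans[i]}\t{margin[i + 1]}\n")


def write_haplotypes_tsv(path: str | Path, consensus: ConsensusHaplotypes) -> None:
    panel = consensus.panel
    hap_a, hap_b = consensus.alleles()
    pd.DataFrame({
        "chrom": [panel.chroms[i] for i in panel.chrom_index],
        "pos": panel.pos, "hapA": hap_a, "hapB": hap_b,
        "phase_set": consensus.phase_set,
        "assign_margin": consensus.assign_margin,
    }).to_csv(path, sep="\t", index=False)
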