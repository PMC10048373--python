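"""Readers and writers for the plain-text formats the pipeline consumes.

bedGraph depth tracks, VCF 4.2 (parsed with cyvcf2), PSL-like synteny-block
TSV, FASTA index (fai) length tables, jellyfish-histo-compatible 2-column
k-mer histograms, and BED/JSON result files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .covsex import ParCall, SexInference
from .hetscan import HetTrack, VariantRecord
from .synthgen import GenomeModel, SimVariant
from .syntkar import InversionCall, SyntenyBlock, SyntenyBlockSet

__all__ = [
    "write_bedgraph",
    "read_bedgraph",
    "write_vcf",
    "read_vcf",
    "write_blocks_tsv",
    "read_blocks_tsv",
    "read_fai",
    "write_fai",
    "write_kmer_histogram",
    "read_kmer_histogram",
    "write_genome_fasta",
    "write_par_bed",
    "write_par_json",
    "write_het_track",
    "write_inversions_tsv",
    "write_fastq",
]


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(depth: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encoded 0-based half-open bedGraph; zero-depth runs kept."""
    with open(path, "w") as fh:
        for chrom, arr in depth.items():
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]}\n")


def read_bedgraph(
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-base depth arrays.

    Positions not covered by any interval get depth 0. When
    ``chrom_lengths`` is given, arrays are allocated at those lengths (and
    chromosomes with no intervals still appear, all zero); otherwise each
    array extends to the last interval end seen.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            intervals.setdefault(chrom, []).append((int(s), int(e), float(v)))
    out: dict[str, np.ndarray] = {}
    names = chrom_lengths.keys() if chrom_lengths else intervals.keys()
    for chrom in names:
        ivs = intervals.get(chrom, [])
        length = (
            chrom_lengths[chrom]
            if chrom_lengths
            else max((e for _, e, _ in ivs), default=0)
        )
        arr = np.zeros(length, dtype=np.int32)
        for s, e, v in ivs:
            arr[s:e] = int(v)
        out[chrom] = arr
    return out


# --------------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=selkie
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=SP,Number=1,Type=Integer,Description="Phred-scaled strand bias P-value">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(
    records: Iterable[SimVariant],
    genome: GenomeModel,
    path: str | Path,
    sample: str = "sample",
) -> None:
    """Serialize simulated variants as VCF 4.2 (positions converted to 1-based)."""
    contigs = "".join(
        f"##contig=<ID={c.name},length={c.length}>\n" for c in genome.chromosomes
    )
    gt = {"het": "0/1", "hom_ref": "0/0", "hom_alt": "1/1", "missing": "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t{r.qual:g}\t.\t.\t"
                f"GT:DP:GQ:SP\t{gt[r.genotype]}:{r.dp}:{r.gq}:{int(round(r.sp))}\n"
            )


def read_vcf(path: str | Path, sample_index: int = 0) -> list[VariantRecord]:
    """Parse a VCF into :class:`~selkie.hetscan.VariantRecord` objects.

    Genotypes come from the first (or indexed) sample; FORMAT fields DP, GQ,
    SP are read per-sample, QUAL from the site. Positions become 0-based.
    """
    from cyvcf2 import VCF

    gt_name = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}
    out: list[VariantRecord] = []
    for v in VCF(str(path)):
        def fmt(name: str) -> float | None:
            try:
                arr = v.format(name)
            except KeyError:
                return None
            if arr is None:
                return None
            val = float(arr[sample_index].item() if arr.ndim else arr[sample_index])
            return None if np.isnan(val) or val < 0 else val

        out.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS - 1,
                qual=v.QUAL,
                dp=fmt("DP"),
                gq=fmt("GQ"),
                sp=fmt("SP"),
                genotype=gt_name[int(v.gt_types[sample_index])],
                is_snp=v.is_snp,
            )
        )
    return out


# ---------------------------------------------------------- synteny blocks

_BLOCK_COLS = ["ref_chrom", "ref_start", "ref_end",
               "query_chrom", "query_start", "query_end", "orientation"]


def write_blocks_tsv(block_set: SyntenyBlockSet, path: str | Path) -> None:
    block_set.to_frame().to_csv(path, sep="\t", index=False)


def read_blocks_tsv(
    path: str | Path,
    ref_lengths: Mapping[str, int] | None = None,
    query_lengths: Mapping[str, int] | None = None,
) -> SyntenyBlockSet:
    df = pd.read_csv(path, sep="\t")
    missing = set(_BLOCK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"block TSV missing columns: {sorted(missing)}")
    blocks = [
        SyntenyBlock(
            str(r.ref_chrom), int(r.ref_start), int(r.ref_end),
            str(r.query_chrom), int(r.query_start), int(r.query_end),
            str(r.orientation),
        )
        for r in df.itertuples()
    ]
    return SyntenyBlockSet(
        blocks,
        dict(ref_lengths or {}),
        dict(query_lengths or {}),
    )


# ------------------------------------------------------------- fai / FASTA

def read_fai(path: str | Path) -> dict[str, int]:
    """Scaffold name -> length from a samtools faidx index (or 2-column TSV)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split("\t")
            out[parts[0]] = int(parts[1])
    return out


def write_fai(lengths: Mapping[str, int], path: str | Path) -> None:
    offset = 0
    with open(path, "w") as fh:
        for name, ln in lengths.items():
            fh.write(f"{name}\t{ln}\t{offset}\t{ln}\t{ln + 1}\n")
            offset += ln + 1


def write_genome_fasta(genome: GenomeModel, path: str | Path, seed: int = 0) -> None:
    """Random-base FASTA realization of a genome model (synthetic sequence)."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for c in genome.chromosomes:
            fh.write(f">{c.name}\n")
            seq = bases[rng.integers(0, 4, c.length)].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ----------------------------------------------------------- k-mer spectra

def write_kmer_histogram(hist: Mapping[int, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mult in sorted(hist):
            fh.write(f"{mult}\t{hist[mult]}\n")


def read_kmer_histogram(path: str | Path) -> dict[int, int]:
    out: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            mult, count = line.split()[:2]
            out[int(mult)] = int(count)
    return out


# ------------------------------------------------------------ result files

def write_par_bed(call: ParCall, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e in call.segments:
            label = "PAR" if call.par == (s, e) else "diploid_segment"
            fh.write(f"{call.x_name}\t{s}\t{e}\t{label}\n")


def write_par_json(
    call: ParCall,
    sex: SexInference,
    level: float,
    path: str | Path,
) -> None:
    payload = {
        "x_chrom": call.x_name,
        "par": list(call.par) if call.par else None,
        "par_length": call.par_length,
        "threshold": call.threshold_used,
        "flag": call.flag,
        "x_ratio": sex.x_ratio,
        "sex": sex.label,
        "genome_level": level,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_het_track(track: HetTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\thet_count\tdensity\n")
        for chrom, wins in track.windows.items():
            for w in wins:
                fh.write(f"{chrom}\t{w.start}\t{w.end}\t{w.het_count}\t{w.density:.6g}\n")


def write_inversions_tsv(calls: Sequence[InversionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_chrom\tref_start\tref_end\tquery_chrom\tn_blocks\t"
                 "span\tscale_class\tshared_with\n")
        for c in calls:
            fh.write(
                f"{c.ref_chrom}\t{c.ref_start}\t{c.ref_end}\t{c.query_chrom}\t"
                f"{c.n_blocks}\t{c.span}\t{c.scale_class}\t"
                f"{','.join(sorted(c.sharing)) or '.'}\n"
            )


def write_fastq(records: Iterable, path: str | Path) -> int:
    """Write Biopython SeqRecords as FASTQ; returns the record count."""
    from Bio import SeqIO

    n = 0
    with open(path, "w") as fh:
        for rec in records:
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n
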