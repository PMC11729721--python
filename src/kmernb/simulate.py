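"""Seeded synthetic genomes and error-bearing short reads.

Stands in for reference genomes and a short-read simulator so the whole
pipeline is testable without downloads. Genomes are i.i.d. base sequences
at a configurable GC content; reads are drawn uniformly over start
positions and strands, with independent per-base substitution errors (no
indels — the Illumina short-read setting). Read ids embed the truth
(source genome, start, strand), and everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .database import MANIFEST_COLUMNS, GenomeRecord
from .kmers import reverse_complement

__all__ = [
    "SimParams",
    "SimRead",
    "random_genome",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
    "write_truth_tsv",
    "synthetic_community",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Simulation knobs.

    Defaults model one bacterial-scale study condition: 100 kb genomes at
    balanced GC, 100 reads per class of 150 bp (Illumina short reads) with
    a 1% per-base substitution rate.
    """

    genome_length: int = 100_000
    gc_content: float = 0.5
    n_reads: int = 100
    read_length: int = 150
    substitution_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError(f"gc_content must be in [0, 1], got {self.gc_content}")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError(
                f"substitution_rate must be in [0, 1), got {self.substitution_rate}"
            )
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str


def random_genome(params: SimParams) -> str:
    """One random genome sequence: i.i.d. bases, P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    rng = np.random.default_rng(params.seed)
    at = (1.0 - params.gc_content) / 2.0
    gc = params.gc_content / 2.0
    idx = rng.choice(4, size=params.genome_length, p=[at, gc, gc, at])
    return "".join(_BASES[idx])


def simulate_reads(genome: str, genome_id: str, params: SimParams) -> list[SimRead]:
    """Draw reads uniformly from a genome with substitution errors.

    Start positions are uniform over the valid range, strand is uniform
    (forward / reverse complement), and each base is substituted with
    probability ``substitution_rate`` to one of the 3 alternatives
    uniformly. Read ids carry ``genome_id|start|strand|index`` truth.
    """
    if len(genome) < params.read_length:
        raise ValueError("genome shorter than read_length")
    rng = np.random.default_rng(params.seed)
    L = params.read_length
    starts = rng.integers(0, len(genome) - L + 1, size=params.n_reads)
    strands = rng.integers(0, 2, size=params.n_reads)  # 0 = forward, 1 = reverse
    reads: list[SimRead] = []
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(params.n_reads):
        start = int(starts[i])
        seq = genome[start : start + L]
        strand = "-" if strands[i] else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        err_mask = rng.random(L) < params.substitution_rate
        if err_mask.any():
            offsets = rng.integers(1, 4, size=int(err_mask.sum()))
            chars = list(seq)
            for pos, off in zip(np.flatnonzero(err_mask), offsets):
                chars[pos] = "ACGT"[(base_index[chars[pos]] + off) % 4]
            seq = "".join(chars)
        reads.append(SimRead(read_id=f"{genome_id}|{start}|{strand}|{i}", sequence=seq))
    return reads


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fastq(reads: Sequence[SimRead], path: str | Path, quality: str = "I") -> None:
    lines = []
    for r in reads:
        lines += [f"@{r.read_id}", r.sequence, "+", quality * len(r.sequence)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_tsv(
    reads: Sequence[SimRead], genome_id: str, class_id: str, path: str | Path, append: bool = False
) -> None:
    lines = [] if append else ["read_id\tgenome_id\tclass_id"]
    lines += [f"{r.read_id}\t{genome_id}\t{class_id}" for r in reads]
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def _synthetic_lineage(i: int) -> tuple[str, ...]:
    # nested moduli (2, 4, 8, ...) give a consistent hierarchy: a class's
    # residue mod 2^j determines its residue mod 2^(j-1), so every genus
    # sits under exactly one family, and so on up to superkingdom
    return (
        f"sk{i % 2}",
        f"p{i % 4}",
        f"c{i % 8}",
        f"o{i % 16}",
        f"f{i % 32}",
        f"g{i % 64}",
        f"s{i}",
    )


def synthetic_community(
    n_classes: int,
    out_dir: str | Path,
    params: SimParams,
    genomes_per_class: int = 1,
) -> list[GenomeRecord]:
    """Generate a community of random genomes with a manifest.

    One FASTA per genome under ``out_dir/genomes/``, plus ``manifest.tsv``.
    Classes get a nested synthetic lineage so evaluation at every rank is
    meaningful. Deterministic in ``params.seed``.
    """
    out_dir = Path(out_dir)
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    records: list[GenomeRecord] = []
    for ci in range(n_classes):
        for gi in range(genomes_per_class):
            gid = f"class{ci:03d}_g{gi}"
            gseed = (params.seed * 1_000_003 + ci * 131 + gi) % 2**31
            seq = random_genome(replace(params, seed=gseed))
            fasta = out_dir / "genomes" / f"{gid}.fasta"
            write_fasta([(gid, seq)], fasta)
            records.append(
                GenomeRecord(
                    genome_id=gid,
                    class_id=f"s{ci}",
                    source_path=str(fasta),
                    lineage=_synthetic_lineage(ci),
                )
            )
    header = "\t".join(MANIFEST_COLUMNS)
    rows = [
        "\t".join((r.genome_id, r.class_id, r.source_path) + r.lineage) for r in records
    ]
    (out_dir / "manifest.tsv").write_text("\n".join([header] + rows) + "\n")
    return records
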