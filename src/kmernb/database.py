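"""Per-genome k-mer count database: build, persist, extend incrementally.

The database is a directory::

    <root>/
        dbspec.tsv          # k and canonicality of every table in the store
        manifest.tsv        # genome_id, class_id, fasta_path + 7-rank lineage
        counts/<genome_id>.nbk.tsv

One count file per genome — the genome is the scoring unit (the classifier
emits per-genome log-likelihoods); the species-level class is a label join
through the manifest. Adding a genome never touches another genome's count
file, which is what makes incremental growth cheap: counting is per-genome
and the smoothing denominator ``N_G + V`` involves only that genome's total
and the closed-form vocabulary size.

Count file format (version 1)::

    #nbk<TAB>1
    #k<TAB><k>
    #canonical<TAB><0|1>
    #genome<TAB><genome_id>
    #total<TAB><N_G>
    <kmer><TAB><count>          # ascending lexicographic, no zero counts

Plain text, sorted keys: human-auditable, diff-stable, byte-deterministic.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .kmers import CountTable, KmerSpec, count_kmers, merge_counts

__all__ = [
    "GenomeRecord",
    "Database",
    "RANKS",
    "train_genome",
    "save_counts",
    "load_counts",
    "read_manifest",
    "open_maybe_gzip",
]

RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

MANIFEST_COLUMNS = ("genome_id", "class_id", "fasta_path") + RANKS

COUNT_FILE_SUFFIX = ".nbk.tsv"


@dataclass(frozen=True)
class GenomeRecord:
    """One reference genome: identity, species-level class, source FASTA."""

    genome_id: str
    class_id: str
    source_path: str
    lineage: tuple[str, ...] = ("",) * 7  # 7 rank slots, "" = unassigned

    def __post_init__(self) -> None:
        if len(self.lineage) != 7:
            raise ValueError(
                f"lineage must have 7 rank slots, got {len(self.lineage)}"
            )


def open_maybe_gzip(path: str | Path, mode: str = "rt"):
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _fasta_records(path: str | Path) -> Iterator:
    fmt = "fasta"
    with open_maybe_gzip(path) as fh:
        yield from SeqIO.parse(fh, fmt)


def train_genome(fasta: str | Path, spec: KmerSpec) -> CountTable:
    """Count the k-mers of every record in a (possibly gzipped) FASTA file.

    Records are counted independently and merged: k-mers never span two
    records, since contigs are not physically contiguous. An empty file or
    one with no valid windows yields an empty table, not an error.
    """
    table = CountTable(spec=spec)
    for rec in _fasta_records(fasta):
        table = merge_counts(table, count_kmers(str(rec.seq), spec))
    return table


def save_counts(
    table: CountTable, spec: KmerSpec, genome_id: str, path: str | Path
) -> None:
    """Write a count table in the sorted, versioned text format.

    Byte-deterministic: the same table always produces the same file.
    """
    lines = [
        "#nbk\t1",
        f"#k\t{spec.k}",
        f"#canonical\t{1 if spec.canonical else 0}",
        f"#genome\t{genome_id}",
        f"#total\t{table.total}",
    ]
    for kmer in sorted(table.counts):
        lines.append(f"{kmer}\t{table.counts[kmer]}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_counts(path: str | Path) -> tuple[CountTable, KmerSpec, str]:
    """Read a count file back; validates header, ordering and total.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()

    def fail(lineno: int, msg: str):
        raise ValueError(f"{path}: line {lineno}: {msg}")

    header: dict[str, str] = {}
    for want, lineno in (("nbk", 1), ("k", 2), ("canonical", 3), ("genome", 4), ("total", 5)):
        if lineno > len(lines):
            fail(lineno, f"missing header line #{want}")
        parts = lines[lineno - 1].split("\t")
        if len(parts) != 2 or parts[0] != f"#{want}":
            fail(lineno, f"expected '#{want}<TAB>value', got {lines[lineno - 1]!r}")
        header[want] = parts[1]
    if header["nbk"] != "1":
        fail(1, f"unsupported format version {header['nbk']!r}")
    if header["canonical"] not in ("0", "1"):
        fail(3, f"canonical flag must be 0 or 1, got {header['canonical']!r}")
    try:
        k = int(header["k"])
        declared_total = int(header["total"])
    except ValueError:
        fail(2, "k and total must be integers")
    spec = KmerSpec(k=k, canonical=header["canonical"] == "1")

    # bulk parse, locating the offending line only when a check fails
    data = lines[5:]
    pairs = [ln.split("\t") for ln in data]
    for i, p in enumerate(pairs):
        if len(p) != 2:
            fail(6 + i, f"expected '<kmer><TAB><count>', got {data[i]!r}")
    kmers = [p[0] for p in pairs]
    counts = {}
    try:
        for p in pairs:
            counts[p[0]] = int(p[1])
    except ValueError:
        for i, p in enumerate(pairs):
            if not p[1].isdigit():
                fail(6 + i, f"non-integer count {p[1]!r}")
    if len(counts) != len(kmers):
        seen: set[str] = set()
        for i, w in enumerate(kmers):
            if w in seen:
                fail(6 + i, f"duplicate k-mer {w!r}")
            seen.add(w)
    if kmers != sorted(kmers):
        for i in range(1, len(kmers)):
            if kmers[i] <= kmers[i - 1]:
                fail(6 + i, f"k-mers not in ascending order at {kmers[i]!r}")
    for i, (w, n) in enumerate(counts.items()):
        if n <= 0:
            fail(6 + i, f"non-positive count {n} for {w!r}")
    total = sum(counts.values())
    if total != declared_total:
        fail(5, f"declared total {declared_total} != sum of counts {total}")
    table = CountTable(spec=spec, counts=counts, total=total)
    table.validate()
    return table, spec, header["genome"]


def read_manifest(path: str | Path) -> list[GenomeRecord]:
    """Parse a manifest TSV into genome records.

    Columns (header required): genome_id, class_id, fasta_path, then the 7
    ranks superkingdom..species. Empty rank cells mean "unassigned".
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty manifest")
    header = lines[0].split("\t")
    if tuple(header) != MANIFEST_COLUMNS:
        raise ValueError(
            f"{path}: manifest header must be {list(MANIFEST_COLUMNS)}, got {header}"
        )
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(MANIFEST_COLUMNS):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(MANIFEST_COLUMNS)} columns, "
                f"got {len(cells)}"
            )
        records.append(
            GenomeRecord(
                genome_id=cells[0],
                class_id=cells[1],
                source_path=cells[2],
                lineage=tuple(cells[3:10]),
            )
        )
    return records


def _write_manifest(path: Path, records: Iterable[GenomeRecord]) -> None:
    lines = ["\t".join(MANIFEST_COLUMNS)]
    for r in records:
        lines.append("\t".join((r.genome_id, r.class_id, r.source_path) + r.lineage))
    path.write_text("\n".join(lines) + "\n")


class Database:
    """Incrementally growable store of per-genome count tables.

    Create with :meth:`create`, reopen with :meth:`open`. ``add_genome``
    counts one genome and persists its table; existing count files are
    never read or rewritten, so the store built by sequential adds is
    identical, file for file, to one built in any other order.
    """

    def __init__(self, root: Path, spec: KmerSpec, members: list[GenomeRecord]):
        self.root = Path(root)
        self.spec = spec
        self.members = members

    # -- construction -----------------------------------------------------

    @classmethod
    def create(cls, root: str | Path, spec: KmerSpec) -> "Database":
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        (root / "counts").mkdir(exist_ok=True)
        (root / "dbspec.tsv").write_text(
            f"k\t{spec.k}\ncanonical\t{1 if spec.canonical else 0}\n"
        )
        db = cls(root, spec, [])
        db._flush_manifest()
        return db

    @classmethod
    def open(cls, root: str | Path) -> "Database":
        root = Path(root)
        spec_lines = (root / "dbspec.tsv").read_text().splitlines()
        kv = dict(ln.split("\t") for ln in spec_lines if ln)
        spec = KmerSpec(k=int(kv["k"]), canonical=kv["canonical"] == "1")
        members = read_manifest(root / "manifest.tsv")
        return cls(root, spec, members)

    # -- incremental growth ----------------------------------------------

    def add_genome(self, genome: GenomeRecord) -> "Database":
        """Count one genome's k-mers and persist them; returns self.

        Existing members' count files are untouched. Raises on duplicate
        ``genome_id``.
        """
        if any(m.genome_id == genome.genome_id for m in self.members):
            raise ValueError(f"duplicate genome_id {genome.genome_id!r}")
        table = train_genome(genome.source_path, self.spec)
        save_counts(table, self.spec, genome.genome_id, self.count_path(genome.genome_id))
        self.members.append(genome)
        self._flush_manifest()
        return self

    def _flush_manifest(self) -> None:
        _write_manifest(self.root / "manifest.tsv", self.members)

    # -- access -----------------------------------------------------------

    def count_path(self, genome_id: str) -> Path:
        return self.root / "counts" / f"{genome_id}{COUNT_FILE_SUFFIX}"

    def load_table(self, genome_id: str) -> CountTable:
        table, spec, gid = load_counts(self.count_path(genome_id))
        if spec != self.spec:
            raise ValueError(
                f"count file for {genome_id!r} has spec {spec}, database has {self.spec}"
            )
        if gid != genome_id:
            raise ValueError(
                f"count file {self.count_path(genome_id)} declares genome {gid!r}"
            )
        return table

    def class_of(self, genome_id: str) -> str:
        for m in self.members:
            if m.genome_id == genome_id:
                return m.class_id
        raise KeyError(genome_id)

    def disk_footprint(self) -> dict[str, int]:
        """Byte size of each member's count file."""
        out = {}
        for m in self.members:
            p = self.count_path(m.genome_id)
            if not p.exists():
                raise FileNotFoundError(f"missing count file for {m.genome_id!r}: {p}")
            out[m.genome_id] = os.path.getsize(p)
        return out

    def __len__(self) -> int:
        return len(self.members)
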