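"""Naive Bayes read scoring against a per-genome count database.

Each query read is scored against every training genome G with an
add-1 (Laplace) smoothed multinomial log-likelihood over its k-mers::

    score(read, G) = sum_w  c_read(w) * ln( (freq_G(w) + 1) / (N_G + V) )

where the sum runs over the read's valid k-mer windows (counted on the fly,
no temporary files), ``freq_G`` is the genome's stored count, ``N_G`` its
total window count, and ``V`` the closed-form vocabulary size. The +1
pseudo-count gives unseen k-mers a nonzero probability, so every read gets
a finite score against every genome; the smoothed probabilities over the
full vocabulary sum to exactly 1 per genome. Logs are natural.

The per-(read, genome) summation order is fixed — ascending k-mer
lexicographic — so batch size, memory budget and thread count can change
only which tables are resident when, never the floating-point result.
The best genome is the argmax; ties break toward the lexicographically
smaller genome_id.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .database import Database, open_maybe_gzip
from .kmers import CountTable, KmerSpec, count_kmers, vocabulary_size

__all__ = [
    "QueryRead",
    "ScoreResult",
    "smoothed_log_prob",
    "score_read",
    "classify_batch",
    "minimum_memory",
    "iter_query_reads",
    "write_results_tsv",
    "write_full_matrix",
]

# Sizing model for the memory contract: resident dict representation of a
# count table costs roughly this many bytes per count-file byte, and each
# in-flight read reserves fixed input/output buffer space.
TABLE_OVERHEAD_FACTOR = 8
READ_BUFFER_BYTES = 1024
OUTPUT_BUFFER_BYTES = 256

DEFAULT_BATCH_SIZE = 1000  # per-worker workload capacity
FULL_MODE_MAX_ROWS = 1_000_000
FULL_MODE_MAX_COLS = 16_000


@dataclass(frozen=True)
class QueryRead:
    """One query read; the sequence may contain ambiguous bases (N)."""

    read_id: str
    sequence: str


@dataclass
class ScoreResult:
    """Classification of one read.

    ``best_log_likelihood`` is in natural-log units. ``no_kmers`` flags a
    read that contributed no valid k-mer windows: such reads score 0.0
    against every genome and are still emitted (the classifier labels all
    reads), with the tie-break picking the first genome_id.
    """

    read_id: str
    best_genome_id: str
    best_class_id: str
    best_log_likelihood: float
    no_kmers: bool = False
    full_scores: dict[str, float] | None = None


def smoothed_log_prob(count: int, total: int, v: int) -> float:
    """ln((count + 1) / (total + V)) — add-1 smoothed k-mer log-probability."""
    return math.log((count + 1) / (total + v))


def score_read(read: QueryRead, table: CountTable, spec: KmerSpec, v: int) -> float:
    """Log-likelihood of one read under one genome's smoothed k-mer model.

    The read's k-mers are counted on the fly; terms are summed in ascending
    k-mer order. A read with zero valid windows scores 0.0.
    """
    read_counts = count_kmers(read.sequence, spec)
    if read_counts.total == 0:
        return 0.0
    score = 0.0
    for w in sorted(read_counts.counts):
        score += read_counts.counts[w] * smoothed_log_prob(
            table.counts.get(w, 0), table.total, v
        )
    return score


def minimum_memory(db: Database, batch_size: int) -> int:
    """Smallest workable memory budget in bytes for ``classify_batch``.

    One resident count table (the largest, at the documented overhead
    factor) plus input and output buffers for one batch of reads. Monotone
    non-decreasing in ``batch_size``.
    """
    footprint = db.disk_footprint()
    largest = max(footprint.values(), default=0)
    return TABLE_OVERHEAD_FACTOR * largest + batch_size * (
        READ_BUFFER_BYTES + OUTPUT_BUFFER_BYTES
    )


def _chunks(seq: Sequence, size: int) -> Iterator[Sequence]:
    for i in range(0, len(seq), size):
        yield seq[i : i + size]


def _score_precounted(
    sorted_items: list[tuple[str, int]],
    counts: dict[str, int],
    total: int,
    v: int,
    cache: dict[int, float],
) -> float:
    """Same arithmetic and order as :func:`score_read`, with the read's
    k-mers pre-counted and per-genome log terms memoized by count value."""
    score = 0.0
    for w, c in sorted_items:
        n = counts.get(w, 0)
        lp = cache.get(n)
        if lp is None:
            lp = math.log((n + 1) / (total + v))
            cache[n] = lp
        score += c * lp
    return score


def classify_batch(
    reads: Sequence[QueryRead],
    db: Database,
    mode: str = "max",
    batch_size: int = DEFAULT_BATCH_SIZE,
    memory_budget: int | None = None,
    threads: int = 1,
) -> list[ScoreResult]:
    """Score reads against every genome in the database.

    Parameters
    ----------
    mode : {"max", "full"}
        "max" keeps only the best genome per read; "full" additionally
        retains every (read, genome) log-likelihood.
    batch_size : int
        Reads resident at once. Results are identical for any value >= 1.
    memory_budget : int or None
        Bytes available; caps how many genome tables are concurrently
        resident (never the arithmetic). None = no cap. Below the
        documented minimum → error stating that minimum.
    threads : int
        Worker threads scoring disjoint read partitions; results are
        independent of this value.
    """
    if len(db) == 0:
        raise ValueError("empty database: nothing to classify against")
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    if mode not in ("max", "full"):
        raise ValueError(f"mode must be 'max' or 'full', got {mode!r}")

    footprint = db.disk_footprint()
    largest = max(footprint.values(), default=0)
    buffers = batch_size * (READ_BUFFER_BYTES + OUTPUT_BUFFER_BYTES)
    if memory_budget is None:
        n_resident = len(db)
    else:
        min_mem = minimum_memory(db, batch_size)
        if memory_budget < min_mem:
            raise ValueError(
                f"memory_budget {memory_budget} below minimum {min_mem} "
                f"(one resident table + buffers for batch_size={batch_size})"
            )
        per_table = TABLE_OVERHEAD_FACTOR * largest
        n_resident = max(1, (memory_budget - buffers) // per_table) if per_table else len(db)
        n_resident = min(n_resident, len(db))

    v = vocabulary_size(db.spec)
    spec = db.spec
    genome_ids = sorted(m.genome_id for m in db.members)
    class_by_genome = {m.genome_id: m.class_id for m in db.members}
    reads = list(reads)

    n = len(reads)
    best_score = [-math.inf] * n
    best_gid = [genome_ids[0]] * n
    no_kmers = [False] * n
    full: list[dict[str, float]] | None = (
        [dict() for _ in range(n)] if mode == "full" else None
    )

    # genome-major streaming: each resident genome chunk is loaded from disk
    # once and every read batch flows past it, so a tight memory budget
    # costs re-counting of query k-mers (cheap, in-memory) rather than
    # repeated count-file parsing
    batch_starts = list(range(0, n, batch_size))
    executor = ThreadPoolExecutor(max_workers=threads) if threads > 1 else None
    try:
        for gid_chunk in _chunks(genome_ids, n_resident):
            tables = {gid: db.load_table(gid) for gid in gid_chunk}
            for start in batch_starts:
                batch = reads[start : start + batch_size]
                # on-the-fly query counting: tallied per batch, items
                # pre-sorted so the per-pair summation order is fixed
                precounted = []
                for i, r in enumerate(batch):
                    ct = count_kmers(r.sequence, spec)
                    precounted.append(sorted(ct.counts.items()) if ct.total else None)
                    no_kmers[start + i] = ct.total == 0
                for gid in gid_chunk:  # ascending id order within the chunk
                    table = tables[gid]
                    cache: dict[int, float] = {}

                    def score_one(items, _t=table, _c=cache):
                        if items is None:
                            return 0.0
                        return _score_precounted(items, _t.counts, _t.total, v, _c)

                    if executor is not None and len(batch) > 1:
                        scores = list(executor.map(score_one, precounted))
                    else:
                        scores = [score_one(items) for items in precounted]

                    for i, s in enumerate(scores):
                        j = start + i
                        if s > best_score[j]:  # strict: ties keep the smaller gid
                            best_score[j] = s
                            best_gid[j] = gid
                        if full is not None:
                            full[j][gid] = s
    finally:
        if executor is not None:
            executor.shutdown()

    return [
        ScoreResult(
            read_id=r.read_id,
            best_genome_id=best_gid[j],
            best_class_id=class_by_genome[best_gid[j]],
            best_log_likelihood=best_score[j],
            no_kmers=no_kmers[j],
            full_scores=dict(full[j]) if full is not None else None,
        )
        for j, r in enumerate(reads)
    ]


# -- query input / result output -----------------------------------------


def iter_query_reads(path: str | Path) -> list[QueryRead]:
    """Read query reads from FASTA or FASTQ (gzip accepted); qualities ignored."""
    path = Path(path)
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    reads = []
    seen = set()
    with open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            if rec.id in seen:
                raise ValueError(f"duplicate read_id {rec.id!r} in {path}")
            seen.add(rec.id)
            reads.append(QueryRead(read_id=rec.id, sequence=str(rec.seq)))
    return reads


def write_results_tsv(
    results: Iterable[ScoreResult],
    lineage_by_class: dict[str, tuple[str, ...]],
    path: str | Path,
) -> None:
    """Default (max-mode) output: one row per read, lineage ';'-joined."""
    lines = [
        "read_id\tbest_genome_id\tbest_class_id\tmax_log_likelihood\t"
        "no_kmer_flag\tlineage"
    ]
    for r in results:
        lineage = lineage_by_class.get(r.best_class_id, ("",) * 7)
        lines.append(
            f"{r.read_id}\t{r.best_genome_id}\t{r.best_class_id}\t"
            f"{r.best_log_likelihood!r}\t{1 if r.no_kmers else 0}\t"
            + ";".join(lineage)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_full_matrix(
    results: Sequence[ScoreResult],
    out_prefix: str | Path,
    max_rows: int = FULL_MODE_MAX_ROWS,
    max_cols: int = FULL_MODE_MAX_COLS,
) -> list[Path]:
    """Full-mode matrix output, chunked to at most max_rows x max_cols cells
    per file (defaults sized to what a spreadsheet can ingest).

    Rows are reads in input order, columns genome_ids ascending. Files are
    named ``<prefix>.r<i>c<j>.tsv`` for row-chunk i, column-chunk j.
    """
    if not results:
        return []
    if any(r.full_scores is None for r in results):
        raise ValueError("write_full_matrix requires results from mode='full'")
    genome_ids = sorted(results[0].full_scores)
    out_prefix = Path(out_prefix)
    written: list[Path] = []
    row_chunks = list(_chunks(list(results), max_rows))
    col_chunks = list(_chunks(genome_ids, max_cols))
    for i, rows in enumerate(row_chunks):
        for j, cols in enumerate(col_chunks):
            lines = ["read_id\t" + "\t".join(cols)]
            for r in rows:
                lines.append(
                    r.read_id + "\t" + "\t".join(repr(r.full_scores[g]) for g in cols)
                )
            p = out_prefix.parent / f"{out_prefix.name}.r{i}c{j}.tsv"
            p.write_text("\n".join(lines) + "\n")
            written.append(p)
    return written
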