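"""Smoothed scoring and batched classification: exact arithmetic examples,
normalization, tie-breaks, and the batching/memory/threading contract."""

import itertools
import math

import pytest

from kmernb.classify import (
    QueryRead,
    classify_batch,
    iter_query_reads,
    minimum_memory,
    score_read,
    smoothed_log_prob,
    write_full_matrix,
    write_results_tsv,
)
from kmernb.database import Database, GenomeRecord
from kmernb.kmers import (
    CountTable,
    KmerSpec,
    canonical_form,
    count_kmers,
    reverse_complement,
    vocabulary_size,
)
from kmernb.simulate import SimParams, random_genome, simulate_reads, write_fasta


class TestSmoothedLogProb:
    @pytest.mark.parametrize(
        "count,total,v,expected",
        [
            (0, 0, 10, math.log(1 / 10)),
            (2, 3, 10, math.log(3 / 13)),
        ],
    )
    def test_direct_arithmetic(self, count, total, v, expected):
        assert smoothed_log_prob(count, total, v) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_probabilities_sum_to_one_over_full_vocabulary(self, k):
        """Σ (f_i + 1)/(N_G + V) over every possible k-mer is exactly 1."""
        spec = KmerSpec(k, True)
        genome = random_genome(SimParams(genome_length=3000, seed=k))
        table = count_kmers(genome, spec)
        v = vocabulary_size(spec)
        vocab = {
            canonical_form("".join(t)) for t in itertools.product("ACGT", repeat=k)
        }
        assert len(vocab) == v
        s = sum(
            math.exp(smoothed_log_prob(table.counts.get(w, 0), table.total, v))
            for w in vocab
        )
        assert s == pytest.approx(1.0, abs=1e-9)


class TestScoreRead:
    SPEC = KmerSpec(2, True)
    TABLE = CountTable(SPEC, {"AC": 2, "CG": 1}, 3)

    def test_seen_kmer(self):
        s = score_read(QueryRead("r", "AC"), self.TABLE, self.SPEC, 10)
        assert s == pytest.approx(math.log(3 / 13), abs=1e-12)

    def test_unseen_kmer_smoothed(self):
        # windows TT,TT -> canonical AA twice, count 0
        s = score_read(QueryRead("r", "TTT"), self.TABLE, self.SPEC, 10)
        assert s == pytest.approx(2 * math.log(1 / 13), abs=1e-12)

    def test_no_valid_windows_scores_zero(self):
        assert score_read(QueryRead("r", "NN"), self.TABLE, self.SPEC, 10) == 0.0


def _build_db(tmp_path, n_genomes, length, k=7, seed=0, name="db"):
    db = Database.create(tmp_path / name, KmerSpec(k, True))
    genomes = {}
    for i in range(n_genomes):
        gid = f"g{i:02d}"
        seq = random_genome(SimParams(genome_length=length, seed=seed + i))
        p = tmp_path / f"{name}_{gid}.fasta"
        write_fasta([(gid, seq)], p)
        db.add_genome(GenomeRecord(gid, f"s{i}", str(p)))
        genomes[gid] = seq
    return db, genomes


@pytest.fixture(scope="module")
def mid_db(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("mid_db")
    db, genomes = _build_db(tmp, 5, 8000, k=7, seed=42)
    reads = []
    for i, (gid, seq) in enumerate(sorted(genomes.items())):
        for sr in simulate_reads(
            seq, gid, SimParams(genome_length=8000, n_reads=8, read_length=120,
                                substitution_rate=0.0, seed=100 + i)
        ):
            reads.append(QueryRead(sr.read_id, sr.sequence))
    return db, genomes, reads


class TestClassifyBatch:
    def test_tie_break_prefers_smaller_genome_id(self, tmp_path):
        seq = random_genome(SimParams(genome_length=1000, seed=1))
        db = Database.create(tmp_path / "db", KmerSpec(5, True))
        for gid in ("gB", "gA"):  # insertion order must not matter
            p = tmp_path / f"{gid}.fasta"
            write_fasta([(gid, seq)], p)
            db.add_genome(GenomeRecord(gid, f"c{gid}", str(p)))
        res = classify_batch([QueryRead("r", seq[:60])], db)
        assert res[0].best_genome_id == "gA"

    def test_empty_database_rejected(self, tmp_path):
        db = Database.create(tmp_path / "db", KmerSpec(5, True))
        with pytest.raises(ValueError, match="empty database"):
            classify_batch([QueryRead("r", "ACGT")], db)

    def test_results_independent_of_batch_size(self, mid_db):
        db, _, reads = mid_db
        ref = classify_batch(reads, db, batch_size=1000)
        for bs in (1, 7):
            alt = classify_batch(reads, db, batch_size=bs)
            assert [(r.read_id, r.best_genome_id, r.best_log_likelihood) for r in alt] == [
                (r.read_id, r.best_genome_id, r.best_log_likelihood) for r in ref
            ]

    def test_results_independent_of_threads_and_memory(self, mid_db):
        db, _, reads = mid_db
        ref = classify_batch(reads, db)
        min_mem = minimum_memory(db, 1000)
        for threads, budget in [(4, None), (1, min_mem), (4, 4 * min_mem)]:
            alt = classify_batch(reads, db, threads=threads, memory_budget=budget)
            assert [(r.best_genome_id, r.best_log_likelihood) for r in alt] == [
                (r.best_genome_id, r.best_log_likelihood) for r in ref
            ]

    def test_full_mode_best_is_max_of_matrix(self, mid_db):
        db, _, reads = mid_db
        res = classify_batch(reads[:10], db, mode="full")
        for r in res:
            assert set(r.full_scores) == {m.genome_id for m in db.members}
            best = min(sorted(r.full_scores), key=lambda g: (-r.full_scores[g], g))
            assert r.best_genome_id == best
            assert r.best_log_likelihood == max(r.full_scores.values())

    def test_strand_invariance_end_to_end(self, mid_db):
        db, _, reads = mid_db
        fwd = classify_batch(reads[:20], db, mode="full")
        rc = classify_batch(
            [QueryRead(r.read_id, reverse_complement(r.sequence)) for r in reads[:20]],
            db,
            mode="full",
        )
        for a, b in zip(fwd, rc):
            assert a.full_scores == b.full_scores

    def test_read_with_no_kmers_still_emitted_and_flagged(self, mid_db):
        db, _, _ = mid_db
        res = classify_batch([QueryRead("r", "N" * 30)], db)
        assert res[0].no_kmers
        assert res[0].best_log_likelihood == 0.0
        assert res[0].best_genome_id == "g00"  # tie-break over all-equal scores

    def test_label_recovery_on_error_free_reads(self, mid_db):
        db, _, reads = mid_db
        res = classify_batch(reads, db)
        correct = sum(1 for r in res if r.best_genome_id == r.read_id.split("|")[0])
        assert correct == len(reads)

    def test_brute_force_oracle_agreement(self, tmp_path):
        """Independent scorer: recount each genome with a naive per-window
        dictionary, sum logs term by term; must match classify_batch."""
        db, genomes = _build_db(tmp_path, 3, 3000, k=5, seed=7)
        spec = db.spec
        v = vocabulary_size(spec)
        reads = []
        for i, (gid, seq) in enumerate(sorted(genomes.items())):
            for sr in simulate_reads(
                seq, gid, SimParams(genome_length=3000, n_reads=5, read_length=80,
                                    substitution_rate=0.02, seed=i)
            ):
                reads.append(QueryRead(sr.read_id, sr.sequence))
        res = classify_batch(reads, db, mode="full")

        def naive_counts(seq):
            d = {}
            for i in range(len(seq) - spec.k + 1):
                w = seq[i : i + spec.k]
                if set(w) <= set("ACGT"):
                    rcw = reverse_complement(w)
                    if rcw < w:
                        w = rcw
                    d[w] = d.get(w, 0) + 1
            return d

        tables = {gid: naive_counts(seq) for gid, seq in genomes.items()}
        for r, read in zip(res, reads):
            rc = naive_counts(read.sequence)
            n_read = sum(rc.values())
            for gid, counts in tables.items():
                total = sum(counts.values())
                expected = 0.0
                for w in sorted(rc):
                    expected += rc[w] * math.log((counts.get(w, 0) + 1) / (total + v))
                if n_read == 0:
                    expected = 0.0
                assert abs(r.full_scores[gid] - expected) < 1e-9


class TestMinimumMemory:
    def test_monotone_in_batch_size_and_bounded_below(self, mid_db):
        db, _, _ = mid_db
        largest = max(db.disk_footprint().values())
        prev = minimum_memory(db, 0)
        assert prev >= largest
        for bs in (1, 2, 4, 8, 1024):
            cur = minimum_memory(db, bs)
            assert cur >= prev
            prev = cur

    def test_budget_below_minimum_rejected_with_value(self, mid_db):
        db, _, reads = mid_db
        min_mem = minimum_memory(db, 1000)
        with pytest.raises(ValueError, match=str(min_mem)):
            classify_batch(reads[:2], db, memory_budget=min_mem - 1)


class TestResultIO:
    def test_query_fastq_and_duplicate_ids(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r1\nTTTT\n+\nIIII\n")
        with pytest.raises(ValueError, match="duplicate read_id"):
            iter_query_reads(p)
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nTTTT\n+\nIIII\n")
        reads = iter_query_reads(p)
        assert [r.read_id for r in reads] == ["r1", "r2"]

    def test_results_tsv_deterministic(self, mid_db, tmp_path):
        db, _, reads = mid_db
        res = classify_batch(reads[:5], db)
        lineages = {m.class_id: m.lineage for m in db.members}
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_results_tsv(res, lineages, p1)
        write_results_tsv(classify_batch(reads[:5], db), lineages, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_full_matrix_chunking_respects_limits(self, mid_db, tmp_path):
        db, _, reads = mid_db
        res = classify_batch(reads[:9], db, mode="full")
        files = write_full_matrix(res, tmp_path / "m", max_rows=4, max_cols=2)
        # 9 reads / 4 rows -> 3 row chunks; 5 genomes / 2 cols -> 3 col chunks
        assert len(files) == 9
        for f in files:
            lines = f.read_text().splitlines()
            assert len(lines) - 1 <= 4
            assert len(lines[0].split("\t")) - 1 <= 2
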