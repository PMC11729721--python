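# Methods

## Model and assumptions

kmernb treats each reference genome as a multinomial distribution over its
k-mers and scores a read against genome *G* by the smoothed log-likelihood

    LL(r|G) = Σ_w c_r(w) · ln( (freq_G(w) + 1) / (N_G + V) ),

the naive Bayes assumption being that a read's k-mer windows are
independent draws. This deliberately ignores the overlap dependence of
adjacent windows; the statistic is used only for the argmax over genomes,
where the shared dependence structure largely cancels.

**Smoothing numerator.** The estimator is standard add-1 (Laplace)
smoothing, `(freq + 1)/(N_G + V)`. A variant without the `+1` in the
numerator can be found written down in the literature around this family
of classifiers, but it assigns probability 0 to unseen k-mers and hence an
undefined log-likelihood for any read containing one; add-1's standard
form is both the numerical necessity and the stated intent, so it is the
only behavior implemented.

**Vocabulary size.** `V` uses closed forms: `4^k` non-canonical;
`(4^k + 4^(k/2))/2` canonical even k (the correction term counts
self-reverse-complementary k-mers, which have no distinct partner);
`4^k/2` canonical odd k. An alternative reading defines `V` as the number
of k-mers observed at least once anywhere in the database; we use the
closed forms, which are parameter-free, independent of database
composition (so adding a genome never changes other genomes' scores), and
exact for odd k where no palindromes exist. The closed forms are verified
against brute-force enumeration for k ≤ 8 in the test suite.

**Canonical counting.** Each window is mapped to the lexicographically
smaller (A<C<G<T, uppercase) of itself and its reverse complement. This
makes counts — and therefore scores — exactly strand-invariant, and
roughly halves the stored key set for k ≥ 9 where most k-mers occur in a
long genome.

**Ambiguous bases.** Windows containing any character outside {A,C,G,T}
are skipped entirely (not randomized, not split). This is deterministic
and matches common k-mer tool practice. K-mers never span FASTA records:
contigs are not physically contiguous.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| k | 9 | bases | classic operating point for this classifier family; sweeps of 9–15 trade recall against time/storage |
| canonical | true | — | strand invariance + ~2× storage saving |
| batch_size | 1000 | reads | per-worker workload capacity; any value ≥ 1 gives identical results |
| memory_budget | none | bytes | caps concurrently resident count tables; never changes arithmetic |
| threads | 1 | — | worker threads over read partitions; results independent of the value |
| -r / -c | 1 000 000 / 16 000 | rows/cols | full-matrix chunk limits, sized to what a spreadsheet ingests |

## Numerical choices

* Natural log throughout; scores are comparable only within one (k,
  canonical, V) configuration.
* The per-(read, genome) summation runs in ascending k-mer lexicographic
  order. With the order fixed, batching, memory budgets and threading
  cannot perturb floating-point results, which is what makes the
  byte-identical determinism contract testable.
* Ties in the argmax break toward the lexicographically smaller genome_id;
  a read with zero valid windows scores 0.0 everywhere, is emitted with
  the tie-break winner, and carries a `no_kmer_flag` in the output.
* Loading is genome-major: each resident chunk of count tables is parsed
  once and all read batches stream past it, so a tight memory budget costs
  re-counting of query k-mers (cheap, in memory) rather than repeated
  count-file parsing. Threading uses a thread pool over read partitions;
  with the summation order fixed this is determinism-first — the
  parallelism exists to honor the "results independent of thread count"
  contract in the API, not to chase speedups.

## Storage format

One plain-text count file per genome (`counts/<genome_id>.nbk.tsv`):
five `#`-prefixed header lines (format version, k, canonicality, genome
id, total) followed by `kmer<TAB>count` lines in ascending order, zero
counts never stored. Sorted plain text is human-auditable, diff-stable and
byte-deterministic, which is what the incremental-training guarantee is
stated in terms of: count files of existing genomes are bit-for-bit
untouched by later adds. Class and lineage metadata live in a separate
manifest TSV so taxonomy can be re-assigned without recounting. The
memory model used for the budget contract estimates a resident table at 8
bytes per file byte plus fixed per-read input/output buffer reservations;
it is a documented contract, not a measurement.

## The simulator, and what passing tests do not show

`simulate` draws genomes as i.i.d. bases at a configured GC content and
reads uniformly over start positions and strands with independent per-base
substitutions (uniform over the three alternatives, no indels — the
Illumina short-read regime). Defaults: 100 kb genomes, GC 0.5, 100 reads
per class, 150 bp reads, 1% substitution rate. Read ids embed
`genome|start|strand` truth; everything is deterministic per seed.

Real genomes are not i.i.d.: they share homologous regions, repeat
families, and conserved genes across taxa, and real lineages reflect
actual phylogeny. Synthetic genomes are mutually unrelated, so closed-set
label recovery is much easier than on real data (near-perfect at k=9),
and open-set generalization to held-out classes is near chance — the
synthetic lineage labels carry no sequence signal. Passing tests therefore
demonstrate the correctness of the machinery (counting, smoothing, argmax,
metrics, invariance contracts), not field accuracy on real communities.

## Evaluation conventions

Micro precision/recall pool all predictions; since the classifier labels
every read, the two are identical by construction, and the test suite
asserts this identity exactly. Macro measures average per-class
precision/recall over the labels present in the truth set: a truth label
never predicted contributes 0 to both; a predicted label absent from the
truth set is excluded. This convention matches scikit-learn's macro
averaging with `labels=` the truth-label set and `zero_division=0`, which
the tests use as a cross-check.

The 5-fold CV harness shuffles classes once (seeded), takes contiguous
fifths as test folds (remainder classes to the last fold), trains a
database per fold on the remaining classes, simulates reads from the
held-out classes and reports all 7 ranks. Because held-out classes cannot
be predicted at the species rank, open-set species-level numbers measure
collisions only; the meaningful open-set signal is at ranks above the
holdout. A `closed_set=True` control trains on all genomes and verifies
label recovery.

Bray–Curtis dissimilarity between rank-level profiles is computed over the
union of taxa on normalized weights; unassigned rank names accumulate
under a reserved `unassigned` taxon so profiles always sum to 1. Any
abundance-threshold filter (e.g. showing only taxa above 2%) is applied
for display only, never before the dissimilarity is computed.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` run at desk scale: communities
of 10–20 genomes of 20–100 kb, 100 reads per class, one 1 Mb genome for
the storage-ratio measurement, and a reduced-scale CV smoke (10 classes ×
20 reads). These sizes exercise every code path, including the
memory-budgeted streaming, while keeping a full run in minutes.

## Known limitations

* No confidence measure or novelty detection on the log-likelihood
  distribution: every read is labeled, even reads from taxa absent from
  the database.
* Scoring is per genome; counts are never merged per species class. The
  alternative (pooling a class's genomes into one model) would change
  smoothing denominators and is intentionally not implemented.
* The simulator has no indels, no coverage bias and no empirical error
  profiles.
* Plain-text count storage is transparent but not compact; no 2-bit or
  minimizer-based encodings.
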