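"""Per-rank classification metrics and the cross-validation harness.

Micro precision/recall pool all predictions (no class-imbalance
correction); because this classifier labels every read — it never abstains
— a false positive for one class is a false negative for another, so
micro-precision and micro-recall coincide exactly. Macro measures compute
precision/recall per class and average with equal class weight.

Macro averaging universe: the labels present in the truth set. A truth
label that is never predicted contributes recall 0 and precision 0; a
label predicted but absent from the truth set is excluded from the macro
averages. This convention is fixed so results are exactly reproducible.

The 5-fold cross-validation harness shuffles the class list once
(seeded), takes contiguous fifths as test folds, trains a database on the
remaining classes' genomes, simulates reads from the held-out classes,
classifies, and reports metrics at all 7 ranks. Since held-out classes
cannot be predicted at the species level, species-rank numbers in the
open-set design measure only collisions; evaluation is meaningful at the
ranks above the holdout. A closed-set control (test reads drawn from
training genomes) is provided for verification.
"""

from __future__ import annotations

import math
import random
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import QueryRead, ScoreResult, classify_batch
from .database import Database, GenomeRecord
from .kmers import KmerSpec
from .simulate import SimParams, simulate_reads
from .taxonomy import RANKS, UNASSIGNED, LineageTable

__all__ = [
    "LabeledPrediction",
    "FoldPlan",
    "metrics_at_rank",
    "make_folds",
    "run_cv",
]

N_FOLDS = 5


@dataclass(frozen=True)
class LabeledPrediction:
    read_id: str
    true_class_id: str
    predicted_class_id: str


def metrics_at_rank(
    preds: Sequence[LabeledPrediction], table: LineageTable, rank: str
) -> dict:
    """Micro/macro precision and recall plus a confusion matrix at one rank.

    Class ids are mapped to rank-level taxon names through their lineages
    (empty names become "unassigned"). Returns a dict with keys
    micro_precision, micro_recall, macro_precision, macro_recall and
    confusion (a DataFrame: rows = true labels, columns = predicted).
    """
    if not preds:
        raise ValueError("empty prediction set")
    idx = RANKS.index(rank)

    def label(class_id: str) -> str:
        return table.lineage_of(class_id)[idx] or UNASSIGNED

    pairs = [(label(p.true_class_id), label(p.predicted_class_id)) for p in preds]
    n = len(pairs)
    correct = sum(1 for t, p in pairs if t == p)
    micro = correct / n  # no abstentions: pooled precision == pooled recall

    truth_labels = sorted({t for t, _ in pairs})
    pred_labels = sorted({p for _, p in pairs})
    true_count = {l: 0 for l in truth_labels}
    pred_count: dict[str, int] = {}
    hit_count = {l: 0 for l in truth_labels}
    for t, p in pairs:
        true_count[t] += 1
        pred_count[p] = pred_count.get(p, 0) + 1
        if t == p:
            hit_count[t] += 1

    recalls = [hit_count[l] / true_count[l] for l in truth_labels]
    precisions = [
        hit_count[l] / pred_count[l] if pred_count.get(l) else 0.0
        for l in truth_labels
    ]
    macro_recall = sum(recalls) / len(truth_labels)
    macro_precision = sum(precisions) / len(truth_labels)

    confusion = pd.DataFrame(0, index=truth_labels, columns=pred_labels, dtype=int)
    for t, p in pairs:
        confusion.loc[t, p] += 1

    return {
        "micro_precision": micro,
        "micro_recall": micro,
        "macro_precision": macro_precision,
        "macro_recall": macro_recall,
        "confusion": confusion,
    }


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every class to the fold in which it is tested."""

    seed: int
    assignments: Mapping[str, int]  # class_id -> fold index 1..N_FOLDS

    def test_classes(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignments.items() if f == fold)


def make_folds(class_ids: Sequence[str], seed: int) -> FoldPlan:
    """Seeded shuffle, contiguous fifths as test folds.

    The first fifth of the shuffled class list is fold 1's test set, and
    so on; classes left over by integer division go to the last fold.
    """
    classes = list(class_ids)
    if len(set(classes)) != len(classes):
        raise ValueError("duplicate class ids")
    if len(classes) < N_FOLDS:
        raise ValueError(f"need at least {N_FOLDS} classes, got {len(classes)}")
    rng = random.Random(seed)
    rng.shuffle(classes)
    size = len(classes) // N_FOLDS
    assignments: dict[str, int] = {}
    for fold in range(1, N_FOLDS + 1):
        lo = (fold - 1) * size
        hi = fold * size if fold < N_FOLDS else len(classes)
        for c in classes[lo:hi]:
            assignments[c] = fold
    return FoldPlan(seed=seed, assignments=assignments)


def _read_genome_sequence(fasta: str | Path) -> str:
    from .database import _fasta_records

    return "".join(str(rec.seq) for rec in _fasta_records(fasta))


def _simulate_fold_reads(
    records: Sequence[GenomeRecord],
    test_classes: Sequence[str],
    reads_per_class: int,
    sim: SimParams,
    seed: int,
) -> tuple[list[QueryRead], dict[str, str]]:
    """Reads for the test classes, split across each class's genomes."""
    reads: list[QueryRead] = []
    truth: dict[str, str] = {}
    by_class: dict[str, list[GenomeRecord]] = {}
    for r in records:
        by_class.setdefault(r.class_id, []).append(r)
    for ci, cls in enumerate(sorted(test_classes)):
        members = by_class[cls]
        base, rem = divmod(reads_per_class, len(members))
        for gi, rec in enumerate(members):
            n = base + (1 if gi < rem else 0)
            if n == 0:
                continue
            genome = _read_genome_sequence(rec.source_path)
            rseed = (seed * 7_368_787 + ci * 613 + gi) % 2**31
            sim_reads = simulate_reads(
                genome, rec.genome_id, replace(sim, n_reads=n, seed=rseed)
            )
            for sr in sim_reads:
                reads.append(QueryRead(read_id=sr.read_id, sequence=sr.sequence))
                truth[sr.read_id] = cls
    return reads, truth


def run_cv(
    records: Sequence[GenomeRecord],
    spec: KmerSpec,
    reads_per_class: int,
    sim: SimParams,
    seed: int,
    workdir: str | Path | None = None,
    closed_set: bool = False,
) -> dict:
    """5-fold cross-validation over the classes of a genome manifest.

    For each fold: train a database on the training-fold genomes (all
    genomes when ``closed_set`` — the sanity control where test classes
    are represented in training), simulate ``reads_per_class`` reads from
    each test-fold class, classify, and compute metrics at all 7 ranks.

    Returns ``{"plan": FoldPlan, "folds": {fold: {rank: metrics}},
    "aggregate": DataFrame}`` where the aggregate holds mean and sd of
    each metric across folds, indexed by rank.
    """
    lineage = LineageTable.from_records(records)
    classes = sorted({r.class_id for r in records})
    plan = make_folds(classes, seed)

    per_fold: dict[int, dict[str, dict]] = {}
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        base.mkdir(parents=True, exist_ok=True)
        for fold in range(1, N_FOLDS + 1):
            test_classes = plan.test_classes(fold)
            train_records = [
                r
                for r in records
                if closed_set or r.class_id not in set(test_classes)
            ]
            db = Database.create(base / f"fold{fold}", spec)
            for r in train_records:
                db.add_genome(r)
            reads, truth = _simulate_fold_reads(
                records, test_classes, reads_per_class, sim, seed * N_FOLDS + fold
            )
            results = classify_batch(reads, db)
            preds = [
                LabeledPrediction(
                    read_id=res.read_id,
                    true_class_id=truth[res.read_id],
                    predicted_class_id=res.best_class_id,
                )
                for res in results
            ]
            per_fold[fold] = {
                rank: metrics_at_rank(preds, lineage, rank) for rank in RANKS
            }

    rows = []
    for rank in RANKS:
        row: dict[str, float | str] = {"rank": rank}
        for metric in ("micro_precision", "micro_recall", "macro_precision", "macro_recall"):
            vals = [per_fold[f][rank][metric] for f in per_fold]
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            row[f"{metric}_mean"] = mean
            row[f"{metric}_sd"] = sd
        rows.append(row)
    aggregate = pd.DataFrame(rows).set_index("rank")
    return {"plan": plan, "folds": per_fold, "aggregate": aggregate}
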