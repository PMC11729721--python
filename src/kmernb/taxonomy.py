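"""Lineage lookup and rank-level abundance profiles.

Every species-level class carries a fixed 7-slot lineage
(superkingdom, phylum, class, order, family, genus, species); an empty
string marks an unassigned rank. Classified reads aggregate into a
relative-abundance profile at any rank, with unassigned mass kept under
the reserved taxon name "unassigned" so profiles stay normalized.
Profiles are compared with the Bray–Curtis dissimilarity

    BC(p, q) = 1 - 2 * sum_t min(p_t, q_t) / (sum_t p_t + sum_t q_t)

over the union of taxa: 0 for identical communities, 1 for disjoint ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .database import RANKS, GenomeRecord

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "LineageTable",
    "AbundanceProfile",
    "profile_from_results",
    "bray_curtis",
    "write_profile_tsv",
    "read_profile_tsv",
]

UNASSIGNED = "unassigned"


class LineageTable:
    """Map from class_id to its 7-rank lineage."""

    def __init__(self, lineages: Mapping[str, tuple[str, ...]]):
        for cid, lin in lineages.items():
            if len(lin) != 7:
                raise ValueError(f"class {cid!r}: lineage must have 7 slots, got {len(lin)}")
        self._lineages = dict(lineages)

    @classmethod
    def from_records(cls, records: Iterable[GenomeRecord]) -> "LineageTable":
        """Build from manifest records; classes with several genomes must agree."""
        lineages: dict[str, tuple[str, ...]] = {}
        for r in records:
            prev = lineages.get(r.class_id)
            if prev is not None and prev != r.lineage:
                raise ValueError(
                    f"class {r.class_id!r} has conflicting lineages in manifest"
                )
            lineages[r.class_id] = r.lineage
        return cls(lineages)

    def lineage_of(self, class_id: str) -> tuple[str, ...]:
        try:
            return self._lineages[class_id]
        except KeyError:
            raise KeyError(f"unknown class_id {class_id!r}") from None

    def name_at(self, class_id: str, rank: str) -> str:
        """Taxon name of a class at a rank; "" if unassigned there."""
        return self.lineage_of(class_id)[RANKS.index(rank)]

    def joined(self, class_id: str) -> str:
        return ";".join(self.lineage_of(class_id))

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self._lineages)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self._lineages

    def class_ids(self) -> list[str]:
        return sorted(self._lineages)


@dataclass
class AbundanceProfile:
    """Relative abundances of taxa at one rank; weights sum to 1."""

    rank: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("negative abundance weight")
        s = sum(self.weights.values())
        if self.weights and abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {s}, expected 1")


def profile_from_results(results: Sequence, table: LineageTable, rank: str) -> AbundanceProfile:
    """Aggregate classified reads into a relative-abundance profile.

    Each read contributes 1/n_reads to the taxon named at ``rank`` in its
    best class's lineage; empty rank names accumulate under "unassigned".
    """
    if not results:
        raise ValueError("empty result set: no reads to profile")
    idx = RANKS.index(rank)
    counts: dict[str, int] = {}
    for r in results:
        name = table.lineage_of(r.best_class_id)[idx] or UNASSIGNED
        counts[name] = counts.get(name, 0) + 1
    n = len(results)
    return AbundanceProfile(rank=rank, weights={t: c / n for t, c in counts.items()})


def bray_curtis(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """Bray–Curtis dissimilarity between two same-rank profiles, in [0, 1]."""
    if p.rank != q.rank:
        raise ValueError(f"rank mismatch: {p.rank!r} vs {q.rank!r}")
    taxa = set(p.weights) | set(q.weights)
    shared = sum(min(p.weights.get(t, 0.0), q.weights.get(t, 0.0)) for t in taxa)
    total = sum(p.weights.values()) + sum(q.weights.values())
    if total == 0:
        return 0.0
    return 1.0 - 2.0 * shared / total


def write_profile_tsv(profile: AbundanceProfile, path: str | Path) -> None:
    lines = ["rank\ttaxon\trelative_abundance"]
    for taxon in sorted(profile.weights):
        lines.append(f"{profile.rank}\t{taxon}\t{profile.weights[taxon]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_tsv(path: str | Path) -> AbundanceProfile:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "rank\ttaxon\trelative_abundance":
        raise ValueError(f"{path}: not a profile TSV")
    rank = None
    weights: dict[str, float] = {}
    for ln in lines[1:]:
        r, taxon, w = ln.split("\t")
        if rank is None:
            rank = r
        elif r != rank:
            raise ValueError(f"{path}: mixed ranks {rank!r} and {r!r}")
        weights[taxon] = float(w)
    if rank is None:
        raise ValueError(f"{path}: empty profile")
    return AbundanceProfile(rank=rank, weights=weights)
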