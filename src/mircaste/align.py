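"""Full-length, ungapped, mismatch-bounded matching of tags to references.

Small-RNA tags are matched over their entire length against reference
sequences with at most ``k`` substitutions and no gaps — the matching model
of short-pattern genome mappers such as PatMaN.  The index uses a
seed-and-extend strategy: by the pigeonhole principle, a tag aligned with
at most ``k`` mismatches must carry at least one of ``k + 1`` disjoint
exact seed blocks, so exact seed lookup followed by full Hamming
verification recovers *every* hit an exhaustive scan would.  Queries too
short to carry ``k + 1`` seeds fall back to a windowed scan, keeping the
exhaustiveness contract unconditional.

Genome mapping uses both strands at k<=1; mature-miRNA assignment uses the
sense strand at k<=2, requiring the tag to lie entirely within the mature
sequence (the mature may overhang the tag, never vice versa).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Hit:
    """A full-length ungapped alignment of a tag to a reference window."""

    reference: str
    offset: int  # 0-based start of the window on the reference
    strand: str  # '+' or '-'
    mismatches: int


def _hamming_leq(a: str, b: str, k: int) -> int:
    """Hamming distance if <= k, else -1 (early exit)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return -1
    return mm


class ReferenceIndex:
    """Exact q-mer index over a set of reference sequences.

    ``seed_len`` trades memory for candidate counts; queries with
    ``(k + 1) * seed_len`` longer than the tag use the scan fallback.
    Results are identical to an exhaustive Hamming scan by construction.
    """

    def __init__(self, references: Mapping[str, str], seed_len: int = 8):
        if seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        self.references = dict(references)
        self.seed_len = seed_len
        self._table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.references.items():
            for pos in range(len(seq) - seed_len + 1):
                self._table[seq[pos : pos + seed_len]].append((name, pos))
        self._table = dict(self._table)

    def find(
        self, tag: str, k: int, strands: str = "+-"
    ) -> list[Hit]:
        """Every (reference, offset, strand) with Hamming distance <= k.

        The tag is reverse-complemented for '-' strand queries; offsets are
        0-based window starts on the reference in all cases.
        """
        if k < 0:
            raise ValueError("k must be >= 0")
        hits: set[Hit] = set()
        for strand in strands:
            query = tag if strand == "+" else revcomp(tag)
            L = len(query)
            if (k + 1) * self.seed_len > L:
                self._scan(query, k, strand, hits)
                continue
            for i in range(k + 1):
                o = i * self.seed_len
                seed = query[o : o + self.seed_len]
                for name, pos in self._table.get(seed, ()):
                    start = pos - o
                    ref = self.references[name]
                    if start < 0 or start + L > len(ref):
                        continue
                    mm = _hamming_leq(query, ref[start : start + L], k)
                    if mm >= 0:
                        hits.add(Hit(name, start, strand, mm))
        return sorted(hits)

    def _scan(self, query: str, k: int, strand: str, hits: set[Hit]) -> None:
        L = len(query)
        for name, ref in self.references.items():
            for start in range(len(ref) - L + 1):
                mm = _hamming_leq(query, ref[start : start + L], k)
                if mm >= 0:
                    hits.add(Hit(name, start, strand, mm))


def match_full_length(
    tag: str, index: ReferenceIndex, k: int, strands: str = "+-"
) -> list[Hit]:
    """Functional wrapper over :meth:`ReferenceIndex.find`."""
    return index.find(tag, k, strands)


# ---------------------------------------------------------------------------
# genome mapping


@dataclass
class MappingStats:
    """Redundant (count-weighted) vs non-redundant (tag-weighted) mapping."""

    total_redundant: int = 0
    total_nonredundant: int = 0
    mapped_redundant: int = 0
    mapped_nonredundant: int = 0

    @property
    def redundant_pct(self) -> float | None:
        if self.total_redundant == 0:
            return None
        return 100.0 * self.mapped_redundant / self.total_redundant

    @property
    def nonredundant_pct(self) -> float | None:
        if self.total_nonredundant == 0:
            return None
        return 100.0 * self.mapped_nonredundant / self.total_nonredundant


def map_to_genome(
    tags: Mapping[str, int], index: ReferenceIndex, k: int = 1
) -> tuple[dict[str, list[Hit]], MappingStats]:
    """Map collapsed tags to the genome; a tag maps iff it has >= 1 hit.

    Returns the per-tag hit lists (mapped tags only) and mapping statistics.
    Empty tag sets yield stats with undefined (None) percentages.
    """
    hits_by_tag: dict[str, list[Hit]] = {}
    stats = MappingStats()
    for seq, count in tags.items():
        stats.total_redundant += count
        stats.total_nonredundant += 1
        hits = index.find(seq, k, "+-")
        if hits:
            hits_by_tag[seq] = hits
            stats.mapped_redundant += count
            stats.mapped_nonredundant += 1
    return hits_by_tag, stats


# ---------------------------------------------------------------------------
# mature-miRNA assignment


@dataclass(frozen=True)
class MiRNAAssignment:
    """One tag's count contribution to one mature miRNA."""

    tag: str
    mirna: str
    mismatches: int
    count_contribution: float


@dataclass
class AssignmentResult:
    per_mirna: dict[str, float] = field(default_factory=dict)
    assignments: list[MiRNAAssignment] = field(default_factory=list)
    incident_redundant: int = 0
    total_redundant: int = 0

    @property
    def incidence_fraction(self) -> float | None:
        """Count-weighted share of the input tags incident to any miRNA."""
        if self.total_redundant == 0:
            return None
        return self.incident_redundant / self.total_redundant


def assign_to_mirbase(
    tags: Mapping[str, int],
    mature_sequences: Mapping[str, str],
    k_m: int = 2,
    seed_len: int = 5,
) -> AssignmentResult:
    """Assign tags to mature miRNAs: sense-strand, full-length, <= k_m mismatches.

    A tag is incident to a mature miRNA when it aligns ungapped over its
    full length *within* the mature sequence at any offset.  Only the
    minimal-mismatch stratum is kept per tag; a tag matching m distinct
    miRNAs at that stratum contributes count/m to each (equal split).
    """
    if not mature_sequences:
        raise ValueError("mature miRNA catalog is empty")
    index = ReferenceIndex(mature_sequences, seed_len=seed_len)
    result = AssignmentResult()
    for seq, count in tags.items():
        result.total_redundant += count
        hits = index.find(seq, k_m, strands="+")
        if not hits:
            continue
        best = min(h.mismatches for h in hits)
        mirnas = sorted({h.reference for h in hits if h.mismatches == best})
        share = count / len(mirnas)
        result.incident_redundant += count
        for name in mirnas:
            result.assignments.append(
                MiRNAAssignment(seq, name, best, share)
            )
            result.per_mirna[name] = result.per_mirna.get(name, 0.0) + share
    return result
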