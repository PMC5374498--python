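"""Raw-read cleaning for HD-adapter small-RNA libraries.

The cleaning chain drops reads with ambiguous bases, locates the 3' adapter
and removes it together with the HD signature (the degenerate bases ligated
immediately 5' of the adapter), discards inserts shorter than the minimum
length, and collapses the surviving inserts into distinct tags with counts.
Counts give the *redundant* total (all reads); the number of distinct tags
is the *non-redundant* total (unique sequences).  Base qualities are never
used.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: Illumina TruSeq small-RNA 3' adapter (RA3).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_L_MIN = 16
DEFAULT_HD_LENGTH = 4
DEFAULT_MIN_OVERLAP = 7


@dataclass
class PreprocessStats:
    """Read accounting for one library; the four sinks partition the input."""

    input_reads: int = 0
    discarded_ambiguous: int = 0
    discarded_no_adapter: int = 0
    discarded_short: int = 0
    accepted_reads: int = 0
    l_min: int = DEFAULT_L_MIN
    hd_length: int = DEFAULT_HD_LENGTH

    def check(self) -> None:
        total = (
            self.discarded_ambiguous
            + self.discarded_no_adapter
            + self.discarded_short
            + self.accepted_reads
        )
        if total != self.input_reads:
            raise AssertionError(
                f"read accounting broken: {total} != {self.input_reads}"
            )


def discard_ambiguous(
    reads: Iterable[tuple[str, str, str]], stats: PreprocessStats | None = None
) -> Iterator[tuple[str, str, str]]:
    """Yield only reads whose sequence contains no N, preserving order."""
    for rid, seq, qual in reads:
        if "N" in seq:
            if stats is not None:
                stats.discarded_ambiguous += 1
            continue
        yield rid, seq, qual


def trim_adapter_and_hd(
    seq: str,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    hd_length: int = DEFAULT_HD_LENGTH,
) -> str | None:
    """Remove the 3' adapter and the HD signature; return the insert.

    Finds the leftmost position ``p >= hd_length`` at which the adapter
    prefix of length ``min_overlap`` occurs exactly (zero mismatches);
    everything from the ``hd_length`` bases preceding it onward is removed.
    Returns ``None`` when no such occurrence exists — including adapter
    hits that leave fewer than ``hd_length`` preceding bases.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    probe = adapter[:min_overlap]
    if len(probe) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    p = seq.find(probe, hd_length)
    if p == -1:
        return None
    return seq[: p - hd_length]


def length_filter(
    inserts: Iterable[str], l_min: int = DEFAULT_L_MIN
) -> list[str]:
    """Keep exactly the inserts of length >= ``l_min``."""
    return [s for s in inserts if len(s) >= l_min]


def collapse(inserts: Iterable[str]) -> Counter:
    """Collapse inserts to distinct tags with counts (order-invariant)."""
    return Counter(inserts)


def preprocess_reads(
    reads: Iterable[tuple[str, str, str]],
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    hd_length: int = DEFAULT_HD_LENGTH,
    l_min: int = DEFAULT_L_MIN,
) -> tuple[Counter, PreprocessStats]:
    """Run the full cleaning chain over an iterable of (id, seq, qual)."""
    stats = PreprocessStats(l_min=l_min, hd_length=hd_length)
    tags: Counter = Counter()
    probe = adapter[:min_overlap]
    if len(probe) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    find = str.find
    for _rid, seq, _qual in reads:
        stats.input_reads += 1
        if "N" in seq:
            stats.discarded_ambiguous += 1
            continue
        # inlined trim_adapter_and_hd (hot loop)
        p = find(seq, probe, hd_length)
        if p == -1:
            stats.discarded_no_adapter += 1
        elif p - hd_length < l_min:
            stats.discarded_short += 1
        else:
            stats.accepted_reads += 1
            tags[seq[: p - hd_length]] += 1
    stats.check()
    return tags, stats


def _open_maybe_gzip(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (id, sequence, quality) records from a (possibly gzipped) FASTQ."""
    with _open_maybe_gzip(path) as fh:
        yield from FastqGeneralIterator(fh)


def preprocess_fastq(
    path: str | Path,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    hd_length: int = DEFAULT_HD_LENGTH,
    l_min: int = DEFAULT_L_MIN,
) -> tuple[Counter, PreprocessStats]:
    """Clean one FASTQ library into collapsed tags plus read accounting."""
    return preprocess_reads(
        read_fastq(path), adapter=adapter, min_overlap=min_overlap,
        hd_length=hd_length, l_min=l_min,
    )


def write_tags_fasta(tags: Counter, path: str | Path) -> None:
    """Write collapsed tags as FASTA with count-annotated headers.

    Header dialect: ``>tag_<i>_x<count>``; tags ordered by descending count,
    ties broken by sequence, so output is deterministic.
    """
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(
            sorted(tags.items(), key=lambda kv: (-kv[1], kv[0])), start=1
        ):
            fh.write(f">tag_{i}_x{count}\n{seq}\n")


def read_tags_fasta(path: str | Path) -> Counter:
    tags: Counter = Counter()
    seq_id = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                seq_id = line[1:]
            elif line:
                count = int(seq_id.rsplit("_x", 1)[1])
                tags[line] += count
    return tags
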