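"""Synthetic small-RNA sequencing experiments with known ground truth.

Generates a random genome with embedded mature miRNA sequences, and
multi-library FASTQ experiments that emulate an HD-adapter TruSeq small-RNA
run: each read is a mature-miRNA (or random "junk") insert, followed by the
degenerate HD signature (4 random nucleotides ligated next to the 3'
adapter to reduce ligation bias), followed by the 3' adapter sequence, all
truncated to a fixed read length.  Per-miRNA abundances, between-replicate
dispersion, spiked fold changes between phenotypes, sequencing-error rate
and the junk fraction are all controlled by :class:`SimDesign`, and the
realized per-library read counts are returned as ground truth so the
downstream pipeline can be validated read-for-read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mircaste.preprocess import DEFAULT_ADAPTER

#: Simulated reads run past the ligated 3' adapter into downstream flanking
#: sequence, so short inserts still fill a whole read.
SIM_ADAPTER = DEFAULT_ADAPTER + "AACTCCAGTCAC"

DEFAULT_PHENOTYPES = ("EW", "LW", "EQ", "LQ")

JUNK = "_junk"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _B2I[_c] = _i


# ---------------------------------------------------------------------------
# reference + catalog


@dataclass(frozen=True)
class MiRNAEntry:
    """One mature miRNA: name, sequence and its genomic origin."""

    name: str
    sequence: str
    contig: str
    start: int  # 0-based
    strand: str = "+"


@dataclass
class MiRNACatalog:
    """Named mature miRNA sequences used for read assignment and simulation."""

    entries: list[MiRNAEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("catalog miRNA names must be unique")
        for e in self.entries:
            if len(e.sequence) < 16:
                raise ValueError(f"{e.name}: mature sequence shorter than 16 nt")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def sequences(self) -> dict[str, str]:
        return {e.name: e.sequence for e in self.entries}

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(self.sequences(), path)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MiRNACatalog":
        """Load a mature-miRNA FASTA; genomic positions are unknown (-1)."""
        entries = [
            MiRNAEntry(rec.id, str(rec.seq).upper().replace("U", "T"), "", -1)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(entries)


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _adapter_confusable(seq: str, adapter: str, min_overlap: int = 7) -> bool:
    # Inserts that contain (or end in a prefix of) the trimming probe can be
    # truncated during adapter removal; the generator avoids them so the
    # noiseless round-trip is exact.
    probe = adapter[:min_overlap]
    if probe in seq:
        return True
    return any(seq.endswith(probe[:s]) for s in range(3, min_overlap))


def generate_reference(
    seed: int,
    n_mirnas: int,
    genome_length: int,
    contig: str = "contig1",
    mirna_length_range: tuple[int, int] = (20, 24),
    adapter: str = SIM_ADAPTER,
) -> tuple[dict[str, str], MiRNACatalog]:
    """Random genome with ``n_mirnas`` mature miRNAs embedded on the + strand.

    Each catalog sequence appears verbatim in the genome at its recorded
    coordinate; the rest of the genome is random background.  Deterministic
    for a given ``seed``.
    """
    if n_mirnas < 0 or genome_length <= 0:
        raise ValueError("n_mirnas must be >= 0 and genome_length positive")
    if n_mirnas > 0 and genome_length < n_mirnas * 200:
        raise ValueError(
            f"cannot pack {n_mirnas} miRNAs into {genome_length} nt "
            "(need >= 200 nt of genome per miRNA)"
        )
    rng = np.random.default_rng([int(seed), 101])
    genome = bytearray(_random_seq(rng, genome_length), "ascii")
    entries: list[MiRNAEntry] = []
    seen: set[str] = set()
    lo, hi = mirna_length_range
    if n_mirnas > 0:
        slot = genome_length // n_mirnas
        for i in range(n_mirnas):
            while True:
                length = int(rng.integers(lo, hi + 1))
                seq = _random_seq(rng, length)
                if seq not in seen and not _adapter_confusable(seq, adapter):
                    break
            start = i * slot + int(rng.integers(0, slot - length + 1))
            genome[start : start + length] = seq.encode("ascii")
            seen.add(seq)
            entries.append(MiRNAEntry(f"mir-{i + 1:03d}", seq, contig, start))
    return {contig: genome.decode("ascii")}, MiRNACatalog(entries)


# ---------------------------------------------------------------------------
# experiment design


@dataclass(frozen=True)
class Spike:
    """A known between-phenotype fold change for one miRNA.

    ``up`` names the phenotype of the pair in which the miRNA is more
    highly expressed, by a factor ``fold_change``.
    """

    mirna: str
    phenotype_a: str
    phenotype_b: str
    fold_change: float
    up: str

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.up not in (self.phenotype_a, self.phenotype_b):
            raise ValueError("spike 'up' phenotype must be one of the pair")

    @property
    def down(self) -> str:
        return (
            self.phenotype_b if self.up == self.phenotype_a else self.phenotype_a
        )

    @property
    def comparison(self) -> tuple[str, str]:
        return (self.phenotype_a, self.phenotype_b)


@dataclass
class SimDesign:
    """Study design for a synthetic multi-library experiment.

    ``base_abundance`` maps each miRNA to its expected proportion of a
    library's reads before spiking; together with ``junk_fraction`` the
    proportions are normalized to sum to 1.  A spike lowers the miRNA's
    proportion by its fold change in the *down* phenotype of its pair (the
    junk pool absorbs the freed mass), so the expected between-phenotype
    ratio equals the nominal fold change exactly.
    """

    base_abundance: dict[str, float]
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    replicates_per_phenotype: int = 4
    spikes: tuple[Spike, ...] = ()
    depth: int = 500_000
    error_rate: float = 0.005
    junk_fraction: float = 0.25
    adapter: str = SIM_ADAPTER
    hd_length: int = 4
    read_length: int = 50
    dispersion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_abundance.values()):
            raise ValueError("base_abundance entries must be nonnegative")
        if not 0 <= self.junk_fraction < 1:
            raise ValueError("junk_fraction must be in [0, 1)")
        if self.replicates_per_phenotype < 1 or self.depth < 0:
            raise ValueError("invalid replicates_per_phenotype or depth")
        total = sum(self.base_abundance.values())
        if total > 0:
            scale = (1.0 - self.junk_fraction) / total
            self.base_abundance = {
                k: v * scale for k, v in self.base_abundance.items()
            }
        spiked = {s.mirna for s in self.spikes}
        missing = spiked - set(self.base_abundance)
        if missing:
            raise ValueError(f"spiked miRNAs absent from base_abundance: {missing}")
        for s in self.spikes:
            for p in (s.phenotype_a, s.phenotype_b):
                if p not in self.phenotypes:
                    raise ValueError(f"spike references unknown phenotype {p!r}")

    @property
    def library_ids(self) -> list[str]:
        return [
            f"{p}{r + 1}"
            for p in self.phenotypes
            for r in range(self.replicates_per_phenotype)
        ]


def default_design(
    catalog: MiRNACatalog,
    seed: int = 0,
    n_spiked: int = 6,
    spike_fold: float = 16.0,
    spike_comparison: tuple[str, str] = ("LW", "LQ"),
    spiked_base: float = 0.008,
    **overrides,
) -> SimDesign:
    """The default study conditions: 4 phenotypes x 4 replicates, skewed
    per-miRNA abundances, and ``n_spiked`` miRNAs spiked ``spike_fold``-fold
    between late-instar workers and queens (alternating direction)."""
    if n_spiked > len(catalog):
        raise ValueError("more spikes requested than catalog miRNAs")
    rng = np.random.default_rng([int(seed), 202])
    names = catalog.names
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(names))
    weights /= weights.sum() if len(names) else 1.0
    base = dict(zip(names, weights))
    if n_spiked:
        rest = 1.0 - n_spiked * spiked_base
        other_total = sum(v for n, v in base.items() if n not in names[:n_spiked])
        for j, n in enumerate(names):
            if j < n_spiked:
                base[n] = spiked_base
            elif other_total > 0:
                base[n] *= rest / other_total
    a, b = spike_comparison
    spikes = tuple(
        Spike(names[j], a, b, spike_fold, up=(a if j % 2 else b))
        for j in range(n_spiked)
    )
    return SimDesign(base_abundance=base, spikes=spikes, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# read generation


def _library_index(design: SimDesign, phenotype: str, replicate: int) -> int:
    return (
        design.phenotypes.index(phenotype) * design.replicates_per_phenotype
        + replicate
    )


def _expected_proportions(
    design: SimDesign, names: Sequence[str], phenotype: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-category proportions (miRNAs..., junk) for one library."""
    base = np.array([design.base_abundance.get(n, 0.0) for n in names])
    scale = np.ones(len(names))
    for s in design.spikes:
        if phenotype == s.down:
            scale[names.index(s.mirna)] /= s.fold_change
    w = base * scale
    junk = 1.0 - w.sum()  # design junk plus mass freed by down-spiking
    # replicate-level biological noise: log-normal factor per miRNA
    w = w * np.exp(rng.normal(0.0, design.dispersion, size=len(names)))
    p = np.append(w, max(junk, 0.0))
    return p / p.sum()


def _fill_reads(
    block: np.ndarray, insert: bytes, design: SimDesign, rng: np.random.Generator
) -> None:
    """Write ``insert + HD + adapter`` reads (length-truncated) into ``block``."""
    rl = design.read_length
    n = block.shape[0]
    ib = np.frombuffer(insert, dtype=np.uint8)
    m = min(len(ib), rl)
    block[:, :m] = ib[:m]
    pos = len(ib)
    if pos < rl:
        hd_end = min(pos + design.hd_length, rl)
        if hd_end > pos:
            block[:, pos:hd_end] = _BASES[
                rng.integers(0, 4, size=(n, hd_end - pos))
            ]
        need = rl - hd_end
        if need > 0:
            if len(design.adapter) < need:
                raise ValueError(
                    f"adapter ({len(design.adapter)} nt) too short to fill a "
                    f"{rl} nt read from a {len(ib)} nt insert"
                )
            ab = np.frombuffer(design.adapter.encode("ascii"), dtype=np.uint8)
            block[:, hd_end:] = ab[:need]


def simulate_library(
    catalog: MiRNACatalog,
    design: SimDesign,
    phenotype: str,
    replicate: int,
    out_path: str | Path,
) -> dict[str, int]:
    """Write one library's FASTQ and return its true per-miRNA read counts.

    The returned dict maps miRNA name -> realized read count, with junk
    reads under the key ``"_junk"``.  Counts sum to ``design.depth``.
    """
    if phenotype not in design.phenotypes:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if not 0 <= replicate < design.replicates_per_phenotype:
        raise ValueError("replicate index out of range")
    names = catalog.names
    min_insert = min([len(e.sequence) for e in catalog] + [16])
    if len(design.adapter) < design.read_length - min_insert - design.hd_length:
        raise ValueError(
            "adapter too short to fill the read length for the shortest insert"
        )
    rng = np.random.default_rng(
        [design.seed, 303, _library_index(design, phenotype, replicate)]
    )
    p = _expected_proportions(design, names, phenotype, rng)
    counts = rng.multinomial(design.depth, p)
    rl = design.read_length
    arr = np.empty((design.depth, rl), dtype=np.uint8)
    seqs = catalog.sequences()
    row = 0
    for name, cnt in zip(names, counts[:-1]):
        if cnt:
            _fill_reads(arr[row : row + cnt], seqs[name].encode(), design, rng)
            row += cnt
    junk_count = int(counts[-1])
    if junk_count:
        lengths = rng.integers(16, 31, size=junk_count)
        order = np.argsort(lengths, kind="stable")
        lengths = lengths[order]
        start = row
        for length in range(16, 31):
            k = int((lengths == length).sum())
            if not k:
                continue
            block = arr[start : start + k]
            block[:, :length] = _BASES[rng.integers(0, 4, size=(k, length))]
            _fill_junk_tail(block, length, design, rng)
            start += k
    if design.error_rate > 0 and design.depth:
        mask = rng.random(arr.shape) < design.error_rate
        n_err = int(mask.sum())
        if n_err:
            idx = _B2I[arr]
            idx[mask] = (idx[mask] + rng.integers(1, 4, size=n_err)) % 4
            arr = _BASES[idx]
    perm = rng.permutation(design.depth)
    arr = arr[perm]
    lib_id = f"{phenotype}{replicate + 1}"
    _write_fastq(arr, lib_id, out_path)
    true_counts = {n: int(c) for n, c in zip(names, counts[:-1])}
    true_counts[JUNK] = junk_count
    return true_counts


def _fill_junk_tail(
    block: np.ndarray, insert_len: int, design: SimDesign, rng: np.random.Generator
) -> None:
    rl = design.read_length
    pos = insert_len
    if pos >= rl:
        return
    hd_end = min(pos + design.hd_length, rl)
    if hd_end > pos:
        block[:, pos:hd_end] = _BASES[
            rng.integers(0, 4, size=(block.shape[0], hd_end - pos))
        ]
    need = rl - hd_end
    if need > 0:
        ab = np.frombuffer(design.adapter.encode("ascii"), dtype=np.uint8)
        block[:, hd_end:] = ab[:need]


def _write_fastq(arr: np.ndarray, lib_id: str, path: str | Path) -> None:
    rl = arr.shape[1] if arr.ndim == 2 else 0
    qual = "I" * rl
    data = arr.tobytes()
    with open(path, "w") as fh:
        chunk: list[str] = []
        for i in range(arr.shape[0]):
            s = data[i * rl : (i + 1) * rl].decode("ascii")
            chunk.append(f"@{lib_id}.{i + 1}\n{s}\n+\n{qual}\n")
            if len(chunk) >= 100_000:
                fh.write("".join(chunk))
                chunk.clear()
        fh.write("".join(chunk))


# ---------------------------------------------------------------------------
# whole experiments


@dataclass
class Experiment:
    """Paths and ground truth for one simulated multi-library experiment."""

    sample_sheet: pd.DataFrame  # library_id, phenotype, replicate, path
    truth_counts: pd.DataFrame  # miRNA (and _junk) x library true read counts
    truth_table: pd.DataFrame   # per spiked (miRNA, comparison): fold change
    directory: Path


def make_experiment(
    catalog: MiRNACatalog, design: SimDesign, outdir: str | Path
) -> Experiment:
    """Simulate every phenotype x replicate library of ``design``.

    Writes one FASTQ per library plus ``samples.tsv``, ``truth_counts.tsv``
    and ``truth_table.tsv`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    counts: dict[str, dict[str, int]] = {}
    for phenotype in design.phenotypes:
        for rep in range(design.replicates_per_phenotype):
            lib_id = f"{phenotype}{rep + 1}"
            path = outdir / f"{lib_id}.fastq"
            counts[lib_id] = simulate_library(catalog, design, phenotype, rep, path)
            rows.append(
                {"library_id": lib_id, "phenotype": phenotype,
                 "replicate": rep + 1, "path": str(path)}
            )
    sheet = pd.DataFrame(rows)
    truth_counts = pd.DataFrame(counts).fillna(0).astype(int)
    truth_counts = truth_counts.reindex(catalog.names + [JUNK])
    trows = [
        {
            "miRNA": s.mirna,
            "comparison": f"{s.phenotype_a}_vs_{s.phenotype_b}",
            "phenotype_a": s.phenotype_a,
            "phenotype_b": s.phenotype_b,
            "fold_change": s.fold_change,
            "up": s.up,
            "true_de": s.fold_change >= 2.0,
        }
        for s in design.spikes
    ]
    truth_table = pd.DataFrame(
        trows,
        columns=["miRNA", "comparison", "phenotype_a", "phenotype_b",
                 "fold_change", "up", "true_de"],
    )
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth_counts.to_csv(outdir / "truth_counts.tsv", sep="\t",
                        index_label="miRNA")
    truth_table.to_csv(outdir / "truth_table.tsv", sep="\t", index=False)
    return Experiment(sheet, truth_counts, truth_table, outdir)
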