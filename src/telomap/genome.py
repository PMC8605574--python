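"""Genome assembly and genomic-interval data model with FASTA/BED I/O.

All coordinates are 0-based, half-open ``[start, end)`` everywhere in the
package; BED is the native interval format. Any 1-based input must be
converted at the reader boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO


class GenomeError(ValueError):
    """Raised for malformed genomes, intervals, or files."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)``."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeAssembly:
    """An ordered set of named chromosomes with optional sequence.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp, in chromosome order.
    sequences
        Optional mapping chromosome name -> nucleotide string (A/C/G/T/N).
        When present each sequence length must equal the declared length.
    """

    def __init__(
        self,
        chrom_lengths: Dict[str, int],
        sequences: Optional[Dict[str, str]] = None,
    ) -> None:
        names = list(chrom_lengths)
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names")
        for name, length in chrom_lengths.items():
            if length <= 0:
                raise GenomeError(f"chromosome {name!r} has non-positive length")
        if sequences is not None:
            for name in names:
                if name not in sequences:
                    raise GenomeError(f"missing sequence for chromosome {name!r}")
                if len(sequences[name]) != chrom_lengths[name]:
                    raise GenomeError(
                        f"sequence length for {name!r} does not match declared "
                        f"length {chrom_lengths[name]}"
                    )
        self.chrom_names: List[str] = names
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths)
        self._sequences = dict(sequences) if sequences is not None else None
        self._seq_arrays: Dict[str, np.ndarray] = {}

    @property
    def has_sequence(self) -> bool:
        return self._sequences is not None

    def sequence(self, chrom: str) -> str:
        if self._sequences is None:
            raise GenomeError("assembly carries no sequence")
        return self._sequences[chrom]

    def seq_array(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (cached)."""
        if chrom not in self._seq_arrays:
            self._seq_arrays[chrom] = np.frombuffer(
                self.sequence(chrom).encode("ascii"), dtype=np.uint8
            )
        return self._seq_arrays[chrom]

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_lengths:
            raise GenomeError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise GenomeError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chrom_lengths[iv.chrom]}"
            )


@dataclass
class IntervalSet:
    """A collection of :class:`GenomicInterval` with a provenance tag."""

    intervals: List[GenomicInterval] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.intervals = list(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            name=self.name,
        )

    def validate(self, assembly: GenomeAssembly) -> "IntervalSet":
        for iv in self.intervals:
            assembly.validate_interval(iv)
        return self

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome sorted ``(starts, ends)`` arrays."""
        out: Dict[str, List[Tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        arrays = {}
        for chrom, pairs in out.items():
            pairs.sort()
            a = np.asarray(pairs, dtype=np.int64)
            arrays[chrom] = (a[:, 0], a[:, 1])
        return arrays

    def total_length(self) -> int:
        """Sum of interval lengths (double-counts overlapping bases)."""
        return sum(len(iv) for iv in self.intervals)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals: overlapping or abutting spans are merged."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def union_length(iset: IntervalSet) -> int:
    """Number of distinct bases covered by the set (no double counting)."""
    return sum(len(iv) for iv in merge_intervals(iset))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a multi-record FASTA into an assembly, order preserved.

    Sequences are case-normalized to uppercase. Duplicate record names and
    empty records are errors.
    """
    lengths: Dict[str, int] = {}
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise GenomeError(f"duplicate FASTA record {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeError(f"empty FASTA record {rec.id!r}")
        seqs[rec.id] = seq
        lengths[rec.id] = len(seq)
    if not lengths:
        raise GenomeError(f"no FASTA records in {path}")
    return GenomeAssembly(lengths, seqs)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in assembly.chrom_names:
            fh.write(f">{chrom}\n")
            seq = assembly.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED and chrom-sizes
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path, assembly: Optional[GenomeAssembly] = None, name: str = ""
) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into an IntervalSet.

    When an assembly is given every interval is validated against it; an
    out-of-bounds or unknown-chromosome line raises an error naming the line.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = GenomicInterval(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3] if len(fields) > 3 else None,
                )
            except (ValueError, GenomeError) as exc:
                raise GenomeError(f"{path}:{lineno}: {exc}") from exc
            if assembly is not None:
                try:
                    assembly.validate_interval(iv)
                except GenomeError as exc:
                    raise GenomeError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return IntervalSet(intervals, name=name or Path(path).stem)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in iset.sorted():
            if iv.label is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a two-column ``name TAB length`` table into a sequence-less assembly."""
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GenomeError(f"{path}:{lineno}: expected 'name<TAB>length'")
            if fields[0] in lengths:
                raise GenomeError(f"{path}:{lineno}: duplicate chromosome {fields[0]!r}")
            lengths[fields[0]] = int(fields[1])
    return GenomeAssembly(lengths)


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in assembly.chrom_names:
            fh.write(f"{chrom}\t{assembly.chrom_lengths[chrom]}\n")


# ---------------------------------------------------------------------------
# Derived interval sets and composition
# ---------------------------------------------------------------------------

def telomere_windows(
    assembly: GenomeAssembly, window_bp: int = 15_000, name: str = "telomeres"
) -> IntervalSet:
    """Terminal windows of each chromosome, clamped and merged.

    Two intervals per chromosome, ``[0, min(w, L))`` and ``[max(0, L-w), L)``;
    when ``2*w >= L`` the two windows merge into one full-chromosome span.
    ``window_bp == 0`` yields an empty set.
    """
    if window_bp < 0:
        raise GenomeError("window_bp must be >= 0")
    intervals: List[GenomicInterval] = []
    if window_bp == 0:
        return IntervalSet([], name=name)
    for chrom in assembly.chrom_names:
        L = assembly.chrom_lengths[chrom]
        left = GenomicInterval(chrom, 0, min(window_bp, L))
        right = GenomicInterval(chrom, max(0, L - window_bp), L)
        intervals.extend(merge_intervals([left, right]))
    return IntervalSet(intervals, name=name)


_GC_CODES = frozenset(b"GC")
_ACGT_CODES = frozenset(b"ACGT")


def gc_content(iset: IntervalSet, assembly: GenomeAssembly) -> float:
    """GC fraction over the union of bases covered by the set.

    ``(#G + #C) / (#A + #C + #G + #T)``; N bases are excluded from the
    denominator. Overlapping intervals are unioned so no base is counted
    twice. Raises if the union covers no A/C/G/T base.
    """
    if not assembly.has_sequence:
        raise GenomeError("assembly carries no sequence")
    if len(iset) == 0:
        raise GenomeError("empty interval set")
    gc = 0
    acgt = 0
    for iv in merge_intervals(iset):
        assembly.validate_interval(iv)
        sub = assembly.seq_array(iv.chrom)[iv.start : iv.end]
        gc += int(np.count_nonzero((sub == ord("G")) | (sub == ord("C"))))
        acgt += int(
            np.count_nonzero(
                (sub == ord("A")) | (sub == ord("C")) | (sub == ord("G")) | (sub == ord("T"))
            )
        )
    if acgt == 0:
        raise GenomeError("intervals cover only N bases")
    return gc / acgt


def genome_intervals(assembly: GenomeAssembly, name: str = "genome") -> IntervalSet:
    """One full-length interval per chromosome."""
    return IntervalSet(
        [GenomicInterval(c, 0, assembly.chrom_lengths[c]) for c in assembly.chrom_names],
        name=name,
    )
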