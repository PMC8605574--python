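"""Interval-overlap counting and randomization ("iteration") tests.

Overlap between two interval sets is counted on the query side: the number
of query intervals intersecting at least one subject interval by >= 1 bp,
each query counted at most once (matching fractions quoted as k out of the
binding-site count). Significance comes from shuffling the query set:
each interval keeps its length and chromosome and is placed uniformly over
the valid positions, avoiding an exclusion set and self-overlap, and the
empirical p-value uses the add-one rule so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import (
    GenomeAssembly,
    GenomeError,
    GenomicInterval,
    IntervalSet,
    gc_content,
    merge_intervals,
)


@dataclass
class OverlapTestResult:
    observed: float
    null_counts: np.ndarray
    empirical_p: float
    n_iter: int
    shuffle_mode: str = "same_chrom"

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts, ddof=1)) if len(self.null_counts) > 1 else 0.0


# ---------------------------------------------------------------------------
# Overlap counting
# ---------------------------------------------------------------------------

def _merged_arrays(iset: IntervalSet) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    merged = merge_intervals(iset)
    by: Dict[str, List[Tuple[int, int]]] = {}
    for iv in merged:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in by.items():
        a = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (a[:, 0], a[:, 1])
    return out


def _count_against_merged(
    starts: np.ndarray, ends: np.ndarray, subj: Tuple[np.ndarray, np.ndarray]
) -> int:
    """Queries hitting a merged (disjoint, sorted) subject track."""
    s_starts, s_ends = subj
    idx = np.searchsorted(s_starts, ends, side="left")
    hit = (idx > 0) & (s_ends[np.maximum(idx - 1, 0)] > starts)
    return int(np.count_nonzero(hit))


def count_overlaps(query: IntervalSet, subject: IntervalSet) -> int:
    """Number of query intervals intersecting >= 1 subject interval by >= 1 bp."""
    subj = _merged_arrays(subject)
    total = 0
    for chrom, (starts, ends) in query.by_chrom().items():
        if chrom in subj:
            total += _count_against_merged(starts, ends, subj[chrom])
    return total


# ---------------------------------------------------------------------------
# Interval shuffling
# ---------------------------------------------------------------------------

class ShuffleEngine:
    """Reusable length/chromosome-preserving shuffler for one query set.

    Precomputes per-chromosome interval lengths and the merged exclusion
    track so repeated shuffles (randomization tests) are cheap. Placement is
    rejection sampling: uniform over the chromosome's valid start range,
    redrawn while an interval hits the exclusion track or a previously
    placed interval of the same shuffle.
    """

    def __init__(
        self,
        iset: IntervalSet,
        assembly: GenomeAssembly,
        exclude: Optional[IntervalSet] = None,
        max_tries: int = 1000,
    ) -> None:
        self.assembly = assembly
        self.max_tries = max_tries
        self.chroms: List[str] = []
        self.lengths: List[np.ndarray] = []
        by = {}
        for iv in iset:
            assembly.validate_interval(iv)
            by.setdefault(iv.chrom, []).append(len(iv))
        for chrom, lens in by.items():
            self.chroms.append(chrom)
            self.lengths.append(np.asarray(lens, dtype=np.int64))
        self.exclude = _merged_arrays(exclude) if exclude is not None else {}

    def shuffle_arrays(
        self, rng: np.random.Generator
    ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """One shuffle as per-chromosome (starts, ends) arrays."""
        out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, lens in zip(self.chroms, self.lengths):
            L = self.assembly.chrom_lengths[chrom]
            max_start = L - lens
            if (max_start < 0).any():
                raise GenomeError(f"interval longer than chromosome {chrom!r}")
            n = len(lens)
            starts = np.empty(n, dtype=np.int64)
            pending = np.arange(n)
            excl = self.exclude.get(chrom)
            tries = 0
            while len(pending):
                tries += 1
                if tries > self.max_tries:
                    raise GenomeError(
                        f"shuffle placement infeasible on {chrom!r} "
                        f"after {self.max_tries} rounds"
                    )
                draw = (rng.random(len(pending)) * (max_start[pending] + 1)).astype(np.int64)
                starts[pending] = draw
                ends = starts + lens
                bad = np.zeros(n, dtype=bool)
                if excl is not None:
                    e_starts, e_ends = excl
                    idx = np.searchsorted(e_starts, ends, side="left")
                    bad |= (idx > 0) & (e_ends[np.maximum(idx - 1, 0)] > starts)
                # greedy sweep: accept a maximal non-overlapping subset,
                # redraw the rest (rejected intervals only)
                run_end = -1
                for k in np.argsort(starts, kind="stable"):
                    if bad[k]:
                        continue
                    if starts[k] >= run_end:
                        run_end = int(ends[k])
                    else:
                        bad[k] = True
                pending = np.flatnonzero(bad)
            out[chrom] = (starts, starts + lens)
        return out

    def shuffle(self, rng: np.random.Generator, name: str = "shuffled") -> IntervalSet:
        arrays = self.shuffle_arrays(rng)
        intervals = []
        for chrom, (starts, ends) in arrays.items():
            intervals.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        return IntervalSet(intervals, name=name)


def shuffle_intervals(
    iset: IntervalSet,
    assembly: GenomeAssembly,
    exclude: Optional[IntervalSet] = None,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> IntervalSet:
    """Length- and chromosome-preserving uniform reshuffle of a set."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ShuffleEngine(iset, assembly, exclude, max_tries).shuffle(rng)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def overlap_permutation_test(
    query: IntervalSet,
    subject: IntervalSet,
    assembly: GenomeAssembly,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    exclude: Optional[IntervalSet] = None,
) -> OverlapTestResult:
    """One-sided (enrichment) randomization test of query/subject overlap.

    ``p = (1 + #{null >= observed}) / (1 + n_iter)`` (add-one rule).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subj = _merged_arrays(subject)
    observed = count_overlaps(query, subject)
    engine = ShuffleEngine(query, assembly, exclude)
    null = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        arrays = engine.shuffle_arrays(rng)
        c = 0
        for chrom, (starts, ends) in arrays.items():
            if chrom in subj:
                c += _count_against_merged(starts, ends, subj[chrom])
        null[i] = c
    p = (1 + int(np.count_nonzero(null >= observed))) / (1 + n_iter)
    return OverlapTestResult(
        observed=observed, null_counts=null, empirical_p=p, n_iter=n_iter
    )


class _GcPrefix:
    """Per-chromosome prefix sums of GC and A/C/G/T counts for fast set GC."""

    def __init__(self, assembly: GenomeAssembly) -> None:
        self.gc: Dict[str, np.ndarray] = {}
        self.acgt: Dict[str, np.ndarray] = {}
        for chrom in assembly.chrom_names:
            a = assembly.seq_array(chrom)
            is_gc = (a == ord("G")) | (a == ord("C"))
            is_acgt = is_gc | (a == ord("A")) | (a == ord("T"))
            self.gc[chrom] = np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])
            self.acgt[chrom] = np.concatenate([[0], np.cumsum(is_acgt, dtype=np.int64)])

    def set_gc(self, arrays: Dict[str, Tuple[np.ndarray, np.ndarray]]) -> float:
        gc = 0
        acgt = 0
        for chrom, (starts, ends) in arrays.items():
            gc += int((self.gc[chrom][ends] - self.gc[chrom][starts]).sum())
            acgt += int((self.acgt[chrom][ends] - self.acgt[chrom][starts]).sum())
        if acgt == 0:
            raise GenomeError("intervals cover only N bases")
        return gc / acgt


def gc_permutation_test(
    iset: IntervalSet,
    assembly: GenomeAssembly,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    exclude: Optional[IntervalSet] = None,
) -> OverlapTestResult:
    """One-sided randomization test of a set's GC content vs shuffled sets.

    The statistic is :func:`telomap.genome.gc_content` of the set; the null
    distribution is the GC of length/chromosome-preserving shuffles.

    Note: the observed statistic unions overlapping intervals while shuffled
    sets are non-overlapping by construction, so both sides count bases once.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = gc_content(iset, assembly)
    prefix = _GcPrefix(assembly)
    engine = ShuffleEngine(iset, assembly, exclude)
    null = np.empty(n_iter, dtype=np.float64)
    for i in range(n_iter):
        null[i] = prefix.set_gc(engine.shuffle_arrays(rng))
    p = (1 + int(np.count_nonzero(null >= observed))) / (1 + n_iter)
    return OverlapTestResult(
        observed=observed, null_counts=null, empirical_p=p, n_iter=n_iter
    )
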