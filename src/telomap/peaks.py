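"""Sliding-window peak calling for tiling-array ChIP data.

Implements the binding-site discovery procedure: per-track
standardization and per-probe median across replicates, a sliding-window
caller with a Gaussian null estimated by mirroring the negative window
scores about zero (the classic ChIP-chip windowing scheme), Bonferroni
correction across windows, merging of significant windows, a >=k-of-n
replicate consensus, and whole-peak removal of telomere-window hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeError, GenomicInterval, IntervalSet, merge_intervals


@dataclass
class ProbeSignalTrack:
    """Per-replicate tiling-array log2(IP/input) ratios on a probe grid.

    Probes must be sorted and non-overlapping within a chromosome; values
    must be finite.
    """

    chrom: np.ndarray  # object array of chromosome names, probe-parallel
    start: np.ndarray
    end: np.ndarray
    value: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=np.float64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if not (len(self.chrom) == len(self.start) == len(self.end) == len(self.value)):
            raise GenomeError("probe arrays must be parallel")
        if not np.isfinite(self.value).all():
            raise GenomeError("non-finite log-ratio values")

    def __len__(self) -> int:
        return len(self.value)

    def same_grid(self, other: "ProbeSignalTrack") -> bool:
        return (
            len(self) == len(other)
            and bool(np.array_equal(self.start, other.start))
            and bool(np.array_equal(self.end, other.end))
            and bool(np.array_equal(self.chrom, other.chrom))
        )

    def chrom_order(self) -> List[str]:
        seen: Dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "log2_ratio": self.value,
                "replicate": self.replicate_id,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, replicate_id: str = "") -> "ProbeSignalTrack":
        return cls(
            chrom=df["chrom"].to_numpy(object),
            start=df["start"].to_numpy(np.int64),
            end=df["end"].to_numpy(np.int64),
            value=df["log2_ratio"].to_numpy(np.float64),
            replicate_id=replicate_id or str(df["replicate"].iloc[0]) if "replicate" in df else replicate_id,
        )


def write_tracks(tracks: Sequence[ProbeSignalTrack], path: str | Path) -> None:
    pd.concat([t.to_dataframe() for t in tracks]).to_csv(path, sep="\t", index=False)


def read_tracks(path: str | Path) -> List[ProbeSignalTrack]:
    df = pd.read_csv(path, sep="\t")
    return [
        ProbeSignalTrack.from_dataframe(g, replicate_id=str(rep))
        for rep, g in df.groupby("replicate", sort=True)
    ]


@dataclass
class PeakCall:
    """A called peak: merged significant windows with provenance."""

    interval: GenomicInterval
    window_p: float  # smallest Bonferroni-adjusted p among merged windows
    support: int = 1  # number of replicates confirming


# ---------------------------------------------------------------------------
# Replicate combination
# ---------------------------------------------------------------------------

def median_standardize(tracks: Sequence[ProbeSignalTrack]) -> ProbeSignalTrack:
    """Standardize each track to mean 0 / sd 1, then take per-probe medians.

    All tracks must share one probe grid; a zero-variance track is an error.
    """
    if not tracks:
        raise GenomeError("no tracks supplied")
    ref = tracks[0]
    for t in tracks[1:]:
        if not ref.same_grid(t):
            raise GenomeError("tracks are not on a common probe grid")
    z = []
    for t in tracks:
        sd = float(np.std(t.value, ddof=1)) if len(t) > 1 else 0.0
        if sd == 0:
            raise GenomeError(f"zero-variance track {t.replicate_id!r}")
        z.append((t.value - t.value.mean()) / sd)
    med = np.median(np.vstack(z), axis=0)
    return ProbeSignalTrack(
        chrom=ref.chrom.copy(),
        start=ref.start.copy(),
        end=ref.end.copy(),
        value=med,
        replicate_id="median",
    )


# ---------------------------------------------------------------------------
# Sliding-window caller
# ---------------------------------------------------------------------------

def call_peaks(
    track: ProbeSignalTrack,
    window_bp: int = 500,
    step_bp: int = 125,
    alpha: float = 0.05,
) -> List[PeakCall]:
    """Call peaks from one track with a mirrored-null sliding window.

    Windows tile each chromosome at ``step_bp``; a window's score is the
    mean log-ratio of the probes overlapping it. The null is a zero-mean
    Gaussian whose sd is estimated from the negative window scores mirrored
    about zero. Because a window's score variance scales with the number of
    probes it covers, the null sd is estimated separately for each
    probe-count stratum (windows covering k probes), falling back to the
    pooled estimate for sparse strata. One-sided p-values are Bonferroni-
    corrected over the total number of scored windows, and significant
    overlapping or abutting windows are merged into single peaks.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")

    win_chrom: List[str] = []
    win_start: List[np.ndarray] = []
    win_score: List[np.ndarray] = []
    win_nprobes: List[np.ndarray] = []
    for chrom in track.chrom_order():
        m = track.chrom == chrom
        starts = track.start[m]
        ends = track.end[m]
        values = track.value[m]
        if len(values) == 0:
            raise GenomeError(f"no probes on chromosome {chrom!r}")
        L = int(ends[-1])
        w_starts = np.arange(0, L, step_bp, dtype=np.int64)
        w_ends = np.minimum(w_starts + window_bp, L)
        # probes overlapping [ws, we): first with end > ws, last with start < we
        i0 = np.searchsorted(ends, w_starts, side="right")
        i1 = np.searchsorted(starts, w_ends, side="left")
        keep = i1 > i0
        cs = np.concatenate([[0.0], np.cumsum(values)])
        scores = (cs[i1[keep]] - cs[i0[keep]]) / (i1[keep] - i0[keep])
        win_chrom.extend([chrom] * int(keep.sum()))
        win_start.append(w_starts[keep])
        win_score.append(scores)
        win_nprobes.append((i1 - i0)[keep])

    starts_all = np.concatenate(win_start)
    scores_all = np.concatenate(win_score)
    nprobes_all = np.concatenate(win_nprobes)
    n_windows = len(scores_all)

    neg = scores_all[scores_all < 0]
    if neg.size == 0:
        raise GenomeError(
            "all window scores are positive; the mirrored null is inestimable"
        )
    pooled_sd = float(np.sqrt(np.mean(neg**2)))
    null_sd = np.full(n_windows, pooled_sd)
    for k in np.unique(nprobes_all):
        m = nprobes_all == k
        neg_k = scores_all[m & (scores_all < 0)]
        if m.sum() >= 50 and neg_k.size >= 20:
            null_sd[m] = float(np.sqrt(np.mean(neg_k**2)))
    p = stats.norm.sf(scores_all / null_sd)
    p_adj = np.minimum(p * n_windows, 1.0)
    sig = np.flatnonzero(p_adj < alpha)

    chrom_arr = np.asarray(win_chrom, dtype=object)
    peaks: List[PeakCall] = []
    cur: Optional[Tuple[str, int, int, float]] = None  # chrom, start, end, min_p
    for k in sig:
        c = chrom_arr[k]
        ws = int(starts_all[k])
        we = ws + window_bp
        pk = float(p_adj[k])
        if cur is not None and cur[0] == c and ws <= cur[2]:
            cur = (c, cur[1], max(cur[2], we), min(cur[3], pk))
        else:
            if cur is not None:
                peaks.append(PeakCall(GenomicInterval(cur[0], cur[1], cur[2]), cur[3]))
            cur = (c, ws, we, pk)
    if cur is not None:
        peaks.append(PeakCall(GenomicInterval(cur[0], cur[1], cur[2]), cur[3]))
    return peaks


# ---------------------------------------------------------------------------
# Consensus and telomere subtraction
# ---------------------------------------------------------------------------

def replicate_consensus(
    peaksets: Sequence[Sequence[PeakCall]], min_support: int = 3
) -> List[PeakCall]:
    """Regions supported by >= ``min_support`` distinct replicates.

    Candidate regions are the connected components of the union of all
    peaks; a region is retained iff peaks from at least ``min_support``
    distinct replicates intersect it by >= 1 bp. The result is invariant to
    replicate order.
    """
    if len(peaksets) < min_support:
        raise GenomeError(
            f"need >= {min_support} peak sets, got {len(peaksets)}"
        )
    all_peaks: List[Tuple[GenomicInterval, int, float]] = []
    for rep_idx, peaks in enumerate(peaksets):
        for pc in peaks:
            all_peaks.append((pc.interval, rep_idx, pc.window_p))
    if not all_peaks:
        return []
    regions = merge_intervals(iv for iv, _, _ in all_peaks)

    out: List[PeakCall] = []
    for region in regions:
        reps = set()
        min_p = 1.0
        for iv, rep_idx, p in all_peaks:
            if iv.overlaps(region):
                reps.add(rep_idx)
                min_p = min(min_p, p)
        if len(reps) >= min_support:
            out.append(PeakCall(region, min_p, support=len(reps)))
    return out


def subtract_telomeric(
    peaks: Union[Sequence[PeakCall], IntervalSet], telomere_set: IntervalSet
) -> List[PeakCall]:
    """Drop whole peaks that intersect any telomere window by >= 1 bp."""
    if isinstance(peaks, IntervalSet):
        peaks = [PeakCall(iv, float("nan")) for iv in peaks]
    tel = merge_intervals(telomere_set)
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in tel:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for pc in peaks:
        hit = any(pc.interval.overlaps(t) for t in by_chrom.get(pc.interval.chrom, ()))
        if not hit:
            kept.append(pc)
    return kept


def peaks_to_intervals(peaks: Sequence[PeakCall], name: str = "peaks") -> IntervalSet:
    return IntervalSet([pc.interval for pc in peaks], name=name)


def write_peaks_bed(peaks: Sequence[PeakCall], path: str | Path) -> None:
    """BED6 with the adjusted p-value in the score column."""
    with open(path, "w") as fh:
        for k, pc in enumerate(
            sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start)), 1
        ):
            iv = pc.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{k}\t{pc.window_p:.3g}\t.\n"
            )
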