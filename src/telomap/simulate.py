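"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes, at a
scaled-down multi-chromosome genome, with ground-truth labels emitted
alongside every dataset so each downstream stage has an answer key:

* a genome of i.i.d. bases at a background GC fraction with planted TG-rich
  sites of elevated GC placed mid-arm, one per contact-map bin;
* per-replicate tiling-array log-ratio tracks with Gaussian noise, additive
  peaks at planted sites, and per-replicate dropout;
* Hi-C read pairs drawn from an explicit ground-truth contact-weight map
  combining intra-chromosomal distance decay, an inter-chromosomal floor,
  telomere-telomere clustering (Rabl-like), binding-site clustering, and a
  planted subset of sites anchored at the telomere cluster;
* feature interval sets with an exactly controlled overlap count;
* binomial colony counts for the telomere-healing assay.

One global seed fans out to per-generator child streams by a fixed
derivation, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genome import (
    GenomeAssembly,
    GenomeError,
    GenomicInterval,
    IntervalSet,
)
from .hic import PAIR_COLUMNS, digest, assign_fragments
from .peaks import ProbeSignalTrack

# fixed stream keys for the per-generator child seeds
_STREAMS = {
    "genome": 1,
    "chip": 2,
    "features": 3,
    "hic": 4,
    "healing": 5,
    "qpcr": 6,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent child generator for a named stream of one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticConfig:
    """All generator parameters; defaults are the study conditions emulated.

    Fractions are in [0, 1]; ``decay_exponent`` is the intra-chromosomal
    power-law exponent alpha > 0; ``telomere_boost`` (beta >= 1) multiplies
    telomere-telomere contact weights; ``planted_tel_fraction`` is the
    fraction of binding sites planted as telomere-proximal.
    """

    seed: int = 0
    n_chrom: int = 16
    chrom_length_bp: int = 200_000
    base_gc: float = 0.38
    n_ntbs: int = 64
    ntbs_len_bp: int = 1_000
    ntbs_gc: float = 0.52
    ntbs_margin_bp: int = 50_000
    probe_spacing_bp: int = 250
    peak_amplitude: float = 5.0
    noise_sd: float = 1.0
    replicate_detect_prob: float = 0.9
    n_replicates: int = 5
    n_pairs: int = 2_000_000
    decay_exponent: float = 1.0
    inter_floor: float = 0.3
    telomere_boost: float = 3.0
    ntbs_clustering: float = 4.0
    ntbs_tel_affinity: float = 3.0
    planted_tel_fraction: float = 0.14
    hic_bin_bp: int = 10_000
    read_len_bp: int = 75
    healing_freq: float = 1.0
    n_colonies: int = 200

    def __post_init__(self) -> None:
        for name in (
            "base_gc",
            "ntbs_gc",
            "replicate_detect_prob",
            "planted_tel_fraction",
            "healing_freq",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.telomere_boost < 1:
            raise ValueError("telomere_boost must be >= 1")
        if self.ntbs_clustering < 1 or self.ntbs_tel_affinity < 1:
            raise ValueError("clustering boosts must be >= 1")
        if self.probe_spacing_bp >= self.ntbs_len_bp:
            raise ValueError("probe_spacing_bp must be smaller than ntbs_len_bp")
        if self.n_ntbs % self.n_chrom != 0:
            raise ValueError("n_ntbs must be divisible by n_chrom")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Genome with planted TG-rich sites
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float, tg_bias: float = 0.0) -> np.ndarray:
    """i.i.d. bases at a given GC fraction.

    ``tg_bias`` in [0, 1) shifts composition toward T and G at fixed GC:
    P(G) = gc*(1+tg_bias)/2, P(T) = (1-gc)*(1+tg_bias)/2.
    """
    pg = gc * (1 + tg_bias) / 2
    pc = gc - pg
    pt = (1 - gc) * (1 + tg_bias) / 2
    pa = 1 - gc - pt
    idx = rng.choice(4, size=n, p=[pa, pc, pg, pt])
    return _BASES[idx]


def make_genome(config: SyntheticConfig) -> Tuple[GenomeAssembly, IntervalSet]:
    """Generate the toy genome and the planted binding-site coordinates.

    Background bases are i.i.d. with GC = ``base_gc``; planted sites are
    TG-biased stretches with GC = ``ntbs_gc``, placed outside the terminal
    ``ntbs_margin_bp`` of each chromosome with each site's midpoint in a
    distinct contact-map bin (so sites and bins correspond one-to-one for
    the spatial analysis).
    """
    rng = child_rng(config.seed, "genome")
    L = config.chrom_length_bp
    bin_bp = config.hic_bin_bp
    per_chrom = config.n_ntbs // config.n_chrom

    lo_bin = -(-config.ntbs_margin_bp // bin_bp)  # first bin fully past margin
    hi_bin = (L - config.ntbs_margin_bp) // bin_bp - 1  # last bin before margin
    n_central = hi_bin - lo_bin + 1
    if n_central < per_chrom:
        raise GenomeError(
            "genome too small for requested sites: "
            f"{n_central} central bins per chromosome, need {per_chrom}"
        )
    if config.ntbs_len_bp > bin_bp:
        raise GenomeError("ntbs_len_bp must not exceed hic_bin_bp")

    sequences: Dict[str, str] = {}
    lengths: Dict[str, int] = {}
    planted: List[GenomicInterval] = []
    site_id = 0
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1:02d}"
        seq = _random_bases(rng, L, config.base_gc)
        bins = rng.choice(np.arange(lo_bin, hi_bin + 1), size=per_chrom, replace=False)
        bins.sort()
        for b in bins:
            bin_start = int(b) * bin_bp
            start = bin_start + int(
                rng.integers(0, bin_bp - config.ntbs_len_bp + 1)
            )
            end = start + config.ntbs_len_bp
            seq[start:end] = _random_bases(
                rng, config.ntbs_len_bp, config.ntbs_gc, tg_bias=0.55
            )
            site_id += 1
            planted.append(GenomicInterval(chrom, start, end, label=f"NTBS_{site_id:03d}"))
        sequences[chrom] = seq.tobytes().decode("ascii")
        lengths[chrom] = L
    assembly = GenomeAssembly(lengths, sequences)
    return assembly, IntervalSet(planted, name="planted_ntbs")


# ---------------------------------------------------------------------------
# ChIP-chip replicate tracks
# ---------------------------------------------------------------------------

def make_chip_replicates(
    assembly: GenomeAssembly,
    planted: IntervalSet,
    config: SyntheticConfig,
    n_reps: Optional[int] = None,
) -> List[ProbeSignalTrack]:
    """Per-replicate probe log-ratio tracks with peaks at planted sites.

    Probes tile each chromosome contiguously at ``probe_spacing_bp``.
    Background values are Normal(0, noise_sd); in each replicate each
    planted site is detected independently with probability
    ``replicate_detect_prob``, and detected sites add
    ``peak_amplitude * noise_sd`` to every probe overlapping the site.
    """
    rng = child_rng(config.seed, "chip")
    n_reps = config.n_replicates if n_reps is None else n_reps
    spacing = config.probe_spacing_bp

    chrom_arrs = []
    start_arrs = []
    for chrom in assembly.chrom_names:
        L = assembly.chrom_lengths[chrom]
        starts = np.arange(0, L, spacing, dtype=np.int64)
        chrom_arrs.append(np.full(len(starts), chrom, dtype=object))
        start_arrs.append(starts)
    chroms = np.concatenate(chrom_arrs)
    starts = np.concatenate(start_arrs)
    lens = np.array([assembly.chrom_lengths[c] for c in chroms], dtype=np.int64)
    ends = np.minimum(starts + spacing, lens)

    # probe index ranges overlapping each planted site, per chromosome
    site_slices: List[Tuple[int, int]] = []
    for iv in planted:
        m = np.flatnonzero(chroms == iv.chrom)
        c_starts = starts[m]
        c_ends = ends[m]
        i0 = int(np.searchsorted(c_ends, iv.start, side="right"))
        i1 = int(np.searchsorted(c_starts, iv.end, side="left"))
        site_slices.append((m[0] + i0, m[0] + i1))

    tracks = []
    for rep in range(n_reps):
        values = rng.normal(0.0, config.noise_sd, size=len(starts))
        detected = rng.random(len(site_slices)) < config.replicate_detect_prob
        for (a, b), hit in zip(site_slices, detected):
            if hit:
                values[a:b] += config.peak_amplitude * config.noise_sd
        tracks.append(
            ProbeSignalTrack(
                chrom=chroms.copy(),
                start=starts.copy(),
                end=ends.copy(),
                value=values,
                replicate_id=f"rep{rep + 1}",
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Feature tracks with controlled overlap
# ---------------------------------------------------------------------------

def make_feature_track(
    planted_ntbs: IntervalSet,
    assembly: GenomeAssembly,
    n_features: int,
    n_overlapping: int,
    seed: int,
    feature_len_bp: int = 500,
    name: str = "feature",
) -> IntervalSet:
    """Feature intervals of which exactly ``n_overlapping`` hit planted sites.

    Each overlapping feature targets a distinct planted site (>= 1 bp
    intersection); the remaining features are placed uniformly avoiding all
    planted sites, so ``count_overlaps(planted, features) == n_overlapping``.
    """
    if n_overlapping > min(n_features, len(planted_ntbs)):
        raise ValueError("n_overlapping exceeds n_features or planted count")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS["features"],)))
    intervals: List[GenomicInterval] = []

    targets = rng.choice(len(planted_ntbs), size=n_overlapping, replace=False)
    for k, t in enumerate(targets):
        site = planted_ntbs[int(t)]
        L = assembly.chrom_lengths[site.chrom]
        # start range guaranteeing >= 1 bp intersection
        lo = max(0, site.start - feature_len_bp + 1)
        hi = min(L - feature_len_bp, site.end - 1)
        start = int(rng.integers(lo, hi + 1))
        intervals.append(
            GenomicInterval(site.chrom, start, start + feature_len_bp, label=f"{name}_{k+1}")
        )

    by_chrom = planted_ntbs.by_chrom()
    n_rest = n_features - n_overlapping
    placed = 0
    tries = 0
    while placed < n_rest:
        tries += 1
        if tries > 1000 * n_rest + 1000:
            raise GenomeError("feature placement infeasible")
        chrom = assembly.chrom_names[int(rng.integers(len(assembly.chrom_names)))]
        L = assembly.chrom_lengths[chrom]
        if L < feature_len_bp:
            continue
        start = int(rng.integers(0, L - feature_len_bp + 1))
        end = start + feature_len_bp
        if chrom in by_chrom:
            s, e = by_chrom[chrom]
            j = int(np.searchsorted(s, end, side="left"))
            if j > 0 and e[j - 1] > start:
                continue
        placed += 1
        intervals.append(
            GenomicInterval(chrom, start, end, label=f"{name}_{n_overlapping + placed}")
        )
    return IntervalSet(intervals, name=name)


# ---------------------------------------------------------------------------
# Hi-C pairs from a ground-truth contact-weight map
# ---------------------------------------------------------------------------

@dataclass
class HicTruth:
    """Answer key emitted with every synthetic Hi-C dataset."""

    bin_size: int
    ntbs_bins: np.ndarray  # global bin of each site, parallel to the site set
    planted_site_idx: np.ndarray  # indices of telomere-proximal sites
    planted_bins: np.ndarray
    telomere_bins: Dict[str, Tuple[int, int]]  # chrom -> (first, last) global bin
    weight_matrix: np.ndarray  # ground-truth symmetric contact weights


def _bin_geometry(assembly: GenomeAssembly, bin_size: int):
    nbins = {c: -(-assembly.chrom_lengths[c] // bin_size) for c in assembly.chrom_names}
    offsets = {}
    off = 0
    for c in assembly.chrom_names:
        offsets[c] = off
        off += nbins[c]
    return nbins, offsets, off


def ground_truth_weights(
    assembly: GenomeAssembly,
    ntbs_bins: np.ndarray,
    planted_bins: np.ndarray,
    config: SyntheticConfig,
) -> Tuple[np.ndarray, Dict[str, Tuple[int, int]]]:
    """Ground-truth symmetric contact-weight matrix of the generator.

    Structure (alpha = decay exponent, beta = telomere_boost):

    * intra-chromosomal base weight ``(|i-j| + 1) ** -alpha``;
    * inter-chromosomal base weight ``inter_floor``;
    * telomere x telomere entries (all ends, Rabl-like clustering) x beta;
    * binding-site x binding-site entries x ``ntbs_clustering``;
    * binding-site x telomere entries x ``ntbs_tel_affinity``;
    * planted sites are anchored at the telomere cluster: their weight to
      each telomere bin of their own chromosome becomes ``beta`` (the
      zero-distance weight, as if colocalized with the telomere), and to
      other telomere bins ``beta * inter_floor``, taking the maximum with
      the unanchored weight.
    """
    nbins, offsets, n = _bin_geometry(assembly, config.hic_bin_bp)
    alpha = config.decay_exponent

    chrom_idx = np.empty(n, dtype=np.int64)
    local = np.empty(n, dtype=np.int64)
    for k, c in enumerate(assembly.chrom_names):
        sl = slice(offsets[c], offsets[c] + nbins[c])
        chrom_idx[sl] = k
        local[sl] = np.arange(nbins[c])

    same = chrom_idx[:, None] == chrom_idx[None, :]
    dist = np.abs(local[:, None] - local[None, :])
    W = np.where(same, (dist + 1.0) ** -alpha, config.inter_floor)

    tel_bins: Dict[str, Tuple[int, int]] = {}
    tel_list = []
    for c in assembly.chrom_names:
        first = offsets[c]
        last = offsets[c] + nbins[c] - 1
        tel_bins[c] = (first, last)
        tel_list.extend([first, last])
    tel = np.zeros(n, dtype=bool)
    tel[tel_list] = True
    ntbs = np.zeros(n, dtype=bool)
    ntbs[np.unique(ntbs_bins)] = True

    W[np.ix_(tel, tel)] *= config.telomere_boost
    W[np.ix_(ntbs, ntbs)] *= config.ntbs_clustering
    W[np.ix_(ntbs, tel)] *= config.ntbs_tel_affinity
    W[np.ix_(tel, ntbs)] *= config.ntbs_tel_affinity

    beta = config.telomere_boost
    anchor_cis = beta  # zero-distance decay weight: colocalized with the telomere
    anchor_trans = beta * config.inter_floor
    tel_idx = np.flatnonzero(tel)
    for b in np.unique(planted_bins):
        for t in tel_idx:
            w_anchor = anchor_cis if chrom_idx[t] == chrom_idx[b] else anchor_trans
            w = max(W[b, t], w_anchor)
            W[b, t] = w
            W[t, b] = w
    return W, tel_bins


def make_hic_pairs(
    assembly: GenomeAssembly,
    ntbs: IntervalSet,
    config: SyntheticConfig,
) -> Tuple[pd.DataFrame, HicTruth]:
    """Sample Hi-C read pairs from the ground-truth contact-weight map.

    Exactly ``n_pairs`` pairs are drawn multinomially over bin pairs, with
    read positions uniform inside each bin and strands uniform. Same-
    fragment pairs are nudged onto the neighbouring restriction fragment so
    that virtually all pairs survive classification as valid products.
    Returns the BEDPE-like pair table and the :class:`HicTruth` answer key.
    """
    rng = child_rng(config.seed, "hic")
    bin_size = config.hic_bin_bp
    nbins, offsets, n = _bin_geometry(assembly, bin_size)

    mids = np.array([iv.midpoint() for iv in ntbs], dtype=np.int64)
    ntbs_bins = np.array(
        [offsets[iv.chrom] + m // bin_size for iv, m in zip(ntbs, mids)], dtype=np.int64
    )
    n_planted = math.ceil(config.planted_tel_fraction * len(ntbs))
    planted_idx = np.sort(rng.choice(len(ntbs), size=n_planted, replace=False))
    planted_bins = ntbs_bins[planted_idx]

    W, tel_bins = ground_truth_weights(assembly, ntbs_bins, planted_bins, config)

    iu, ju = np.triu_indices(n)
    w = W[iu, ju].astype(np.float64)
    counts = rng.multinomial(config.n_pairs, w / w.sum())
    nz = counts > 0
    bins_i = np.repeat(iu[nz], counts[nz])
    bins_j = np.repeat(ju[nz], counts[nz])

    # geometry lookup arrays per global bin
    bin_chrom = np.empty(n, dtype=object)
    bin_start = np.empty(n, dtype=np.int64)
    bin_end = np.empty(n, dtype=np.int64)
    for c in assembly.chrom_names:
        sl = slice(offsets[c], offsets[c] + nbins[c])
        bin_chrom[sl] = c
        loc = np.arange(nbins[c], dtype=np.int64)
        bin_start[sl] = loc * bin_size
        bin_end[sl] = np.minimum((loc + 1) * bin_size, assembly.chrom_lengths[c])

    def positions(bins: np.ndarray) -> np.ndarray:
        lo = bin_start[bins]
        hi = bin_end[bins]
        return lo + (rng.random(len(bins)) * (hi - lo)).astype(np.int64)

    pos1 = positions(bins_i)
    pos2 = positions(bins_j)
    strands = np.array(["+", "-"], dtype=object)
    strand1 = strands[rng.integers(0, 2, size=len(bins_i))]
    strand2 = strands[rng.integers(0, 2, size=len(bins_i))]
    chrom1 = bin_chrom[bins_i]
    chrom2 = bin_chrom[bins_j]

    # nudge same-fragment pairs onto the next restriction fragment
    rmap = digest(assembly)
    close = (chrom1 == chrom2) & (np.abs(pos1 - pos2) < 2_000)
    if close.any():
        f1 = assign_fragments(rmap, chrom1[close], pos1[close])
        f2 = assign_fragments(rmap, chrom2[close], pos2[close])
        same = f1 == f2
        if same.any():
            idx = np.flatnonzero(close)[same]
            for k, frag in zip(idx, f2[same]):
                c = chrom2[k]
                starts = rmap.frag_starts[c]
                loc = frag - rmap.frag_offsets[c]
                if loc + 1 < len(starts):
                    pos2[k] = starts[loc + 1]
                elif loc > 0:
                    pos2[k] = starts[loc] - 1
                # single-fragment chromosome: leave as is

    order = rng.permutation(len(bins_i))
    pairs = pd.DataFrame(
        {
            "chrom1": chrom1[order],
            "pos1": pos1[order],
            "strand1": strand1[order],
            "chrom2": chrom2[order],
            "pos2": pos2[order],
            "strand2": strand2[order],
            "read_len": np.full(len(bins_i), config.read_len_bp, dtype=np.int64),
        }
    )
    truth = HicTruth(
        bin_size=bin_size,
        ntbs_bins=ntbs_bins,
        planted_site_idx=planted_idx,
        planted_bins=planted_bins,
        telomere_bins=tel_bins,
        weight_matrix=W,
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# Healing-assay colony counts and qPCR tables
# ---------------------------------------------------------------------------

def make_healing_counts(
    freq: float, n_colonies: int, seed: int, construct: str = "construct"
) -> pd.DataFrame:
    """Binomial resistant-colony count at a stated telomere-addition frequency."""
    if not (0.0 <= freq <= 1.0):
        raise ValueError("freq must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS["healing"],))
    )
    resistant = int(rng.binomial(n_colonies, freq))
    return pd.DataFrame(
        {"construct": [construct], "total": [n_colonies], "resistant": [resistant]}
    )


def make_qpcr_table(
    fold_by_locus: Dict[str, float],
    n_reps: int = 5,
    seed: int = 0,
    ct_noise_sd: float = 0.0,
    control_locus: str = "ARO1",
    efficiency: float = 2.0,
    input_ct: float = 20.0,
    control_ip_over_input: float = 0.01,
) -> pd.DataFrame:
    """Ct table engineered so each locus has a known fold over the control.

    Per replicate the control locus gets IP/Input = ``control_ip_over_input``
    and each target IP/Input = fold * control value, converted to Cts at the
    given amplification efficiency; optional independent Gaussian Ct noise
    per channel on top (zero noise gives the folds exactly).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS["qpcr"],))
    )
    rows = []
    loci = {control_locus: 1.0, **fold_by_locus}
    for rep in range(1, n_reps + 1):
        for locus, fold in loci.items():
            ratio = control_ip_over_input * fold
            ct_input = input_ct
            ct_ip = input_ct - math.log(ratio) / math.log(efficiency)
            if ct_noise_sd:
                ct_input += rng.normal(0, ct_noise_sd)
                ct_ip += rng.normal(0, ct_noise_sd)
            rows.append((locus, "Input", f"rep{rep}", ct_input))
            rows.append((locus, "IP", f"rep{rep}", ct_ip))
    return pd.DataFrame(rows, columns=["locus", "channel", "replicate", "Ct"])


# ---------------------------------------------------------------------------
# Table writers (plain-text external interfaces)
# ---------------------------------------------------------------------------

def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False, columns=PAIR_COLUMNS)


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise GenomeError(f"pairs table missing columns: {sorted(missing)}")
    return df
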