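"""Telomere-proximity classification of binding sites from balanced Hi-C.

For each binding site the statistic compares the site's maximum balanced
contact probability with the two telomere bins of its own chromosome
(``tel_score``) against its mean contact probability with all other
binding-site bins (``ntbs_score``, self excluded). A site is classified
telomere-proximal iff ``tel_score > ntbs_score`` (strict; ties are
site-proximal). Significance of the whole set's telomere proximity against
randomized control regions uses a one-sided two-sample Wilcoxon rank-sum
test on the per-site telomere scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .genome import GenomeAssembly, GenomeError, GenomicInterval, IntervalSet
from .hic import ContactMatrix
from .overlap import ShuffleEngine

TELOMERE_PROXIMAL = "telomere_proximal"
NTBS_PROXIMAL = "ntbs_proximal"


@dataclass
class ProximityResult:
    site: GenomicInterval
    bin: int
    tel_score: float
    ntbs_score: float
    proximity_class: Optional[str]
    excluded: bool = False


@dataclass
class ProximityTestResult:
    statistic: float  # Mann-Whitney U of site scores vs control scores
    p_value: float
    median_sites: float
    median_controls: float
    n_sites: int
    n_controls: int


def sites_to_bins(
    iset: IntervalSet, matrix: ContactMatrix
) -> Tuple[np.ndarray, np.ndarray]:
    """Map each site to the bin containing its midpoint.

    Returns (global bin ids, excluded flags); a site whose bin is masked out
    of the balancing support is flagged excluded. Midpoints exactly on a bin
    boundary fall in the downstream bin (half-open convention).
    """
    bins = np.array(
        [matrix.bin_index(iv.chrom, iv.midpoint()) for iv in iset], dtype=np.int64
    )
    excluded = ~matrix.mask[bins]
    return bins, excluded


def telomere_bins(matrix: ContactMatrix, k: int = 1) -> Dict[str, np.ndarray]:
    """The ``k`` terminal bins at each end of every chromosome."""
    out = {}
    for chrom in matrix.chrom_names:
        first, last = matrix.chrom_bins(chrom)
        kk = min(k, matrix.chrom_nbins[chrom])
        out[chrom] = np.unique(
            np.concatenate([np.arange(first, first + kk), np.arange(last - kk + 1, last + 1)])
        )
    return out


def classify_sites(
    matrix: ContactMatrix,
    ntbs: IntervalSet,
    k_tel_bins: int = 1,
    all_telomeres: bool = False,
) -> Tuple[List[ProximityResult], Dict[str, float]]:
    """Classify each site as telomere-proximal or site-proximal.

    ``tel_score`` is the maximum contact probability with the telomere bins
    of the site's own chromosome (or of all chromosomes when
    ``all_telomeres``); ``ntbs_score`` is the mean contact probability with
    the bins of all other sites (sites sharing a bin are collapsed to one
    bin for scoring; masked entries are dropped from the mean). The summary
    reports counts and fractions over non-excluded sites.
    """
    if matrix.state != "balanced":
        raise GenomeError("classification requires a balanced matrix")
    if len(ntbs) < 2:
        raise GenomeError("need >= 2 sites")
    bins, excluded = sites_to_bins(ntbs, matrix)
    tel = telomere_bins(matrix, k=k_tel_bins)
    all_tel = np.unique(np.concatenate(list(tel.values())))
    uniq = np.unique(bins[~excluded])

    m = matrix.matrix
    mask = matrix.mask
    results: List[ProximityResult] = []
    n_tel = 0
    n_ntbs = 0
    n_excl = 0
    for iv, b, ex in zip(ntbs, bins, excluded):
        if ex:
            n_excl += 1
            results.append(
                ProximityResult(iv, int(b), float("nan"), float("nan"), None, True)
            )
            continue
        tbins = all_tel if all_telomeres else tel[iv.chrom]
        tbins = tbins[mask[tbins]]
        others = uniq[(uniq != b) & mask[uniq]]
        if len(tbins) == 0 or len(others) == 0:
            n_excl += 1
            results.append(
                ProximityResult(iv, int(b), float("nan"), float("nan"), None, True)
            )
            continue
        tel_score = float(m[b, tbins].max())
        ntbs_score = float(m[b, others].mean())
        cls = TELOMERE_PROXIMAL if tel_score > ntbs_score else NTBS_PROXIMAL
        if cls == TELOMERE_PROXIMAL:
            n_tel += 1
        else:
            n_ntbs += 1
        results.append(ProximityResult(iv, int(b), tel_score, ntbs_score, cls, False))
    n_used = n_tel + n_ntbs
    summary = {
        "n_sites": len(ntbs),
        "n_excluded": n_excl,
        "n_telomere_proximal": n_tel,
        "n_ntbs_proximal": n_ntbs,
        "frac_telomere_proximal": n_tel / n_used if n_used else float("nan"),
        "frac_ntbs_proximal": n_ntbs / n_used if n_used else float("nan"),
    }
    return results, summary


def _tel_scores_for_bins(
    matrix: ContactMatrix,
    bins: np.ndarray,
    chroms: Sequence[str],
    tel: Dict[str, np.ndarray],
    all_telomeres: bool,
) -> np.ndarray:
    all_tel = np.unique(np.concatenate(list(tel.values())))
    out = np.full(len(bins), np.nan)
    m = matrix.matrix
    mask = matrix.mask
    for i, (b, chrom) in enumerate(zip(bins, chroms)):
        if not mask[b]:
            continue
        tbins = all_tel if all_telomeres else tel[chrom]
        tbins = tbins[mask[tbins]]
        if len(tbins):
            out[i] = m[b, tbins].max()
    return out[np.isfinite(out)]


def proximity_randomization_test(
    matrix: ContactMatrix,
    ntbs: IntervalSet,
    assembly: GenomeAssembly,
    n_iter: int = 20,
    seed: int | np.random.Generator = 0,
    exclude: Optional[IntervalSet] = None,
    k_tel_bins: int = 1,
    all_telomeres: bool = False,
) -> ProximityTestResult:
    """Wilcoxon rank-sum test of site telomere scores vs shuffled controls.

    Controls are ``n_iter`` length/chromosome-preserving shuffles of the
    site set (avoiding ``exclude``), pooled; the one-sided alternative is
    that sites have *greater* telomere contact than controls. Degenerate
    all-tied inputs give p = 1 with a warning.
    """
    if matrix.state != "balanced":
        raise GenomeError("test requires a balanced matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tel = telomere_bins(matrix, k=k_tel_bins)

    bins, _ = sites_to_bins(ntbs, matrix)
    site_scores = _tel_scores_for_bins(
        matrix, bins, [iv.chrom for iv in ntbs], tel, all_telomeres
    )

    engine = ShuffleEngine(ntbs, assembly, exclude)
    control_scores = []
    for _ in range(n_iter):
        arrays = engine.shuffle_arrays(rng)
        for chrom, (starts, ends) in arrays.items():
            mids = (starts + ends) // 2
            cbins = matrix.chrom_offsets[chrom] + mids // matrix.bin_size
            control_scores.append(
                _tel_scores_for_bins(
                    matrix, cbins, [chrom] * len(cbins), tel, all_telomeres
                )
            )
    controls = np.concatenate(control_scores)
    if len(site_scores) == 0 or len(controls) == 0:
        raise GenomeError("no scorable sites or controls")
    if np.ptp(np.concatenate([site_scores, controls])) == 0:
        warnings.warn("all telomere scores tied; test degenerate", RuntimeWarning)
        return ProximityTestResult(
            statistic=float("nan"),
            p_value=1.0,
            median_sites=float(np.median(site_scores)),
            median_controls=float(np.median(controls)),
            n_sites=len(site_scores),
            n_controls=len(controls),
        )
    res = stats.mannwhitneyu(site_scores, controls, alternative="greater")
    return ProximityTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_sites=float(np.median(site_scores)),
        median_controls=float(np.median(controls)),
        n_sites=len(site_scores),
        n_controls=len(controls),
    )
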