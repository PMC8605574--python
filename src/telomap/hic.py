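"""Hi-C contact-map construction from mapped read pairs.

The stages mirror a standard Hi-C post-alignment pipeline: in-silico
restriction digestion (DpnII, ^GATC), classification of read pairs into
valid / self-ligation / non-ligation products by their restriction
fragments, proportional binning of valid pairs into fixed-size genomic bins
(each pair contributes unit mass, split between bins by base overlap of the
two read spans), and Sinkhorn-Knopp balancing of the symmetric raw matrix so
every row and column over the support sums to 1.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, GenomeError, GenomicInterval, IntervalSet

PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "read_len"]

VALID = "valid"
SELF_LIGATION = "self_ligation"
NON_LIGATION = "non_ligation"


class BalanceError(RuntimeError):
    """Raised when balancing is requested on an unsuitable matrix."""


# ---------------------------------------------------------------------------
# Restriction digestion
# ---------------------------------------------------------------------------

@dataclass
class RestrictionMap:
    """Per-chromosome restriction fragments as sorted start positions.

    ``frag_starts[chrom]`` holds the start of every fragment (the first entry
    is 0, the rest are cut sites); fragments partition ``[0, L)`` exactly.
    Fragment ids are global, in chromosome order.
    """

    chrom_names: List[str]
    chrom_lengths: Dict[str, int]
    frag_starts: Dict[str, np.ndarray]
    frag_offsets: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        offset = 0
        for chrom in self.chrom_names:
            self.frag_offsets[chrom] = offset
            offset += len(self.frag_starts[chrom])
        self.n_fragments = offset

    def fragments(self, chrom: str) -> List[GenomicInterval]:
        starts = self.frag_starts[chrom]
        ends = np.append(starts[1:], self.chrom_lengths[chrom])
        return [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]


def digest(assembly: GenomeAssembly, motif: str = "GATC") -> RestrictionMap:
    """In-silico digestion: one cut at the first base of every motif hit.

    DpnII cuts 5' of GATC (^GATC), so the cut coordinate is the motif start.
    A motif-free chromosome yields a single fragment ``[0, L)``.
    """
    if not assembly.has_sequence:
        raise GenomeError("digestion requires sequence")
    frag_starts: Dict[str, np.ndarray] = {}
    pattern = re.compile(motif.upper())
    for chrom in assembly.chrom_names:
        seq = assembly.sequence(chrom)
        cuts = [m.start() for m in pattern.finditer(seq) if m.start() > 0]
        frag_starts[chrom] = np.asarray([0] + cuts, dtype=np.int64)
    return RestrictionMap(
        list(assembly.chrom_names), dict(assembly.chrom_lengths), frag_starts
    )


def assign_fragment(rmap: RestrictionMap, chrom: str, pos: int) -> int:
    """Global id of the fragment whose half-open span contains ``pos``.

    A position exactly on a cut site belongs to the downstream fragment.
    """
    if not (0 <= pos < rmap.chrom_lengths[chrom]):
        raise GenomeError(f"position {chrom}:{pos} out of bounds")
    local = int(np.searchsorted(rmap.frag_starts[chrom], pos, side="right")) - 1
    return rmap.frag_offsets[chrom] + local


def assign_fragments(
    rmap: RestrictionMap, chroms: Sequence[str], positions: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`assign_fragment` over parallel chrom/pos arrays."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    out = np.empty(len(positions), dtype=np.int64)
    for chrom in np.unique(chroms):
        m = chroms == chrom
        pos = positions[m]
        if pos.size and (pos.min() < 0 or pos.max() >= rmap.chrom_lengths[chrom]):
            raise GenomeError(f"position out of bounds on {chrom}")
        local = np.searchsorted(rmap.frag_starts[chrom], pos, side="right") - 1
        out[m] = local + rmap.frag_offsets[chrom]
    return out


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

def classify_pairs(
    pairs: pd.DataFrame, rmap: RestrictionMap
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Classify read pairs by restriction fragment and strand.

    Reads on different fragments (any chromosomes) form a *valid* Hi-C
    product. Same-fragment pairs are ligation artifacts: convergent (inward
    pointing) strands indicate an unligated fragment (*non_ligation*, a
    dangling end); divergent or equal strands indicate a circularized or
    re-ligated fragment (*self_ligation*). Positions are used only to orient
    same-fragment pairs (leftmost read first).

    Returns the table with ``frag1``/``frag2``/``pair_class`` columns added,
    plus a census of class counts.
    """
    df = pairs.copy()
    df["frag1"] = assign_fragments(rmap, df["chrom1"].to_numpy(), df["pos1"].to_numpy())
    df["frag2"] = assign_fragments(rmap, df["chrom2"].to_numpy(), df["pos2"].to_numpy())
    same = (df["frag1"] == df["frag2"]).to_numpy()

    pos1 = df["pos1"].to_numpy()
    pos2 = df["pos2"].to_numpy()
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    # orient each same-fragment pair by position: left read's strand first
    left_first = pos1 <= pos2
    left_strand = np.where(left_first, s1, s2)
    right_strand = np.where(left_first, s2, s1)
    convergent = (left_strand == "+") & (right_strand == "-")

    cls = np.where(same, np.where(convergent, NON_LIGATION, SELF_LIGATION), VALID)
    df["pair_class"] = cls
    census = {
        VALID: int(np.count_nonzero(cls == VALID)),
        NON_LIGATION: int(np.count_nonzero(cls == NON_LIGATION)),
        SELF_LIGATION: int(np.count_nonzero(cls == SELF_LIGATION)),
    }
    return df, census


def deduplicate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Optional exact-coordinate duplicate removal (off by default upstream)."""
    return pairs.drop_duplicates(
        subset=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Contact matrix
# ---------------------------------------------------------------------------

class ContactMatrix:
    """Genome-wide binned symmetric contact matrix.

    The dense matrix holds full symmetric entries: off-diagonal mass is
    mirrored, the diagonal is not doubled, and "total mass counting each
    pair once" is ``(sum + trace) / 2``. ``state`` is ``raw`` or
    ``balanced``; masked bins (zero raw marginal) are excluded from
    balancing and their entries read as missing (NaN).
    """

    def __init__(
        self,
        matrix: np.ndarray,
        bin_size: int,
        chrom_names: Sequence[str],
        chrom_lengths: Dict[str, int],
        state: str = "raw",
        mask: Optional[np.ndarray] = None,
        converged: bool = True,
        balance_iterations: int = 0,
        balance_residual: float = float("nan"),
    ) -> None:
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.bin_size = int(bin_size)
        self.chrom_names = list(chrom_names)
        self.chrom_lengths = dict(chrom_lengths)
        self.state = state
        self.chrom_nbins: Dict[str, int] = {
            c: -(-chrom_lengths[c] // bin_size) for c in self.chrom_names
        }
        self.chrom_offsets: Dict[str, int] = {}
        off = 0
        for c in self.chrom_names:
            self.chrom_offsets[c] = off
            off += self.chrom_nbins[c]
        self.n_bins = off
        if self.matrix.shape != (self.n_bins, self.n_bins):
            raise ValueError("matrix shape does not match binning")
        self.mask = (
            np.ones(self.n_bins, dtype=bool) if mask is None else np.asarray(mask, bool)
        )
        self.converged = converged
        self.balance_iterations = balance_iterations
        self.balance_residual = balance_residual

    # -- indexing ----------------------------------------------------------
    def bin_index(self, chrom: str, pos: int) -> int:
        if not (0 <= pos < self.chrom_lengths[chrom]):
            raise GenomeError(f"position {chrom}:{pos} out of bounds")
        return self.chrom_offsets[chrom] + pos // self.bin_size

    def bin_interval(self, global_bin: int) -> GenomicInterval:
        for chrom in self.chrom_names:
            off = self.chrom_offsets[chrom]
            if off <= global_bin < off + self.chrom_nbins[chrom]:
                local = global_bin - off
                start = local * self.bin_size
                return GenomicInterval(
                    chrom, start, min(start + self.bin_size, self.chrom_lengths[chrom])
                )
        raise IndexError(global_bin)

    def chrom_bins(self, chrom: str) -> Tuple[int, int]:
        """Global [first, last] bin ids of a chromosome (inclusive)."""
        off = self.chrom_offsets[chrom]
        return off, off + self.chrom_nbins[chrom] - 1

    # -- quantities --------------------------------------------------------
    def total_mass(self) -> float:
        """Total contact mass counting each pair once."""
        return float((self.matrix.sum() + np.trace(self.matrix)) / 2.0)

    def contact_probability(self, bin_i: int, bin_j: int) -> float:
        """Symmetric accessor; masked bins read as NaN, not zero."""
        if not (self.mask[bin_i] and self.mask[bin_j]):
            return float("nan")
        return float(self.matrix[bin_i, bin_j])

    # -- text I/O ----------------------------------------------------------
    def write_text(self, path: str | Path) -> None:
        """Coordinate-list (bin_i, bin_j, value) text format with header."""
        with open(path, "w") as fh:
            fh.write("#telomap-contact-matrix\tv1\n")
            fh.write(f"#bin_size\t{self.bin_size}\n")
            fh.write(f"#state\t{self.state}\n")
            fh.write(f"#converged\t{int(self.converged)}\n")
            for c in self.chrom_names:
                fh.write(f"#chrom\t{c}\t{self.chrom_lengths[c]}\n")
            fh.write("#mask\t" + ",".join(str(int(m)) for m in self.mask) + "\n")
            ii, jj = np.nonzero(np.triu(self.matrix))
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\t{float(self.matrix[i, j])!r}\n")

    @classmethod
    def read_text(cls, path: str | Path) -> "ContactMatrix":
        bin_size = None
        state = "raw"
        converged = True
        chrom_names: List[str] = []
        chrom_lengths: Dict[str, int] = {}
        mask: Optional[np.ndarray] = None
        triplets: List[Tuple[int, int, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    fields = line[1:].split("\t")
                    if fields[0] == "bin_size":
                        bin_size = int(fields[1])
                    elif fields[0] == "state":
                        state = fields[1]
                    elif fields[0] == "converged":
                        converged = bool(int(fields[1]))
                    elif fields[0] == "chrom":
                        chrom_names.append(fields[1])
                        chrom_lengths[fields[1]] = int(fields[2])
                    elif fields[0] == "mask":
                        mask = np.array([bool(int(x)) for x in fields[1].split(",")])
                elif line:
                    i, j, v = line.split("\t")
                    triplets.append((int(i), int(j), float(v)))
        if bin_size is None or not chrom_names:
            raise GenomeError(f"malformed contact-matrix file {path}")
        n = sum(-(-chrom_lengths[c] // bin_size) for c in chrom_names)
        m = np.zeros((n, n))
        for i, j, v in triplets:
            m[i, j] = v
            m[j, i] = v
        return cls(
            m, bin_size, chrom_names, chrom_lengths, state=state, mask=mask,
            converged=converged,
        )


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def _read_spans(
    pos: np.ndarray, strand: np.ndarray, read_len: np.ndarray, chrom_len: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Aligned span of each read on forward coordinates, clipped to bounds.

    '+' reads cover ``[pos, pos+len)``; '-' reads cover ``[pos+1-len, pos+1)``.
    """
    fwd = strand == "+"
    start = np.where(fwd, pos, pos + 1 - read_len)
    end = np.where(fwd, pos + read_len, pos + 1)
    start = np.clip(start, 0, None)
    end = np.minimum(end, chrom_len)
    return start.astype(np.int64), end.astype(np.int64)


def bin_pairs(
    valid_pairs: pd.DataFrame,
    assembly: GenomeAssembly,
    bin_size: int = 10_000,
) -> ContactMatrix:
    """Bin valid pairs into a raw contact matrix, splitting reads by overlap.

    Each read end is an interval of its aligned length; the read's unit mass
    is divided between bins proportional to base overlap, and the pair's
    contribution to entry (i, j) is the product of the two ends' bin masses,
    symmetrized. Total matrix mass equals the number of pairs up to float
    rounding. Requires ``read_len <= bin_size`` so a read spans at most two
    bins.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    nb_total = sum(-(-assembly.chrom_lengths[c] // bin_size) for c in assembly.chrom_names)
    cm = ContactMatrix(
        np.zeros((nb_total, nb_total)),
        bin_size,
        assembly.chrom_names,
        assembly.chrom_lengths,
        state="raw",
    )
    n = len(valid_pairs)
    if n == 0:
        return cm
    if int(valid_pairs["read_len"].max()) > bin_size:
        raise ValueError("read_len larger than bin_size is not supported")

    offsets = valid_pairs["chrom1"].map(cm.chrom_offsets).to_numpy(np.int64)
    offsets2 = valid_pairs["chrom2"].map(cm.chrom_offsets).to_numpy(np.int64)
    lens1 = valid_pairs["chrom1"].map(assembly.chrom_lengths).to_numpy(np.int64)
    lens2 = valid_pairs["chrom2"].map(assembly.chrom_lengths).to_numpy(np.int64)
    rl = valid_pairs["read_len"].to_numpy(np.int64)

    def end_masses(pos, strand, offs, clen):
        start, end = _read_spans(pos, strand, rl, clen)
        b0 = start // bin_size
        boundary = (b0 + 1) * bin_size
        span = (end - start).astype(np.float64)
        in_first = np.minimum(end, boundary) - start
        frac0 = np.where(span > 0, in_first / np.maximum(span, 1), 1.0)
        nbins_here = -(-clen // bin_size)
        b1 = np.minimum(b0 + 1, nbins_here - 1)
        return offs + b0, offs + b1, frac0, 1.0 - frac0

    i0, i1, fi0, fi1 = end_masses(
        valid_pairs["pos1"].to_numpy(np.int64), valid_pairs["strand1"].to_numpy(),
        offsets, lens1,
    )
    j0, j1, fj0, fj1 = end_masses(
        valid_pairs["pos2"].to_numpy(np.int64), valid_pairs["strand2"].to_numpy(),
        offsets2, lens2,
    )

    nb = cm.n_bins
    flat = np.zeros(nb * nb)
    for bi, fi in ((i0, fi0), (i1, fi1)):
        for bj, fj in ((j0, fj0), (j1, fj1)):
            w = fi * fj
            nz = w > 0
            flat += np.bincount(bi[nz] * nb + bj[nz], weights=w[nz], minlength=nb * nb)
    acc = flat.reshape(nb, nb)
    sym = acc + acc.T - np.diag(np.diag(acc))
    cm.matrix = sym
    return cm


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def balance(
    cm: ContactMatrix, tol: float = 1e-8, max_iter: int = 1000
) -> ContactMatrix:
    """Sinkhorn-Knopp balancing of a symmetric non-negative matrix.

    Uses the symmetric variant (a single scaling vector): the matrix is
    repeatedly divided by ``sqrt(r_i * r_j)`` where ``r`` are current row
    sums, until the largest row-sum deviation from 1 over the support is
    below ``tol``. Bins with zero raw marginal are masked out of the support
    and left zero. Non-convergence within ``max_iter`` is reported on the
    returned matrix (``converged=False``) with a warning.
    """
    if cm.state != "raw":
        raise BalanceError("matrix is not in raw state")
    m = cm.matrix
    if m.min() < 0:
        raise BalanceError("matrix has negative entries")
    if not np.allclose(m, m.T):
        raise BalanceError("matrix is not symmetric")
    support = m.sum(axis=1) > 0
    sub = m[np.ix_(support, support)].astype(np.float64).copy()
    converged = False
    residual = float("inf")
    it = 0
    for it in range(1, max_iter + 1):
        r = sub.sum(axis=1)
        residual = float(np.abs(r - 1.0).max()) if r.size else 0.0
        if residual < tol:
            converged = True
            break
        s = np.sqrt(r)
        sub /= np.outer(s, s)
    else:
        it = max_iter
    if not converged:
        r = sub.sum(axis=1)
        residual = float(np.abs(r - 1.0).max()) if r.size else 0.0
        converged = residual < tol
    if not converged:
        warnings.warn(
            f"Sinkhorn-Knopp did not converge in {max_iter} iterations "
            f"(residual {residual:.3g})",
            RuntimeWarning,
        )
    out = np.zeros_like(m)
    out[np.ix_(support, support)] = sub
    return ContactMatrix(
        out,
        cm.bin_size,
        cm.chrom_names,
        cm.chrom_lengths,
        state="balanced",
        mask=support,
        converged=converged,
        balance_iterations=it,
        balance_residual=residual,
    )


def rebalance(cm: ContactMatrix, tol: float = 1e-8, max_iter: int = 1000) -> ContactMatrix:
    """Balance an already-balanced matrix (idempotence check helper)."""
    raw_again = ContactMatrix(
        cm.matrix, cm.bin_size, cm.chrom_names, cm.chrom_lengths, state="raw",
        mask=cm.mask,
    )
    return balance(raw_again, tol=tol, max_iter=max_iter)
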