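# Methods

This note documents the models and procedures implemented in `telomap`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data do and do not establish about real data.

## Coordinates and data model

All coordinates are 0-based half-open `[start, end)`; BED is the native
interval format and any 1-based source must be converted at its reader.
Overlap everywhere means ≥1 shared base; abutting intervals do not overlap.
Interval sets may contain overlapping members, but whenever a base must not
be counted twice (GC content, union lengths) the set is merged first.

Telomeric windows are the terminal `window_bp` of each chromosome end
(merged if they meet), default **15 kb**. The underlying studies subtract
"telomeric sequences" without defining the window; 15 kb covers the
telomeric repeats plus the subtelomeric X/Y′ elements of *S. cerevisiae*
and is exposed as a parameter because the choice is a convention, not a
measurement.

## Peak calling (ChIP-chip)

Input is one log₂(IP/input) value per probe per replicate. Two combination
routes are provided, mirroring common practice: per-replicate calling
followed by consensus (the route that defines the reported site set), and
calling on the per-probe **median of standardized tracks** (each track
scaled to mean 0, sd 1 before the median).

The caller is a sliding-window scheme in the ChIPOTle family:

* windows of `window_bp` at `step_bp` tile each chromosome; a window's
  score is the mean of the probes overlapping it;
* the null is a zero-mean Gaussian whose sd is estimated by **mirroring
  the negative window scores** about zero, `sd = sqrt(mean(s² | s<0))` —
  the assumption is that true binding only adds signal, so the negative
  tail is uncontaminated;
* because a window's score variance scales inversely with the number of
  probes it covers, the null sd is estimated **per probe-count stratum**
  (windows covering k probes), falling back to the pooled estimate for
  strata with <50 windows or <20 negative scores. With a pooled sd the
  sparser stratum is anticonservative (measured ≈3× the nominal
  false-peak expectation on flat noise; stratification restores it);
* one-sided p-values are **Bonferroni**-corrected over all scored windows
  (matching the classical tool's default, not FDR), windows with
  `p_adj < α` are merged when they overlap or abut, and the merged peak
  keeps the smallest adjusted p.

Defaults `window_bp=500`, `step_bp=125`, `α=0.05`. The window approximates
chromatin sonication fragments (200–1000 bp); the authors' original
parameterization is unrecorded, so these are package defaults, not claims.

Consensus keeps the connected components of the union of all replicate
peaks that are intersected (≥1 bp) by peaks from ≥`min_support` distinct
replicates (default **3 of 5**). A fraction-overlap requirement would also
be defensible; ≥1 bp is the simplest rule consistent with "identified in
at least three replicates" and the threshold is configurable. Telomere
subtraction removes intersecting peaks whole rather than trimming them.

An all-positive score vector makes the mirrored null inestimable and is an
error, never a silent fallback.

## qPCR enrichment and healing frequency

IP/Input for one locus is `E^(Ct_input − Ct_ip)` with amplification
efficiency `E = 2.0` by default (perfect doubling); fold enrichment is the
per-replicate ratio of target over control locus (`ARO1`). Statistics are
mean ± SEM (`sd/√n`, n−1 estimator) and a two-tailed two-sample Student's
t-test of the target's per-replicate folds against the control's
(identically 1); a Welch variant is a flag. Technical-replicate averaging
below the biological level is intentionally not modelled.

Healing frequency is the percentage of α-aminoadipate-resistant colonies
after HO induction, kept as an exact rational (`Fraction(100·k, n)`)
before any formatting so `freq·n/100 == k` holds exactly.

## Randomization ("iteration") tests

`count_overlaps(query, subject)` counts query intervals hit by ≥1 bp,
each at most once — matching enrichment fractions quoted as *k/N* with the
site count as denominator.

Shuffles preserve each interval's length and chromosome and draw starts
uniformly over valid positions, avoiding an exclusion track and
self-overlap. Placement is iterative rejection: all pending intervals are
redrawn, a maximal non-overlapping subset is accepted by a greedy sweep in
start order, the rest are redrawn (a bounded number of rounds; failure is
an error). For a single interval this is exactly uniform (verified by
chi-square); for dense sets the joint distribution is approximately, not
exactly, the uniform over non-overlapping configurations — the same
compromise made by common interval-shuffling tools.

The empirical p is `(1 + #{null ≥ observed}) / (1 + N)` — never zero, and
super-uniform (valid) by construction. Two properties matter in practice:

* for **continuous** statistics (GC content) the p-value is uniform under
  the null to the 1/(N+1) grid;
* for **integer** statistics (overlap counts) ties make the p
  conservative; the coarser the count distribution, the stronger the
  conservatism. Calibration near the nominal level requires a query set
  large enough that the null count spans many values.

Defaults: `n_iter=1000` (a floor of p ≈ 10⁻³; reported values of
p < 10⁻⁴ imply ≥10⁴ iterations — configurable), shuffles stay on their
original chromosome (conservative, composition-preserving; cross-chromosome
placement is a flag), and the alternative is one-sided enrichment.

## Hi-C contact maps

The pipeline consumes already-mapped pairs (alignment is commodity;
nothing model-specific happens before fragment assignment).

* **Digestion**: one cut at the first base of each ^GATC occurrence
  (DpnII); fragments partition each chromosome exactly; a motif-free
  chromosome is one fragment.
* **Classification**: reads on different fragments → *valid*; same
  fragment with convergent (inward) strands → *non-ligation* (dangling
  end); same fragment, divergent or equal strands → *self-ligation*
  (circularized / re-ligated — the two are lumped, and counted, as one
  class). Positions are used only to orient same-fragment pairs.
  Duplicate removal is off by default (a flag enables exact-coordinate
  deduplication) since the source protocol does not state it.
* **Binning** at `bin_size` (default **10 kb**): each read end is an
  interval of its aligned length (`+`: `[pos, pos+len)`, `−`:
  `[pos+1−len, pos+1)`, clipped); its unit mass is split across bins by
  base overlap and the pair contributes the product mass to each bin
  pair, so each pair adds exactly 1 to the map, split between entries.
  The stored matrix is fully symmetric with the diagonal not doubled;
  total mass counting each pair once is `(sum + trace)/2` and equals the
  valid-pair count to float precision.
* **Balancing**: symmetric Sinkhorn–Knopp — divide by `√(rᵢrⱼ)` of the
  current row sums until `max|row_sum − 1| < tol` over the support
  (default `tol=1e-8`, `max_iter=1000`). Bins with zero raw marginal are
  masked out of the support, left zero, and read back as missing (NaN),
  never as zero contact. Non-convergence is reported on the result and
  warns rather than raising; the CLI maps it to a dedicated exit code.
  No sparsity-percentile filtering is applied.

## Telomere proximity

Sites and telomeres are assigned to the bin containing their midpoint
(boundary midpoints go downstream, half-open). Telomere bins default to
the single terminal bin at each chromosome end (configurable to k bins).
Per site: `tel = max` balanced contact with the two telomere bins of the
site's **own chromosome** (an `all_telomeres` mode maxes over all ends —
both readings of "one of the two telomeres" are defensible; cis is the
literal one and is the default), `ntbs = mean` contact with all other
site bins (self excluded, masked entries dropped; sites sharing a bin are
collapsed to one bin for scoring but reported individually). The class is
telomere-proximal iff `tel > ntbs` strictly; ties are site-proximal
because the claim being operationalized is "higher than". Classification
is invariant to global rescaling of the matrix.

The randomization test pools per-site telomere scores over `n_iter`
shuffles of the site set (default 20, avoiding a configurable exclusion
zone) and applies a one-sided two-sample Wilcoxon rank-sum (sites >
controls). All-tied inputs give p = 1 with a warning. Because Sinkhorn
scaling makes rows comparable, cross-row comparison of telomere entries is
meaningful; the exclusion zone should match the placement domain of the
sites being tested, otherwise the control distance-to-telomere
distribution differs by construction.

## Synthetic data: what it emulates

`SyntheticConfig` defaults are the emulated study conditions: 16
chromosomes × 200 kb, background GC 0.38, 64 planted TG-rich sites of 1 kb
at GC 0.52, probe spacing 250 bp, peak amplitude 5σ, per-replicate
detection 0.9, 5 replicates, 2·10⁶ Hi-C pairs, decay exponent α=1,
telomere boost β=3, planted telomere-proximal fraction f=0.14, 10-kb bins,
75-bp reads. One global seed fans out to fixed per-generator child streams
(`numpy` `SeedSequence` spawn keys), so a config is a complete, replayable
description of a dataset; ground-truth labels are always returned.

Sites are placed outside a 50-kb margin at each chromosome end, each in a
distinct 10-kb bin. The margin keeps every site's nearest telomere ≥5 bins
away so genomic distance alone cannot flip the proximity classification;
one-site-per-bin keeps the site↔bin correspondence one-to-one for the
answer key.

The Hi-C ground truth is an explicit bin-pair weight map:

* intra-chromosomal decay `(d+1)^−α` in bin units (generic polymer-like
  decay), inter-chromosomal floor `w₀ = 0.3`;
* telomere×telomere weights ×β (Rabl-like clustering of chromosome ends);
* site×site weights ×γ (`ntbs_clustering = 4`) — binding sites cluster
  spatially, the property that makes most sites score closer to each
  other than to telomeres;
* site×telomere weights ×τ (`ntbs_tel_affinity = 3`) — the whole site
  set sits somewhat nearer the telomere cluster than random regions,
  which is what the rank-sum test detects;
* the planted fraction f of sites is **anchored**: their weight to each
  cis telomere bin is raised to β·w(0) (zero-distance), and to other
  telomere bins β·w₀, modelling sites colocalized with the telomere
  cluster irrespective of genomic position.

The four structural constants (w₀, γ, τ, anchor strength) were fixed
jointly by a weight-budget argument and validated once on the exact
pre-sampling map: Sinkhorn balancing rescales each row by its total mass,
so any affinity that inflates site rows (γ, τ) is partly cancelled in
*cross-row* comparisons while *within-row* comparisons (the classifier)
are unaffected. The constants are chosen so that, after that cancellation,
within-row margins separate anchored from unanchored sites by ≥2× and the
cross-row site/control telomere-score ratio stays well above 1. With them,
the classifier recovers f exactly at f ∈ {0, 0.14, 0.5, 1} and the
rank-sum test rejects at p ≈ 10⁻¹⁴ for f = 0.14.

Pairs are drawn multinomially from the weight map (exactly `n_pairs`),
positions uniform within bins, strands uniform; same-fragment pairs are
nudged onto the neighbouring restriction fragment so ≥95% (in practice
~100%) classify as valid — the generator exercises the classifier without
modelling ligation chemistry.

**What passing tests do not show**: the generator has i.i.d. background
sequence (no isochores, repeats or mappability structure), no probe-level
GC bias or spatial autocorrelation in array noise, no duplicate reads,
sequencing errors or diploid homolog ambiguity, and a stylized contact
model (no loops, compartments or replication-timing structure). Results on
it validate the *machinery* — calibration, conservation, invariants,
parameter recovery — not performance on any real dataset.

The homogeneous null for calibration checks is β=γ=τ=1, f=0 with controls
shuffled over the same placement margin as the sites: with clustering
boosts active, site rows carry extra mass and balancing systematically
depresses their telomere entries, so "no planted fraction" alone is not an
exchangeable null.

## Numerical choices

* Balancing tolerance 1e-8 on the max row-sum deviation; convergence is
  checked before each scaling step, so re-balancing a balanced matrix is
  a one-iteration no-op.
* Binning uses dense accumulation via `bincount`; order of input pairs
  cannot affect the result beyond float associativity (verified).
* Peak merging treats abutting windows/peaks as one region.
* Empirical p-values use the add-one rule; permutation floors are
  1/(n_iter+1) by construction.
* Degenerate inputs fail loudly: zero-variance tracks, all-positive score
  vectors, empty interval sets, zero colony totals, masked-bin queries
  (NaN, distinguished from zero).

## Problem sizes

Default test and acceptance runs use the 16×200-kb genome with 2·10⁶
pairs for proximity recovery, 5·10⁵ pairs for multi-seed calibration
sweeps, 10⁴–10⁶ pairs for conservation checks, 100 seeds for the
false-peak expectation and 500 simulations for permutation calibration —
sizes at which every statistical margin in the suite is several sigma wide
while a full run stays in the minutes range on one CPU.

## Known limitations

* The shuffler's joint distribution over dense non-overlapping sets is
  approximate (see above); single-interval uniformity is exact.
* The discrete overlap p is conservative for small query sets; this is a
  property of permutation tests on coarse statistics, not an
  implementation artifact.
* `read_len > bin_size` is unsupported in binning (a read would span >2
  bins); irrelevant at 75-bp reads vs 10-kb bins.
* The Wilcoxon p-value uses the tie-corrected normal approximation for
  large samples (scipy's default), which saturates around 10⁻¹⁶ —
  adequate here.
* The CLI's `composition` stage measures called peaks, which are wider
  than the planted sites; their GC is therefore intermediate between
  background and planted values. The acceptance script reports the
  planted-set GC, which is the generator's construction target.
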