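# telomap

Analyses for mapping where telomerase binds *inside* chromosomes and asking
whether those internal sites are spatially close to telomeres.

In budding yeast, the catalytic telomerase subunit Est2 occupies hundreds of
non-telomeric binding sites (NTBS) across the genome. Characterising such a
site set raises four recurring computational problems, and `telomap`
implements each as a reusable, tested library with a thin CLI:

1. **ChIP-chip peak calling** — tiling-array log₂(IP/input) tracks are
   standardized per replicate, scanned with a sliding window against a
   Gaussian null estimated from the mirrored negative window scores
   (the classic ChIPOTle scheme), Bonferroni-corrected, and filtered to
   peaks reproduced in ≥3 of 5 biological replicates, with telomeric
   windows subtracted.
2. **Composition and feature-overlap statistics** — GC content of the site
   set and its overlap with feature tracks (G-quadruplexes, R-loops,
   Pif1 sites, …) are tested by randomization: query intervals are
   reshuffled length- and chromosome-preserving, and the empirical
   enrichment p-value is `(1 + #{null ≥ obs}) / (1 + N)`.
3. **Hi-C contact maps** — mapped read pairs are sorted into DpnII (^GATC)
   restriction fragments, classified into valid / self-ligation /
   non-ligation products, binned at 10 kb with each read's unit mass split
   between bins proportional to overlap, and balanced with the
   Sinkhorn–Knopp algorithm so every row and column of the contact matrix
   sums to 1.
4. **Telomere-proximity classification** — each site *i* is scored by
   `tel(i) = max_t P(b_i, t)` over the two telomere bins *t* of its own
   chromosome and `ntbs(i) = mean_j P(b_i, b_j)` over all other site bins;
   it is telomere-proximal iff `tel(i) > ntbs(i)` (strict). Whole-set
   proximity versus shuffled control regions is tested with a one-sided
   Wilcoxon rank-sum on the per-site telomere scores.

Because the raw microarray and sequencing data are not needed to test any of
this machinery, the package ships a first-class synthetic-data generator
(`telomap.simulate`) that produces every input the pipeline consumes — a
multi-chromosome genome with planted TG-rich sites, per-replicate probe
tracks with dropout, Hi-C pairs drawn from an explicit ground-truth contact
model with a planted telomere-proximal fraction, feature tracks with an
exact overlap count, and binomial colony counts for the telomere-healing
assay — always together with the ground-truth labels.

## Worked example

Run the whole pipeline on the default synthetic dataset (16 chromosomes ×
200 kb, 64 planted sites, 5 replicates, 2·10⁶ Hi-C pairs, 14% of sites
planted telomere-proximal):

```sh
telomap all --outdir run1 --seed 1
```

which logs, stage by stage:

```
simulate: 64 planted sites, 2000000 Hi-C pairs
callpeaks: per-replicate [61, 57, 62, 59, 62]; consensus 64 non-telomeric
composition: NTBS GC 0.463 vs genome 0.383 (p=0.000999)
overlap G4: 8/64 (null 1.7, p=0.000999)
overlap Rloop: 18/64 (null 3.8, p=0.000999)
overlap Pif1: 24/64 (null 10.0, p=0.000999)
hic: 1999999 valid / 2000000 pairs; balanced in 23 iters (residual 6.2e-09)
proximity: 85.9% site-proximal / 14.1% telomere-proximal (Wilcoxon p=1.61e-06)
healing TG80: 200/200 = 100.0%
healing N80: 0/200 = 0.0%
```

Reading the output: each replicate recovers ~60 of the 64 planted sites
(per-replicate detection is 0.9 by design); the 3-of-5 consensus restores
all 64 with no spurious calls. The called peaks are G+C-enriched over the
0.38-GC background (called peaks are slightly wider than the planted 1-kb
sites, which dilutes their GC below the planted 0.52; the permutation p
sits at the 1/(N+1) floor either way). All three feature tracks are
enriched at the floor. Virtually every Hi-C pair survives fragment-level
classification, the balanced matrix has unit marginals to 6·10⁻⁹, and the
proximity classifier recovers exactly the planted 14% telomere-proximal
fraction, with the site set as a whole significantly closer to telomeres
than shuffled controls.

Artifacts (BED, TSV, JSON, a contact-map heatmap, `manifest.json` with
parameters, seeds and input checksums) land in `run1/`. All stages are
driven by one YAML config (`telomap all --config my.yaml`); every stage can
be re-run individually and is byte-reproducible for a fixed seed.

The same operations are available as a library:

```python
from telomap import (SyntheticConfig, make_genome, make_hic_pairs,
                     classify_pairs, bin_pairs, balance, classify_sites, digest)

cfg = SyntheticConfig(seed=1)
assembly, sites = make_genome(cfg)
pairs, truth = make_hic_pairs(assembly, sites, cfg)
classified, census = classify_pairs(pairs, digest(assembly))
matrix = balance(bin_pairs(classified[classified.pair_class == "valid"], assembly))
results, summary = classify_sites(matrix, sites)
print(summary["frac_telomere_proximal"])   # 0.140625 — the planted fraction
```

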