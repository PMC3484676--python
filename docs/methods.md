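# Methods

This note documents the models, parameter choices and numerical decisions
behind regulonkit, and what the synthetic benchmarks do and do not show
about real data.

## Replicate reconciliation

Two ChIP replicates are reconciled purely on summit coordinates: peaks on
the same chromosome with |summit₁ − summit₂| ≤ `max_dist` (default 200 bp)
are candidate pairs, matched **one-to-one** greedily by ascending distance,
with ties broken by the lower replicate-1 summit, then the lower
replicate-2 summit. One-to-one matching is what makes the class accounting
additive (|A| + |B| = |rep1|, |A| + |C| = |rep2|); a nearest-neighbor rule
with reuse could let one replicate-2 peak absorb two replicate-1 peaks and
break the partition. How the original Perl tooling of such studies resolved
multi-way ambiguities is generally unrecorded, so the greedy rule is a
documented package choice, validated against an exhaustive O(n²) matcher on
hundreds of random instances. Class A pairs are represented downstream by
their replicate-1 member (replicate 1 being the deeper library with the
larger intensity range). Duplicate summits within one replicate are
rejected at read time: the summit is the identity key of this procedure.

## TSS assignment and distance summaries

A peak links to *every* TSS within the window (default 2 kb, inclusive:
"within 2 kb" is read as ≤ 2000, and the boundary is tested explicitly);
one-to-many links are intentional, since a single promoter-proximal peak
can face two divergent genes. Signed distance is strand-aware, negative
upstream. Both the all-links and nearest-TSS-only views are available; the
nearest-only view feeds the distance histogram.

Distances are binned at 100 bp over [−window, +window]. The "smooth curve"
is a centered **binomial-weighted** window (default 3 bins: ¼, ½, ¼). A
flat boxcar was rejected on proof: comparing adjacent boxcar means cancels
every shared bin, so the mode decision between the two bins straddling a
peak rests entirely on the outermost bins — with a Normal(−205, 40) offset
distribution the recovered mode would be a coin flip. The binomial kernel
keeps the center bin dominant (and tends to a Gaussian as the window
grows); with it, the mode bin contains −205 in ≥ 95/100 seeds at n = 1000.
Smoothed-curve ties are resolved by higher raw count, then the bin center
nearest zero, then upstream.

The intensity summary uses the lower-middle median for even n, the
max/median ratio, and the count of peaks exceeding 10× the median —
the outlier notion appropriate to intensity distributions spanning about
an order of magnitude.

## Motif model and exact p-values

A PWM stores per-position base probabilities and a background composition;
windows score as summed log-odds in bits. The null distribution of a single
window score under i.i.d. background is computed exactly by column-wise
convolution after rounding each column's scores to a 0.01-bit grid; the
discretization error is bounded by width × granularity/2 ≈ 0.06 bits for a
12-mer and is validated against full 4^w enumeration for widths ≤ 8.
Zero-probability cells map to a sentinel far below the reachable range.
Windows containing non-ACGT letters are skipped and the trial count m
reduced; an all-N region returns an explicit "unscorable" result rather
than a silent p = 1.

The sequence-level statistic is the best-hit p-value over both strands,

p_seq = 1 − (1 − p_site)^m,  m = 2 × (scorable windows),

a Šidák correction that treats window placements as independent trials.
Two consequences are worth knowing:

* **Width floor.** The smallest attainable p_seq is 1 − (1 − p_min)^m with
  p_min ≥ Πᵢ q(consensusᵢ). An 8-bp motif in a 200-bp region bottoms out
  near 6×10⁻³ under uniform background — it can *never* clear 10⁻⁴. This is
  why presence thresholds are calibrated per motif: the scramble contrast
  selects ~10⁻⁴ for 11–12-bp motifs with exact-consensus sites but ~10⁻²
  for the 8-bp DREF-like palindrome, and looser thresholds again when
  planted sites carry mismatches.
* **Clumping.** For motifs whose high-scoring words partially overlap
  themselves (or their reverse complement), overlapping windows are not
  independent and p_seq is slightly conservative (CDF below uniform by up
  to a few percent). The null-uniformity benchmark therefore uses a probe
  motif whose consensus was chosen to minimize shifted autocorrelation with
  itself and its reverse complement; for such motifs the p-values are
  uniform to within KS sampling noise at n = 2000.

Scrambles are mononucleotide (exact letter-permutation, preserving base
composition); a doublet shuffle preserving dinucleotide counts is available
as an option but off by default, matching the "scrambled sequences of
similar composition" design. Calibration compares the fraction of real
regions called at each candidate threshold (decade steps 10⁻²…10⁻⁶)
against the mean over five scrambles and picks the maximizing threshold,
ties toward stringency. On background-only regions the scrambled call
fraction at threshold t estimates t itself, since the sequence-level p is
approximately uniform under the null.

Presence is boolean per (region, motif): multiple hits of one motif count
once. MAST-style multi-motif statistics are deliberately not composed;
downstream analyses consume per-motif booleans.

## Enrichment, constellations, categories

Constellation counting partitions scorable regions by their exact motif
subset; unscorable regions are excluded from every denominator. Background
enrichment compares bound-region fractions against five independent random
sets of 1000 unbound-promoter windows, strand-aware [TSS−300, TSS−100);
the ratio of bound fraction to background mean is reported per motif with
an empirical z-score against the five background fractions. No
multiple-testing correction is applied to ratios. Category profiling takes
an explicit gene→category TSV (multi-membership allowed) — category
curation (GO pooling etc.) is an upstream editorial step, kept auditable
as an input — and reports, per category, the fraction of genes any of
whose peaks contains each motif, plus a "none" column and an "all" row.

## Cross-species overlap

Ortholog families are either the explicit `family_id` column or, when
absent, connected components of the bipartite fly–human link graph (the
natural reading of "orthologous family" for many-to-many orthology). A
family is bound in both species iff ≥ 1 fly member and ≥ 1 human member
are bound. Venn partitions are exact membership-vector counts, guarded at
five sets. Category enrichment of a gene subset within a universe uses the
hypergeometric upper tail (lower tail flagged for depletion) with
Benjamini–Hochberg correction across categories; the test choice is an
interpretive default, as published comparisons of this kind often name no
statistic. Gene identifiers are case-sensitive opaque strings; no symbol
translation is attempted.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

* **Genome**: i.i.d. bases at GC 0.42 (fruit-fly-like); TSSs placed
  uniformly per chromosome subject to a minimum spacing of twice the 2-kb
  assignment window (so peak→gene links are unambiguous) and a 400-bp edge
  margin; strands 50/50.
* **Peaks**: shared summits at TSS + round(Normal(−205, 40)) in the gene's
  transcription direction — the −205-bp center reproduces the canonical
  promoter-proximal offset, the 40-bp SD is a free choice keeping ~95% of
  summits within ±80 bp of it — duplicated into both replicates with
  independent Normal(0, 30) jitter (30 bp keeps essentially every true pair
  within the 200-bp matching radius: P(|Δ| > 200) ≈ 2×10⁻⁶). Replicate-
  specific extras sit at further random TSSs, > 200 bp from everything by
  the spacing guarantee. Intensities are LogNormal(log 20, 0.8) — median
  ≈ 20 and an order-of-magnitude bulk span; no generating model for
  intensities is established, so this is a stand-in. Exact summit
  collisions are nudged by +1 bp (summits are identity keys).
* **Motif plants**: per gene and motif, a Bernoulli(frequency) coin plants
  one instance at a uniform offset and strand within the promoter window
  [TSS−300, TSS−100) — the same window used for background extraction, so
  planted and background regions are commensurate. Instance bases are the
  consensus with probability `motif_plant_strength` (default 0.95), else a
  background draw; strength 1.0 writes the exact consensus, whose rescore
  attains the PWM maximum. Overlapping plants for one gene are re-drawn up
  to 20 times, then reported as failures. A ledger records every plant.
* **Determinism**: one integer seed, split into per-stage substreams
  (genome / plants / peaks), so outputs are byte-identical across runs and
  changing one stage's parameters does not perturb another's draws.
* **Default sizes**: 200 shared + 150/20 replicate-specific peaks over
  2 × 1 Mb — a desk-scale instance that runs in under a second. The
  benchmark script scales up to the genome-scale accounting instance
  (1236/951/101 peaks, 3500 genes, 4 × 3.7 Mb) which still runs in
  seconds.

**What the generator does not emulate**: read-level noise and peak-caller
artifacts (peak calls are emitted directly), nucleosome structure and
chromatin state, composition heterogeneity (isochores, CpG islands,
repeats), overlapping genes and isoform TSS diversity, and correlated
motif placement (plants are independent across motifs given the gene).
Passing the benchmarks therefore demonstrates the correctness of the
analysis machinery under its stated model, not robustness to every
pathology of real chromatin data.

## Bundled PWMs

The bundled E2F (11 bp), DREF (8 bp, with a deliberately weak eighth
column, as the canonical DRE 8-mer's final base is poorly conserved),
FOXJ2 (10 bp) and RAM (12 bp) matrices are **synthetic, illustrative
stand-ins** built from plausible consensi with heterogeneous column
probabilities (0.68–0.90 consensus weight, unevenly split alternatives):
no real position weight matrices for this panel are published, and none of
the bundled numbers should be read as binding specificities. The
heterogeneous columns also give the score distributions dense support,
which the exact-p-value machinery needs to behave well.

## Benchmark problem sizes

The shipped checks use: the 1236/951/101 genome-scale accounting instance;
500 random ≤ 50-peak instances against the exhaustive matcher; full 4^8
enumeration for 8-bp PWMs; 500 promoter regions with a motif planted in
half for calibration recovery; 100 × 1000 draws for mode recovery; 2000
background sequences for the KS uniformity check; and 1000 random
instances for the partition invariants. Each runs in seconds; the sizes
were chosen to give the statistical assertions ≥ 3σ margins.
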