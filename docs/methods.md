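# Methods

## The co-occurrence model

The unit of observation is an exon with its two intronic flanks stored in
transcript orientation.  Motif presence is binary per exon-region: an exon
either contains a k-mer somewhere in the 50-nt window or it does not, however
many times it occurs.  For an ordered pair (Ui upstream, Dj downstream) the
null model is independence of the two presence indicators, under which the
joint count over N exons is hypergeometric with margins (N, n_Ui, n_Dj).

Real flanks violate this null grossly through base composition alone: the
two flanks of an exon sit in the same GC isochore, so their GC contents are
strongly correlated (r ~ 0.73), and GC-rich motifs co-occur massively without
any specific pairing.  The correction stratifies exons twice — into 20 rows
by upstream-window GC and 20 columns by downstream-window GC, each row and
column holding N/20 exons (equal-occupancy quantile binning; ties broken by
exon identifier for determinism).  Presence frequencies are estimated per
stratum, the expected joint count is summed over the 400 boxes,

    k' = sum_{x,y} K_{x,y} q_Ui(y) q_Dj(x),

and the downstream margin is adjusted to n'_Dj = N k'/n_Ui so that the
hypergeometric mean matches k'.  Exact upper and lower tail probabilities of
the observed joint count k^a are then computed under
f(k | N, n_Ui, n'_Dj).  Which margin is adjusted is configurable
(downstream by default; upstream or both give similar results).

Significance uses the enrichment (upper) tail only, at the fixed cutoff
alpha = 1/4^(2k); the lower tail is reported but not thresholded.  With
4^(2k) hypotheses this cutoff implies about one background pair per scan.
k defaults to 5: for ~80,000 exons and 46 window positions a specific
pentamer pairing expects ~161 positional co-hits while a hexamer pairing
expects only ~10 — pentamers are the longest motifs with genome-scale power.

### Per-stratum frequencies

q is computed against the *actual* occupancy of each stratum rather than the
nominal N/20; the two differ by at most one exon and the actual count makes
the single-stratum limit exact: with a 1 x 1 grid, n'_Dj = n_Dj identically
and the test collapses onto the plain hypergeometric (verified in tests).

### Numerical choices

* **Exact tails, vectorized.**  Tail sums are computed with a gammaln-based
  starting term and the pmf ratio recurrence, always summing away from the
  distribution mode so terms decay geometrically; a lane stops when its next
  term falls below 1e-18 of its accumulated sum.  On the near side of the
  mode the complementary tail is used.  Agreement with scipy's
  `hypergeom.sf/cdf` is ~1e-13 relative at N <= 200 and better than 1e-10 at
  N = 20,000; a full 1M-pair scan of 20,000 exons takes a few seconds on one
  CPU.  No normal or Poisson approximation is used anywhere.
* **Margin rounding.**  n'_Dj is rounded half-to-even after snapping to nine
  decimals: q values are small rationals, so exact .5 ties are common and
  must not depend on float summation order.  The margin is then clamped so
  k^a stays inside the hypergeometric support; at a clamped bound the tail
  probability degenerates to the boundary pmf and the record is flagged.
* **n_Ui = 0 or n_Dj = 0.**  No test is possible; p = 1 is recorded.
* **N bases.**  Windows containing N are excluded from motif counting and GC
  computation; the exon is dropped from that regional analysis only.

## Region geometry

Coordinates are splice-site-relative, 1-based in magnitude, inclusive at
both ends: -1 is the last intron base before the acceptor AG boundary, +1
the first intron base after the donor.  Default windows Ud = [-100,-51],
Up = [-64,-15], Dp = [+7,+56], Dd = [+51,+100] exclude the polypyrimidine
tract (-14..-1) and the donor consensus (+1..+6).  Distance scans use
symmetric 50-nt blocks [-(d+49),-d] / [+d,+d+49]; the border windows (d = 0)
respect the same consensus exclusions and therefore coincide with Up/Dp.

## Splice-site scoring

Consensus values (CV) follow the position-specific weight-matrix scheme of
Shapiro and Senapathy: the window score s is the sum of per-position
frequencies of the observed bases, scaled to
cv = 100 (s - s_min)/(s_max - s_min).  Window extents are the standard
acceptor window (intron -14..-1 plus the first exon base, 15 positions) and
donor window (last 3 exon bases plus intron +1..+6, 9 positions).  s_min
takes the per-position minimum over bases actually observed in the training
corpus; a window containing an unobserved base scores below s_min and is
clamped to cv = 0.  PWMs are estimated from the corpus's own splice-site
windows (the source corpus for the matrix is a user choice; any table of
per-position frequencies can be supplied).

Pseudo exons are intron-internal candidates of exon-like length (50-250 nt)
bounded by canonical AG/GT with cv >= 75 (acceptor) and >= 78 (donor), at
least 100 nt from a real exon; all thresholds boundary-inclusive.  Pseudo
splice sites are AG/GT-anchored positions in a real exon's flank, at least
100 nt from the authentic site, scoring at least as high as it.

## Corpus filters

Applied in order, with a per-exon rejection log:

1. **Alternative-splice-site dedup.**  Records of one gene representing
   alternative 3' (resp. 5') sites within 50 nt are collapsed to one record
   chosen by a seeded RNG.  Records carry no genomic coordinates, so
   co-membership is inferred from the sequences themselves: alt-3'ss records
   sharing their downstream flank whose upstream flanks align under a shift
   of <= 50 nt are treated as sites of the same exon (mirrored for 5').
2. **Similarity purge.**  Both exons of any pair whose upstream windows and
   downstream windows are each similar are removed.  Similarity is k-mer-set
   Jaccard >= 0.8 at k = 11 — a deterministic, index-accelerated stand-in
   for an alignment search; random 50-nt windows essentially never share an
   11-mer, so candidate generation is near-linear.
3. **Extreme GC.**  Exons whose relevant window GC is below 0.20 or above
   0.80 are dropped.

Filtering is idempotent.

## Controls

The **GC-balanced shuffle** permutes region sequences uniformly at random
within classes of identical integer G+C count (51 possible classes for a
50-nt window — the strictest reading of "same GC content", which preserves
the GC grid exactly).  Each side is shuffled independently; fixed points are
allowed.  The shuffle preserves the corpus-wide multiset of region sequences
and therefore every single-region statistic (GC histograms, motif marginals
n_Ui, n_Dj) exactly, while destroying cross-region pairing: rescanning a
shuffled corpus measures the method's false-positive background.  Because
exact discrete tails are conservative — the largest attainable p-value below
alpha averages about alpha/2 — the background mean is of order 0.5-1 pairs
per million tests.

Cross-region evaluation reports each discovered pair's p-value in the other
three window pairings plus a comparability flag marking whether the null
expected count there is within a factor of two of the defining region's.

## Downstream statistics

* **Exon strength.**  Exons carrying >= 1 significant pair are matched 1:1
  to exons carrying none, exactly on the integer G+C counts of both windows
  (greedy within class, seeded; unmatched exons dropped and logged).
  Features: fraction of exonic nucleotides covered by user-supplied ESE/ESS
  hexamer sets (interval union), and splice-site CVs.  Group comparison uses
  Welch's t-test by default (Mann-Whitney optional).  The display
  normalization maps each two-group comparison onto [-1, +1] by subtracting
  the midpoint and dividing by the maximum deviation.
* **Pairing conservation** is alignment-free: a motif is conserved iff it
  occurs anywhere in the ortholog's corresponding window.  The statistic is
  the conditional proportion P(partner conserved | one side conserved),
  computed in either direction.  Controls replace one motif by a same-G+C
  k-mer whose pairing p-value with the partner exceeds 0.05 (uniformly
  sampled among qualifiers, seeded).  The control must replace the motif
  whose conservation is being *scored*; replacing the conditioning-side
  motif leaves the scored partner functionally paired and the comparison has
  no power.  Controls are k-mers of the scan's k throughout.
* **SNP density.**  For the motifs of discovered pairs, an occurrence is
  "paired" when the partner is present in the partner window of the same
  exon, else "alone"; the fraction of occurrences overlapping >= 1 SNP (any
  of the k positions) is compared between classes with a two-proportion
  z-test and binomial standard errors.  Input SNPs are expected pre-filtered
  for repeats and multi-mapping.
* **Tissue bias.**  A gene is tissue-specific where its expression exceeds
  its own cross-tissue median by more than two standard deviations (strict
  inequality; per-gene statistics, sample sd).  For a pair, the per-tissue
  fraction F_E of its genes that are specific is compared against 10,000
  draws of control genes matched on exon count (nearest-count pooling when a
  count class is too small), none of whose exons carry the pair.  Empirical
  p-values use add-one smoothing, (count + 1)/(iterations + 1), so no p is
  zero; ties contribute to both tails, hence p_enrich + p_deplete >= 1.
  Significance cutoff 0.001.  Concordance with an RNA-binding protein is a
  one-sided binomial test at 0.5 on the number of significant tissues where
  the protein's expression deviates from its own median in the matching
  direction — one defensible construction of an unspecified procedure, and
  labelled as such.
* **Synergy.**  From molar band quantities, I = inc/(inc + skip), S = 1 - I,
  skipping fitness W_x = S_x/S_0, and SI = W_UD - W_U W_D; SI < 0 means
  synergy.  SI is computed per transfection replicate and summarized as
  mean +- SEM, propagating replicate-level variability; |SI| < 1e-12
  classifies as "none".  All quantities are invariant to rescaling every
  band by a common factor.

## The synthetic corpus

The generator emulates exactly the features the analyses rely on:

* **GC structure.**  A latent per-exon isochore value plus per-side noise
  sets each flank's GC target; bases are drawn iid with
  P(G) = P(C) = GC/2.  The variance split is calibrated analytically so the
  *realized* window-GC correlation hits the target (default r = 0.73),
  accounting for the binomial sampling floor p(1-p)/50 of a finite window;
  this requires a realized GC standard deviation of at least ~0.135, and the
  default 0.14 (mean 0.45) matches the dispersion of human intronic flanks.
  At N = 20,000 the realized r lands within +-0.01 of target.
* **Planting.**  Configured pairs are written into their windows at uniform
  (or fixed) offsets, overwriting the background sequence, for fractions
  f_both (both sides), f_u, f_d (single-sided).  Overlapping plants in one
  window are resampled; an unplantable motif is skipped rather than recorded
  wrongly, keeping the truth ledger exactly faithful to the emitted
  sequences (asserted over whole corpora in tests).
* **Orthologs** substitute bases at rate mu outside planted motifs; a
  planted motif survives intact with probability rho_pair (planted as a
  pair) or rho_single, else mutates like background.  **SNPs** are per-base
  Bernoulli at base_rate, multiplied inside pair-planted motifs.
  **Expression** is per-gene lognormal noise across tissues with designated
  (gene, tissue) cells boosted to median + effect_sd x sd.
* All randomness derives from one seed through named substreams, so adding
  a component never perturbs another's stream; identical seeds give
  byte-identical corpora.

What the generator does *not* emulate: dinucleotide structure (no CpG
depletion by default), repeats, isochore spatial maps, alignment gaps, or
realistic splice-site haplotype structure.  Passing tests therefore
demonstrate correctness of the statistics under their stated model, not
performance on real genomes.

One emergent property matters for recovery tests: planting a pair also
creates genuinely co-occurring *overlap-shifted* variants (a planted GGAGG
makes AGGAG present whenever the preceding random base is A, jointly with
the partner).  These are true co-occurrences of the emitted corpus, and an
exact test must discover them — the recovery criterion therefore scores
discoveries through a truth-aware attribution step: exact planted pairs,
plant-derived pairs (both motifs overlap-compatible with a planted pair),
and unexplained discoveries, bounding only the last.

## Problem sizes used in the test suite

Scan-level checks run at N = 150-5,000 with k = 2-5; the background
calibration runs the full stated conditions (N = 20,000, ten shuffles,
k = 5), feasible because the vectorized scan takes ~5 s per corpus.
Recovery uses ten seeded corpora of 5,000 exons; conservation ten corpora of
4,000; SNP density ten corpora of 17,000 (>= 5,000 paired occurrences per
side).  The loop-based reference implementation is compared at N = 200,
k = 3, where it is exhaustive.

## Known limitations

* The similarity purge approximates an alignment search by k-mer Jaccard;
  diverged-but-homologous regions below 80% 11-mer sharing are not purged.
* The equal-occupancy grid requires N >= n_bins exons and leaves residual
  within-stratum GC correlation that slightly inflates the background at
  very large N; the shuffle control quantifies it.
* The tissue-bias control pool widens to nearest exon counts when an exact
  count class is exhausted; with very small expression panels the
  permutation floor (1/(iterations+1)) limits attainable significance.
* Conservation treats a motif as conserved on mere presence anywhere in the
  ortholog window; positional conservation is not assessed.
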