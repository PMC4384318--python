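# Methods

## The calling model

ampcnv tests for copy-number differences between one sample and one control
enriched with the identical multiplex-PCR primer pool. The observable per
primer *i* is the read-count pair (*C<sub>Si</sub>*, *C<sub>Ci</sub>*). Absolute counts are
dominated by per-amplicon PCR efficiency, which is sequence-determined and
therefore almost identical between sample and control for the same primer;
the ratio *C<sub>Si</sub>*/*C<sub>Ci</sub>* cancels it. Log2 ratios are median-centred across
the whole panel, which removes library-size differences under the
assumption that fewer than half of all primers lie in CNV-affected regions.
Zero counts (true dropouts, homozygous deletions) get a continuity
correction of 0.5 on the zero side only, so deletion signal is kept rather
than silently discarded; the number of corrected primers is reported.

The unit of calling is a cluster of amplicons assumed to share one
copy-number state. Positional clustering splits each chromosome recursively
at the largest remaining gap; a split must either leave at least 10
amplicons on both sides or use a gap over 250 kbp, and clusters under 100
amplicons are only ever split at gaps of at least 100 kbp. The small-cluster
condition is treated as necessary (a sub-100-amplicon cluster never splits
below 100 kbp even when both halves would be large enough); the boundary
semantics are strict ">" for 250 kbp and "≥" for 100 kbp. Gap means the
difference of primer 5′ coordinates of adjacent sorted members — at 100 kbp
scales the distinction from end-to-start distance (amplicons are 120–180 bp)
is negligible. Ties between equal largest gaps split at the leftmost. With
gene annotation available, clustering can instead be taken verbatim from
the labels (one cluster per chromosome+gene), which is also the mode used
when every gene should be one reporting unit.

## Outlier pruning

Ratios can be corrupted for reasons unrelated to copy number: variants
under a primer binding site, failed reactions, mapping artifacts. Rather
than modelling causes, the pruning loop removes whatever breaks normality:
while a Shapiro–Wilk test on the cluster's (unweighted) normalized ratios
rejects at p ≤ 0.05, the element with the largest |x<sub>i</sub> − μ\*| from the
current *weighted* mean is removed and the test repeated, to a hard cap of
⌊n/3⌋ removals ("at most one third", read conservatively via floor).
Distance ties are broken toward the smaller weight, then the earlier
genomic position, making the output deterministic. Constant-valued
clusters terminate the loop immediately (nothing is an outlier; the W
statistic is undefined there anyway).

## Weighted statistics and scores

Deep primers carry more information, so each surviving ratio is weighted by
its total depth w<sub>i</sub> = C<sub>Si</sub> + C<sub>Ci</sub>. With W = Σw<sub>i</sub>:

    mu*      = (1/W) Σ w_i x_i
    sigma_w2 = (1/(W−1)) Σ w_i (x_i − mu*)²      (unbiased, count weights)
    n*       = W² / Σ w_i²                        (effective sample size)
    SE       = z(1−α/2, n*−1) · sigma_w / √n*     (α default 0.05)
    t        = √n* (mu* − mu0)/sigma_w,  mu0 = 0
    p        = 2 · Pr(T_{n*} ≤ −|t|)

The degrees of freedom are deliberately asymmetric — n\*−1 for the SE
quantile, n\* for the p-value — matching the definitions this caller
implements; both accept fractional df. Because the weights are raw counts,
the W−1 denominator makes σ<sub>w</sub>² scale-dependent in the weights; this is the
definition used throughout, and the equal-weight chain collapses to the
textbook one-sample t-test exactly when w<sub>i</sub> ≡ 1.

The copy number is N<sub>S</sub> = N<sub>C</sub>·2^μ\* with interval N<sub>C</sub>·2^(μ\*±SE). N<sub>C</sub> is 2
for autosomes; for chrX/chrY it follows the control's sex (X: 2 female / 1
male; Y: 0 female / 1 male). Sex defaults to "unknown", which leaves X/Y
clusters uncallable rather than silently assuming diploidy; chrY against a
female control is uncallable (N<sub>C</sub> = 0). N<sub>S</sub> stays real-valued — calls are
classified by direction, not by rounding to integers.

Two Phred-like scores summarize a cluster:

    phi = sqrt(sigma_w) · (1 + |mu*|)
    Q   = −10 log10(p) · phi          (call iff Q ≥ 50)
    P   = −10 ln(SE)

φ exists because raw p-values discriminate poorly when dispersion varies
between clusters: suspiciously flat clusters reach tiny p-values from
trivial offsets (false positives), while noisy clusters with real events
miss the threshold (false negatives). Multiplying the Phred-scaled p by the
square root of the weighted standard deviation — boosted by the effect
magnitude — rebalances both tails; the radicand is the standard deviation,
not the standard error, per the defining formula. Consequences accepted as
designed: a cluster with exactly zero variance has φ = 0 and can never be
called regardless of μ\* (flagged via p-value/t conventions: t = ±∞, p = 0
when μ\* ≠ 0), and p-value underflow below the smallest positive double is
clamped (logged) so Q stays finite — Q is a ranking score, not an
inferential quantity. P may be negative when SE > 1; a non-positive SE
reports P as missing.

Clusters become uncallable when n < 3 (Shapiro–Wilk minimum), when fewer
than 10 primers survive pruning (`min_cluster`), or when N<sub>C</sub> is 0/unknown.
Uncallable clusters are still emitted (FILTER `nocall` with a REASON tag)
for auditability, as are no-change clusters (ALT `.`), suppressible by
flag. No multiple-testing correction is applied across clusters: the fixed
Q ≥ 50 threshold is the decision rule.

## VCF representation

Q is the discriminating score, but VCF's FILTER column is categorical, so
QUAL carries Q (2 decimals) and FILTER the derived category (PASS when
Q ≥ threshold, else `q50`). ALT is symbolic `<DUP>`/`<DEL>`; INFO carries
END (1-based inclusive span end), SVTYPE=CNV, CN/CNMIN/CNMAX, PREC (the P
score), NP (n) and NEP (n′). Output is byte-deterministic for identical
inputs and configuration.

## Multiple controls

Several controls are combined into one synthetic control by per-site
arithmetic averaging of their counts, kept fractional (exact rationals
during accumulation) — rounding would bias low-count primers. Sites are
matched by (chrom, pos, direction); primer names are free text and never
used as keys. Sample/control sites that do not overlap are dropped with a
warning; zero overlap is an error, since identical primer pools are a
precondition of the whole method.

## The simulator

`simulate_comparison` emulates the data-generating process the caller
assumes. Per amplicon, a shared efficiency e<sub>i</sub> = 2^N(0, efficiency_sd)
multiplies both means; counts are negative-binomial with mean
depth·e<sub>i</sub>·copies/2 and variance m + m²/k (size k = `dispersion`). Planted
truth is an integer (N<sub>C</sub>, N<sub>S</sub>) per cluster. Sample-only outliers hit each
amplicon with probability `outlier_rate`, multiplying the sample mean by
2^shift with |shift| ≥ 1 — the primer-site-variant failure mode the pruning
loop targets. An optional per-cluster log2 bias between sample and control
(`cluster_bias_sd`, default 0) models region-level library effects that are
not copy-number changes; it is what creates the low-dispersion
false-positive regime in the φ ablation experiment.

Defaults model a realistic panel run: depth 1000× (mid-range of the
500–2000× such panels are sequenced to), efficiency_sd 0.15 (≈ ±10%
between-amplicon efficiency spread), NB size 100 (log-ratio SD ≈ 0.2 at
this depth), outlier rate 2%. What the simulator does **not** model:
read-level artifacts (alignment, mappability, GC tracking along the
genome), correlated outliers hitting whole clusters, sample impurity or
subclonal mixtures, and inter-run batch structure beyond the optional
cluster bias. Passing operating-characteristic tests therefore demonstrate
the statistical engine under the model's own assumptions, not performance
on any particular wet-lab dataset.

## Numerical and testing choices

Simulation sizes were chosen so every check runs comfortably on one CPU:
the operating-characteristics run uses 12 comparisons × 40 clusters × 40
amplicons (480 clusters, 120 true single-copy events), where sensitivity
and specificity at Q ≥ 50 are expected ≥ 0.95/0.97; at these settings the
measured values are 1.0/1.0 with margin to spare. The P-score calibration
claims ("P > 20 ⇒ copy-number error generally under 20%", "P > 30 ⇒ under
10%") are operationalized at an 80% quantile to be testable. The
dispersion-correction ablation mixes NB sizes {10, 30, 100, 1000} with a
0.1 log2 cluster bias and compares the optimal FPR+FNR sum of Q against
the uncorrected Phred-scaled p-value. Reference values for the t
distribution in the unit tests were computed with R's `qt`/`pt` and frozen.

## Known limitations

No intra-cluster segmentation or breakpoint detection; no sample-purity or
subclone modelling; calls need at least ten normally distributed primer
ratios per cluster; X/Y calling requires the control's sex; the median
baseline breaks down if half or more of the panel is CNV-affected. BAM
ingestion (primer trimming and counting) is out of scope — the count TSV
is the interface.
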