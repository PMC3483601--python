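# Methods

## Scope and model

`flysrna` implements a small RNA-seq profiling pipeline for inducible
*Drosophila* disease models: libraries of ~15–30 nt RNAs sequenced into a 3'
adapter, annotated hierarchically, quantified per miRNA arm, and tested for
differential expression between paired induced and uninduced conditions of
the same genotype. A companion scan searches the same libraries for small
CAG-repeat RNAs against the disease transgene. Because the original raw
libraries are not available, the package ships a first-class synthetic-data
generator whose outputs carry the statistical structure every stage assumes;
all tests and calibration studies run on it.

## Preprocessing

Adapter clipping takes the first full occurrence of the adapter
(`CTGTAGGCACCATCAAT` by default), else the longest adapter prefix of at least
`min_overlap` (default 5) nt that is a suffix of the read — inserts longer
than `read_length − adapter_length` leave only a truncated adapter on the
read, so pure full-match clipping would systematically miss long inserts.
Reads without an adapter are kept by default (`discard_untrimmed` flips
this). The length filter is strict: a 19 nt read passes, an 18 nt read does
not.

Matching allows 0 or 1 mismatch on both strands. The index enumerates exact
occurrences of the two query halves (a ≤1-mismatch placement must contain one
exact half — pigeonhole) and verifies candidates with a capped Hamming scan;
`N` never counts as a match, and queries containing `N` fall back to a direct
scan. Internal coordinates are 0-based half-open; TSV exports are 1-based.

## Annotation cascade

Reads are assigned to the **first** tier with a hit in the order miRNA
stem-loops, other ncRNAs, transposons, introns, mRNAs; leftovers that match
the toy genome count as intergenic, and reads matching nothing are reported
as `unmatched` outside the six classes, so the class counts are mutually
exclusive and sum to the matched total (checked per sample). Multiple hits
within one tier count once; the representative reference is the hit with the
fewest mismatches, ties broken by lexicographic reference id, then smallest
offset, then plus strand — an arbitrary but deterministic rule, needed for
reproducible stem-loop-level counting. tRNA/rRNA/miscRNA are sub-labels of
the ncRNA tier, reported separately.

## Arm assignment

For each stem-loop of length `L`, candidate splits are the integers within 20
of `L // 2`, clipped into `[1, L−1]`. For a split `s`, upstream reads are
intervals with `end ≤ s`, downstream reads those with `start ≥ s`; a read
with `start < s < end` spans the split and is discarded at that candidate.
Since `U(s)+D(s) ≤ T`, the split nearest the total is the one maximizing
`U+D`; ties resolve to the smallest `|s − midpoint|`, then the smaller `s`
(so an empty profile returns the midpoint). Duplicate hits of one read are
deduplicated to the best placement before profiling. When reads tile the
whole precursor the 5p/3p attribution is arbitrary, but `U + D + discarded =
T` always holds, so the per-stem-loop total still reflects precursor
expression.

## Differential expression

* **Size factors** — median over all-positive rows of the count ratio to the
  row geometric mean. Rows with zeros are excluded from the reference set, so
  all-zero rows never affect normalization. Note the geometric-mean
  reference makes the factors equivariant only up to a common constant:
  multiplying one library by `c` multiplies its factor by `c^((m−1)/m)` and
  every other factor by `c^(−1/m)`; ratios of factors, normalized-count
  ratios and fold changes are what is invariant.
* **Dispersions** — the NB variance model is `v = mu + alpha*mu^2`. Gene-wise
  `alpha` comes from within-group moments: per replicate group (the two
  condition groups, plus the reference controls as their own group), the
  variance of normalized counts minus the shot-noise term `q_g * mean(1/s_j)`
  is divided by the squared group mean; per-group estimates are pooled by
  degrees of freedom. Pooling the per-group *ratios* (rather than pooling raw
  variances against one overall mean) keeps the estimator unbiased for genes
  whose group means genuinely differ. The trend `alpha(mu) = a0 + a1/mu` is
  fit by non-negative least squares on the unfloored estimates; the final
  dispersion is `max(gene-wise floored at 0, fitted)` under the default
  sharing mode "maximum". This max rule deliberately trades power for
  robustness against genes more variable than the trend: in calibration it
  keeps the null p < 0.01 rate below nominal (~0.008 at alpha = 0.1, 2+2
  samples with 8 reference controls), and it is why recovery of planted
  4-fold effects in a 2 vs 2 design saturates around 5–7 of 10 at
  padj < 0.01 — even with the true dispersion supplied, the exact test's
  median recovery under those conditions is 8/10, and any estimation noise
  passed through the max rule costs one to three more. Three replicates per
  condition recover >90% of planted 4-fold effects.
* **Exact test** — conditional on the total `K = K_A + K_B`, the group sums
  follow NB laws with means `q*S_A`, `q*S_B` (`q = K/(S_A+S_B)`, `S` the
  size-factor sums) and variances summing the per-sample model,
  `q*S + alpha*q^2*sum(s_j^2)`. The two-sided p-value sums the probabilities
  of all splits at most as probable as the observed one, normalized over all
  splits; it reduces to the exact conditional binomial test in the Poisson
  limit. `K = 0` returns p = 1 by convention. The reference controls never
  enter the tested contrast — they only sharpen the dispersion estimate.
* **Multiple testing** — Benjamini–Hochberg step-up (via statsmodels),
  thresholded at padj < 0.01 by default; a flag switches to raw p.
* **QC** — per-sample Pearson correlation of `log1p` normalized counts
  against the per-gene median of the control samples. The log scale is
  essential, not cosmetic: on the linear scale the replicate correlation is
  bounded by `sqrt(var(mu)/(var(mu)+alpha*E[mu^2]))` no matter how deep the
  libraries are, so the observed "all replicates above 0.99" regime is only
  reproducible on log counts, which is also how such replicate comparisons
  are conventionally plotted. At a realistic depth (~10^7 reads/library,
  200 species spanning four decades, alpha = 0.05) all simulated replicates
  exceed 0.99.
* **Head/body classification** — significant arms of a head-vs-body contrast
  split by their WholeBody/Head ratio (<1 head-enriched, >1 head-depleted);
  cross-dataset agreement is the fraction of shared arms whose ratios fall on
  the same side of 1 (ratios exactly 1 are counted concordant and reported
  separately). The −ΔΔCt helper converts qPCR cycle values to fold changes
  against the mean of two normalizer genes.

## sCAG scan

Reads of ≥15 nt (below the cascade's >18 nt filter, because published repeat
hits go down to 15 nt — the scan therefore consumes trimmed reads upstream of
the length filter) are aligned to the transgene on both strands by a
semi-global dynamic program whose edit moves are substitutions and
single-nucleotide read insertions; deletions are excluded, matching the
"mismatch or insertion" bookkeeping of the published per-hit table. Default
`max_edits` is 2, the largest value the published hits show. One hit per
read: fewest edits, then — because placements tie pervasively inside a
trinucleotide repeat — a footprint start inside the declared repeat region
wins, then the leftmost start, then the plus strand. A read is "in repeat"
iff its 1-based footprint start lies inside the printed repeat coordinates,
and the repeat length used for reads/kb densities is `end − start` (not
`end − start + 1`): this start-based, end−start convention reproduces all
three published density values (12, 10, 26) simultaneously. Densities are
rounded half-up to integers.

## Synthetic data

`build_toy_reference` plants non-overlapping loci on a random genome (default
20 kb): 70–100 nt stem-loop hairpins with a 22 nt arm near each end, one or
more tRNA/rRNA/misc loci, a transposon, an intron, an mRNA and an intergenic
locus, plus an optional transgene of random flanks around a `(CAG)_n` tract.
Counts are drawn NB with mean `depth_j * q_i * fold_i(condition_j)` and
variance `mu + alpha*mu^2`; arm baseline expressions are log-uniform (default
50–800 at unit depth), library depths log-uniform over 0.7–1.4 so size-factor
estimation is non-trivial, and the default dispersion is 0.1. Reads are arm
substrings with ±1 nt end wobble (exercising the split search's spanning-read
rule), at most one substitution per read at the configured error rate, the
adapter appended, and random padding/truncation to 36 nt. Truth labels live
in sidecar TSVs, never in the FASTQ. Spiked repeat reads carry a constructed
number of substitutions (positions ≥4 nt apart, away from read ends,
rejection-checked so the minimum ungapped distance to the transgene equals
the planted edit count), so a downstream scan must recover the edit profile
exactly.

What the generator does **not** model: position- or quality-dependent
sequencing error, indels in ordinary reads, PCR duplicates, ligation bias,
isomiR end heterogeneity beyond ±1 nt, or cross-mapping between paralogous
miRNAs (planted loci are random, hence effectively unique). Passing
round-trip tests therefore demonstrates the pipeline's internal correctness,
not robustness to those real-data artifacts.

## Numerical and degenerate-input choices

Exact-test probabilities are computed in log space and compared with a 1e−8
relative tie tolerance; normalization errors out with a diagnostic when no
row is all-positive; dispersion estimation demands at least one group with
two replicates and points the caller to reference controls otherwise;
zero-variance QC profiles return NaN rather than raising; all-zero genes are
dropped before testing and counted in `attrs["n_filtered"]`; fold change of a
zero baseline is reported as `+inf`. Every stochastic routine takes an
explicit seed and is bit-reproducible; pipeline runs with the same config and
seed produce byte-identical reports.

## Problem sizes used in the shipped studies

The analysis drivers use 8 stem-loops × 12 samples with ~40–400 expected
reads per arm; the calibration studies use 300 genes × 12 samples with 200
null runs and 11 planted runs; oracle comparisons use 1000 random stem-loop
profiles, 200 random 20-mers against 2 kb references, and 150 random
read/transgene alignment pairs. These sizes were chosen as the smallest at
which the estimators' behavior is stable.
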