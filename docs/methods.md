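# Methods

## Scope and data model

The unit of analysis is a representative transcript per gene: the longest
isoform, at least 500 nt, ties broken by lexicographically smallest
transcript id (a determinism convention; biology gives no preference).
Transcripts are held in spliced, sense-strand coordinates as a contiguous
partition 5'UTR | CDS | 3'UTR of 0-based half-open intervals; GTF/GFF3 I/O
converts from/to 1-based inclusive genomic coordinates, and minus-strand
features are reversed so every span is 5'→3' on the sense strand. The stop
codon is counted as part of the CDS (Ensembl convention), so codon-level
statistics include the stop family. A CDS whose length is not divisible by
3 is flagged and excluded from codon analyses, never silently repaired.

## Composition metrics

**GC content** is (G+C)/(A+C+G+T). N bases are excluded from both numerator
and denominator, so composition is computed on the informative bases of
masked sequence; a region with no informative base (including an empty
UTR) yields a missing value, not an error. **GC3** applies the same rule to
the string of codon third (wobble) positions.

**RSCU** ("normalized relative usage") for codon c of an amino acid with
n_syn synonymous codons is

    RSCU(c) = freq(c) · n_syn / Σ_family freq

so the family mean over observed codons is 1 and values below 1 mark
under-used codons. Stop codons form their own 3-codon family. Two senses of
"low usage codon" are exposed, matching how the two are used in practice:
the *broad set* (every synonymous codon with RSCU < 1; 29 codons on the
bundled human reference, 22 of them A/U-ending) and the *per-amino-acid
lowest* codon (18 codons — Met and Trp have no choice; 14 are NNA/NNU, the
exceptions encoding Thr, Ser, Pro, Ala). Per-CDS low-usage frequency and
count use the 18-codon lowest set. Log2 usage ratios between two transcript
groups add a pseudocount of 0.5 to raw counts before normalization so
codons absent from one group stay finite.

**Codon-usage reference.** A 64-entry human codon-usage table ships with
the package (counts per million, derived from the classic GenBank-aggregate
per-thousand frequencies). The published table rounds Gly GGA and GGG to
the same per-thousand value, which leaves their order against the Gly
family mean unresolved at printed precision; the fixture resolves that
rounding tie with GGA marginally above and GGG marginally below the family
mean (totals preserved), the resolution consistent with the printed human
low-usage audit. Every other entry is the standard published value.

**tRNA adaptation** is the tAI-style geometric mean of per-codon weights
(normalized to max 1) over sense codons; zero weights are floored at 1e-4
with a warning rather than collapsing the product. The bundled weight file
is *synthetic* — scaled codon-usage frequencies, adequate for exercising
the score; measured amino-acylated tRNA abundances should be supplied for
biological use.

## Fate table

Per-gene measurements are outer-joined on gene id with missingness
preserved (no silent row loss). Differential-expression testing is consumed
as input, never recomputed; the simple library-size-normalized log2 ratio
estimator exists only so the synthetic pipeline is self-contained. Derived
columns: translation-rate fold-change = polysomal − total log2 fold-change
(the polysomal/total ratio proxies translation rate, and differencing
isolates translational regulation from abundance change); protein yield =
protein abundance / mRNA abundance; P-body classes ("PB-in"/"PB-out")
require both |log2 enrichment| ≥ 1 and a significance flag (p < 0.05),
both configurable. Changes in total mRNA after silencing a decay factor are
reported as stabilization — an interpretive assumption, since transcription
is not measured. Gene recombination rates are overlap-weighted averages of
genetic-map interval rates (cM/Mb) across the gene span.

## Rank statistics

All correlation work is rank-based: the variables mix nearly linear and
strongly non-linear relationships, and Spearman handles both uniformly.
Pairwise complete-case deletion is applied per correlation (the right
policy for patchy fate tables; listwise deletion would discard most genes).
Partial Spearman rank-transforms every variable (average ranks), then
residualizes x and y on the controls and correlates the residuals —
equivalent to the inverse-rank-correlation-matrix route whenever that is
defined, but well-behaved in the edge cases: a variable fully explained by
its controls returns 0 with a warning, collinear controls raise. The
p-value uses the t approximation with n − 2 − k degrees of freedom.

Comparing two dependent overlapping correlations r_xy vs r_xz uses the
Meng–Rosenthal–Rubin z statistic on Fisher-transformed coefficients with
the f = (1 − r_yz)/(2(1 − r̄²)) term capped at 1. Mann–Whitney U follows
the scipy policy (exact for small tie-free samples, tie-corrected normal
approximation otherwise); U is reported for the first sample. P-values are
floored at 1e-300.

**Binning conventions.** Class schemes are left-closed ([lo, hi)), with
open outer classes. The canonical six GC classes run <40% to >60% in
5-point steps; transcript-length classes run <1.5 kb to >10 kb with
interior edges (1.5, 2.5, 4, 6, 10) kb — the interior edges, like the
subdivided >60% 5'UTR classes and the interior edges of the six 3'UTR-GC
classes, are configurable conventions, not canonical values. GC histograms
use 0.7% increments spanning the observed range. Tendency curves sort by x
and cut equal-count blocks of 500 transcripts, merging a trailing block
smaller than half the bin size into its neighbor. Boxplot-style summaries
report 10/25/50/75/90 percentiles with linear interpolation (type-7), the
convention the tests pin down.

## Metagene profiles

Per-base depth in transcript coordinates (alignment is out of scope) is
partitioned into 20 contiguous bins with edges ⌊i·L/20⌋ — near-equal
segments differing by at most one base (largest-remainder allocation) — and
normalized to proportions. Group profiles are unweighted means over
transcripts with nonzero reads, so each gene counts equally regardless of
expression; this also sidesteps cross-condition library-size normalization,
since proportion vectors are scale-free. The 5' summary is the mass of the
first k bins (default k = 2, the first 10% of the transcript — the 5'
window is a convention, exposed as a parameter).

## Target sets and clustering

Target lists are consumed as plain gene-id TSVs with a provenance tag
(CLIP, RIP, motif, miRTarBase); source-specific filtering happens upstream.
Unresolved ids are counted and reported, never dropped silently. Heatmap
rows are ordered by increasing median target GC. Transcript/dataset
clustering uses 1 − Kendall τ distance with average linkage on complete
rows (row-wise deletion, counts reported); τ-b (tie-corrected) is used
because it is the defensible modern convention where legacy tools leave tie
handling undocumented. miRNA sequences arriving in RNA alphabet are mapped
U→T on ingestion.

## Synthetic data generator

The generator defines the study conditions the tests certify; what it does
*not* emulate bounds what passing tests show about real data.

* **Transcriptomes.** Per-gene CDS GC targets are drawn from a
  two-component normal mixture (weights 0.55/0.45, means 42%/55% GC, sds
  5/6 points, clipped to [30%, 72%]) emulating the wide, mildly bimodal
  human mRNA GC distribution. Region lengths are log-normal with medians
  150 nt (5'UTR), 430 codons (CDS) and 800 nt (3'UTR), near human medians.
  CDSs are built by sampling amino acids from a fixed human-like background
  and choosing synonymous codons with a third-base G/C probability solved
  linearly from the GC target, then rejection-resampled until the realized
  GC is within ±2 points; ATG start, single terminal TAA, no internal stop
  by construction. 3'UTR GC tracks CDS GC (+N(0, 4 points)); 5'UTR GC sits
  ~10 points higher, as in human transcripts. Targets outside [25%, 85%]
  GC are rejected as infeasible. No splicing realism, read-level
  simulation or sequencing error is modeled.
* **Fate tables.** A Gaussian copula couples the observed GC values (via
  normal scores) to the fate variables. Pairwise Spearman targets against
  GC default to the magnitudes the analysis is designed to detect
  (P-body enrichment −0.64, DDX6 total +0.45, DDX6 translation rate −0.53,
  DDX6 total in a second cell line +0.59, XRN1 +0.41, PAT1B −0.50, plus
  weaker CLIP/yield/haplo-insufficiency/recombination terms). Pearson
  copula parameters use 2·sin(πρ_s/6) so rank targets are hit; cross
  terms among fate variables follow a single-GC-factor structure
  (ρ_ij = ρ_i·ρ_j), which is PSD by construction and makes fate variables
  conditionally independent given GC — the property the partial-correlation
  recovery test exploits. Marginals are monotone transforms (normal for
  log2 fold-changes, beta for scores, log-normal for yield, gamma for
  recombination), which leave rank correlations untouched. The polysomal
  fold-change is derived as total + translation so the
  translation-rate invariant holds exactly.
* **Coverage.** Poisson(mean 200) reads per transcript placed uniformly; a
  designated set has a Binomial(n, skew) subset placed uniformly in the
  first 10% of positions. Because the uniform background already puts 10%
  of reads there, an injected skew q raises the bins-1–2 mass by 0.9·q —
  the closed form the detection tests check against.
* **Target sets.** Members are sampled without replacement (Gumbel top-k)
  with weights exponential in GC, the tilt calibrated by root-finding so
  the weighted population median meets the requested offset. The median of
  a 500-gene sample carries ≈1 GC point of sampling noise, so recovery is
  certified to ±1 point (seeded). Requested medians outside the population
  range raise. Set overlap is permitted. Synthetic miRNAs couple their own
  GC (uniform 35–65%) to their target sets' median GC at 80% strength.

All generators are pure functions of (spec, seed); sub-generators derive
independent streams from the seed.

## Numerical and design choices

* Isoform ties, bin-edge closure, quartile interpolation and codon-order
  tie-breaks are all fixed conventions, chosen once and pinned by tests, so
  reruns are byte-identical.
* The copula coordinate set uses the translation-rate fold-change (not the
  polysomal one) as primary, deriving polysomal = total + translation;
  this keeps the fate-table invariant exact while targeting the
  correlation the analysis actually reports.
* Pipeline outputs are tidy TSVs written with a fixed float format; the
  manifest records the package version, seed and SHA-256 of every input and
  output, and is byte-identical across reruns with the same seed.
* Default problem sizes (300-gene demo bundle, n = 10000 copula draws,
  600-transcript coverage runs) keep any single stage in seconds while
  leaving estimator noise well inside the certified tolerances.

## Known limitations

Synthetic fate structure is single-factor: real datasets carry
correlation among fate variables beyond what GC induces, so multivariate
statements (e.g. clustering geometry) are only weakly constrained by the
generator. The codon-usage reference is a genome-aggregate table, not a
cell-type-specific one. The tRNA weight file is synthetic. Coverage
simulation has no positional bias other than the injected 5' skew, so
metagene tests certify the estimator, not robustness to real library
artifacts. The analysis consumes fold-change tables as given —
normalization and dispersion modeling upstream are the caller's
responsibility.
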