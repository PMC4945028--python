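# Methods

This note documents the models and procedures implemented in `xdense`, the
assumptions behind them, the parameters that matter, and what the synthetic
data do and do not establish.

## Coordinates, sequences, labels

All intervals are 0-based half-open (BED native; GFF3 start is decremented on
read). Sequences are uppercase over `ACGTN`. N is allowed in genomes but is
never part of a repeat run or motif match (any scan window containing N is
skipped), and N bases remain in density denominators. Chromosome class labels
(X / autosome / other) come from a YAML side-car rather than name heuristics,
because chromosome naming and arm (Muller element) assignment differ across
species; only labeled chromosomes enter X:A ratios, which also makes explicit
which assembly entries (e.g. unplaced or heterochromatic scaffolds) are in
the denominators. The midpoint of an even-length interval is the floor of
(start+end)/2, a deterministic tie-break used for peak centers and all
distance calculations.

## PWM scanning with exact p-values

A PWM stores per-position base frequencies (rows sum to 1). Scanning scores a
window by the log-odds in bits, log2((f + ε)/(1 + 4ε) / b), with a scoring
pseudocount ε = 0.01 that bounds scores away from −∞ and a background b that
is uniform 0.25 by default (a genome-derived mononucleotide background is
supported; the uniform default favors reproducibility). Scores are rounded to
multiples of 1/1000 bit; the null distribution of the total rounded score of
a background k-mer is the convolution of per-position score distributions,
computed exactly by dynamic programming, and the p-value of a hit is the tail
P(S ≥ s) of that distribution. On the rounded scale the DP is *exactly*
equivalent to enumerating all 4^w k-mers (the test suite verifies equality to
1e−12 for w ≤ 8); the only approximation is the rounding itself, which
perturbs any single window score by at most w·0.0005 bit. Hits are all
positions (both strands, overlapping included) with p ≤ the threshold,
default 1e−4.

PWMs built from sequence sets use pseudocount 0.5: f = (count + 0.5)/(n + 2).
Information content per position is log2(4) + Σ_b f·log2 f, i.e. 2 bits minus
the column entropy: 2 for a degenerate column, 0 for a uniform one. Motif
distance is the per-position root-mean-square difference of frequencies,
averaged over a caller-chosen position range so that motif cores and flanks
can be compared separately. Alignment of sequences to a PWM takes the
maximum-score offset/strand with ties broken by smaller offset, then +
strand.

## PBM probe analysis

Probes carry a 36-nt variable region (optionally inside a 60-nt probe whose
last 24 nt are a constant primer) and replicate fluorescence intensities
summarized by their median. Intensity work is on log2 scale wherever a log is
required; the base is fixed and documented here because results depend only
on monotonicity.

*Thresholding.* Bound/unbound classification uses a strict `>` at the
threshold (default 6500 fluorescence units; the boundary value is unbound).
The data-driven threshold is the minimum of a Gaussian KDE (Silverman
bandwidth) of log2 intensities between the two highest density modes; fewer
than two modes is an explicit no-bimodality failure rather than a guess.

*Mixture model.* A two-component Gaussian mixture is fitted to log2
intensities by EM, initialized from the empirical median split, converged at
an absolute log-likelihood change < 1e−8 or 500 iterations (non-convergence
is reported, not raised). Means are reported sorted; "strongly bound" is the
set with posterior probability ≥ 0.95 of the higher-mean component. A
standard-deviation floor of 1e−3 of the sample SD prevents component
collapse.

*MRE labels.* Sequences with best scan p < 1e−4 are MRE+, best p > 1e−3 are
MRE−; the gap (1e−4, 1e−3] is labeled `ambiguous` explicitly, since neither
published rule covers it.

*Flank-separation scan.* Each bound and unbound sequence is aligned to the
core PWM; for every extension (a, b) with a ≤ max5, b ≤ max3 the
(a + core + b)-mer around the core match is extracted, and overlap(a, b) is
the percentage of bound k-mers shared with unbound k-mers. The default
counts distinct k-mer *types* (order-independent and deterministic); a
token mode counting bound sequences is available. Token-mode overlap is
provably non-increasing as the window grows and is asserted; type-mode
overlap shares the property in practice but not as a theorem (the distinct
k-mer denominator grows with the window), so violations warn rather than
abort. The minimal window is the zero-overlap cell minimizing a+b (ties to
smaller a); the total motif length is core width + a + b. Sequences too
short for a window are dropped from that cell with counts reported.

*Repeat-length stratification.* Each probe is assigned the maximal GA-run
length in its variable region; lengths ≥ 11 are pooled into one bin, since a
36-bp variable region leaves few probes with more than 11 units.

## k-mer + shape regression

Aligned equal-length sequences are encoded as position-specific indicator
columns (4 per position for 1-mers, 16 per adjacent pair, 64 per triple) and
four DNA-shape features per eligible position, looked up from the pentamer
centered there (minor groove width and propeller twist belong to the central
base, roll and helix twist to the central step). The two positions at each
edge lack pentamer context and are dropped, not padded. Shape columns are
z-scored by default so that one ridge penalty is commensurate across feature
families.

Ridge regression minimizes ‖y − Xw − w0‖² + λ‖w‖² with an unpenalized
intercept, solved deterministically by Cholesky on the centered normal
equations; a singular system at λ = 0 is an explicit failure. Cross-validated
R² uses seeded fold assignment and is defined as the squared Pearson
correlation between predicted and held-out responses (the sum-of-squares
definition is available behind a flag). When λ is not fixed it is selected
per training split from a 17-point grid 1e−4…1e4 by inner 5-fold CV. Model
comparison shares the fold assignment across encodings and reports paired
t and Wilcoxon signed-rank p-values plus relative gain in percent. On
synthetic data the shape table is random and uncorrelated with any planted
rule, so shape features can only match — never beat — the sequence features
that generated the signal; this is the expected (and tested) behavior, and it
means synthetic runs demonstrate correct bookkeeping, not the real-data
contribution of shape.

## Repeat runs and densities

A repeat run is a maximal in-phase tandem array of a unit (GA by default;
units of length 1–6 supported, homopolymer-as-dinucleotide flagged).
`AGAGAG` contains one maximal (GA)₂ run: scanning considers every offset, so
the longest in-phase run is always found; a run of n units spans exactly 2n
bases. GA and TC (reverse-complement) runs are pooled by default because a
repeat tract is strand-symmetric as a genomic feature; a forward-only flag
exists. Counting conventions: *maximal* (a run of n units counts once, at
length n) and *cumulative* (it counts at every length k ≤ n); both are
produced because both appear in published repeat tabulations. Densities are
counts per Mb of chromosome length (N included). The pooled X:A ratio is
(Σ X counts / Σ X lengths) / (Σ autosome counts / Σ autosome lengths);
per-arm ratios are also available; a zero autosomal count makes the ratio
absent, never infinite. Exact-consensus motif-hit counting is greedy
non-overlapping left-to-right on both strands (a self-overlapping consensus
would otherwise be inflated); a PWM-threshold mode counts scanner hits
instead, since published "binding sequence hits" are ambiguous between the
two — both are provided.

## Peak landscape statistics

Neighbor distances are midpoint-to-midpoint on the same chromosome;
inter-chromosomal neighbors are undefined. For each site, d̄(n) is the mean
distance to its n nearest neighbors (n = 1…4 by default); the category value
is the mean over sites, and sites with fewer than n same-chromosome
neighbors are excluded from that n with counts reported. Randomization
places the same number of midpoints per chromosome uniformly (no
mappability or gap masking, and no exclusion near chromosome ends); the
normalized statistic is observed d̄(n) divided by the median of 10 seeded
randomized sets — values below 1 indicate clustering. A peak is "around CES"
if its midpoint is within the median nearest-neighbor (n = 1) distance of
X-chromosome peaks from any CES midpoint; n = 1 is a choice (the reference
"median distance" does not fix n) and is configurable.

Metagene profiles map each feature midpoint within one gene length of a gene
to x = (signed distance from the TSS along transcription)/gene length,
spanning [−1, +2]; minus-strand genes are flipped; a feature in several gene
windows counts once per window (a deduplicating mode exists). Per-bin values
are count/(n_genes · bin width), so total mass equals incidences per gene —
an identity the tests assert. The body:5′ ratio compares pooled densities in
(TSS+250, TTS] versus [TSS−250, TSS+250], optionally normalized to the X
group. Locus enrichment is ((chip+1)/chip library)/((input+1)/input
library); the pseudocount keeps zero-input loci finite, and library-size
normalization means globally proportional tracks have enrichment 1.

The two-sample KS test computes D from the ECDFs directly; p-values use the
asymptotic Kolmogorov distribution with the effective sample size
n_e = nm/(n+m) and the Stephens small-sample adjustment
(√n_e + 0.12 + 0.11/√n_e)·D, switching to the exact distribution when
min(n, m) ≤ 25. At n = m = 100 the resulting α = 0.05 decision rule has
exact type-I level 0.054 (the lattice of achievable D values makes exactly
0.05 unattainable); the calibration test checks a 2000-simulation estimate
against [0.04, 0.06]. KS p-values across many pairwise comparisons are
reported raw; an optional Benjamini–Hochberg column can be added but is
never used for headline outputs.

## Synthetic data and what it shows

Every generator is a pure function of (config, seed); a root seed fans out
to per-generator child seeds through a stable 32-bit hash, so regenerating
one artifact never disturbs another, and identical calls are byte-identical.

*Genomes.* Background bases are uniform; the background is then sanitized so
that no chance maximal run (≥ 2 units) of the planted unit or its reverse
complement survives — without this, a 1-Mb uniform chromosome would contain
~15 chance (GA)₄ runs and exact count recovery would be impossible. Planted
runs are placed non-adjacently with guard bases chosen so no two-unit tandem
spans the run boundary, keeping each planted run maximal at exactly its
configured length; recovery of planted counts for k ≥ 2 is therefore exact,
and planted X:A ratios are recovered exactly. CES are windows that can carry
extra planted runs. Chance single units (k = 1) remain at their natural
frequency.

*Probe sets.* Bound probes carry a consensus 4-nt 5′ flank + 8-bp GA core +
3-nt 3′ flank inside random context (resampled so the core occurs exactly
once and never on the minus strand); unbound probes carry the same core with
random non-consensus flank pairs. Deterministic "near-miss" unbound probes —
copies of a bound probe mutated at the single base just outside the (4, 3)
window on either side — pin overlap(a, b) > 0 for every window with a < 4 or
b < 3, while the flank-pair exclusion guarantees overlap = 0 iff a ≥ 4 and
b ≥ 3. The recoverable minimal window is therefore (4, 3) (total 15 bp) *by
construction*, which is the point: the test establishes that the scan
recovers a planted truth, not that real probes have this structure.
Intensities are base_class + effect·min(GA units, 10) + Gaussian replicate
noise (defaults: bound base 7000, unbound 2500, effect 400/unit, plateau at
10 units, noise SD 300, 8 replicates), giving a bimodal intensity histogram
and a monotone-then-flat intensity/repeat-length curve. A separate generator
plants pure GA-run series probes for the repeat-length analysis.

*Peaks, genes, coverage, shape.* Clustered peak sets draw half of the X
peaks around CES (SD 200 bp), 30% around scattered minor centers (5× wider)
and the rest uniform, emulating the observed clustering hierarchy (tightest
at CES, intermediate elsewhere on X, none on autosomes); uniform mode places
everything uniformly. Genes are non-overlapping with log-normal lengths and
random strands. Coverage is per-base Poisson with planted ChIP multipliers
over chosen loci (counts, not reads — read simulation is out of scope).
Shape tables draw uniformly within documented plausible ranges (MGW
2.8–6.2 Å, ProT −17–0°, Roll −8–8°, HelT 30–40°) and are complete over all
1024 pentamers.

What passing does *not* show: synthetic genomes have uniform base
composition and no transposons, gaps, or imperfect repeats, so real-genome
repeat densities, mappability artifacts and assembly quality are untested;
the synthetic shape table carries no physical signal; Poisson coverage lacks
fragment-length and GC effects.

## Problem sizes

The default test suite and the acceptance script run at desk scale, chosen
so the whole stack exercises in well under a minute of compute per stage:
1-Mb chromosomes (3 Mb genomes) for density and clustering analyses, 400
probes for the flank scan, n = 5000 for mixture recovery, n = 3000 aligned
20-mers for the regression comparison, 1000 random sequences for the
repeat-engine oracle, 2000 simulations for KS calibration, and exhaustive
4^w enumeration up to w = 8 for the scanner oracle.

## Known limitations

Imperfect (mismatch-tolerant) repeats, de novo motif discovery, read
alignment and peak calling are out of scope; peaks, coverage and PWMs are
inputs. The exact-consensus hit count's greedy non-overlap policy is one of
several defensible conventions (documented above). Type-level flank-scan
overlap can in pathological cases rise with window growth (see above);
token mode is the provably monotone alternative. The EM mixture assumes two
Gaussian components on log intensity; heavy-tailed intensity distributions
will inflate the strong-set boundary.
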