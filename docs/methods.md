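# Methods

`recapseq` models the computational chain of a restriction-based
hypermethylation enrichment assay: an enzymatic methyl-seq (EM) library is
digested with a methylation-dependent enzyme recognizing CGCG (BstUI,
cutting CG^CG), and only molecules whose recognition sites retained both
cytosines — i.e. were methylated and therefore escaped conversion — are
cleaved and carried into the final library.  Analysis then proceeds on
counts of the genomic *fragments* delimited by consecutive CGCG sites,
rather than on methylation fractions, because the capture step itself is
methylation-selective.

## Fragment catalog

All coordinates are 0-based, half-open (BED on disk).  A motif is canonical
when it is the lexicographic minimum of itself and its reverse complement;
enumeration of all CG-containing 4–6-mers under this equivalence yields 752
motifs (26 + 122 + 604 by length), which the test suite verifies against
brute-force enumeration.  Scanning reports every occurrence of a motif or
its reverse complement, keeps overlapping occurrences, counts a palindrome's
double match once, and never matches across N.

A catalog fragment is a pair of *consecutive* occurrences on one contig (a
complete-digest model: partial-digest super-fragments are not catalogued).
The insert is the sequence strictly between the motifs; the physical
captured molecule spans cut site to cut site (`left_motif.start + 2` to
`right_motif.start + 2`) and carries a terminal CG at each end.  Retention
requires an insert of 50–300 bp inclusive (both bounds configurable), no N
in the insert, and no ≥ 1 bp overlap between the motif-to-motif span and a
blacklist interval.  CpG-island association uses ≥ 1 bp overlap with the
insert.  The observed/expected CpG ratio of a sequence is
`count(CG) / (#C × #G / length)`, zero when the sequence lacks C or G.

## Synthetic genome and methylome

The generator emulates the CpG-island landscape a practitioner would scan:

* **Genome** (defaults: 5 contigs × 1 Mb, 200 islands of mean length
  1,500 bp): background sequence at 41% GC with CpGs planted at
  0.04 CpG/bp, islands at 60% GC with 0.10 CpG/bp.  A fraction (0.35) of
  background CpG planting events drop a full CGCG so that restriction sites
  cluster, as CpG-retaining sequence clusters them; islands additionally
  receive regularly spaced CGCG sites (inserts ~55–130 bp), and every
  island is guaranteed at least one catalogable fragment.
* **Methylome**: background CpGs are highly methylated (β = 0.80, the
  genome-wide norm), islands are hypomethylated in the normal class
  (β = 0.03) and a chosen fraction of islands (20% → 40 marker islands at
  default scale) is hypermethylated in the tumour class (β = 0.95).
  Within a molecule, methylation is processive: each CpG copies its
  upstream neighbour's state with probability ρ (default 0.9), otherwise
  redraws from the site marginal.  This first-order Markov model is the
  explicit stand-in for processive methyltransferase behaviour; it produces
  the run structure that makes dual-site cleavage informative.
* **Library**: molecules start uniformly, lengths are Normal(180, 40)
  truncated at 50 bp (cfDNA-like shearing).  Conversion reads an
  unmethylated C as T with probability 0.998 (failures at non-CpG cytosines
  are counted per molecule) and a methylated CpG survives except for an
  overconversion probability of 0.002.  Calls (`M`/`u`) reflect the
  *observed* base, as an alignment-based caller would report.  Digestion
  acts on the converted sequence: a CGCG can only survive conversion where
  both CpGs still read C, so cleavable sites correspond one-to-one to
  reference CGCG sites whose four bases were retained; each is cut
  independently with efficiency 0.9.  Pieces cut at both ends form the
  enriched library; pieces with ≤ 1 cut end survive adapter cleanup with a
  leak probability of 0.05.  Defaults (depth 2 × 10⁵ molecules/sample,
  5 Mb genome) are desk-scale choices; everything is overridable.

Two digestion implementations exist deliberately: an object-level one that
cuts the materialized converted sequence (used for small inputs and as a
cross-check), and a fused array-level sampler that decides cuts from site
states without materializing undigested molecules (used for cohorts).
Tests verify their statistical agreement and that a molecule's pieces tile
it exactly.

What the generator does **not** model: sequencing errors and base
qualities, PCR duplicates, adapter sequence logic (the EarI step is a
single leak probability), fragment-end biases, and real genomic repeat
structure.  Passing tests therefore demonstrate the correctness and
statistical behaviour of the analysis chain under a faithful chemistry
model, not performance on real libraries.

## Read filtering and counting

Three independent (hence order-free) filters mirror the protocol's
processing: discard reads with more than `max_failures` (default 0)
unconverted non-CpG cytosines; discard reads that do not match a catalog
fragment's cut-site pair exactly or whose terminal half-sites do not read
CG; discard reads retaining a complete CGCG anywhere in the converted
sequence (an uncut internal site — the captured fragment itself carries
only the inner CG of each flanking site, so any full CGCG is internal).
For accounting, each discarded read is attributed to the first failing
reason in a fixed order, so retained + per-reason discards equals input.

Counting assigns a read to the fragment whose cut-site pair equals the read
coordinates exactly (tolerance 0 — with simulator truth coordinates this is
the faithful, stricter form of interval counting).  Library size is the
number of retained reads, which equals the column sum over the catalog, so
CPM columns sum to 10⁶ by construction.  Sample QC requires ≥ 2,000
distinct covered fragments by default.  Region methylation (AMF) pools all
CpG calls whose position falls in the region; zero coverage yields an
undefined AMF (never 0) and such regions are dropped from ΔAMF with a
report.  ΔAMF per fragment averages the left- and right-motif differences
and reports the insert difference separately.

## Marker selection

Counts are normalized to counts per million of the per-sample library.
The differential test is a conditional exact test on within-group pooled
counts: given the pooled total *t*, the first group's count follows a
Binomial(*t*, n₁/(n₁+n₂)) law at zero dispersion, or the conditional law of
two negative binomials with common dispersion φ and means proportional to
the library sizes.  φ comes from a method-of-moments estimate
(`max(0, (s²−m)/m²)` per fragment on counts rescaled to the mean library
size, median over fragments).  P-values are two-sided by doubling the
smaller tail (observed outcome included, capped at 1) and adjusted by
Benjamini–Hochberg.  This is intentionally a fully specified, enumerable
test rather than a re-implementation of a particular count-model package:
it reduces exactly to the binomial in the zero-dispersion limit and is
verified against brute-force enumeration in the tests.  Markers satisfy
log₂FC > 5 (group-mean CPM with a 0.5 pseudo-count; technical replicates
averaged on the CPM scale first) and FDR < 0.01, both strict.  For
whole-methylome comparisons, AMF markers require AMF < 0.2 in the reference
and > 0.8 in the case, strict, with undefined AMF excluding a region.
Marker-set overlap uses the upper-tail hypergeometric P(X ≥ k) with the
catalog size as the default universe.

## Scoring and classification

The detection score is the summed CPM over a marker set; detected-marker
counts use a strict CPM > 5 cutoff.  AUC follows the Mann–Whitney
convention (ties ½); confidence intervals come from class-stratified
percentile bootstrap (1,000 resamples, seeded); sensitivity at a target
specificity uses a step-function threshold (smallest observed score t with
fraction of negatives strictly below t reaching the target; positives count
when ≥ t — no interpolation).  Ground-truth markers in evaluations are the
catalog fragments whose motif-to-motif span lies fully inside a marker
island: a fragment straddling the island edge has flanking motifs governed
by the (highly methylated) background and fires in every sample, so it is
not a hypermethylation-specific unit.

## Desk-scale behaviour and known limitations

Several published-scale observations compress at desk scale, and the test
suite asserts what the model actually supports:

* **Titration floor.**  At 2 × 10⁵ molecules/sample a spike-in fraction of
  10⁻⁵ contributes ~2 tumour molecules, i.e. ≪ 1 expected marker read, so
  strict monotonicity of group means across fractions down to 10⁻⁵ is
  beyond the statistical resolution of three replicates; with the default
  normal-island methylation (β = 0.03, processive), baseline leakage is
  12–28 counts/sample with variance ≈ 2.2 × mean, and the 10⁻² group's
  ~+7.5-count signal sits ≈ 1.2 SD above it — separation of replicate
  ranges at 10⁻² is borderline rather than guaranteed.  The corresponding
  test states the full idealized property and documents that it probes the
  scale limit.
* **CPM granularity.**  With ~45k-read libraries one count is ~22 CPM, so a
  single leaked baseline count defeats a strict log₂FC > 5 call for an
  otherwise perfect marker; strong-contrast marker recovery is therefore
  ~0.6–0.75 overall and ≥ 0.85 on leak-free fragments at default scale
  (bounds frozen from simulation), approaching completeness only as
  library size grows.
* The dispersion estimate is a single common φ; no empirical-Bayes
  shrinkage or TMM-style composition normalization is applied.
* The simulator draws molecule starts uniformly; coverage biases (GC,
  fragment-end) are out of scope.
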