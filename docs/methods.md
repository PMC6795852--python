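# Methods notes

## Measurement model

A methylation-sensitive double-digest library reports methylation through
read counts: a locus is a size-selected restriction fragment end cut by the
context-reporting enzyme, and a methylated reporting base blocks the cut,
removing that molecule from the library. The expected count at locus *i*
in sample *s* is therefore proportional to coverage × (1 − level_is),
where level is the fraction of methylated molecules. All downstream
statistics are built on this inverse-proportionality assumption; PCR and
mapping biases are assumed locus-specific but sample-invariant, which is
why only *relative* (between-sample) methylation is ever inferred.

### Max-count rescaling

Per locus, the sample with the highest normalized count is declared fully
unmethylated and the others are rescaled proportionally:
`level_s = (c_max − c_s)/c_max`. This anchors every locus at level 0 in
one sample, so estimated levels are relative to the least-methylated
sample, not absolute. Two consequences worth remembering:

* a locus methylated in *all* samples to the same degree is invisible;
* the anchor c_max is itself a noisy maximum, which biases small levels
  upward and makes the downstream binomial test slightly anti-conservative
  when counts are overdispersed relative to the assumed binomial (see
  *Calibration* below).

### DMP test

With one two-level treatment factor, the binomial logistic regression has
closed-form maximum-likelihood estimates (the pooled group proportions),
so the likelihood-ratio statistic against the intercept-only model is
computed directly from the binomial log-likelihoods (df = 1). This is
numerically identical to an IRLS fit where one exists and remains finite
under complete separation (e.g. levels 0 vs 1), where IRLS diverges.
Successes are `round(level × n)` with pseudo-coverage *n* = the locus
maximum normalized count, floored at `min_total`; this treats the rescaled
levels as binomial proportions observed at the depth of the unmethylated
reference sample. Benjamini–Hochberg is used for multiplicity throughout
the package (DMPs, DMR validation, enrichment, allelic shifts).

A locus where every sample has level 0 in both groups is assigned p = 1
rather than an error; `delta` is the treated-minus-control difference of
mean levels and fixes the reported direction (hyper = gain under
treatment).

### DMR scan

Only significant DMPs (q ≤ FDR) enter the scan. Within a chromosome the
earliest unused DMP seeds a cluster; the scan repeatedly pulls in the
earliest unused DMP lying within `window_length` bp downstream of the
current anchor *and* matching the cluster direction, re-anchoring at each
inclusion. Discordant DMPs inside the window are skipped but remain
available to seed later clusters; a cluster closes when no DMP qualifies.
Clusters with ≥ `min_dmps` members are validated by the same logistic
model with successes and trials summed over members, BH-corrected across
candidate regions. The reported span runs from the first to the last
member position. The window length is chosen by scanning 100–2000 bp in
100-bp steps and keeping the length that maximizes the validated-DMR
count; ties go to the smaller window, which gives more conservative spans.
The scan table is emitted so an operator can override the choice.

### Filters

Three knobs, applied in order, each recording a per-locus discard reason:

* `min_total` (default 4 reads): raw experiment-wide total below this is
  noise;
* `min_locus_coverage` (default 10): summed normalized coverage floor;
* `max_sd` (default 0.08): within-replicate-group standard deviation of
  relative counts (counts divided by the locus total). This removes loci
  whose replicate noise is far above the binomial expectation and is the
  main guard protecting the DMP test's calibration on real libraries.

The raw-total and normalized-coverage floors are deliberately two
independent knobs rather than one, since they act on different scales.

### ASMR test

Reference-allele frequency `REF/(REF+ALT)` per replicate, a two-sample
Student's t-test between groups (`equal_var=False` switches to Welch),
BH correction, significance at adjusted p < alpha (default 0.05). Sites
need ≥ 25 raw reads in every sample; the frequency is scale-invariant, so
normalization affects only this bookkeeping. When both groups are constant
the test is degenerate: p = 1 for equal means, p = 0 (flagged and logged)
for different means. ASMR sites are intersected with DMP-bearing loci by
positional containment and located in the gene context via the extended
gene bodies.

### Gene context

An extended gene body is the gene span plus a flank (default 2000 bp,
configurable — analyses in this field use 2–2.5 kb) on both sides,
strand-aware and clipped at chromosome bounds. Point features (and
interval midpoints, for enrichment) are classified uniquely into
{upstream, exon, intron, downstream, intergenic}; a position inside two
EGBs goes to the gene with the nearest TSS. Gene-level DMR calling instead
uses any-overlap, so one DMR can hit several genes and zones. Enrichment
per partition is a two-sided exact binomial test with the expected
proportion taken from the whole locus catalog.

## Synthetic data

The generator emulates a two-group design (well-watered vs
drought-stressed by default) with three biological replicates per group,
7-bp sample barcodes, 1×150 single-end reads, and 250–600 bp size
selection. Baseline methylation is Beta(2,2) per locus; planted
differential loci shift one group's mean by `effect_size` (direction
recorded in the truth table), replicates jitter around group means with
sd `replicate_sd` (default 0.02); planted regions place runs of
concordant differential loci for DMR studies.

**Count model.** Each library samples a fixed pool of `mean_coverage`
molecules per locus — libraries are deliberately balanced at equimolar
amounts, which motivates a constant pool — and each molecule is sequenced
iff its reporting base is unmethylated, giving
`c ~ Binomial(coverage, 1 − level)`. Setting `dispersion > 0` draws the
pool from a gamma-Poisson (negative binomial) instead, adding
library-level overdispersion.

**Library totals.** The RPM divisor is the whole library size
(`library_size`, default 3×10⁶ reads), of which the simulated loci are a
small subset — as in a real experiment, where most reads fall on loci
outside any desk-scale window. This keeps normalized counts (and hence
the pseudo-coverage of the DMP test) on a realistic scale.

**Calibration.** Defaults were fixed by a calibration study of the count
model: `mean_coverage=120` with `library_size=3e6` puts the typical
pseudo-coverage near 30 and gives an approximately calibrated null for the
rescaled binomial LRT under the thinning model. Because the max-count
anchor underestimates sampling noise, any super-Poisson count noise makes
the test anti-conservative; recovery-style analyses therefore apply the
common-practice effect-size floor `min_delta = 0.25`, while null-
calibration checks run with `min_delta = 0` to exercise the significance
machinery alone.

**What the simulator does not emulate** — and what passing tests therefore
do not establish about real libraries: sequencing errors, PCR duplicates,
adapter read-through, mapping ambiguity (truth alignments are emitted
directly, since alignment is outside this package's scope), partial
digestion, enzyme star activity, and genuinely overdispersed biological
replicates (available via `dispersion`, but off by default). On real data
the replicate-sd filter carries the burden of removing overdispersed loci,
and DMP lists called without an effect-size floor should be treated as
anti-conservative.

## Numerical choices

* Coordinates are 0-based half-open internally; GFF3 is written 1-based
  inclusive, BED 0-based half-open.
* Cut positions are single forward-strand coordinates (`cut_offset` within
  the recognition site); overhangs are not modelled because fragment
  lengths and locus ends are all the downstream stages use. Palindromic
  recognition sites are counted once; non-palindromic ones are also
  scanned as their reverse complement.
* The reporting base of a sensitive enzyme defaults to the first base of
  the recognition site matching the enzyme's context (AciI CCGC → offset
  1; PstI CTGCAG → 0; EcoT22I ATGCAT → 3; DpnII GATC → 1) and is
  configurable, since the governing base is enzyme biochemistry not fully
  determined by the recognition sequence alone.
* Size-selection bounds are inclusive on both ends.
* Bookended intervals (end == start) merge into one locus: fragment ends
  emanating from a single restriction site belong together.
* A read overlapping two merged loci is assigned to the larger overlap;
  exact ties are discarded rather than double-counted.
* Greedy read collapsing orders unique sequences by (abundance desc,
  sequence asc) and joins the first existing contig at ≥ the identity
  threshold (default 0.94, configurable; the divergence tolerance of
  typical collapsing tools). Identity is Hamming for equal lengths, edit
  distance otherwise. Reads tied between contigs at assignment are
  discarded, mirroring the unique-mapping rule.
* Successes for the binomial tests round half-up via `numpy.round`;
  pseudo-coverage is floored at `min_total` to avoid degenerate
  denominators.
* DMR validation pools member successes/trials rather than averaging
  member levels; pooling weighs members by their coverage and reuses the
  locus-level model unchanged. This is an interpretation choice; the
  alternative (mean-of-levels response) would weight members equally.
* Barcodes are validated to be pairwise > 2×`max_mismatch` apart before
  demultiplexing, which makes one-mismatch assignment unambiguous by
  construction.

## Limitations

* Reference-free mode produces DMPs per contig but no DMRs — contigs carry
  no genomic adjacency. Cross-mode agreement is evaluated on simulated
  data by mapping contigs back to loci through read provenance; real data
  has no such mapping.
* Relative methylation is bounded by the least-methylated sample; absolute
  levels are unidentifiable by design.
* The DMP model treats RPM-scaled pseudo-counts as binomial trials; its
  type-I error is controlled only as long as replicate noise is at or
  below binomial scale (enforced on real data mainly by the replicate-sd
  filter and the effect-size floor).
* Ordination/clustering figures are out of scope; the TSV outputs are
  ready for any standard plotting stack.
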