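# Methods

## The screen being analysed

`chronoscreen` analyses pooled CRISPR knockout screens designed to ask
whether a drug's fitness effects depend on circadian administration time.
The experimental layout it assumes: cells transduced with a genome-wide
guide library are synchronised (serum shock defines zeitgeber time ZT0),
split, and treated with drug or vehicle at two phases — ZT16 and ZT28 — with
an untreated baseline taken before the split.  Sequencing the integrated
guides in each population gives a guide x sample count matrix; guides whose
knockouts change drug fitness at one phase but not the other identify
time-specific sensitivity/resistance genes.  The motivating application is
5-fluorouracil chronochemotherapy in colorectal cancer cells, where
pyrimidine-metabolism genes are under clock control, but nothing in the
package is specific to that drug.

## Guide counting

Reads are assigned by exact (zero-mismatch) spacer lookup.  The default
`scan` mode slides a spacer-length window across each read and is therefore
independent of trimming or amplicon layout; `fixed_offset` mode extracts a
single window when the layout is known.  A read hitting spacers of two
distinct guides is counted *ambiguous* and assigned to neither — integer
counts are required downstream, so reads are never split fractionally.
Matching is forward-strand by default with an opt-in reverse-complement
pass, reflecting the fixed orientation of amplicon sequencing.  Per sample
the counter reports total/mapped/ambiguous/unmapped reads (which sum
exactly), the mapping rate, mean and median per-guide coverage, the
zero-count guide fraction and the Gini index of counts.  The QC verdict
flags samples under a configurable mapping-rate threshold (default 75%, the
bar genome-wide screens are typically held to) and checks median coverage
against a target band (default 100–300x).

## Median normalization

Depth differences are removed before fold changes are formed.  The default
`median_scaling` method divides each sample by
`size_factor = sample_median / reference`, where the reference is the
median of per-sample medians; afterwards every sample's median guide value
equals the reference.  This is the most literal reading of "median
normalization"; `median_ratio` (DESeq-style median of ratios to a
geometric-mean pseudo-reference over guides positive in all samples) is
provided as a robust alternative for zero-inflated data.  Nontargeting
guides participate in size-factor estimation — they are part of the
sequenced library and are removed only afterwards, at hit calling.  A zero
sample median is an error (with a pointer to `median_ratio`), not a silent
fallback.

## The fold-change set algebra

Hit calling is rule-based at the guide level.  Because transduction and
knockout efficacy vary guide to guide, the procedure gates individual
guides first and only then asks for gene-level concordance:

1. **A1..D1.** From the normalized matrix (A = ZT16 vehicle, B = ZT16 drug,
   C = ZT28 vehicle, D = ZT28 drug), drop nontargeting guides, drop guides
   failing the zero filter, then add a pseudocount (default 1) everywhere.
   The default zero-filter scope `any_sample` removes a guide that is zero
   in any of the four screen samples, so all four datasets share one guide
   index — which the set algebra implicitly requires; `all_samples`
   (remove only all-zero guides) is offered as the alternative reading.
2. **Guide gates.** r16 = B1/A1 and r28 = D1/C1 per guide.  Enriched:
   ratio ≥ 2 (inclusive); depleted: ratio < 0.5 (strict).  These populate
   B2/D2 (enrichment) and A2/C2 (depletion).  The inclusivities follow the
   printed inequalities exactly, as do the strong gates below.
3. **Gene calls.** For each side, a *primed* set takes genes with at least
   `min_concordant_guides` (default 2) distinct gated guides, and a
   *strong* ("double-primed") set rescues genes with a single guide past
   the strong threshold (ratio ≥ 5, or < 0.2 on the depletion side).  The
   per-timepoint call is their union, e.g. B3 = B2′ ∪ B2″.  "Concordance"
   is interpreted as ≥ 2 distinct guides — the only operational reading
   with three guides per gene — and is exposed as a parameter.
4. **Time-specific sets.** B4 = B3 \ D3 and D4 = D3 \ B3 (ZT16- and
   ZT28-specific resistance), A4/C4 likewise on the depletion side; the
   intersections B3 ∩ D3 and A3 ∩ C3 are reported separately as the
   time-independent calls.

The full provenance — per-guide values and ratios, gate flags, and the rule
that admitted each gene — is retained in a `DatasetLedger` and written as
guide-level and gene-level TSVs with a YAML parameter sidecar.

Numerical choices: ratios are exact quotients of values decimal-rounded to
12 places (Python `round`, i.e. correct decimal rounding, not a scaled
multiply), so gate membership at boundary ratios like 2.0 is stable across
platforms.  The pseudocount guarantees positive denominators, so no
special-casing of zero is needed after filtering.  The baseline sample
takes no part in hit calling; it exists for QC.

## Pathway enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for overlap k between the query (size n in-universe) and a pathway
(size K) drawn from a universe of N genes, computed with
`scipy.stats.hypergeom.sf`, with Benjamini–Hochberg adjustment across the
collection per query (raw p is retained).  The universe defaults to the
genes actually screened, not the whole genome — hits can only come from
screened genes, and a genomic background would inflate significance.
Pathway collections are user-supplied GMT files; no licensed pathway data
ships with the package (tests use small synthetic collections).  A
Venn-style intersection of two enriched lists at a q cutoff supports
comparing pathway calls across assays.

## The synthetic screen generator

The generator is first-class, tested code: it defines the study conditions
under which the pipeline is validated.

* **Representation.** Guide baseline abundances are log-normal
  (`sdlog = 0.4`, normalised to mean 1), emulating uneven plasmid pools;
  this yields a Gini index around 0.2, consistent with a well-maintained
  library.
* **Counts.** Negative binomial around abundance x coverage with
  `var = mu + alpha * mu^2`, `alpha = 0.005` by default.  This mild
  overdispersion reproduces the "uniform, well-correlated samples" regime
  of a high-coverage screen (replicate log-count Pearson r ≈ 0.95 at
  300x); noisier screens are modelled by raising `alpha`.
* **Effects.** A planted gene carries a multiplicative fitness effect
  (default 8-fold) on the mean of its effective guides in the drugged
  sample(s) of its class — ZT16-only, ZT28-only, or both.  Vehicle and
  baseline are effect-free.  `effective_guide_fraction` (default 1,
  configurable down to 1/3) models inactive guides and stresses the
  concordance rule.  Defaults plant 20 + 20 + 10 genes at 300x coverage.
* **Library preset.** The genome-wide preset holds 58,028 guides with
  1,000 nontargeting controls.  Since 57,028 targeting guides are
  3 x 19,009 + 1, the preset gives 19,009 synthetic genes three guides each
  and one designated gene a fourth — the unique assignment honouring all
  the published counts at once.  Spacers are seeded random unique 20-mers.
  A 2,000-gene `scaled_profile` with the same structure is used for
  routine validation; the full preset is exercised where only composition
  matters.
* **Reads.** The FASTQ writer embeds each counted spacer at a fixed offset
  (default 10) inside lentiviral-vector flanking sequence in 50-nt reads
  with constant quality 'I'; the on-library read multiset per sample equals
  the count matrix exactly.  Contaminant reads are uniform random sequence
  added so they form `contaminant_fraction` of the file
  (`round(n_on * f / (1 - f))` extra reads).  There is no base-error model
  beyond the contaminant fraction, and no simulation of infection MOI,
  selection kinetics or cell-cycle effects.

What passing tests therefore show: the counting, normalization and algebra
stages are exact and self-consistent, and under realistic noise the
procedure recovers strong planted timepoint-specific effects essentially
completely while making essentially no false calls.  What they do not
show: behaviour under sequencing error inside the spacer (exact matching
discards such reads), strong guide-efficacy heterogeneity, batch effects,
or effect sizes near the fold-change gates — the rule-based caller has no
error control, and weak or discordant effects will be missed by design.

## Problem sizes and determinism

Validation runs use the 2,000-gene scaled library (7,000 guides), 50
replicate screens for recovery scoring, 1,000 random small matrices for
oracle equivalence, and ~120,000 reads per sample for read-level checks —
sizes chosen so the whole suite runs on a laptop in a few minutes while
keeping every statistical check well-powered.  All randomness flows from
explicit integer seeds (`numpy.random.default_rng`); identical configs
produce bit-identical outputs, and the pipeline writes no timestamps into
its outputs so reruns can be compared by checksum.

## Known limitations

* Exact matching trades sensitivity for specificity; a 1% per-base error
  rate costs roughly 18% of reads at 20-nt spacers, which the mapping-rate
  QC will surface but the counter will not recover.
* The set algebra returns sets, not ranked lists or p-values; it cannot
  trade off false positives against false negatives, and its thresholds
  (2, 0.5, 5, 0.2) are conventions, exposed as parameters rather than
  fitted.
* With a single sample per condition there is no replicate-based variance
  estimate; the nontargeting guides are the only empirical null, and they
  are used for exclusion rather than calibration.
* Which final set corresponds to "sensitive at ZT28" depends on whether
  one reads knockout-depletion (C4) or knockout-enrichment (D4) as
  sensitivity for the biology at hand; the pipeline reports all four sets
  and lets the enrichment step be pointed at any of them.
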