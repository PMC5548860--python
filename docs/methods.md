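# Methods

## Scope and data model

The package analyses ultra-deep amplicon sequencing of a 50-gene panel
(207 amplicons, 22 027 covered bp, 2 800 pre-specified hotspot sites) for
paired plasma cfDNA and white-blood-cell (WBC) DNA. Internal coordinates are
0-based half-open everywhere; the mpileup text dialect (1-based) is converted
only at the I/O boundary. Indels, soft-clipped bases and fusions are out of
scope: all per-read and per-position statistics are computed over
match/mismatch alignment columns only, so "mutant" always means a single-base
substitution against the reference.

The packaged *replica panel* is a synthetic stand-in that reproduces the
study panel's cardinalities on a synthetic reference (one contig per gene,
near-even amplicon lengths, hotspots placed uniformly). The real hg19 primer
coordinates were never published; none of the statistics computed here depend
on genomic position, only on panel structure. The replica files are the
deterministic output of `simulate_reference_and_panel(seed=22027)`.

## Filters

Three filters, with **strict** inequalities exactly as the protocol words
them (boundaries survive):

| filter | rule | boundary behaviour |
|---|---|---|
| per-read mutant fraction | discard if > 0.05 | a read at exactly 5 % is kept |
| base quality | mask if Phred < 30 | Q30 is kept |
| locus depth | remove if < 10 000× | 10 000× is kept |
| position MAF cap | remove if > 0.1 | exactly 0.1 is kept |

The per-read fraction is computed on all aligned bases *before* quality
masking — hypermutation is a property of the read, not of its surviving
bases. The two orderings are not distinguished by the protocol text; this
one is the conservative reading and is fixed, not configurable. Bases paired
to a reference `N` never count on either side of any ratio. Quality-masked
bases contribute to neither the numerator nor the depth of a pileup column,
so every column satisfies depth = Σ counts. Overlapping mate pairs would be
counted as two observations; the read simulator is single-end so the question
does not arise in the synthetic data.

## Per-position and per-gene statistics

The mutant allele frequency (MAF) of a position is the total non-reference
fraction of retained bases; per-alternate fractions are kept alongside for
hotspot calling. The per-gene statistic is the arithmetic mean of
per-position MAFs over the gene's amplicon positions,

    F_gene = (F_1 + ... + F_n) / n,

with n the gene's **total amplicon length**: a panel position with no
surviving pileup column contributes 0 to the numerator but still counts in
n. A `covered_only=True` mode divides by the surviving-position count
instead; the default matches the definition above because the denominator is
defined as the amplicon length, not the covered length. Gene ranking is by
mean F_gene across samples, descending, with lexicographic tie-break for
determinism. The MAF > 0.1 cap is applied per sample before any cohort
averaging.

## Paired concordance

Positions enter a paired analysis only when they pass depth > 10 000× and
MAF > 0.003 **in both members** of the pair (strict, per the inclusion rule
used for the scatter analyses; 0.3 % and 0.003 are the same threshold).
The regression is ordinary least squares of y on x (cfDNA on WBC, or
replicate 2 on replicate 1); Pearson r is symmetric, slope and intercept are
direction-dependent and documented as y-on-x. Adjusted R² uses the
single-predictor formula 1 − (1 − R²)(n − 1)/(n − 2).

Two cohort entry points exist: `cohort_paired_means` averages each position's
MAF across pairs (pair-passing inclusion) and then correlates position means;
`individual_paired_vector` correlates raw positions within one individual.
Whether the cohort average should use pair-passing or per-sample-passing
denominators is not fully determined by the protocol; pair-passing was chosen
because every inclusion rule in the source analyses is stated for both
members at once.

## Hotspot calling and WBC subtraction

A call requires the hotspot's specific alternate to exceed 1 % VAF at a site
depth above 5 000× (both strict). "Depth" is the site's own depth in this
sample; the alternative reading (panel-average depth) was rejected because
calls are per-site decisions. Calls are keyed per (contig, position,
alternate), so two different alternates at one site are distinct calls.

WBC subtraction removes any cfDNA/tumor call whose site shows the same
alternate above `wbc_max_vaf` (default 0.01) in the paired WBC profile. The
source protocol says calls were "filtered by WBC" without a numeric rule;
0.01 mirrors the calling threshold and is configurable. Sites absent from
the WBC profile are retained and flagged `wbc_uncovered` rather than
silently passed or dropped.

## Detection rule and limit of detection

No explicit spike-in detection rule is given by the protocol, so the package
adopts the standard one for ultra-deep amplicon data: at depth n with
alternate count k, test k against the error null Binomial(n, e/3) — e being
the per-base total miscall rate, uniformly spread over the three alternates —
with the exact one-sided p-value P(K ≥ k), and require both p < α (default
0.05) and k ≥ 3. The three-read floor prevents single-error detections at
extreme depth.

The limit of detection is the smallest true fraction f on a 10⁻⁵ grid whose
detection probability reaches the requested power (default 0.95), with the
alternate count modelled as Binomial(n, f): error inflow into the alternate
(≈ e/3) and miscalls away from it are both neglected, so the error rate
enters only through the critical count. This approximation keeps the LOD
slightly conservative and makes it monotone — non-increasing in depth,
non-decreasing in error rate. (Modelling the inflow explicitly makes a tiny
error rate *lower* the LOD while the critical count is pinned at the floor,
which is real under the rule but a misleading property for a detection-limit
summary.) At 30 000× and e = 10⁻⁴ the LOD is 2.6 × 10⁻⁴, consistent with
reliable qualitative detection at 10⁻³.

## Synthetic data generator

The generator encodes the study's data-generating assumptions; its defaults
are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `mean_depth` | 40 000 | Poisson mean of per-position depth |
| `base_error_rate` | 10⁻⁴ | per-base total miscall rate, uniform spectrum |
| `background_scale` | 2 × 10⁻⁴ | mean of the exponential per-position true somatic frequency |
| `background_cap` | 0.05 | ceiling on background clone size |
| `gene_elevation` | NPM1 × 10 | NPM1-like elevated mutability |
| `shared_weight` | 0.9 | fraction of the cfDNA truth drawn from the WBC background |
| `germline_het_density` | 10⁻³ | fraction of positions at 0.5 allele fraction in both materials |
| `overdispersion` | 0 | beta-binomial ρ; > 0 emulates PCR jackpot noise |
| `n_pairs` | 20 | cohort size for the correlation experiments |

Per position, the WBC truth is Exponential(scale × gene multiplier) capped at
0.05 — heavy mass near zero with rare larger clones, the qualitative shape of
somatic backgrounds in normal tissue; no distributional form is prescribed by
the source, so exponential is a package choice. The cfDNA truth is
`shared_weight · WBC + (1 − shared_weight) · independent draw`, an
operationalization of "most cfDNA derives from blood cells" as a per-position
mixture weight. Observed counts are (beta-)binomial at the drawn depth, with
three independent Binomial(depth, e/3) error streams added to the non-reference
bases. Technical replicates are two independent count draws from one truth
table; tumour trios plant truncal and private variants at designed hotspots
(plus WBC-elevated background hotspots so subtraction has real work);
spike-in series draw the nominal fraction at the design depth.

Every generator is a pure function of (config, seed) via
`numpy.random.SeedSequence` tuples, so equal seeds give identical output.
Truth consistency is verified at the pileup level — estimated MAF within 3
binomial standard errors of the truth for ≥ 99 % of positions at 40 000× —
rather than by reconstructing each read's RNG trace.

Count-level simulation (straight to per-position profiles) is the default:
the per-position allele counts are a sufficient statistic for everything
downstream of the read filters, and emitting the ~5.5 million reads a full
40 000× cohort sample implies would add nothing but time. Read-level
simulation (`simulate_reads`, fixed-length 160 bp single-end with normal
Phred qualities) exists to exercise the read filters, SAM I/O and pileup
construction at small scale.

What the generator does **not** emulate: fragment-size distributions, PCR
duplicate families, UMIs, strand bias, amplicon-level depth heterogeneity
(depth is Poisson per position), and genome-scale reference realism. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every artefact of real libraries; the
overdispersion knob exists to probe super-binomial scatter but is not
calibrated to any real dataset.

## Problem sizes

The correlation experiments use 20 WBC/cfDNA pairs over the full 22 027-bp
panel at 40 000×; the spike-in design is 6 variants × 4 levels
(0.0005/0.001/0.005/0.01) × 5 replicates at 30 000×; type-I behaviour is
estimated on 1 000 error-only columns; trio logic uses 6 truncal + 2 × 5
private variants at 100 000× with zero sequencing error so the designed call
sets are recovered exactly. These sizes make the full suite and the
acceptance script each run in well under a minute of simulation time while
leaving every estimate far from its decision boundary.

## Known limitations

* SNV-only: the 5 % per-read filter does not count indels or clips as
  mutant; sites with indel evidence are invisible.
* The WBC subtraction threshold and the detection rule are package choices
  where the protocol is qualitative; both are configurable and documented
  above.
* Cohort-scale headline numbers from the real study (adjusted R² on 309
  pairs, the 0.12 % NPM1 mean) depend on the real sequencing data and are
  emulated only in regime (high shared-background concordance, NPM1 ranked
  first), not in value.
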