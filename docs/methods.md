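# Methods

This note documents the models and procedures implemented in `mitopool`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Coordinate and annotation conventions

All genome coordinates are 1-based inclusive, so an interval 9,631–9,663
has length 33 bp. The mitogenome is circular; origin-spanning features are
represented as two sub-intervals sharing a name, ordered by a `part`
index, and codon reconstruction concatenates the parts in coding order.
Positions covered by no feature are labelled `intergenic`; overlapping
features resolve by type precedence (CDS > rRNA > tRNA > control), then
lexicographic name.

## Variant-effect annotation

Effects are computed directly from the genetic code rather than through
an external annotator: the codon containing a substitution is rebuilt in
reading frame (reverse-complemented for minus-strand genes), translated
before and after under the feature's translation table (vertebrate
mitochondrial, table 2, by default), and classified as synonymous,
missense, stop_gained, stop_lost or start_lost; a start codon mutating
into another valid mitochondrial start (e.g. ATG→ATA) is synonymous, not
start_lost. A position inside several CDS features gets one call per
feature and reports the most severe (stop_gained > stop_lost >
start_lost > missense > synonymous). CDS with incomplete terminal codons
are accepted; positions in the trailing partial codon annotate as
noncoding with a logged warning.

Loss-of-function (LOF) is defined as {stop_gained, stop_lost,
start_lost}. Splice-variant labels cannot arise on an intron-less
mitogenome; they are accepted (and counted as LOF) if present in imported
tables but are never produced.

## Grantham distance and deleteriousness

The Grantham distance combines composition, polarity and molecular
volume:

D(i,j) = ρ·[α(c_i−c_j)² + β(p_i−p_j)² + γ(v_i−v_j)²]^½,
α = 1.833, β = 0.1018, γ = 0.000399.

ρ is computed exactly so the mean over the 190 unordered pairs is 100
(ρ ≈ 50.790), and the integer matrix is the formula rounded to the
nearest unit. Making the formula the single source of truth keeps matrix
and formula consistent on every pair and reproduces the canonical extreme
values (Leu–Ile = 5, Cys–Trp = 215); a handful of entries of the
historically printed table differ by ±1 from its own formula due to
intermediate rounding, and this implementation resolves those in favour
of the formula. A missense change is deleterious when its score strictly
exceeds the threshold (default 150). Stop changes are routed to LOF and
are not Grantham-scored.

## Heteroplasmy calling and filtering

At each site the most frequent non-reference allele is the candidate
minor allele. If it exceeds 50% of reads the site is a consensus
difference: the minor allele is re-derived from the remaining bases
(possibly the reference itself) and fixed differences (minor count zero)
are dropped, so MAF is always in (0, 0.5]. The p-value is the one-sided
exact binomial tail P(X ≥ alt_count | depth, e) under a sequencing-error
null with configurable rate e (default 0.1%, matching the MAF floor).
The caller's p-value model is a deliberate, reproducible replacement for
caller-specific heuristics of pileup-consensus tools.

The filter keeps sites with allele base quality > 20, mapping quality
> 30, MAF > 0.1%, p < 0.05, and depth strictly greater than the median
depth over the sample's candidate sites (even counts: mean of the central
pair). All inequalities are strict. "Median depth" is evaluated on the
pre-filter candidate set and can be frozen and passed back in, which
makes re-filtering idempotent. Base quality is judged per allele by
default — the minor allele's supporting reads — with a `site` mode using
the site mean; per-allele quality is what lets this filter reject
miscall-driven false positives, whose supporting reads have low quality.
NUMT masking is applied to candidates *before* the median-depth filter so
that masked intervals cannot skew the median.

Multi-allelic positions report only the most frequent minor allele (one
row per site); indels are out of scope.

## NUMT screening

Nuclear copies of mtDNA are found with an exact-seed (default 20-mer),
ungapped-extension matcher run on both strands: extension continues while
running identity stays ≥ `min_identity` (default 0.9), stops at two
consecutive mismatches, and is trimmed back to the last matching base, so
an exactly planted copy with non-homologous flanks is recovered at
exactly its planted length. Same-diagonal overlapping hits are merged,
contained hits dropped, and hits shorter than `min_length` (default
25 bp) discarded. Minus-strand hits report the nuclear interval in
reversed order (nuc_start > nuc_end). E-value machinery of full aligners
is intentionally not reproduced; the length/identity cutoffs approximate
the short-hit regime this screen targets. Masking is at site level: any
HP site inside a hit's mitogenome interval is excluded.

## Summary statistics

- **Copy number** C = ploidy × mt_depth / chromosomal mean depth (24
  chromosomes); scale-invariant in the depths.
- **HP burden** per mitogenome is Σ MAF — the expected number of
  heteroplasmic substitutions carried by one mtDNA copy — and per cell is
  Σ MAF × C. This Σ-MAF definition is this package's convention for the
  per-mitogenome rate.
- **Spectrum**: Ts/Tv counts and percentages over all HP sites, plus the
  Tv/Ts ratio (NaN marker when no transitions exist).
- **dN/dS** is the ratio of summed MAFs at nonsynonymous vs synonymous
  coding sites. The default is the raw frequency-sum ratio; with
  `normalize_sites=True` the sums are divided by Nei–Gojobori potential
  site counts computed from the reference CDS. Note that the raw ratio on
  *randomly placed* variants reflects mutational opportunity (≈3 on a
  typical mitogenome since most coding changes are nonsynonymous), not
  selection; large observed ratios therefore indicate frequency mass
  concentrated on nonsynonymous sites.
- **Genetic load ratio** = (LOF + deleterious missense) / all HP sites
  (noncoding sites stay in the denominator). LOF sites contribute to both
  dN and the load count.
- **Paired comparison**: every pool metric is compared across females
  with a paired t-test on per-female differences (df = k−1, two-sided p,
  |t| reported). Shapiro–Wilk on the differences is reported alongside
  but never gates the t-test. All-zero differences give the defined null
  limit t = 0, p = 1; constant nonzero differences are degenerate (no
  finite t) and error out.

## Synthetic pools: what is emulated

`PoolProfile.egg()` and `PoolProfile.hatchling()` encode the study
conditions the package models:

| parameter | egg | hatchling |
|---|---|---|
| pool composition | 500 haploid cells | 100 diploid-soma individuals |
| planted HP sites | 170 | 65 |
| mtDNA depth (mean, CV 5%) | 7,800× | 2,500× |
| transversion fraction | 0.9523 | 0.1462 |
| MAF distribution (log-uniform) | [0.21%, 1.3%] | [0.21%, 37.18%] |
| background miscall rate | 0.1% | 0.1% |

The hatchling depth sits centrally in the 853–4,565× range these pools
are sequenced at; the hatchling transversion fraction is the complement
of the 85.38% transition share (the printed egg shares sum to 100%, so
they are used directly). The MAF family is log-uniform because pooled
mtDNA spectra are strongly skewed toward rare variants and only ranges
and means are available for the real pools; the family and bounds are
configurable, and `loguniform_high_for_mean` pins the distribution mean
to a target (used when recovering target mean MAFs). Pool structure is
modelled implicitly through the site-level MAF distribution, not by
mixing per-individual genomes.

Observed minor-allele counts are binomial(depth, MAF) at per-site depths
drawn as round(normal(mean, 5% CV)). Background miscalls arrive at every
position at the total `error_rate` split evenly over the three
non-reference alleles; at a planted site the heteroplasmic allele
receives no additional miscall reads (miscalls toward it are considered
absorbed in the drawn MAF), keeping the observed MAF an unbiased binomial
draw of the truth. Miscall reads carry low base quality (mean 16) and
true reads high quality (mean 37), which is what the base-quality filter
acts on. An `exact` sampling mode replaces the binomial draw with
rounding for noiseless round-trip checks, and `fixed_spectrum_fixture`
plants sites by effect class with exact MAFs at a depth (default 10⁶)
where count rounding is below 10⁻⁶ — the deterministic twin of the
stochastic generator used for exact ratio checks.

What the generator does **not** emulate: read-level artifacts (strand
bias, position-in-read effects, mapping ambiguity), error-motif
structure, per-individual mixing within a pool, and selection — under
random placement, effect classes follow mutational opportunity.
Consequently, passing recovery tests demonstrates that the pipeline's
estimators are calibrated for spectrum and frequency parameters under a
realistic noise model, not that real-data artifacts are handled.

Coverage summaries are simulated as 24 per-chromosome depths
(normal, CV 2%, truncated positive) plus an mtDNA depth equal to
copies × chromosomal depth / ploidy with the same relative noise, so the
copy-number estimator recovers the planted truth within a few multiples
of the noise CV.

## Numerical choices and degenerate inputs

- Exact binomial tails via `scipy.stats.binom.sf`; no normal
  approximation anywhere in the filter.
- Undefined ratios (no transitions, zero dS, empty site lists) are NaN
  markers, never exceptions; degenerate paired tests raise.
- Median with an even candidate count is the mean of the central pair
  (the numpy convention).
- Ties between overlapping feature calls break by the fixed severity
  order, then first feature; region ties by type precedence then name.
- Zero-depth pileup rows are skipped with a log entry; zero-variance
  Shapiro–Wilk inputs report NaN.
- All simulation randomness flows through `numpy.random.default_rng`
  seeds; a study run derives per-sample seeds from one master seed, so a
  (config, seed) pair reproduces every output byte for byte.

## Problem sizes

The reference used throughout tests and the acceptance script is a
16,615 bp synthetic mitogenome with 13 protein genes (ND6 on the minus
strand), one rRNA, two tRNAs and a control region. Recovery studies use
20 replicates of 200 planted sites per profile; fixture checks use 1,000
annotated sites; the end-to-end determinism check runs the full
six-female study (12 pools) twice. These sizes make every estimator's
Monte-Carlo error small relative to its acceptance band while keeping a
full suite run in seconds.

## Known limitations

- Effect annotation assumes SNVs only; indels and multi-nucleotide
  substitutions are out of scope.
- The NUMT matcher is ungapped and seed-limited: diverged or gapped
  nuclear copies, or copies shorter than the seed, are not found — by
  design, this is a screen, not a genome-wide NUMT annotator.
- The frequency-weighted dN/dS is not a codon-model estimate and is not
  comparable across genomes with different codon composition unless
  site-normalized.
- Base/mapping qualities are summarized per allele as means; no
  read-level quality modelling.
- The per-mitogenome burden (Σ MAF) is one of several possible
  definitions of "HP sites per mitogenome"; comparisons with externally
  derived per-cell counts depend on that convention and on the copy
  number estimate.
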