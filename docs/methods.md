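# Methods

This note records the models behind each `xomap` module, the defaults that
matter, and the choices made where the design was genuinely open.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Meiosis and the synthetic-data generator (`synthdata`)

The generator defines the study conditions under which every downstream
stage is validated.  Defaults mirror the stickleback nuclear-family design:
21 chromosomes of 22 Mb (≈ 462 Mb genome), 93 offspring per family, and
sex-specific genome-wide crossover means of 19.06 (maternal) and 10.81
(paternal) per gamete.  Tests and the CLI fixture scale the genome and
family sizes down (typically 2–3 chromosomes of 2–5 Mb, 12–40 offspring) so
the full pipeline runs in seconds; the statistical structure is unchanged.

**Chiasma placement.**  Per bivalent, chiasma positions follow a stationary
gamma renewal process (shape ν, unit mean spacing) on a map-scaled axis of
length 2 μ, where μ is the target per-gamete mean for that chromosome
(proportional to physical length).  Each chiasma involves the transmitted
chromatid with probability ½, giving gamete crossovers with mean μ and
gamma-flavoured interference; ν = 1 recovers independent (Poisson)
placement.  Defaults ν_F = 3, ν_M = 6 encode interference that is present
in both sexes and stronger in males; the data motivating this give no
parametric model, and gamma renewal is the standard stationary choice.
An *obligate-chiasma* mode places exactly one chiasma per bivalent between
one of the four non-sister chromatid pairs (uniform) and samples one of the
four chromatids: half of gamete chromosomes are then recombinant (0.5
crossovers/chromosome; 10.5 of 21 chromosomes), the minimum-recombination
configuration that `scripts/acceptance.py` recomputes.

**Periphery bias.**  Positions are drawn through the inverse CDF of a
mixture of a genome-uniform density and a uniform density on the two
terminal 15% segments, parameterised directly by the target terminal mass
(defaults 0.70 male, 0.47 female), so the target fractions are inputs, not
emergent.  A target of 0.30 reduces to the uniform density.

**Noise processes.**  Genotyping error flips a genotype with probability ε
(default 0.002).  Gene-conversion-like blips flip the haplotype label over
50 bp–2 kb tracts at 0.2 per gamete-chromosome; these tracts are chosen to
always fail the caller's 50-kb/50-SNP support rule — they exist to test the
filter, not to model conversion biology.  Read depths are Poisson around a
per-offspring coverage drawn from N(10, 3²) (parents 40×), with allele
depths binomial given the genotype.  Optional injections with truth labels:
transmission-distorted sites (family allele frequency pushed to ≈ 0.9) and
systematically erroneous sites, used by the filter tests.

**Inversions.**  An inversion polymorphism is modelled as a region whose
sample orientation is reversed relative to the reference: the transmitted
label sequence is order-reversed inside the region.  A single true
crossover at x inside an inversion (a, b) then appears in reference
coordinates as three switches — at a, at a + b − x, and at b — the triplet
signature the caller corrects.

**Ecotype divergence and suppression.**  Adaptive loci carry extra
divergent SNPs (marine allele = 1) at elevated density (default 5/kb).
Hybrid parents are heterozygous across these loci, and proposed chiasmata
inside them are accepted with probability exp(−k·h), h the heterozygous-SNP
density per kb; k defaults to 0.0713 so the default divergent density
yields ≈ 30% suppression (the motivating observation is qualitative).

**Cohort.**  Each fish carries two 5-locus haplotypes built by a Markov
chain with per-interval switch probability `recombinant_fraction`.  Body
size = date baseline − penalty × (min-crossover score) + N(0, σ²); default
penalty 0.5 mm per event.  Juveniles are survival-thinned with probability
`viability_per_event`^score (default 0.8), which both lowers the juvenile
mean score and increases adjacent-locus LD — the directional predictions
the hybrid-zone tests check.

What the generator does **not** emulate: read alignment and reference bias,
linkage-disequilibrium structure among background SNPs, segregation
distortion of biological origin, overlapping generations in the cohort.
Passing tests therefore validate the algorithms under the stated sampling
models, not the upstream bioinformatics of real sequencing data.

## Phasing (`famphase`)

Informative SNPs are heterozygous in exactly one parent and pass: family
allele frequency within δ = 0.06 of {0.25, 0.5, 0.75} (a tolerance-band
stand-in for model-based clustering of the Mendelian segregation classes);
site mean depth within ±50% of the family mean; parental het read balance
deviating < 30% from one half.  With few offspring the terminal block of a
chromosome can fail the frequency band as a unit (all its sites share one
binomial transmission draw); this disappears at realistic family sizes.

Transmitted alleles come from Mendelian subtraction of the homozygous
parent's contribution; inconsistent genotypes become missing.  Phasing is a
greedy chain: each SNP is oriented to maximise agreement with the
per-offspring majority label over the previous W = 20 phased SNPs (large
enough to bridge isolated errors, small relative to inter-crossover
distances); ties fall back to minimising implied switches against the
previous SNP.  Labels are defined up to a global per-chromosome flip, and
all downstream calls are invariant to that flip (tested).

A second pass removes problem SNPs and rephases: (a) SNPs whose label
disagrees with both flanking neighbours in ≥ 20 offspring — a double-flank
proxy for a per-SNP genotyping-error probability, which detects the same
isolated-flip signature as an HMM posterior without one; (b) SNPs phased to
one haplotype in > 75% of offspring (transmission-distortion proxy).

## Crossover calling (`xocall`)

A switch is a crossover iff the maximal same-label run on each side spans
> 50 kb **and** contains ≥ 50 SNPs (both quantities are required); shorter
flips are absorbed into their flanks, never called.  At chromosome termini
the span requirement is waived for the truncated flank if it still has
≥ 50 SNPs.  The crossover interval is (last SNP of the first run, first SNP
of the second].  Post-filters, in fixed order, each audited:

1. *Family-recurrent*: identical boundary SNPs in ≥ 50% of offspring
   (parental phasing error) — removed in all carriers.
2. *Quality*: all events of offspring with < 2× coverage; events with
   resolution > 1 Mb unless the interval contains **zero** retained
   informative SNPs (then kept, flagged `low_res`; "zero" rather than
   "sparse" is the strict reading of the exemption).
3. *Inversion triplets*: three consecutive events with first-to-third
   midpoint span < 2 Mb, recurring at the same location (boundaries within
   10 kb) in ≥ 2 offspring, mark an inverted region; the outer two events
   are removed and the middle one is reflected
   (new = inv_start + inv_end − old, bounds reordered).

On noise-free synthetic data every called interval contains its true
breakpoint, and recall is 100% for true crossovers whose flanks meet the
support thresholds on retained informative SNPs (tested).

## Map statistics (`mapstats`)

Crossover location is always the interval midpoint.  Map length in
cM = 100 × mean crossovers per gamete; the sex-averaged length uses all
meiotic products jointly; the minimum-chiasmata estimate doubles the
per-gamete mean.  The interference null re-places each gamete-chromosome's
observed number of crossovers independently from the pooled marginal
midpoint distribution — conditioning on counts isolates positional
interference from count overdispersion; significance is the empirical tail
probability of the KS statistic over seeded replicates.  The Gini
coefficient uses the sorted-counts Lorenz form, identical to the
mean-absolute-difference formula (dual-formula tested).  Sliding windows
default to step = window/2; the window tables used for modelling tile with
step = window.

## Hotspots and coldspots (`spotscan`)

Pooled hotspots use genome-tiling 5-kb windows; the null relocates
midpoints uniformly within chromosomes; FDR(k) = mean null windows with
≥ k / observed windows with ≥ k, and the hotspot threshold is the smallest
k with FDR < 0.05 (windowing for the pooled scan is tiling because the
fine-scale scan, below, is midpoint-anchored).  Ecotype-divergent windows:
down-sampled equal-size ecotype sets (events with intervals > 10 kb
excluded), counts within 2.5 kb of every pooled midpoint, pairwise
log2((a+0.1)/(b+0.1)), compared against 2.5%/97.5% envelopes of
random-split fold changes conditional on mean count (quantile bins with
≥ 10 null windows), and additionally ≥ 6 crossovers among the compared
fish.  Coldspots are maximal zero-crossover runs of length ≥ 5/λ with λ the
pool's uniform intensity; the intensity basis is per pool (ecotype × sex by
default) and configurable.  Feature association and peak proximity use
within-chromosome uniform shuffles preserving per-chromosome counts, with
empirical p = (1 + #null ≥ obs)/(1 + n).

## Window models and dominance (`winmodel`)

Per-individual window rates (cM; one individual = one parent of one
family) are modelled by OLS over the marginality-respecting candidate set
{1, sex, ecotype, sex+ecotype, sex×ecotype}, selected by AIC — the set a
backward elimination from the full two-factor model can reach, computed by
all-subsets so the per-window fits vectorise across thousands of windows
and permutations.  Significance is a pooled plug-in FDR: crossover
midpoints are relocated uniformly within chromosomes (preserving
per-individual totals, so only *local* deviations beyond genome-wide
differences score), the overall F of each window's selected model is
compared with the pooled null F distribution, and
FDR(F) = E[null windows ≥ F] / #observed windows ≥ F.  A per-window
empirical-p variant was considered and rejected: pooled nulls stabilise
tail estimates at feasible permutation counts (default n_perm = 2000;
tests use 100).  Effect sizes are differences of group means in cM.
Dominance in ecotype-significant windows, at 5/50/500-kb scales:
raw deviation = hybrid − midparent; scaled ratio divides by half the
parental difference (0 additive, +1 high-parent dominant, −1 low-parent
dominant, |ratio| > 1 over/underdominant; undefined and flagged when the
parents are equal).

## Ancestry (`ancestry`)

Site ancestry is the marine read fraction with pseudocount α = 0.5 (a
binomial-posterior mean; α = 0 gives the raw fraction and skips
zero-coverage sites).  Panel alleles are defined at ≥ 0.8 within-ecotype
frequency (threshold in config; the source description is unquantified).
Per-locus diploid class from mean P(marine): ≥ 0.75 hom-marine, ≤ 0.25
hom-freshwater, else het — symmetric around the diploid expectations 1,
0.5, 0.  The admixture regression is rate ~ ancestry² + ancestry + sex with
an F-test on the squared term.  Rescaled locus profiles map each locus to
[0, 1] with one locus-width flanks (50 interior + 2 × 25 flank bins by
default), average the per-locus density with its orientation flip (making
profiles strand-invariant), and report mean ± s.e. over loci.

## Hybrid-zone fitness (`hzfit`)

The minimum-crossover score is computed by dynamic programming over the
(hap1, hap2) allele phase state along the ordered loci, with missing loci
as free wildcards (a conservative lower bound; a strict mode would drop
incomplete individuals — the DP equals brute-force enumeration over all
243 five-locus genotypes, maximum 8, tested).  Residual length centres
length on sampling-date means.  The score model is OLS of residual length
on score, with companion models adding each locus as main effect and
interaction.  Epistasis: two-locus genotype ANOVA with interaction F-tests
and post hoc Welch contrasts of mismatched vs matched genotype pairs,
reported raw (mirroring the original analysis) plus a BH-adjusted column.
Two-locus LD uses standard EM over double-heterozygote phase ambiguity
(tol 1e-8, ≤ 1000 iterations); all other genotype pairs phase uniquely.
Stage labels: fry = early sampling dates, juvenile = later, configurable.

## Forward simulation (`fwdsim`)

Three linked loci, 8 haplotypes, demes FW1–MAR–FW2 exchanging migrants at
m between neighbours; life cycle migration → multiplicative selection
(1, 1+hs, 1+s per locally favoured allele) → random union and gamete
production → multinomial sampling of 2N gametes.  The transmitting sex is
drawn per gamete, so heterochiasmy (r_F = 2r̄, r_M = 0) changes the
variance structure of recombination while the sex-averaged per-interval
recombination fraction equals r̄ exactly (tested).  Suppression: an
interval's r is multiplied by (1−σ) when the parent is heterozygous with
the interval's flanking divergent alleles in coupling (MMM/FFF-type
diplotype); σ defaults to 0.8.  Scenario bundles — 1: heterochiasmy +
suppression; 2: heterochiasmy only; 3: neither; 5: male recombination
suppressed (r_M = 0, r_F = r̄) — ship as documented defaults (N = 1000,
m = 0.01, s = 0.1, r̄ = 0.01) because the motivating claims are
directional, not numeric; every contrast is computed over replicates with
one-sided rank tests.  Tests run scaled-down bundles (N = 100–300, 40–150
generations, ≥ 200 replicate runs).  A `deterministic=True` path skips the
sampling step, giving the infinite-N recursion used as an independent
oracle for the stochastic engine.

## Numerical and engineering choices

* Coordinates: 1-based SNP positions internally (VCF convention);
  crossovers are (left, right] intervals; BED export is 0-based half-open;
  the round-trip is the identity (tested).
* Every stochastic routine takes a seed (numpy `default_rng`) and is
  bit-reproducible; the CLI passes `--seed` to each stage.
* Every filter logs removals by reason, and audits satisfy
  events_out + removed_by_reason = events_in.
* Degenerate inputs (empty pools, monomorphic loci, singleton dates,
  parents with equal rates, islands covering the genome) return flagged
  results or raise typed errors rather than NaNs.

## Known limitations

* The phaser assumes a single nuclear family; no population reference or
  imputation.
* The AF-cluster filter can drop terminal haplotype blocks wholesale in
  very small families (see above); crossover recall is defined conditional
  on retained-SNP support.
* The hotspot FDR is count-threshold based and therefore conservative at
  very low counts; the divergent-hotspot envelope needs enough shuffles
  (≥ 100) for stable 2.5% quantiles.
* The forward simulator is a 3-locus caricature: no genome-scale linkage,
  no inversion evolution, hermaphroditic mating with sex drawn per gamete.
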