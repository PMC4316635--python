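# Methods

This note documents the models and procedures implemented in `mutline`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Consensus mutation calling

The caller consumes per-line, per-site read counts split by strand
(quality and mapping filters are upstream of this format; the counts are
declared post-alignment).  Definitions, all with strict inequalities:

* **Overall consensus**: the base whose count pooled over all lines
  exceeds 50% of the pooled depth.
* **Line consensus**: the base exceeding 80% of one line's depth.
* **Mutation**: a line consensus differing from the overall consensus.
* **Analyzed site (per line)**: passes the paralog filter, has an overall
  consensus and a line consensus, and the line-consensus base is supported
  by ≥3 forward and ≥3 reverse reads.  Analyzed-site counts are the
  denominators of every rate.
* **Indel call**: an indel allele (< 28 bp) with ≥3 forward and ≥3 reverse
  supporting reads amounting to more than 30% of the line's total reads at
  the site.

The lenient overall-consensus threshold deliberately tolerates multihit
mutations (the same site mutated in several lines); calls shared by more
than half the lines are flagged as suspect ancestral variants but
retained.

**Paralog filter scope.** Reads from a paralogous locus co-mapping to one
site produce apparent heterozygosity in a haploid — a *within-sample*
signature.  The filter therefore drops a site when any line's within-line
minor-allele fraction exceeds 20% (`paralog_scope="line"`).  A pooled
variant (minor fraction of counts summed over lines) is available but is
not the default: with few lines, a genuine mutation in one line already
puts the pooled minor-allele fraction near 1/n_lines, and the pooled test
would discard real mutations while the per-line test retains them and
still catches cross-mapping (which affects every line at the locus).

**Sequencing error** is estimated from sites where every line's consensus
equals the overall consensus: for each consensus base X, the discordant
read fraction at X-sites; plus the pooled rate over the four bases.

**SSR classification** of indel loci uses a tandem-repeat scan: unit
length ≤ 6 bp with ≥ 3 contiguous copies, or a homopolymer run ≥ 4, whose
footprint covers the indel position.  No standard definition exists for
"simple sequence repeat motif" at this granularity; the thresholds are
exposed in `SSRConfig`.

## Rates and spectra

The pooled substitution rate is total count over total exposure,
u = m / Σ_lines(n_l T_l), with per-line rates also reported.  Under the
Poisson model the SE of one line's rate is √(u/(nT)); the pooled SE is the
mean of the per-line SEs divided by √N.  Rate × exposure = count exactly,
by construction.

The six-class conditional spectrum (AT→GC, GC→AT, AT→TA, AT→CG, GC→TA,
GC→CG; ordered-pair notation, each class covering a substitution and its
complement) divides class counts by source-class exposure — n(1−GC)·N·T
for A:T sources, n·GC·N·T for G:C — with exact (Garwood) Poisson CIs.
The Garwood construction was chosen because it is exact at the small
per-class counts that arise in region-restricted spectra.

**Odds-ratio logit test.**  For the GC→AT vs AT→GC asymmetry,
ln OR = ln((π₁/N_GC)/(π₂/N_AT)) is approximately normal with
SE = √(1/π₁ + 1/(N_GC−π₁) + 1/π₂ + 1/(N_AT−π₂)).  The reported one-sided
P defaults to Φ(−|lnOR|/SE) — the tail probability in the direction of the
observed deviation, the conventional way such asymmetries are quoted.
Note this "observed-direction" form is not a calibrated test: under the
null it rejects at twice the nominal level.  For calibration (and for any
pre-registered directional hypothesis) `alternative="less"/"greater"`
gives a proper one-sided test; the test-suite calibration check uses the
directional form and verifies type-I error ≤ 6% at nominal 5%.

**Expected N:S ratio.**  All 64 codons × 3 positions × 3 alternative bases
are enumerated; each change is weighted by codon frequency × the
conditional rate of its substitution class, and translated with the
bacterial code (table 11).  Changes creating or destroying a stop codon
count as nonsynonymous (stop→stop counts synonymous); substitutions in
annotated start codons are always nonsynonymous, since initiator codons
encode fMet regardless of identity.  The expected coding:intergenic ratio
under uniform rates is simply f/(1−f) for coding fraction f.

## Mutation topology

Bins of fixed size (50 kb default, 10 kb for the robustness check) are
tiled in an origin-anchored frame proceeding clockwise; bins never span a
scaffold boundary, and trailing partial segments are dropped rather than
rescaled.  Each bin's A:T-source and G:C-source mutation counts (U₁, U₂)
are combined into the GC-normalized rate U = (U₁/μ̄₁ + U₂/μ̄₂)·μ, where
μ̄₁, μ̄₂ are the genome-wide mean rates of the two source classes and μ
the genomic mean: each class count is converted to the number of sites
expected to have produced it, then scaled back to a rate.  U is invariant
to jointly rescaling (μ̄₁, μ̄₂, μ).

Smoothing uses the order-4 Daubechies wavelet, read as the 8-tap filter
with four vanishing moments (`db4`; the 4-tap `db2` is available for the
other reading of "fourth order").  Boundary handling is periodization —
the chromosome is circular, so the last bin abuts the first — making the
transform orthonormal (perfect reconstruction and energy conservation to
1e-10 at dyadic lengths; odd lengths incur a one-sample boundary
approximation).  The smooth curve is reconstructed from approximation
coefficients at level ⌊log₂(n)/2⌋ by default (configurable): a
low-frequency trend with enough resolution left to localize the
origin/terminus extremes.

## Trinucleotide context

A site's context is its focal base plus 5′/3′ neighbors on the **leading
strand** of its replichore.  The right replichore (origin→terminus
clockwise) reads the reference strand; the left replichore's leading
strand is the reverse complement of the terminus→origin arc, so contexts
there are complement-flipped — the only convention under which the two
replichores yield comparable 64-vectors.  Triplet exposures come from a
3-bp sliding window (1-bp step) over each leading strand; arcs are
treated as linear, so the handful of windows spanning the origin/terminus
junctions are skipped and reported.  Context rate = mutation count /
(triplet count × N lines × T generations); the headline matrix is the
arithmetic mean of the two replichore matrices (pooled-count rates are
also emitted).

Calls on potential methylation targets can be excluded first.  Default
motifs (REBASE consensus, IUPAC): Dam GATC, Dcm CCWGG, EcoKI AACN₆GTGC,
EcoBI TGAN₈TGCT, HgiDII GRCGYC, matched on both strands; the whole motif
footprint is excluded (configurable to the focal base only).  The
replichore comparison is a paired t-test on ln rates over the 64
contexts, dropping zero-rate pairs pairwise.

## Fluctuation tests

Mutant counts per culture follow the Luria–Delbrück distribution with the
Ma–Sandri–Sarkar recursion p₀ = e^(−m), p_k = (m/k)·Σ_{i<k} p_i/(k−i+1).
The distribution's tail is heavy (survival ≈ m/k), so counts above a cap
(2,000) are right-censored in the likelihood, contributing log P(K ≥ cap)
— jackpot cultures carry almost no information about m beyond "large",
and the O(k²) recursion would otherwise be prohibitive.  m̂ maximizes the
replicate log likelihood (coarse geometric grid, then bounded scalar
minimization; the search is capped at m = 700 where e^(−m) underflows
double precision).  The 95% CI is the profile-likelihood interval
(2ΔlnL = 3.84).  The rate conversion is μ̂ = m̂/N_final — mutations per
cell division under binary growth from a small inoculum — with
m̂/(N_final−N₀) available; partial plating is corrected by the standard
m·(f−1)/(f ln f) adjustment.  Rate ratios between assays are reported
with a CI from independent-interval combination.

## Synthetic-data generator

The generator's defaults are the study conditions of the emulated
experiment: 45 lines, 5,240 generations, genome GC 60.71%, substitution
rate 2.34 × 10⁻⁸ and indel rate 1.65 × 10⁻⁹ per site per generation,
ts:tv 39.14, GC→AT:AT→GC rate ratio 0.67, 91.53% coding, 5% prophage,
97.73% of indels in SSRs, 82.72× mean depth, 0.39% per-read error.
Values the study does not pin down were chosen once as field-realistic:
topology amplitude 0.5 (a ≈3× terminus:origin rate swing, matching
published mutator topologies), insertion bias 0.6, ~828-bp genes with
geometric gaps, ~20-kb prophage islands, 1% of the genome in planted SSR
tracts, default context multipliers proportional to the published
64-context matrix (normalized to mean 1).

Mutations are placed as end-state Poisson draws per line × site with rate
r_class(ref) × context multiplier × topology multiplier × T; the joint
multiplier field is normalized to mean 1 over the genome so the
configured mean rate is exact, and multiple hits at one site within a
line collapse to the last drawn state.  The class rates are solved from
(μ, R, ρ): transitions get u₁ per A:T site and u₂ = ρu₁ per G:C site with
(1−g)u₁ + gu₂ = μR/(1+R); each of the four transversion classes gets
v = μ/(2(1+R)).  Selection is not modeled (MA designs minimize it), and
per-line histories are exchangeable end states — the estimators never use
within-line timing.  The sequencing layer draws Poisson depth, Bernoulli
strands, and uniform miscalls at the per-read error rate; an optional
fraction of sites receives a paralog-like second allele at 20–50% of
reads in every line.  Indel reads displace reference reads at their site,
so indel-bearing sites can drop below substitution strand-support
thresholds — as in real pileups.

The fluctuation simulator uses synchronous binary fission with
deterministic mutant-lineage doubling; the MSS likelihood assumes the
Lea–Coulson model.  The mismatch is small at the scales used (verified
against the analytic p₁ within 0.01) and is noted in the tests.

What the generator does **not** emulate: realistic depth dispersion and
strand bias (Poisson/Bernoulli only), alignment and mapping artifacts
beyond the stylized paralog channel, assembly gaps, structural variants
≥ 28 bp, selection, and within-line mutation timing.  Passing recovery
tests therefore demonstrate correctness of the estimators under the
declared statistical model, not robustness to real-data mapping
pathologies.

## Problem sizes used in tests

The recovery checks run at reduced scale chosen to keep the suite quick
while preserving the statistical conditions they probe: caller recovery
on a 1-Mb genome × 5 lines at full depth; context recovery at ≥ 20,000
mutations on 1 Mb × 45 lines; topology recovery on a 4-Mb genome (80
bins of 50 kb); MSS recovery at 500 replicates; odds-ratio calibration
over 2,000 null simulations.

## Known limitations

* The caller consumes read summaries, not alignments; mapper-specific
  artifacts (two-mapper intersection, indel realignment) are upstream.
* Exact reproduction of the published χ² statistics for N:S and
  coding:intergenic comparisons requires the strain's codon-usage table
  and per-line analyzed-site counts, which are inputs, not package data.
* The MSS estimator assumes equal plating and no phenotypic lag or
  mutant-fitness differences.
* Triplets spanning replichore junctions are skipped (negligible edge
  effect, reported in output).
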