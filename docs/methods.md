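# Methods

`archaeome` implements a desk-scale version of the analytical workflow used
to characterize microbiomes recovered from ancient human skeletal remains
and to decide which taxa are genuinely ancient (part of the buried
individual's microbiome) versus modern environmental contamination. All
analyses are driven by a synthetic-data generator with known ground truth,
so every stage is testable without archaeological sequencing data.

## The damage model

Post-mortem DNA decays into short fragments with single-stranded overhangs
at the ends. Cytosines deaminate to uracil — read as thymine — much faster
in single-stranded than double-stranded state, so ancient reads show an
excess of C→T substitutions at their 5′ ends. Sequencing libraries are
blunt-end repaired: 3′ overhangs are removed and 5′ overhangs of the
complementary strand are filled in, which fixes the complementary signal as
G→A at the read's 3′ end.

The generator and the estimator share one parameterization:

* overhang lengths are geometric with per-base termination probability λ,
  so P(L ≥ x) = (1 − λ)^x and the mean overhang length is 1/λ − 1;
* a cytosine inside a single-stranded overhang deaminates with probability
  δ_s, one in the double-stranded interior with probability δ_d;
* every base is additionally substituted with probability ε (sequencing
  error), uniformly to one of the other three bases.

The expected C→T frequency at 5′ position x (1-based) is

    f(x) = δ_s (1 − λ)^x + δ_d (1 − (1 − λ)^x),

mirrored for 3′ G→A, plus the error floor ε/3 applied to the undamaged
remainder. In the generator, 5′-overhang bases carry only the C→T channel
and 3′-terminal bases only the G→A channel (the opposite channel has no
complementary strand to deaminate), while interior bases carry both at δ_d.
A nick parameter is not modeled.

Default simulation conditions for the synthetic studies: δ_s = 0.30,
δ_d = 0.01, λ = 0.40 (mean overhang 1.5) and ε = 0.001 for ancient
sources; modern sources carry ε only. These are typical magnitudes for
well-preserved ancient DNA and sit near the host values the workflow is
designed to compare against. Reads are single-end 75 bp; fragment lengths
are truncated normal (mean 60, sd 15, minimum 25) — the short-fragment
regime of degraded DNA; the exact insert distribution is a free choice of
the generator and is exposed in `SimConfig`. Emitted FASTQ qualities are
constant Q37 (configurable): quality content is irrelevant after
filtering, which these synthetic reads always pass.

## Estimation

`damage.tally_misincorporations` counts, per read position from each end,
reference-C opportunities and observed C→T (5′), and reference-G
opportunities and observed G→A (3′), re-orienting minus-strand alignments
into read coordinates first. The window is K = 25 positions (configurable):
with 75 bp reads and mean overhang ≈ 1.5, essentially the whole terminal
signal lies in the first ~10 positions, and the remaining window pins down
δ_d.

Two numerical choices matter:

* **ε is fixed, not co-estimated.** Transversions carry no deamination
  signal, so the pooled transversion rate gives a plug-in estimate of the
  per-type error floor (ε/3 per specific substitution). Co-estimating ε
  with δ_d is badly confounded at these depths.
* **Reads at the cycle limit are excluded from the 3′ tally.** A read of
  exactly the sequencer's cycle count (75 bp) may come from a fragment
  longer than the read, so its 3′ terminus need not be a fragment end;
  including such reads dilutes the 3′ G→A amplitude by the fraction of
  long fragments. The `cycles` argument implements this exclusion; the 5′
  tally is never affected.

`damage.fit_damage_model` maximizes the product of per-position binomial
likelihoods Binom(k | n, f(x)) over both ends. Optimization is a coarse
grid scan (δ_s, δ_d ∈ {0, 0.05, …, 0.5}; λ ∈ {0.05, …, 0.95}) followed by
L-BFGS-B refinement from the best three grid points; the refined
likelihood never falls below the grid optimum (asserted in tests). The
upper bound of λ is 0.95, not 1: as λ → 1 the overhang term vanishes and
δ_s drifts along an unidentifiable ridge, so undamaged data would report
an arbitrary δ_s; the cap pins δ_s to the observed terminal excess (an
undamaged library then fits δ_s near the error floor, which is the
behavior the group comparisons rely on). Degenerate profiles with no
substitutions at all return δ_s = δ_d = 0 with λ flagged unidentifiable;
profiles with fewer than 500 C or G opportunities (configurable) return an
"insufficient data" result instead of an estimate.

Uncertainty comes from a percentile bootstrap that resamples *reads* (the
exchangeable unit — overhang lengths correlate positions within a read)
using per-read opportunity matrices collected at tally time; when only
aggregated counts are available, a position-wise binomial resample is used
instead. ε is held at its full-data value across replicates. A random-walk
Metropolis sampler over the same likelihood is provided as an alternative
posterior summary; the pipeline consumes the MLE.

## Authentication logic

For each sample, reads are mapped independently against taxon-group genome
subsets — all representative genomes, environmental, all human-related,
oral, gut, pathogen — and against the host genome; a read may contribute
to every group it maps to. Per group, Δ statistics are computed as
**host − group** for δ_s, δ_d and 1/λ − 1, so a modern (undamaged) group
yields a large positive Δδ_s while genuinely ancient groups sit near zero.
Samples are binned by their environmental-genus abundance fraction
(0–25 / 25–50 / 50–75 / 75–100 %, left-closed except the last bin): in
cohorts where human-related taxa are ancient, the pooled microbial damage
decreases across bins while host damage stays flat. The single-class
control restricts both groups to one taxonomy class that contains
environmental and human-related members; the ordering must survive, which
rules out taxon-durability artifacts. Representative species are those
reaching ≥ 10 % relative abundance in at least one sample.

## Profiling and classification

The profiler is a deliberately simplified clade-specific-marker method:
reads are assigned by unique-best ungapped mapping against marker
sequences; reads tying across species are discarded, coordinate duplicates
(reference, start, strand, length) are collapsed. Species abundance is
length-normalized marker coverage, robust-averaged per species (top and
bottom coverage deciles trimmed when a species has ≥ 10 markers, plain
mean otherwise — small marker sets must not trim to nothing), normalized
across species, and aggregated to genus/family/class by summation, so rank
additivity is exact by construction. Viruses and eukaryotes participate in
overall profiles and the kingdom breakdown; habitat classification and
damage grouping use the profile renormalized over bacteria + archaea.

Genus habitat classification is conservative: one observed environmental
species makes the genus environmental; otherwise the human-related
subgroup is unanimous, else the majority of observed species, remaining
ties going to the unspecific "gut/other" subgroup. Classification uses
only species observed in the dataset, so the same genus can be classified
differently across datasets — intended behavior, not a bug. Trait
summaries (gram stain, respiratory type) are abundance-weighted population
shares by default; an unweighted per-taxon mode exists behind a flag.

## Mapping

The internal mapper is exact-seed (16-mer, sparse offsets on both strands)
plus ungapped full-length extension with ≤ 5 mismatches, reporting a read
only at its unique best placement; any tie leaves the read unmapped
(counted in QC). Synthetic reads contain no indels, so ungapped extension
is exact; for real data, SAM from a production aligner can be imported
(`preprocess.read_sam_alignments`, single-M CIGAR records). Coordinates
are 0-based half-open; mismatch positions are 1-based from the read's 5′
end. Duplicate removal is coordinate-only (damaged duplicates differ in
sequence but share provenance). Quality trimming is 3′-only with Q30 /
25 bp thresholds by default.

## What the generator does and does not emulate

Emulated: mixed communities of host + environmental/oral/gut/pathogen
taxa, multinomial read counts, geometric-overhang terminal deamination,
uniform sequencing error, fragment-length variation, strandedness, PCR
duplicates only implicitly (coordinate collisions). Not emulated: indels,
GC bias and other compositional bias, per-cycle error profiles, adapters,
paired ends, real marker databases, conserved regions shared across
genomes (synthetic genomes are i.i.d. uniform, so cross-mapping is rarer
than in real data). Passing tests therefore demonstrate the correctness
and statistical behavior of the algorithms under the stated model, not
performance on real archaeological libraries.

## Problem sizes

The synthetic studies use 5×10⁴ reads per damage-recovery fit (10 seeds),
ten 20-sample authentication cohorts at 3×10³ reads per sample, 10⁵ reads
for the six-taxon mixture, and 6×10⁴-read deep samples for the
shallow-vs-deep comparison — sizes at which the estimators' sampling error
is comfortably inside the tolerances being checked while a full run stays
in the minutes range on one CPU.

## Known limitations

* The mapper is for short, indel-free reads against small reference sets;
  it is not a general-purpose aligner.
* δ_s and λ trade off when the terminal signal is weak (few reads or
  δ_s ≈ δ_d); the bootstrap intervals widen accordingly, and the λ cap
  makes the modern-data limit well-defined rather than estimating a true
  "no overhang" state.
* Abundance estimation assumes markers are unique to their species; the
  generator guarantees this, real marker databases only approximate it.
* The ecology module's hypothesis tests are thin adapters over
  scipy/statsmodels and inherit their assumptions.
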