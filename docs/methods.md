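# Methods

This note documents the models and procedures `selkie` implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
spelled out.

## Coverage model, sex inference, and PAR detection

Read depth is modelled per base. Autosomes and the pseudoautosomal region
(PAR) carry two copies and are simulated at the full mean depth; the male
non-PAR X carries one copy and is simulated at half depth. The default noise
model is Poisson; `depth_dispersion > 1` switches to a negative binomial
parameterised so that variance = dispersion × mean. Real libraries are
over-dispersed by GC bias, mappability and duplication; dispersion is a free
knob (default 1.0), not an inference target, because the windowed-median
statistics downstream are insensitive to moderate over-dispersion.

**Windowed medians.** Depth is summarized as the median over 10 kbp
stacking (non-overlapping) windows. The terminal window of each chromosome
may be shorter and is flagged partial, but it participates in all
computations with its actual median: PARs are terminal structures, and
dropping edge windows would bias exactly the boundary being estimated.

**Whole-genome level.** The normalization denominator is the median of
autosomal window medians. Using the median (not the mean) makes the level
robust to high-copy outliers; excluding the X by default keeps a male's
half-depth X from depressing it. Both choices are exposed
(`autosomes_only`).

**Sex inference.** The ratio of the median non-PAR X window depth to the
genome level is ≈ 0.5 in males and ≈ 1.0 in females; the decision threshold
defaults to 0.75, the midpoint. When a PAR call is supplied its windows are
excluded from the X median — on a real mammalian X the PAR is a few percent
of the chromosome and exclusion barely matters, but it makes the ratio
well-defined even when the PAR is a large fraction of the X, so the
recommended order is `detect_par` first, then `infer_sex(par=...)`.

**PAR detection (two passes).** Pass 1 marks windows with median ≥
threshold × level (default 0.70) and merges adjacent marked windows into
segments. Pass 2 merges consecutive segments whenever the pooled per-base
median across the intervening gap reaches the same cutoff, iterating to a
fixed point; the result is independent of the direction in which gaps are
examined (property-tested). The PAR is the segment abutting an X terminus
with length ≥ `min_par` (default 100 kbp, to suppress single-window noise
segments); when both termini qualify the longer segment wins. A profile
whose single segment spans the whole X (a female-like diploid X) reports the
PAR as absent with the flag "diploid X, PAR not resolvable" rather than
calling the entire chromosome a PAR.

A mathematical remark on pass 2: if every window in a gap is unmarked
(median below the cutoff) and all windows have equal size, the pooled median
over the gap is provably also below the cutoff — the pooled median is
bounded by (max of lower middles + min of upper middles)/2, and each
window's own median already fails. Pass 2 therefore only changes the result
when segments are not aligned to window boundaries (e.g. segments supplied
from another caller, or a partial terminal window inside a gap). It is kept,
and unit-tested at the mechanism level, because the procedure is specified
as part of the boundary-refinement contract and is cheap.

## Variant filtering and heterozygosity

A record is removed iff `QUAL < 20.0 OR SP > 60.0 OR DP < 5.0 OR GQ < 20.0`,
with every comparison strict, exactly as the expression is written — a
record at any threshold value survives. Survivors are then kept iff sample
depth lies inside the closed band [30%, 250%] of the mean genome coverage.
"Coverage" for the band is the sample's FORMAT/DP. The removal tally
attributes each record to the first failing rule in written order (QUAL, SP,
DP, GQ, band), which makes the accounting stable and explainable; records
missing a required FORMAT field are counted as errors and skipped without
aborting the run. Filtering is idempotent (property-tested).

**Ploidy masking.** The male non-PAR X is hemizygous, so a heterozygous
genotype there is an artifact (mismapping, collapsed duplication). For male
samples these genotypes are set to missing before window counting; females
and PAR positions are untouched. A male whose PAR could not be resolved has
the entire X masked, with a warning — the conservative choice, since no het
call on a possibly hemizygous region can be trusted.

**Sliding windows.** Heterozygous SNPs (only SNPs; indels may pass the
filter but never count) are tallied in 1 Mbp windows advanced by 100 kbp, so
each interior SNP contributes to exactly 10 windows. Window counts are
scaled to SNPs/kbp by the window's actual span: windows truncated at the
chromosome end are rescaled rather than dropped, because chromosome-end
densities are biologically elevated and dropping them would bias summaries.

**Summaries.** Min/median/mean/max are taken over window densities; the
mode is the center of the most populated histogram bin at a 0.02 SNPs/kbp
bin width (matching the two-decimal resolution such modes are conventionally
reported at). When the zero bin is a local maximum but not the global mode,
a secondary zero mode is flagged — the signature of a masked hemizygous X in
a male sample.

## Synteny blocks and inversions

Blocks are oriented segments (reference chromosome, reference interval,
query scaffold, query interval, strand); query coordinates are always
ascending, with strand carrying the orientation sense (PSL-like convention).
Blocks below 50 kbp of reference span are discarded (inclusive threshold),
mirroring the minimum block size used when blocks are extracted from
whole-genome alignments.

Each query scaffold is assigned to the reference chromosome receiving the
most aligned bp. Dominant orientation per (query, reference) pair is decided
by aligned-bp majority, not block count — robust to many tiny blocks. A
scaffold is flagged whole-scaffold inverted when ≥ 80% of its aligned bp is
on the minus strand; 50/50 mixtures are reported ambiguous.

Inversion calls are maximal runs of consecutive blocks opposing the pair's
dominant orientation, spanning from the first to the last block on the
reference. `max_intervening` (default 0) tolerates that many
dominant-orientation blocks inside a run before it breaks, which bridges
isolated orientation errors in noisy block sets. Runs spanning ≥ 1 Mbp are
classed "megabase"; the cutoff between short and megabase-scale inversions
is a parameter, not a biological claim. Calls from different query genomes
overlapping reciprocally ≥ 50% on the same reference chromosome are grouped
as shared — the coarse criterion appropriate to block-level (not base-level)
breakpoints.

## Assembly statistics

N50 uses the "cumulative ≥ half of total" convention on descending-sorted
lengths; L50 is the rank at the crossing. The chromosome-scaffold cutoff is
the rank k maximizing L_k / L_{k+1} among the top `search_top` (default 64)
ranks, ties broken to the smallest k; the fold gap is rounded half-up for
display, and a gap ≥ 10-fold flags the assembly as chromosome-scale. BUSCO
percentages are computed with half-up rounding to one decimal and reported
as computed — a published table rounded differently will visibly disagree
rather than being silently matched.

**Spectral genome size.** A k-mer multiplicity histogram from reads is an
error component concentrated at multiplicity 1–2 plus a coverage component
centered near the sequencing depth. The trough t is the first strict local
minimum after multiplicity 1 (auto mode fails loudly on flat histograms
rather than guessing; `min_mult` overrides). The estimate is

    G = Σ_{i ≥ t} i·c_i / λ,    λ = Σ_{i ≥ t} i·c_i / Σ_{i ≥ t} c_i

the above-trough k-mer mass divided by the coverage component's mean
multiplicity. The histogram argmax above the trough is reported as a
diagnostic peak but deliberately not used as the divisor: for a coverage
component with near-integer mean the discrete spectrum has a two-bin tie at
the peak (a Poisson pmf satisfies pmf(λ−1) = pmf(λ) exactly at integer λ),
so the argmax resolves by sampling noise and would bias the estimate by up
to 1/λ. The mean-multiplicity divisor is exact for a spike histogram and
unbiased for any unimodal coverage component with negligible sub-trough
mass; adding error mass below a fixed trough leaves the estimate unchanged
(property-tested).

## The synthetic-data generator

`synthgen` emulates the statistical structure the analyses assume, with
planted ground truth: chromosome layouts with a terminal PAR on X
(start-terminal by default; the terminus is configurable), per-base depth as
described above, heterozygous SNPs placed uniformly per region at a
configured SNPs/kbp density (Poisson counts), QUAL ~ Gamma(4, 50),
DP ~ Poisson(mean depth), GQ ~ min(99, Gamma(4, 15)), SP half-normal with
scale 15 — distributions chosen so the bulk of records passes the default
filter while every rule sees traffic; only the SP > 60 tail matters to the
filter, hence the simple half-normal. The male non-PAR X emits no
heterozygous records at all, by construction. Synteny simulation tiles each
reference chromosome with exponentially sized blocks (mean 200 kbp), forces
cuts at planted inversion edges so inversions are tiled exactly, flips
orientation inside them, and renames query scaffolds through a permutation.
K-mer histograms draw one Poisson multiplicity per distinct genomic k-mer
and add error k-mers with geometric (p = 0.8) multiplicities carrying the
configured fraction of total k-mer mass. The read standardizer cuts reads
to their first `target_len` bases (default 100 bp), drops shorter reads —
reads are only ever cut down, never padded — and subsamples without
replacement to the target fold-coverage (default 20×), erroring with the
achievable coverage when the input falls short.

What is *not* emulated: read-level sequence content and error profiles,
GC/mappability bias in depth, linkage between neighbouring SNPs, indels,
Hi-C contacts, and alignment-induced block noise. Tests passing on this
generator therefore demonstrate the correctness of the window/merge/count
machinery and threshold semantics under the stated noise models — not
robustness to alignment artifacts or reference bias in real libraries.

Every generator is deterministic given (config, seed): two calls with the
same arguments produce byte-identical serialized artifacts.

## Problem sizes and defaults used in tests

Synthetic study conditions: 30× mean depth for coverage analyses, planted
heterozygosity 0.6 SNPs/kbp, 23-mers at 20× with 5% error k-mers for
spectral sizing, 50 kbp minimum block span, 1 Mbp megabase threshold.
Recovery runs use 20 seeds on a 20 Mb genome (two 4 Mb autosomes, 12 Mb X;
PAR drawn 1–10 Mb), a 10 Mb chromosome for density recovery, and a 20 Mb
chromosome with one planted 4 Mb inversion — sizes at which the estimators'
sampling errors are well inside the acceptance bands while the full suite
runs in well under two minutes on one CPU.

## Known limitations

- PAR calls are window-quantized; boundaries are accurate to ± one window
  (10 kbp default), not base-accurate.
- Pass 2 of the PAR merge is inert for window-aligned segments (see above);
  its value is limited to externally supplied or non-aligned segments.
- Dominant-orientation logic assumes one dominant strand per scaffold pair;
  a scaffold assembled from two inverted halves (50/50) is reported
  ambiguous rather than resolved.
- The spectral size estimator assumes a single coverage peak; heterozygous
  (half-depth) shoulders and repeat-induced heavy tails are folded into the
  mass term, which is the standard behaviour of spectral estimators but
  inflates G on highly repetitive genomes.
- Multi-allelic VCF records are reduced to the sample genotype class; a
  record is heterozygous if the called genotype is, regardless of how many
  ALTs the site lists.
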