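# Methods

## Coordinate system and count profiles

All positions are 1-based inclusive in human mtDNA numbering.  A count
profile holds, for one strand of one reference, per-position coverage
`C_j`, read 5′-start counts `S_j` and 3′-end counts `E_j` in
*transcript-sense* coordinates: for the plus strand these coincide with
reference coordinates, for the minus strand position `j` maps to
reference coordinate `L − j + 1`, so "one nucleotide downstream" is
always `j + 1`.  Every profile satisfies the coverage identity
`C_1 = S_1`, `C_j = C_{j−1} + S_j − E_{j−1}`, which is asserted by the
validator and preserved by construction in all producers (alignment
counting, table I/O, merging, both simulators).

Alignment handling is deliberately permissive: no duplicate removal and
no mapping-quality filter by default (fragmentation assays rely on
coincident read ends that such filters would distort; a `min_mapq`
option exists).  Soft-clipped bases never extend the aligned span.
Antisense records are dropped with a logged count, matching
strand-specific library chemistry.  The circular mitochondrial genome is
treated as linear; origin-spanning records are skipped with a warning,
acceptable because the rRNA and mRNA loci of interest are far from the
origin.

## Cleavage-protection score

Cleavage of the bond 3′ of nucleotide `i` produces a fragment 3′ end at
`i` and a fragment 5′ end at `i+1`; the default cleavage count is
therefore `n_i = E_i + S_{i+1}` (single-witness conventions are
selectable for sensitivity analysis).  The protection score is

    A_i = max(0, 1 − (2 n_i + 1) /
                    (max(m_L − s_L, 0)/2 + n_i + max(m_R − s_R, 0)/2 + 1))

with `m`, `s` the mean and population standard deviation of `n` over the
`w = 6` bonds on each side of `i` (the measured position is excluded
from its own flank).  Shrinking each flank mean by one SD (floored at
zero) prevents noisy flanks from inflating protection; the +1
pseudocounts keep the score defined at zero counts; scores are clamped
to [0, 1].  A uniform track scores exactly 0 and a fully protected bond
in an even landscape approaches 1.  Positions qualify only when the
median of the 12 flanking cleavage counts strictly exceeds
`min_median_reads = 15` and the full flank is in bounds.  Two open
choices are pinned here: flank statistics use the *population* SD, and
qualification is evaluated on the cleavage-count track rather than raw
coverage (the track is the quantity the score itself consumes).

## RT-stop score

The stop ratio is `r_i = S_{i+1} / C_{i+1}` — the stall one nucleotide
downstream of a methylated site registers as a read 5′ start at `i+1` —
undefined (never zero) where `C_{i+1} = 0`.  "Coverage at that position"
is read as coverage at the stop position `i+1`, the denominator that
makes `r_i` a proper fraction of observable molecules.  The per-replicate
score is the fold change `F_i = r_i(low) / r_i(high)`; positions with an
undefined or zero high-dNTP ratio are excluded rather than imputed.

## Differential calling

At every position with at least two defined per-replicate scores in each
genotype group, a two-sample two-tailed pooled-variance Student's
*t* test compares knock-out against parental scores, untransformed.
Degenerate zero-pooled-variance comparisons give p = 1 when the means are
equal; otherwise the position is flagged "degenerate-significant" with
p reported as 0 and a warning — with 3 + 3 discrete low-count replicates
this occurs at genuinely extreme contrasts and should be inspected, not
silently trusted.  Raw p-values are the primary output; a
Benjamini–Hochberg q-value column (computed per genotype and method via
statsmodels) is appended without altering the primary calls.

A calibration caveat: the protection score carries a point mass at 0
(clamping), so its null *t*-test rejection rate falls below the nominal
α (measured ≈ 0.016 at α = 0.05) — conservative, never anticonservative.
The continuous RT-stop fold-change score is calibrated to the nominal
rate (measured ≈ 0.045–0.049).  The test suite asserts nominal
calibration on the fold-change score and a conservative bound for the
protection score.

## Mitoribosome occupancy

Footprints are assigned to mitochondrial mRNAs by their 5′-end position
on the sense strand.  Reads are excluded when the 5′ end lies in the
first 15 CDS positions (offsets 0–14; initiating ribosomes), in the last
45 CDS positions (terminating ribosomes), or inside the ATP8/ATP6
(8527–8572) or ND4L/ND4 (10760–10766) overlap, which is ambiguous and
counts toward neither gene.  The windows are one-sided inside the CDS
since footprints outside the CDS are not assigned to the gene at all.
Counts are normalised as reads per million of the library's
positive-sense nuclear-encoded mRNA reads — supplied as an integer per
library, since nuclear alignment is upstream of this package.
Translation efficiency is footprint RPM over RNA-seq RPM; per-gene
occupancy is 100 × knock-out RPM / parental RPM with genes of zero
parental RPM excluded and listed.  Summary statistics (mean, sample SD,
min, median, max) cover included genes only.  The packaged annotation
holds the 13 human mtDNA protein-coding CDSs (GRCh38 chrM) with both
overlap intervals.

## Ancillary quantifications

*SILAC qDGMS*: every heavy/light ratio is divided by the median ratio of
a whole-cell lysate mix (correcting imperfect 1:1 mixing; correction is
a multiplicative group action).  Per-protein enrichment is the mean over
the two reciprocal labelling experiments of the log2 corrected ratio,
with the label-swapped orientation sign-flipped before averaging
(linear-space averaging is available behind a flag); subunit
distributions are summarised by the median.  Proteins present in one
orientation only are flagged incomplete.

*Comparative Ct*: Pfaffl-style efficiency-corrected ratio
`E_t^(Ct_t,cal − Ct_t) / E_ref^(Ct_ref,cal − Ct_ref)` with the
control-group mean Ct values as calibrator and measured per-amplicon
efficiencies (fold per cycle, e.g. 1.93 and 1.95).  Because the
calibrator is a Ct-space mean, the control group's *geometric* mean
level is exactly 1.

*Climbing index*: with `c_k` flies completing exactly `k` of `K = 5`
successful climbs, `CI = Σ k·c_k / (K·N)` — the weighted performance
normalised to the maximum possible score, invariant to rescaling all
counts.

## Simulators

All generators are pure functions of (parameters, truth, seed), using
NumPy `SeedSequence` spawning for per-replicate substreams;
bit-reproducibility is guaranteed within a package version, not across
RNG algorithm changes.

*Alkaline fragmentation*: each internal bond receives a mean-1 gamma
cleavage propensity with variance φ (default 0.3, emulating
sequence-dependent hydrolysis; φ = 0 gives a uniform landscape),
multiplied by `1 − protection` at planted sites.  A fragment is a pair
of cut points drawn independently in proportion to the propensities,
accepted when its length falls in the sequenced size-selection window
(default 25–55 nt); a capped rejection budget turns pathological
configurations into a parameter error.  The propensity landscape is a
property of the reference sequence, so it is drawn once per call and
should be passed explicitly (`bond_weights`) when simulating contrasting
genotypes, making the groups exchangeable under the null.

*RT-stop libraries*: template fragments are uniform over valid
(start, length) pairs; reverse transcription walks 3′→5′ with a
per-nucleotide background drop-off δ (default 0.001) and an additional
stall probability `q_low`/`q_high` when the next template nucleotide is
a planted site, leaving a read 5′ start one nucleotide downstream of the
site.  Fragment ends and stall starts therefore coexist in one profile,
as in real libraries.  The test suite checks the observed stop ratio
against an exact expectation computed by independent fragment
enumeration.

*Footprint libraries*: per-gene counts are Poisson with mean CDS length
× occupancy factor × scale; 5′ positions are uniform over the CDS
offsets that survive the exclusion windows and overlap filter, so
planted occupancy factors propagate directly to filtered counts.

*SILAC tables*: log2 ratios are the planted mtLSU effect (sign-flipped
in the swapped orientation) plus the log2 mixing bias plus Gaussian
noise; an effect-free whole-cell protein set provides the correction
median.

What the simulators do **not** emulate: base-level sequence context,
aligner error and multimapping, ligation and PCR biases, tRNA-punctuated
transcript processing, codon-level ribosome dynamics, or peptide-level
SILAC quantification noise.  Passing recovery tests therefore
demonstrates correctness of the scoring and calling machinery under the
assays' idealised generative assumptions, not robustness to every
artefact of real libraries.

## Problem sizes and numerical choices

Test and acceptance simulations use references of 300–600 nt with
20–100 cleavage events per bond (fragment coverage ≈ 500–2000×, the
depth regime of mitochondrial fragmentation libraries, and comfortably
above the ~300× below which the >15-read flank-median qualification
leaves nothing scorable), three biological replicates per genotype, and
10–20 independent seeds for rate estimates.  Planted contrasts use
protection 0.9 and stall probabilities 0.5 (low dNTP) vs 0.05 (high).
Equality of vectorised scores with literal per-position
re-implementations is asserted to 1e−12; stochastic recovery assertions
use 2–3 standard-error bands derived from the generative model.  Exact
single-site recovery at raw p < 0.05 among three planted sites carries
an irreducible ~10% multiplicity failure rate per run (two null
contrasts at α = 0.05), so recovery tests aggregate over 10 seeds with
thresholds set from that binomial expectation (≥9/10 detection, ≥7/10
exact).

## Known limitations

* Score A's formula family has several published variants; the pinned
  variant (one-SD flank shrinkage, +1 pseudocounts, [0, 1] clamp) is the
  contract here and is frozen by the oracle tests.
* The t-test on clamped protection scores is conservative under the
  null (see above); positions qualified in fewer than two replicates
  per group are reported untestable rather than imputed.
* Occupancy normalisers are taken on trust from the sample sheet; the
  package does not validate them against nuclear alignments.
* Minus-strand profiles use transcript-sense coordinates internally;
  callers exporting minus-strand positions must convert back to
  reference numbering.
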