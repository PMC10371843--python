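# Methods

This note records the model, the statistical procedures, the defaults and
the design choices behind `fmblocks`, including the points where the design
was genuinely open and what the synthetic cohorts do and do not demonstrate.

## Biophysical core

**Energy model.** A PWM (L × 4 base probabilities, pseudocount 1e-4 added
and columns renormalized at construction; regularization is idempotent so
files round-trip) is converted to a PSAM of additive mismatch energies
`E[i,b] = −kT·ln(p[i,b]/max_b p[i,b])`.  The per-column consensus base sits
at energy 0 and the consensus window scores 0 overall.  `kT` defaults to 1
and is not used as a free parameter anywhere in the pipeline; energies are
therefore in units of kT.

**Occupancy.** The Fermi–Dirac occupation probability
`P(S) = 1/(1+exp((E(S)−μ)/kT))` is computed through `scipy.special.expit`,
which is saturation-safe for arbitrarily large arguments.  Sequence
occupancy sums P over every length-L window on the forward strand and (by
default) the reverse complement, implemented as a second scan with the
reverse-complemented energy matrix.  Windows containing N get infinite
energy and contribute exactly 0 — masked sequence is skipped rather than
imputed so no affinity is fabricated.  The implementation is vectorized over
batches of equal-length sequences and over the μ grid; tests pin it against
a brute-force window-by-window oracle at 1e-9 relative tolerance.

**Chemical potential grid.** μ plays the role of TF concentration.  Without
condition-specific estimates it is scanned over a grid; the default is the
integers −8 … −20 (13 values), with 0 … 23 available as the alternate
admissible range.

**dbA and δdbA.** The differential binding affinity of a sequence is defined
here as its log-occupancy minus the mean log-occupancy of B
mononucleotide-shuffled copies (default B = 10; B = 0 reduces dbA to the
plain log-occupancy and is a config switch).  The shuffle permutations are
generated once per comparison and applied identically to the reference and
mutated sequence, so `δdbA = dbA(ref) − dbA(mut)` is exactly 0 when the
sequences are equal and exactly antisymmetric under swapping.  The
per-subject summary across the μ grid is the signed value of maximal
magnitude (the μ at which the effect is strongest); a signed mean is the
config alternative.  Sign convention: δdbA > 0 is binding lost by the
mutation; user-facing tables additionally carry `display_change = −δdbA`.

## Mutation block detection

SNVs are chained per chromosome with strict `< 30 bp` adjacent-position
gaps into clusters (kept when ≥ 2 SNVs from ≥ 2 distinct patients; the same
patient at the same position is counted once, different patients at one
position each count).  Clusters separated by strictly `< 500 bp` merge into
blocks, kept at ≥ 3 SNVs from ≥ 3 patients for cohort runs (2/2 is the
genome-scan alternative).  Coordinates are 0-based half-open internally;
block ids embed 1-based inclusive coordinates
(`block_<k>_<chrom>_<start>_<end>`).

Block significance is an exact binomial upper tail with k = SNVs in the
block, n = span × cohort size and p = the cohort-wide per-bp per-patient SNV
rate over the scanned regions, Bonferroni-corrected over the candidate
blocks.  **Limitation:** the test conditions on the clustering that selected
the block, so at high background rates (≳1e-4/bp/patient) chance clusters
can reach nominal significance; at cohort-realistic rates (~1e-6) the
false-positive rate measured over background-only simulations is ~0 blocks
per genome.  The correction family (candidate blocks, not scanned windows)
is configurable.

## Foreground/background TF testing

For each block, every patient's SNVs are applied jointly to the reference
block sequence (the per-patient heatmaps are per patient, not per SNV).
Background blocks of the same length are placed uniformly over all valid
positions in the scanned regions; each receives the per-patient average
mutation count of the foreground block, with alternate bases drawn from the
cohort's k-mer (default trinucleotide) mutation signature conditioned on the
local reference context.  Unseen contexts fall back to a uniform draw over
the three alternates; reverse-complement collapsing is off by default.

The per-TF test is a two-sided Wilcoxon rank-sum between foreground and
background samples, exact when n+m ≤ 20 without ties, normal approximation
with tie correction otherwise, Bonferroni-corrected over the TFs tested in
the run.  By default one sample per patient and per background block (the
signed max-magnitude aggregate over μ) enters the test: the per-μ values of
one block are strongly correlated, and pooling them as if independent breaks
the exchangeability the rank-sum null requires.  Pooled per-μ mode is
available as `sample_mode="pooled"` for comparison.  Measured under the null
(foreground generated by the background generator), the aggregate-mode
fraction of raw p < 0.05 is ≈ 0.04–0.05.

TFs are *ranked* by (p-value, then effect size = median |aggregate δdbA|,
then name).  The effect-size key matters because under complete
fg/bg separation the rank-sum p floors at the same value for every fully
separated TF; impact then distinguishes the motif actually hit.

**Heatmaps.** Cell(TF, patient) = sign(display_change) × (−log10 p_emp) with
the add-one smoothed empirical probability
`p_emp = (1 + #{|bg| ≥ |patient|}) / (B + 1)`, never 0 so the log is finite;
rows are limited to TFs with expression RPKM ≥ 0.03 (TFs absent from the
expression map are retained — unknown is not unexpressed) and, when
p-values are supplied, to TFs below a display cutoff (0.01 default, 0.001
Bonferroni variant).

**Mutation score.** A single SNV's score is the mean |aggregate δdbA| of the
top 20 TFs ranked by |aggregate| (covering both signs); "top 20 per
direction, union" is a config flag.  ROC/AUC and cumulative top-N rank
accuracy harnesses evaluate the score against verified/random labels; a
pseudo-TF entry in a ranked list counts as a hit when the verified TF is a
cluster member.

## PWM clustering (pseudo-TFs)

PWMs are grouped by DBD family ("UNCLASSIFIED" is its own family) and
clustered within family on a similarity matrix: the mean per-column Pearson
correlation at the best ungapped offset over both orientations, minimum
overlap 4 columns (−1 sentinel when no offset qualifies; both-constant
column pairs score 1, single-constant 0).  The clustering objective is the
affinity-propagation net similarity (exemplar preferences plus
member→exemplar similarities) with preference = median pairwise similarity
and damping 0.9.  Families below 11 members are solved by exact enumeration
of that objective — message-passing AP oscillates or misassigns on tiny
families with tied similarities (two identical motifs can end up in
different clusters); ties prefer more clusters, then the lexicographically
smallest exemplar set.  Larger families use scikit-learn's
AffinityPropagation with a singleton fallback on non-convergence.

Each cluster's representative pseudo-TF is the column-wise mean of members
aligned to the exemplar at their stored offset/orientation, restricted to
columns covered by at least ⌈m/2⌉ members (trimming flanks dominated by a
single member), renormalized, and named `pseudo_<family>_<k>`.

The three computation modes: `PWMs_full` tests every PWM; `C1_full` tests
the pseudo-TFs (a significant pseudo-TF stands for all of its members);
`C1fC2_N` ranks pseudo-TFs per block, expands the top N clusters and
re-tests the member PWMs.  On a library whose clusters are all singletons
the three modes are exact reparametrizations of each other and produce
identical significant-TF sets (verified; background block seeds are derived
from the block id so the modes share backgrounds).

## Block–gene association

Blocks are annotated to four strand-aware gene windows (≥ 1 bp overlap):
gene body [TSS, TES]; TSS window −5 kb/+1 kb; TES window −1 kb/+5 kb; and
distal 5′ −1 Mb … −5 kb.  An oriented window "−U/+D" around base t is
[t−U, t+D+1) on the plus strand and its coordinate reflection [t−D−1, t+U)
on the minus strand, clipped to the chromosome.  Symmetric promoters
("±X bp of TSS") cover X bp on each side of the TSS base (2X+1 bp total).

Associations are kept when the block overlaps a DMR **or** the gene is
differentially expressed, and the block midpoint and gene TSS fall inside
the same TAD interval (midpoint/TSS is the chosen operationalization of
"within the same TAD"; partial-overlap semantics are otherwise undefined).

**Chromatin-state enrichment.** For a gene's M blocks, the actual fraction
overlapping each of the seven states (TSS, PF, E, WE, CTCF, R, T) is
compared with fractions of M blocks drawn without replacement from the pool
of all blocks minus the gene's own; `expected_p` is the fraction of draws
whose state fraction is **strictly greater** than the actual one (ties do
not count), unsmoothed, so it can legitimately be 0.  Draws are vectorized
and deterministic given the seed; tiny pools can be enumerated exhaustively
instead of sampled.  A gene is selected when expected_p < 0.05 in TSS or
enhancer **and at least one of its blocks actually overlaps that state** —
without the presence requirement, a state absent from both the gene's
blocks and the pool yields expected_p = 0 and would mark genes "enriched"
in a state they never touch.  The spec-literal behaviour is available via
`require_presence=False`.

**Limitation (discreteness).** The strict-exceedance p is liberal when the
fraction grid is coarse: with M = 100 blocks per gene the null fraction of
expected_p < 0.05 is ≈ 0.08, and drawing from a pool not much larger than M
shrinks the draw variance and inflates this further.  Near-uniformity holds
in the fine-grid regime; the calibration check uses M = 400 blocks per gene
with a pool of 8000 (measured ≈ 0.060–0.065).  Real cohort genes have few
blocks each; their expected_p values should be read as enrichment scores,
not calibrated p-values.

## Synthetic cohorts

`generate_scenario` builds a uniform-random genome (default 200 kb, one
chromosome), 24 evenly spaced genes on alternating strands, 8 informative
random motifs (dominant base 0.85, one flattened flank column) in 3 DBD
families, a 14-tumor/8-normal expression matrix, and DMR/TAD/state tracks.
Per planted block, three consensus occurrences of one motif are embedded in
a target gene's promoter (offsets 0/22/170 within the block) and three
patients each mutate the maximum-information consensus base of all three
sites to that column's minimum-probability base — the strongest possible
binding-loss signal, chosen to make power tests sharp — giving 9 SNVs from
3 patients satisfying the 30/500 bp chaining rules.  Target genes get a
tumor mean shift of 2 (SD 1) in expression, a DMR over the block, a TSS
chromatin state over the promoter and a TAD shared with their promoter.
Decoy blocks use the same SNV geometry with random alternates in intergenic
repressed chromatin next to non-target genes; background SNVs are uniform at
2e-6 per bp per patient (cohort-realistic) with uniform alternates, so the
derived signature is approximately flat and planted signal is
distinguishable from background-model artifacts.

What passing these tests shows: the statistics are calibrated and the
pipeline recovers strong planted signal with clean decoy rejection under the
model's own assumptions.  What they do not show: performance on real
mutational signatures (UV, AID), realistic expression dispersion, motif
libraries with heavy redundancy, or genomes with repeats and composition
bias — none of which the generator emulates.

## Numerical and procedural choices

- Seeds: every stochastic step takes a seed; work-item seeds are derived
  from the master seed with a multiplicative hash and stay below 2³¹.
  Background-block seeds derive from the block id, making results invariant
  to block enumeration order and identical across computation modes.
- Aggregate tie-break across μ: first index of maximal |δdbA|.
- Degenerate DEG inputs: zero variance in both groups with equal means → p
  = 1; with different means → p = 0.
- Rank-sum with all values identical in both groups → p = 1.
- Parallelism: per-(block × PWM) work items are independent; the
  implementation evaluates them sequentially but batches all sequences of a
  work item into single vectorized occupancy calls, which is what makes the
  default test suite and the acceptance script run in minutes.
- Problem sizes in the acceptance script (25 cohorts for recovery, 150
  null blocks × 5 TFs for rank-sum calibration, 200 genes for enrichment
  calibration, 50 background-only genomes) were chosen to keep Monte-Carlo
  error well inside the tolerance of each check.
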