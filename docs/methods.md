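# Methods

This note documents the models and numerical choices behind `aptaselex`:
what the SELEX simulator generates, how the analysis funnel processes
libraries, which parameters matter, and what the package's tests do and do
not demonstrate about real sequencing data.

## The generative SELEX model

A simulated campaign starts from a pool of distinct DNA variable regions
(default lengths 40–44 nt; RNA inputs are represented by their cDNA, with
U→T normalization on parsing). Each sequence *i* carries a latent affinity
`a_i^T ∈ [0, 1]` for every selector class
`T ∈ {mouse_islet, mouse_acinar, human_islet, human_acinar}`:

- **Background** sequences (`n_background`, default 5×10⁴) draw all
  affinities from Beta(1, 19) (mean 0.05) — weak, uncorrelated binding.
- **Planted families** (`n_families`, default 10) each consist of a seed
  plus a mutational cloud (`cloud_size` = 25 members, per-position
  mutation rate 0.02). Seeds draw a base affinity from U(0.5, 0.9).
  Species-restricted seeds assign it to `mouse_islet` only. Cross-reactive
  seeds (fraction 0.4) bind a conserved epitope: the same affinity —
  discounted by a generalist cost of 0.15 — for both `mouse_islet` and
  `human_islet`. The cost reflects that a mouse-only selection produces a
  library dominated by species-restricted binders (its output stains
  mouse but not human islets), with cross-reactive clones a minority
  until the toggle favours them; without it, cross-reactive families
  would frequently dominate the pre-toggle library, which contradicts
  that observed phenotype. Cloud members inherit the seed's islet
  affinities scaled by `(1 − 0.1)^substitutions`.

One selection round (`run_cycle`) chains four stochastic steps per
sequence with count `c_i`:

1. negative selection: survivors ~ Binomial(`c_i`, `1 − δ·a_i^neg`),
   depletion strength δ = 0.5;
2. positive capture: captured ~ Binomial(survivors, `κ·(a_i^pos)^s`),
   capture scale κ = 0.5;
3. PCR: a per-sequence lognormal gain with mean `pcr_gain` = 100 and
   log-sd `pcr_noise_sd` = 0.3 (noise is per sequence per cycle, not per
   molecule, for tractability);
4. input renormalization: if the amplified pool exceeds `pool_size`
   (default 10⁸ molecules) it is multinomially downsampled to it,
   mirroring the fixed input amount fed into each bench round.

Sequencing is modeled as a multinomial **aliquot** of `depth` reads
(default 2×10⁵) drawn from the molecular pool; the aliquot is what the
analysis sees, but the pool itself — not the aliquot — feeds the next
round. Bottlenecking the carried population at sequencing depth would
collapse diversity even in a selection-free round (a 2×10⁴-read sample of
its own previous sample loses ~37% of singletons per cycle), which is an
artifact of conflating the sequencer with the test tube.

The stringency exponent *s* maps the published wash schedule onto capture:
`s = 1 + 0.25 × (washes beyond the 3-wash baseline)`, giving s = 1.0 for
cycles 1–4, 1.25 for cycles 5–6 and 1.75 for cycles 7–8 and both
post-toggle human rounds. `s = 0` makes capture affinity-blind and defines
the neutral protocol used for calibration tests. No quantitative per-cycle
enrichment strength is available for the real campaigns, so these defaults
are calibrated to make the funnel's qualitative behavior testable
(complexity decay over ~10 rounds, family takeover after the toggle), not
to fit any particular deposited dataset.

All randomness flows through one `numpy.random.Generator` seeded from
`SimConfig.seed`; a (config, seed) pair reproduces a run bit-for-bit.
`run_protocol(config, protocol_seed=...)` optionally re-seeds only the
selection randomness so replicate campaigns share one sequence universe.

## Read processing

Variable regions are located between two constant flanks by best Hamming
match (lowest mismatch count, ties to the left-most offset; an exact
`str.find` fast path covers clean reads). A read is accepted when both
flanks match within `max_mismatch` (default 1 per flank) and the enclosed
region is 40–44 nt and free of N. Rejections are tallied by category
(`no_flank5`, `no_flank3`, `bad_length`, `ambiguous_base`). Reverse-strand
search is off by default: the amplicon protocol fixes orientation.

Frequencies are computed over extraction-passing reads — self-consistent
under varying junk-read rates — while complexity defaults to the
published total-reads denominator (`100 × unique / total`), switchable to
extracted reads. "Undetected" always means an observed count of zero; the
background floor ε = 10⁻⁶ enters only as the fold-change pseudo-frequency
and the enrichment-report detection threshold, never the matrix itself.

## Families, tree, PCA

Pairwise identity is `matches / alignment_length` of an optimal global
alignment under match +1, mismatch −1, linear gap −2 (Biopython's pairwise
aligner; an independent dynamic-programming oracle checks the engine in
the tests). `1 − identity` is a similarity complement, not a metric — the
triangle inequality can fail — so families are formed by average-linkage
agglomeration (SciPy) cut at 1 − 0.80 identity, with sequences canonically
sorted (frequency descending, then lexicographic) so input order is
irrelevant. At most the 5 000 most frequent sequences are clustered; the
quadratic alignment cost makes this cap the practical operating point,
and family mass Φ is dominated by exactly these sequences. The real
campaigns' family counts depend on a multiple-alignment tool's internal
clustering that is not reproducible from the outside, so no particular
family count is a target here.

The candidate tree is Saitou–Nei neighbor joining (scikit-bio) on
`1 − identity`, with negative branch lengths clamped to zero and the
two-taxon case handled as a single evenly split edge. On additive
distances NJ is exact, which the tests exploit by reconstructing random
4–8 taxon trees from their own path distances. Branch representatives are
picked by removing the k−1 longest edges (ties by traversal order;
removals that do not split the current leaf partition are skipped) and
taking each clade's highest-frequency leaf, ties lexicographic.

PCA one-hot encodes sequences over {A, C, G, T} right-padded with an
all-zero gap state, mean-centers, and projects on the top-2 right singular
directions; each component's sign is fixed so its largest-magnitude
loading is positive.

## Selection rules

The toggle rules follow the wording that defined them: "higher than" is
strict, "at least" is non-strict. R1 (undetected before, ≥ 10⁻⁴ after),
R2 (before-frequency > 5×10⁻⁶, detected after, fold change > 10) and R3
(before-frequency > 10⁻⁴, fold change ≥ 2) are evaluated together and a
sequence is reported once under the lowest-numbered rule it satisfies
(R2 and R3 can genuinely overlap; R1 is disjoint from both because it
requires a zero count). An alternative published phrasing of R2 —
post-toggle frequency ≥ 10⁻⁴ with ≥ 10× expansion for any sequence
detected before — is available as the `"results"` preset.

Cross-strategy merging deduplicates exact sequences and flags as
convergent any candidate with a counterpart from the other strategy at
≥ 0.9 alignment identity, the in-table analogue of tree branches that
contain candidates from both selections.

## Assays

The qPCR effect size is `(mean 2^−ΔCT_exp − mean 2^−ΔCT_ctrl) / SD_exp`
with SD the sample (n−1) standard deviation of the experimental
replicates' *linear* values — the only scale on which the formula is
dimensionally coherent, since a ΔCT-scale SD would divide a linear-scale
difference by log-scale units. Classification: strong up-regulation for
effect size > 4, modest for 4 ≥ es > 2, down-regulation for es ≤ −2 (no
published threshold exists for "significant downregulation"; −2 mirrors
the modest-up boundary and is configurable), neutral otherwise.

The saturation fit uses one-site specific binding with a constant
background, `MFI(L) = B_max·L/(K_D + L) + c`, chosen as the simplest model
with an interpretable apparent K_D; no functional form was published for
the titration curves. Least squares runs from three K_D starts (min,
geometric mean, max of the concentration range) and keeps the best
residual sum of squares. The fit is declared unidentifiable when no start
converges, when the amplitude is numerically zero (flat curve), or when
the fitted K_D leaves `[min(L)/100, 100·max(L)]`.

## What the tests show — and do not

The simulator provides ground truth, so recovery tests are exact: on the
default recovery campaign the merged candidate list contains every planted
cross-reactive seed (or a ≥ 0.9-identity cloud member), flags them
convergent, and contains ≤ 5% background; complexity falls strictly every
cycle under selection and stays within 2% of 100 under the neutral
protocol. Across unseeded replicates of the same campaign roughly one run
in five instead yields 3 of 4 cross-reactive families convergent: when the
weakest cross-reactive family is already above 10⁻⁴ before the toggle and
the two human rounds concentrate mass on its stronger siblings, it can
expand by less than 2× and legitimately evades all three rules. That is a
property of threshold rules near their boundaries, not of the
implementation.

The simulator does not model RNA secondary structure, 2′-fluoro
chemistry, bead-partitioning kinetics, PCR substitution errors,
sequencing miscalls, or cross-contamination between cycles; planted
families are point-mutation clouds with multiplicative affinity penalties.
Passing tests therefore demonstrate that the funnel's logic is correct and
its statistics behave as designed under a plausible generative model —
not that any particular biological campaign would yield the same numbers.

## Problem sizes

Default scales were chosen to exercise the funnel's qualitative regimes on
a single CPU: recovery at 5×10⁴ background sequences and 2×10⁵ reads per
cycle over 10 cycles (the full pipeline, FASTQ round trip included, runs
in seconds); the neutral calibration at 10⁶ background sequences and
2×10⁴ reads; rule-oracle checks on randomized tables up to 10⁴ rows;
alignment-based clustering capped at 5 000 sequences per cycle.
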