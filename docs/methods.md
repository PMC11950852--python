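# Methods

This note records the model behind `rapidsim`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want to know about.

## Construct and library arithmetic

The displayed core is initiator + (NNK)₁₅ + Cys, 17 residues, encoded by a
51-nt ATG…TGT frame followed by the SGGLTN linker. DNA is stored T-based;
RNA input is normalised on entry. NNK codons are the 32 triplets with
N ∈ {A,C,G,T} at positions 1–2 and K ∈ {G,T} at position 3; the amber
triplet TAG is a legal NNK member and translates as a stop-flagged position
(the generator excludes it from random regions by default, since the
platform's engineered readthrough applies only to the designed downstream
stop, which is not modelled). The initiator renders as lowercase `y` to keep
it distinguishable from genetically encoded Tyr in fixed-width alignments.

Scale arithmetic is deliberately elementary and exposed as named
operations: `32^L` sequence space; ribosome molecules
= volume × 1.2 pmol/µL × Avogadro; mRNA pmol = ribosome pmol under the
monosome assumption; diversity suppression = 1/recovery. Expected unique
sequences under sampling uses the Poissonisation `D(1 − e^(−n/D))`; a
dilution factor of exactly 1 is treated as "take everything" (identity)
rather than a resampling bottleneck, because the formula's one-copy-
per-sequence assumption does not describe taking the whole tube. Endpoint
subset diversities are stored as measured values, not recomputed from
dilution arithmetic, since real daughter diversities reflect pipetting and
measurement, not clean division.

## Kinetics

Association over the incubation follows the pseudo-first-order 1:1 solution
`f(t) = (k_aC/(k_aC+k_d))(1 − e^(−(k_aC+k_d)t))`; wash survival is
`e^(−k_d·n·t_wash)` with rebinding neglected (no free target in wash
buffer). Family averages are geometric means, which makes
`K_D_avg = k_d_avg/k_a_avg` an algebraic identity rather than an
approximation. Sensorgram simulation uses the same forward model per
analyte concentration with a continuous phase boundary; fitting runs
nonlinear least squares over `(log10 k_a, log10 k_d, log10 Rmax)` with a
two-stage start (off-rate from a log-linear fit of the dissociation tail,
on-rate from the equilibrium plateau). Bounds are
`k_a ∈ [1, 10^9] M⁻¹s⁻¹`, `k_d ∈ [10⁻⁸, 10²] s⁻¹`; flat inputs return a
degenerate-flagged result and zero-decay data pins `k_d` at the lower
bound rather than failing. Noiseless parameter recovery is exact to
solver precision; with noise at 2% of Rmax across five concentrations the
off-rate is recovered within a few percent.

## Selection round

A round is translation sampling → negative selection → positive selection →
PCR. All stages act on exact int64 molecule counts; binomial/multinomial
draws come from per-(round, stage) child streams of one root seed, so
campaigns are bit-for-bit reproducible. Round 1 translates at the scale
that covered the library's diversity (up to 1.1 × 10¹⁴ molecules); later
rounds use the 2.5-µL budget of 1.8 × 10¹² molecules.

Positive-selection survival decomposes as
`capture_efficiency × f_bound × wash_survival + stickiness`, i.e. a
specific path through binding and washing plus a nonspecific carryover
floor. Defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| target concentration | 100 nM | order of the peptide-pool concentration; equimolar-target protocol |
| incubation | 1800 s | 30-min standard |
| washes | 3 × 20 s | three washes per protocol; duration unstated anywhere, chosen by calibration (below) |
| capture efficiency | 0.004 | effective end-to-end capture incl. RT/PCR losses, chosen by calibration (below) |
| background stickiness | 5 × 10⁻⁶ | puts background-dominated round-1 recovery at 0.0005%, inside the observed 0.0005–0.002% window |
| PCR mutation | 10⁻⁴ /base/cycle, 15 cycles, ts:tv 3:1 | textbook Taq-order error rate; ~7% of a 51-nt template mutates per round |

**Calibration argument.** Round-resolved observations pin two combinations
of the free parameters. First, background survival must equal the round-1
recovery window (~5 × 10⁻⁶). Second, per-round enrichment factors
`E = s_binder/s_background` must make (a) a fast-off family
(`k_d ≈ 5 × 10⁻²`) climb from a ~10⁻⁶ starting fraction to dominance of
the smallest library within 7 rounds (needs `E ≈ 10`), while (b) slow-off
families (`k_d ≈ 4 × 10⁻³`) starting near 10⁻⁸ make recovery rise at round
3–4, not earlier (needs `E` of a few hundred). The wash-differential
`e^(Δk_d·W)` fixes the total wash time `W ≈ 60 s`, and the fast-off
family's absolute survival then fixes capture efficiency ≈ 0.4%. These two
values were set from this closed-form argument, not fitted to simulation
output; they are calibration constants of the model, not measured ground
truth.

PCR mutation is tracked explicitly only for the 20 most abundant
sequence-bearing templates per round: each spawns single-point variants
(multinomial over the 153 substitutions of its 51-nt frame, transition-
weighted; start-codon hits stay on the template since an AUG-less construct
is never displayed). Mutants of rarer templates would sit far below the
1/10⁵ sequencing detection floor, so their copies remain unmutated on the
template. Synonymous variants also stay with the template. Nonsynonymous
mutants inherit the template's ground-truth family label and jittered
kinetics (log10 shifts of −0.5 ± 0.5 on `k_a`, +0.5 ± 0.5 on `k_d`:
mutations usually hurt, occasionally help — which lets the simulator
reproduce mutant takeovers of the kind hypothesised from enrichment data).
Premature stops and lost cyclisation Cys get inert kinetics and die at the
next positive selection.

## Synthetic study generator

The generator reproduces the *structure* of a two-lineage, five-library
study: group 1 = 1.1 × 10¹⁴ → 2.2 × 10¹⁰ → 2.9 × 10⁶, group 2 =
3.6 × 10¹² → 2.5 × 10⁸, seven rounds, ~10⁵ reads/round. The scale-down is
representational, not numerical: molecule counts are the nominal ones
(int64 arithmetic is exact to 9 × 10¹⁸), but only planted binders and
their tracked mutants are explicit species; the nonbinder ocean lives in
100 equal-mass bins at lognormal-quantile `k_d` (μ = −1, σ = 0.5 in log10,
`k_a` = 10² M⁻¹s⁻¹ — far below the association threshold, so background
survival is stickiness-dominated).

Four families are planted with centre kinetics at the study-style family
log-averages (5.9 × 10⁵/4.2 × 10⁻³; 1.1 × 10⁵/4.5 × 10⁻³;
5.7 × 10⁵/4.5 × 10⁻²; 2.4 × 10⁵/5.2 × 10⁻²) and sequence-space frequencies
(8 × 10⁻⁹, 4 × 10⁻¹⁰, 2 × 10⁻⁸, 2 × 10⁻⁶) chosen once so that expected
copy numbers `frequency × diversity` reproduce the observed
presence/absence pattern: the fast-off family is sampled even at 2.9 × 10⁶
diversity, the strongest family needs ≥ ~10⁸, and the second slow-off
family needs ≥ ~10¹⁰. Each family is realised as 6 tracked variants per
sampling group (shared down a lineage, disjoint across groups); a variant's
round-1 copies are `Poisson(λ/6) × budget/diversity`, so one tracked
variant aggregates the many near-identical sequence-level variants a real
library would hold at that scale. Family reference cores are kept ≥ 13/15
residues apart and members within 2 codon substitutions of their
reference, which makes single-linkage clustering at the default 0.5
mismatch threshold provably recover the planted partition (inter-member
distance ≥ 9 > 7.5 ≥ threshold > 4 ≥ intra-member distance).

What the generator does **not** emulate: sequencing error and quality
scores (reads are error-free; PCR is the only mutational process),
translation-efficiency and PCR amplification bias between sequences,
target-site competition/saturation, bead-surface effects, and polysomes.
Consequently, passing campaign tests shows the *selection-dynamics* logic
is right under idealised amplification; it does not validate the pipeline
against platform-specific biases, which real deposited reads would probe.

## Enrichment analysis

Triage takes sequences strictly above the abundance threshold (default 2%
of reads), ranked by count with lexicographic tie-breaks, capped at 7
("top 6 or 7" is a cap choice the analyst can set; the selection rule for
6 vs 7 is not specified anywhere, so the cap is a config knob).
Deduplication is exact-string grouping across libraries. Clustering is
ungapped single-linkage on Hamming distance (cores are fixed-length by
construction; gapped/profile methods are out of scope), with consensus
defined per position as the smallest residue set covering ≥ 2/3 of
members, rendered as a wildcard if more than two residues are needed.
Absent-in-round sequences get fraction 0 — at 10⁵ reads a zero count only
bounds abundance below 10⁻⁵.

## Extreme-value module

Two closed forms are provided for the expected best (minimum) `log10 k_d`
among N draws: the quantile surrogate `μ + σ·Φ⁻¹(1/(N+1))` (default; simple,
monotone, exact at N = 1) and the exact order-statistic mean computed by
Gauss–Legendre quadrature of `Φ⁻¹(1 − V^(1/N))` (the Beta-transform of the
minimum), which is the correct comparator for Monte-Carlo *means*. The two
differ by 0.15/0.11/0.07 standard units at N = 10³/10⁶/10¹³ — material when
σ ≈ 0.4, which is why both exist. σ-calibration from a "fold per decades"
statement inverts the loglinear fold expression exactly (no root-finding
needed). Monte-Carlo sampling is direct below N = 10⁷ and switches to the
order-statistic sampler `μ + σ·Φ⁻¹(−expm1(ln U/N))` above it; the expm1
form is numerically stable to N ~ 10¹⁴ and the two samplers agree in
distribution (two-sample KS test in the suite). The model is expressed on
`k_d` because wash stringency makes selection `k_d`-dominated while
observed `k_a` spans a narrow 2 × 10⁴–2 × 10⁶ range; a `K_D` reading is
the same machinery with `k_a` held fixed.

## Problem sizes and test design

The suite runs five-library, seven-round campaigns over 20 seeds (about a
minute; ~2 500 explicit species per campaign after mutant tracking) plus
Monte-Carlo oracles of 200–2 000 replicates; these sizes give standard
errors comfortably inside the asserted tolerances. Stochastic assertions
are formulated against analytic expectations with 3–5 standard-error
bands. The three campaign-level patterns (late recovery rise; fast-off
dominance of the smallest library; slow-off displacement in the largest)
are each required in ≥ 16/20 seeds: the minority exceptions are Poisson
sampling noise in the 2.9 × 10⁶ library — e.g. the strongest family lands
there with probability ~2% per member pool and then legitimately dominates
— which is the sampling mechanism under study, not a failure mode.

## Known limitations

* Survival probabilities are independent per molecule; no target-depletion
  coupling between species, so very abundant binders cannot saturate the
  beads.
* Background bins do not mutate and never spawn binders; de-novo binder
  emergence from the nonbinder ocean is outside the model.
* Wash survival ignores rebinding; with long washes and high target
  density this overstates `k_d` selectivity.
* The mutant-kinetics jitter is a phenomenological prior, not a
  sequence–function map; mutant identities are realistic (single-point,
  transition-biased), their kinetics are not predictive.
* SPR fitting assumes the ideal 1:1 model it simulates; mass-transport
  limitation and bivalent artefacts are out of scope.
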