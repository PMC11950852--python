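# rapidsim

Stochastic simulation and NGS-side analysis of mRNA-display affinity-selection
campaigns, with an extreme-value model linking library diversity scale to the
best binder's dissociation rate.

## Who this is for

mRNA display (including RaPID-style platforms with a reprogrammed
chloroacetyl-Tyr initiator and thioether macrocyclisation) selects
target-binding macrocyclic peptides from libraries of 10^6 to 10^14 unique
mRNA sequences. Practitioners planning such campaigns face concrete
questions: how does library scale change which binder families are even
*sampled*, how does wash stringency translate into selection pressure on the
dissociation rate `k_d`, when should recovery rates start rising, and how
much slower an off-rate does another factor of 10^7 in diversity buy?
`rapidsim` provides a desk-scale, fully seeded model of the whole chain —
library construction, round-by-round selection, deep-sequencing analysis,
and extreme-value statistics — so those questions can be explored
quantitatively before (or alongside) wet-lab work.

## The model

**Library.** The display construct is `AUG-(NNK)15-UGU` plus a
Ser-Gly-Gly-Leu-Thr-Asn linker: an initiator reprogrammed to
N-chloroacetyl-L-Tyr, fifteen NNK codons (32^15 ≈ 3.8 × 10^22 DNA
sequences), and a fixed Cys for macrocyclisation. Under the monosome
assumption each mRNA engages one ribosome and yields one peptide–mRNA
fusion, so translation volume sets a hard molecule budget
(1.2 pmol/µL ≡ 7.2 × 10^11 ribosomes/µL).

**Selection round.** Each species carries 1:1 Langmuir kinetics
(`k_a`, `k_d`, `K_D = k_d/k_a`). Per round, a molecule survives positive
selection with probability

```
p = capture_efficiency × f_bound(k_a, k_d; C, t_inc) × exp(−k_d · n_wash · t_wash) + stickiness
```

where `f_bound` is the pseudo-first-order association solution over the
30-min incubation and the exponential is complex survival through the
washes — the term that makes stringent washing a `k_d`-selection. Survivors
are PCR-amplified back to the pool size with per-base point mutation
(tracked single-point variants re-enter the competition), and each round is
sequenced at ~10^5 reads. The 10^12–10^14 nonbinders are carried as ~100
aggregated lognormal-`k_d` bins, so campaigns at full nominal scale run in
seconds with exact integer molecule counts.

**Analysis.** Reads translate to displayed cores; "positive clones" are
sequences above 2% of a round's reads (top 6–7); clone lists deduplicate
across libraries; equal-length cores cluster into consensus families by
single-linkage Hamming distance; per-round population trajectories and
`k_a`/`k_d` scatter tables come out as plot-ready delimited files.

**Extreme-value model.** With `log10 k_d ~ Normal(μ, σ)` across a random
library, the best binder among N members sits near
`μ + σ·Φ⁻¹(1/(N+1))`, so its expected `log10 k_d` falls linearly in
`log10 N`. `calibrate_sigma` inverts an observed "fold-slowing per decades
of diversity" statement into σ, and `simulate_best_binder` checks the
closed form by Monte Carlo (exact order-statistic sampling for
astronomical N).

## Worked example

```python
from rapidsim.library import TranslationBudget, nnk_theoretical_diversity, ribosome_molecules
from rapidsim.kinetics import KineticParams, dissociation_constant
from rapidsim.evt import EVTParams, calibrate_sigma, simulate_best_binder
from rapidsim.synthetic import FixtureSpec, run_full_study
from rapidsim.selection import family_molecule_fractions

print(f"NNK15 sequence space: {nnk_theoretical_diversity(15):.2e}")
print(f"ribosomes in 150 uL:  {ribosome_molecules(TranslationBudget(150.0)):.2e}")
kd = dissociation_constant(KineticParams(k_a=2.44e5, k_d=51.8e-3))
print(f"K_D of a fast-off clone: {kd*1e9:.0f} nM")

results = run_full_study(FixtureSpec(seed=1))
for lib in ("E6", "E14"):
    res = results[lib]
    rates = " ".join(f"{r.recovery_rate:.1e}" for r in res.rounds)
    fams = family_molecule_fractions(res.rounds[-1].post_state)
    top = max((f for f in fams if f != "background"), key=fams.get)
    print(f"{lib}: recovery per round: {rates}")
    print(f"{lib}: dominant family in round 7: {top} ({fams[top]:.0%})")

sigma = calibrate_sigma(10.0, 7.0, anchor_N=1e6)
s = simulate_best_binder(EVTParams(-1.0, sigma, 1e6), 500, seed=1, method="order-statistic")
l = simulate_best_binder(EVTParams(-1.0, sigma, 1e13), 500, seed=2, method="order-statistic")
print(f"calibrated sigma: {sigma:.3f}")
print(f"best-binder k_d fold-slowing, 1e6 -> 1e13 members: {10**(s.mean-l.mean):.1f}x")
```

prints

```
NNK15 sequence space: 3.78e+22
ribosomes in 150 uL:  1.08e+14
K_D of a fast-off clone: 212 nM
E6: recovery per round: 5.2e-06 5.3e-06 5.7e-06 2.2e-05 5.6e-04 1.4e-03 1.7e-03
E6: dominant family in round 7: F-IV (100%)
E14: recovery per round: 5.2e-06 5.3e-06 1.1e-05 1.3e-03 2.7e-03 2.7e-03 2.7e-03
E14: dominant family in round 7: F-I (97%)
calibrated sigma: 0.385
best-binder k_d fold-slowing, 1e6 -> 1e13 members: 9.7x
```

Reading it: round-1 recovery sits at ~5 × 10⁻⁶ (0.0005%, i.e. diversity
suppressed ~2 × 10⁵-fold) in every library because it is dominated by
nonspecific background. Recovery then rises only once binders enrich —
round 3–4 in the 1.1 × 10¹⁴ library, later in the 2.9 × 10⁶ one. The small
library can only enrich the common fast-off family (F-IV analogue,
`k_d` ≈ 5 × 10⁻² s⁻¹) because the rare slow-off families were never
sampled; the large library sweeps those fast-off families out with slow-off
binders (F-I/F-II analogues, `k_d` ≈ 4 × 10⁻³ s⁻¹). The final lines are the
extreme-value summary of the same phenomenon: ten-fold slower best-binder
`k_d` per seven decades of library diversity.

## Command line

```bash
rapidsim fixtures --seed 1 --out fixtures/          # write a study fixture
rapidsim simulate --seed 1 --out runs/              # 5 libraries x 7 rounds
rapidsim analyze  --counts-dir runs/ --out analysis/ # triage/families/trajectories
rapidsim evt      --seed 1 --out evt.tsv            # best k_d vs library scale
```

All outputs are delimited text with the seed and a config hash embedded in
the header.

## Layout

```
src/rapidsim/
  library.py     construct architecture, translation, scale arithmetic
  kinetics.py    1:1 kinetics, wash survival, sensorgram simulation/fitting
  selection.py   stochastic selection-round simulator
  enrichment.py  read counting, triage, clustering, trajectories
  evt.py         extreme-value statistics of lognormal affinities
  synthetic.py   seeded campaign-fixture generator
  cli.py         command-line entry points
docs/methods.md  model assumptions, calibration, and limitations
```
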