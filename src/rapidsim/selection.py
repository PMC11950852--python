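"""Stochastic round-by-round simulator of an affinity-selection campaign.

One selection round is modelled as four stages acting on integer molecule
counts:

1. **translation sampling** — the mRNA pool is expressed at a fixed ribosome
   budget (one fusion per ribosome); if the pool exceeds the budget it is
   multinomially downsampled.
2. **negative selection** — each molecule is removed with its species'
   nonspecific-binding ("stickiness") probability, once per negative round.
3. **positive selection** — each molecule survives with probability
   ``capture_efficiency * fraction_bound(k_a, k_d, C, t_inc) *
   wash_retention(k_d, n_washes, t_wash) + stickiness * carryover``;
   the recovery rate is recovered/input over all molecules.
4. **PCR amplification** — surviving counts are multinomially rescaled to the
   next round's pool size; each copied base can mutate, spawning tracked
   single-point variant species that re-enter the competition.

Libraries far too diverse to enumerate are represented by ~100 aggregated
background bins holding the nonbinder mass at lognormal-quantile kinetics,
while binder families and their PCR mutants are explicit species. All
randomness flows from one root seed through per-(round, stage) child streams,
so campaigns are bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kinetics import KineticParams, fraction_bound, wash_retention
from .library import DEFAULT_DESIGN, LibraryDesign, translate_display_construct

__all__ = [
    "PeptideSpecies",
    "BackgroundBin",
    "LibraryState",
    "SelectionConfig",
    "RoundResult",
    "CampaignResult",
    "translation_sampling",
    "apply_negative_selection",
    "apply_positive_selection",
    "pcr_amplify",
    "run_campaign",
    "single_point_variants",
    "apply_point_mutation",
    "family_molecule_fractions",
    "BACKGROUND_LABEL",
]

BACKGROUND_LABEL = "background"

#: kinetics assigned to mutants whose construct no longer displays a
#: functional macrocycle (premature stop or lost cyclisation Cys)
DEAD_KINETICS = KineticParams(k_a=10.0, k_d=1.0)

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class PeptideSpecies:
    """A unique selectable species: peptide, optional DNA, kinetics.

    ``family_truth`` carries the generator's ground-truth family label so
    downstream clustering can be scored; PCR mutants inherit it from their
    template.
    """

    id: str
    peptide: str
    kinetics: KineticParams
    dna: Optional[str] = None
    stickiness: float = 0.0
    family_truth: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.stickiness <= 1.0:
            raise ValueError("stickiness must be in [0, 1]")


@dataclass(frozen=True)
class BackgroundBin:
    """Aggregated low-affinity mass at one representative kinetics."""

    kinetics: KineticParams
    stickiness: float = 0.0


@dataclass
class LibraryState:
    """Copy numbers per explicit species plus binned background mass."""

    species: Dict[str, PeptideSpecies] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    background_bins: List[BackgroundBin] = field(default_factory=list)
    background_counts: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.background_bins) != len(self.background_counts):
            raise ValueError("one count per background bin required")
        if any(c < 0 for c in self.counts.values()) or any(
            c < 0 for c in self.background_counts
        ):
            raise ValueError("counts must be nonnegative")

    def total_molecules(self) -> int:
        return sum(self.counts.values()) + sum(self.background_counts)

    def copy(self) -> "LibraryState":
        return LibraryState(
            species=dict(self.species),
            counts=dict(self.counts),
            background_bins=list(self.background_bins),
            background_counts=list(self.background_counts),
        )

    def prune(self) -> "LibraryState":
        """Drop explicit species whose count reached zero (keeps bins)."""
        keep = {sid for sid, c in self.counts.items() if c > 0}
        return LibraryState(
            species={sid: self.species[sid] for sid in keep},
            counts={sid: self.counts[sid] for sid in keep},
            background_bins=list(self.background_bins),
            background_counts=list(self.background_counts),
        )


@dataclass
class SelectionConfig:
    """Round mechanics and their defaults.

    The wash block (3 washes x 20 s) and the effective capture efficiency
    (0.004) are the package's calibration of the verbal selection mechanism:
    together with a background stickiness of ~5e-6 they put round-1,
    background-dominated recovery in the observed 1e-6..1e-5 window and give
    per-round enrichment factors (fast-off binders ~10x, slow-off binders
    ~500x over background) that reproduce the observed round-resolved
    dynamics: recovery rising from round 3-4 in large libraries and later in
    the smallest ones. See the methods note for the calibration argument.
    """

    target_conc: float = 100e-9  # M
    incubation_time: float = 1800.0  # s (30 min)
    n_washes: int = 3
    t_wash: float = 20.0  # s per wash
    capture_efficiency: float = 0.004
    carryover: float = 1.0  # fraction of stickiness surviving the washes
    negative_rounds: int = 1
    pcr_mutation_rate: float = 1e-4  # per base per cycle
    pcr_cycles: int = 15
    transition_weight: float = 3.0  # transition:transversion odds 3:1
    max_mutant_parents: int = 20  # most abundant templates spawn tracked mutants
    mutant_min_parent_copies: int = 1000
    mutant_log10_ka_shift: float = -0.5
    mutant_log10_kd_shift: float = 0.5
    mutant_log10_sd: float = 0.5
    ribosome_budget: int = int(1.8e12)  # molecules per round (2.5 uL scale)
    pcr_target_total: Optional[int] = None  # defaults to ribosome_budget
    read_depth: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.incubation_time <= 0:
            raise ValueError("incubation_time must be positive")
        for name in ("capture_efficiency", "carryover"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.pcr_mutation_rate < 1.0:
            raise ValueError("pcr_mutation_rate must be in [0, 1)")
        if self.n_washes < 0 or self.t_wash < 0 or self.negative_rounds < 0:
            raise ValueError("wash and negative-round settings must be nonnegative")
        if self.ribosome_budget <= 0:
            raise ValueError("ribosome_budget must be positive")


@dataclass
class RoundResult:
    """Positive-selection outcome of one round."""

    round_index: int
    input_total: int
    recovered_total: int
    recovery_rate: float
    post_state: LibraryState
    empty_input: bool = False


@dataclass
class CampaignResult:
    """Per-round results and NGS-style read tables for one library."""

    library: str
    rounds: List[RoundResult]
    read_tables: list  # list[ReadCountTable]

    def recovery_rates(self) -> List[float]:
        return [r.recovery_rate for r in self.rounds]


def _stage_rng(seed: int, round_index: int, stage: int) -> np.random.Generator:
    """Deterministic child stream for one (round, stage) pair."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(round_index, stage))
    )


def _state_vectors(state: LibraryState):
    ids = list(state.counts)
    n_spec = np.array([state.counts[i] for i in ids], dtype=np.int64)
    n_bins = np.array(state.background_counts, dtype=np.int64)
    return ids, n_spec, n_bins


def _rebuild(state: LibraryState, ids, n_spec, n_bins) -> LibraryState:
    return LibraryState(
        species=dict(state.species),
        counts={i: int(c) for i, c in zip(ids, n_spec)},
        background_bins=list(state.background_bins),
        background_counts=[int(c) for c in n_bins],
    ).prune()


def translation_sampling(
    state: LibraryState, ribosome_budget: int, rng: np.random.Generator
) -> LibraryState:
    """Express the pool at the ribosome budget, downsampling if it is larger.

    One ribosome yields one fusion, so a pool of at most ``ribosome_budget``
    molecules passes through unchanged; a larger pool is multinomially
    thinned to the budget (multinomial approximation of the multivariate
    hypergeometric, accurate at these pool sizes).
    """
    if ribosome_budget <= 0:
        raise ValueError("ribosome budget must be positive")
    total = state.total_molecules()
    if total <= ribosome_budget:
        return state.copy()
    ids, n_spec, n_bins = _state_vectors(state)
    n_all = np.concatenate([n_spec, n_bins]).astype(float)
    p = n_all / n_all.sum()
    drawn = rng.multinomial(int(ribosome_budget), p / p.sum())
    return _rebuild(state, ids, drawn[: len(ids)], drawn[len(ids) :])


def apply_negative_selection(
    state: LibraryState, config: SelectionConfig, rng: np.random.Generator
) -> LibraryState:
    """Pre-clear against naked/tag-only beads: removal by stickiness."""
    if config.negative_rounds == 0:
        return state.copy()
    ids, n_spec, n_bins = _state_vectors(state)
    p_keep_spec = np.array(
        [(1.0 - state.species[i].stickiness) ** config.negative_rounds for i in ids]
    )
    p_keep_bins = np.array(
        [(1.0 - b.stickiness) ** config.negative_rounds for b in state.background_bins]
    )
    kept_spec = rng.binomial(n_spec, p_keep_spec) if len(ids) else n_spec
    kept_bins = (
        rng.binomial(n_bins, p_keep_bins) if len(n_bins) else n_bins
    )
    return _rebuild(state, ids, kept_spec, kept_bins)


def _survival_probability(
    kinetics: KineticParams, stickiness: float, config: SelectionConfig
) -> float:
    specific = (
        config.capture_efficiency
        * fraction_bound(kinetics, config.target_conc, config.incubation_time)
        * wash_retention(kinetics.k_d, config.n_washes, config.t_wash)
    )
    return min(1.0, specific + stickiness * config.carryover)


def apply_positive_selection(
    state: LibraryState,
    config: SelectionConfig,
    rng: np.random.Generator,
    round_index: int = 0,
) -> RoundResult:
    """Target-bead capture, incubation and washes; binomial per-copy survival."""
    ids, n_spec, n_bins = _state_vectors(state)
    input_total = int(n_spec.sum() + n_bins.sum())
    if input_total == 0:
        return RoundResult(
            round_index=round_index,
            input_total=0,
            recovered_total=0,
            recovery_rate=0.0,
            post_state=state.copy(),
            empty_input=True,
        )
    p_spec = np.array(
        [
            _survival_probability(state.species[i].kinetics, state.species[i].stickiness, config)
            for i in ids
        ]
    )
    p_bins = np.array(
        [
            _survival_probability(b.kinetics, b.stickiness, config)
            for b in state.background_bins
        ]
    )
    kept_spec = rng.binomial(n_spec, p_spec) if len(ids) else n_spec
    kept_bins = rng.binomial(n_bins, p_bins) if len(n_bins) else n_bins
    recovered = int(kept_spec.sum() + kept_bins.sum())
    return RoundResult(
        round_index=round_index,
        input_total=input_total,
        recovered_total=recovered,
        recovery_rate=recovered / input_total,
        post_state=_rebuild(state, ids, kept_spec, kept_bins),
    )


# ---------------------------------------------------------------------------
# PCR with point mutation


def apply_point_mutation(dna: str, position: int, base: str) -> str:
    """Return ``dna`` with the base at ``position`` replaced by ``base``."""
    if not 0 <= position < len(dna):
        raise ValueError("position outside sequence")
    if base == dna[position]:
        raise ValueError("substitution must change the base")
    return dna[:position] + base + dna[position + 1 :]


def single_point_variants(
    dna: str, transition_weight: float = 3.0, skip_start: bool = True
) -> "tuple[list[tuple[int, str]], np.ndarray]":
    """All single-base substitutions of ``dna`` with transition/transversion weights.

    Substitutions inside the ATG start codon are skipped by default: a
    construct without a start is never displayed, so its copies are treated
    as remaining on the unmutated template.
    """
    variants: List[Tuple[int, str]] = []
    weights: List[float] = []
    start = 3 if skip_start else 0
    for pos in range(start, len(dna)):
        ref = dna[pos]
        for alt in "ACGT":
            if alt == ref:
                continue
            variants.append((pos, alt))
            weights.append(transition_weight if _TRANSITIONS[ref] == alt else 1.0)
    return variants, np.array(weights)


def _mutant_kinetics(
    parent: KineticParams, config: SelectionConfig, rng: np.random.Generator
) -> KineticParams:
    log_ka = math.log10(parent.k_a) + rng.normal(
        config.mutant_log10_ka_shift, config.mutant_log10_sd
    )
    log_kd = math.log10(parent.k_d) + rng.normal(
        config.mutant_log10_kd_shift, config.mutant_log10_sd
    )
    return KineticParams(
        k_a=float(10 ** np.clip(log_ka, 1.0, 8.0)),
        k_d=float(10 ** np.clip(log_kd, -6.0, 2.0)),
    )


def pcr_amplify(
    state: LibraryState,
    config: SelectionConfig,
    target_total: int,
    rng: np.random.Generator,
    design: LibraryDesign = DEFAULT_DESIGN,
) -> LibraryState:
    """Multinomial rescale to ``target_total`` plus per-base point mutation.

    Mutation is tracked explicitly only for the most abundant sequence-bearing
    templates (``max_mutant_parents`` per call): mutants of rarer templates
    would sit far below the sequencing detection floor, so their copies remain
    on the template. A molecule mutates anywhere with probability
    ``1 - (1 - mu)^(L_nt * cycles)``; mutated molecules are spread over
    single-point variants with 3:1 transition:transversion odds (multi-hit
    molecules are counted at their first hit). Variants re-translate and merge
    with existing species or create new ones inheriting the template's
    ground-truth family label.
    """
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    total = state.total_molecules()
    if total == 0:
        return state.copy()
    ids, n_spec, n_bins = _state_vectors(state)
    n_all = np.concatenate([n_spec, n_bins]).astype(float)
    drawn = rng.multinomial(int(target_total), n_all / n_all.sum())
    new_spec = drawn[: len(ids)].astype(np.int64)
    new_bins = drawn[len(ids) :].astype(np.int64)
    out = _rebuild(state, ids, new_spec, new_bins)

    if config.pcr_mutation_rate <= 0 or config.pcr_cycles <= 0:
        return out

    dna_index = {
        sp.dna: sid for sid, sp in out.species.items() if sp.dna is not None
    }
    eligible = sorted(
        (
            sid
            for sid, c in out.counts.items()
            if c >= config.mutant_min_parent_copies and out.species[sid].dna
        ),
        key=lambda sid: (-out.counts[sid], sid),
    )[: config.max_mutant_parents]

    for sid in eligible:
        parent = out.species[sid]
        dna = parent.dna
        assert dna is not None
        n_parent = out.counts[sid]
        p_any = -math.expm1(len(dna) * config.pcr_cycles * math.log1p(-config.pcr_mutation_rate))
        n_mut = int(rng.binomial(n_parent, p_any))
        if n_mut == 0:
            continue
        variants, weights = single_point_variants(dna, config.transition_weight)
        alloc = rng.multinomial(n_mut, weights / weights.sum())
        for (pos, alt), n_v in zip(variants, alloc):
            if n_v == 0:
                continue
            mut_dna = apply_point_mutation(dna, pos, alt)
            result = translate_display_construct(mut_dna, design)
            if result.peptide == parent.peptide and not result.terminated_early:
                continue  # synonymous: molecules stay with the template
            out.counts[sid] -= int(n_v)
            if mut_dna in dna_index:
                out.counts[dna_index[mut_dna]] += int(n_v)
                continue
            if result.terminated_early or (
                design.fixed_cys
                and result.core_peptide is not None
                and not result.core_peptide.endswith("C")
            ):
                kin = DEAD_KINETICS
            else:
                kin = _mutant_kinetics(parent.kinetics, config, rng)
            mut_id = f"{sid}~{pos}{alt}"
            out.species[mut_id] = PeptideSpecies(
                id=mut_id,
                peptide=result.peptide,
                dna=mut_dna,
                kinetics=kin,
                stickiness=parent.stickiness,
                family_truth=parent.family_truth,
            )
            out.counts[mut_id] = int(n_v)
            dna_index[mut_dna] = mut_id
    return out.prune()


def family_molecule_fractions(state: LibraryState) -> "dict[str, float]":
    """Molecule fractions aggregated by ground-truth family label.

    Background bins and species without a truth label are pooled under
    :data:`BACKGROUND_LABEL`.
    """
    total = state.total_molecules()
    if total == 0:
        return {}
    out: Dict[str, float] = {BACKGROUND_LABEL: sum(state.background_counts) / total}
    for sid, c in state.counts.items():
        label = state.species[sid].family_truth or BACKGROUND_LABEL
        out[label] = out.get(label, 0.0) + c / total
    return out


def run_campaign(
    initial: LibraryState,
    config: SelectionConfig,
    n_rounds: int = 7,
    library: str = "library",
    design: LibraryDesign = DEFAULT_DESIGN,
    sample_reads: bool = True,
    expand_background_reads: bool = False,
) -> CampaignResult:
    """Iterate translation -> negative -> positive -> PCR for ``n_rounds``.

    Round 1 is translated at the full scale of the provided pool (campaigns
    size the first translation to cover the library diversity); later rounds
    use ``config.ribosome_budget``. Read tables are multinomial samples of
    each round's recovered pool at ``config.read_depth``.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    from .synthetic import sample_read_counts  # local import: avoids cycle

    pcr_target = config.pcr_target_total or config.ribosome_budget
    state = initial
    rounds: List[RoundResult] = []
    tables = []
    for r in range(1, n_rounds + 1):
        budget = state.total_molecules() if r == 1 else config.ribosome_budget
        state = translation_sampling(
            state, max(budget, 1), _stage_rng(config.rng_seed, r, 0)
        )
        state = apply_negative_selection(state, config, _stage_rng(config.rng_seed, r, 1))
        result = apply_positive_selection(
            state, config, _stage_rng(config.rng_seed, r, 2), round_index=r
        )
        rounds.append(result)
        if sample_reads:
            tables.append(
                sample_read_counts(
                    result.post_state,
                    config.read_depth,
                    _stage_rng(config.rng_seed, r, 4),
                    design=design,
                    expand_background=expand_background_reads,
                    library=library,
                    round_index=r,
                )
            )
        if r < n_rounds:
            state = pcr_amplify(
                result.post_state,
                config,
                pcr_target,
                _stage_rng(config.rng_seed, r, 3),
                design=design,
            )
    return CampaignResult(library=library, rounds=rounds, read_tables=tables)
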