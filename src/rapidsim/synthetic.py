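"""Seeded generator of complete, ground-truth-labelled campaign fixtures.

The generator emulates the structure of a five-library selection study:

* five subsets at diversities 2.9e6 / 2.5e8 / 2.2e10 / 3.6e12 / 1.1e14 in two
  independent sampling lineages (group 1: E14 -> E10 -> E6; group 2:
  E12 -> E8), each translated in round 1 at a ribosome budget covering its
  diversity;
* four planted binder families whose centre kinetics are the study-style
  log-scale family averages, each realised as a handful of sequence variants
  around a family reference motif; a family's expected copy number scales
  with library diversity, so rare families drop out of small subsets by
  Poisson sampling — the mechanism that makes library scale matter;
* lognormally distributed background dissociation rates aggregated into ~100
  equal-mass kinetic bins standing in for the astronomically many nonbinders
  (explicit species are only the planted binders and their PCR mutants);
* seven selection rounds and sequencing at ~1e5 reads per round.

Everything is a deterministic function of (spec, seed); regenerating a
fixture is bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .enrichment import ReadCountTable
from .kinetics import KineticParams
from .library import (
    DEFAULT_DESIGN,
    LINKER_DNA,
    LibraryDesign,
    NNK_CODONS,
    translate_display_construct,
    write_constructs_fasta,
)
from .selection import (
    BackgroundBin,
    CampaignResult,
    LibraryState,
    PeptideSpecies,
    SelectionConfig,
    run_campaign,
)

__all__ = [
    "FamilySpec",
    "LibraryScale",
    "FixtureSpec",
    "CampaignFixture",
    "DEFAULT_FAMILIES",
    "DEFAULT_LIBRARIES",
    "generate_planted_library",
    "generate_campaign_fixture",
    "sample_read_counts",
    "write_fixture",
    "load_fixture",
    "run_full_study",
]


@dataclass(frozen=True)
class FamilySpec:
    """A planted binder family.

    ``frequency`` is the family's share of NNK sequence space that is
    functionally a member, so a library of diversity D samples
    ``Poisson(frequency * D)`` member molecules, split over ``n_members``
    tracked variants. ``k_a_center``/``k_d_center`` are the family's
    geometric-mean kinetics; members jitter around them by
    ``member_jitter_log10`` in log10.
    """

    name: str
    k_a_center: float
    k_d_center: float
    frequency: float
    n_members: int = 6
    member_jitter_log10: float = 0.15
    max_member_mutations: int = 2


#: Family centres follow the study-style log-averages of the four consensus
#: families: two slow-off families (the strong binders), one intermediate and
#: one fast-off family. Frequencies are set so that the fast-off family is
#: sampled even at 2.9e6 diversity while the slow-off families need >= ~1e8
#: (F-I) or >= ~1e10 (F-II) members to be sampled at all — the sampling-loss
#: mechanism under study.
DEFAULT_FAMILIES: Tuple[FamilySpec, ...] = (
    FamilySpec("F-I", k_a_center=5.9e5, k_d_center=4.2e-3, frequency=8e-9),
    FamilySpec("F-II", k_a_center=1.1e5, k_d_center=4.5e-3, frequency=4e-10),
    FamilySpec("F-III", k_a_center=5.7e5, k_d_center=45e-3, frequency=2e-8),
    FamilySpec("F-IV", k_a_center=2.4e5, k_d_center=52e-3, frequency=2e-6),
)


@dataclass(frozen=True)
class LibraryScale:
    """One library subset: nominal diversity and round-1 translation budget."""

    name: str
    diversity: float
    round1_budget: int
    group: str
    parent: Optional[str] = None


DEFAULT_LIBRARIES: Tuple[LibraryScale, ...] = (
    LibraryScale("E6", 2.9e6, int(1.8e12), "group1", parent="E10"),
    LibraryScale("E8", 2.5e8, int(1.8e12), "group2", parent="E12"),
    LibraryScale("E10", 2.2e10, int(1.8e12), "group1", parent="E14"),
    LibraryScale("E12", 3.6e12, int(3.6e12), "group2"),
    LibraryScale("E14", 1.1e14, int(1.1e14), "group1"),
)


@dataclass
class FixtureSpec:
    """Everything needed to regenerate a study fixture deterministically."""

    libraries: Tuple[LibraryScale, ...] = DEFAULT_LIBRARIES
    families: Tuple[FamilySpec, ...] = DEFAULT_FAMILIES
    rounds: int = 7
    read_depth: int = 100_000
    background_mu: float = -1.0  # mean log10 k_d of nonbinders
    background_sigma: float = 0.5
    background_k_a: float = 1e2  # M^-1 s^-1, well below the binding threshold
    background_bins: int = 100
    background_stickiness: float = 5e-6
    min_reference_distance: int = 13  # residues, between family references
    exclude_amber: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if any(lib.diversity <= 0 for lib in self.libraries):
            raise ValueError("library diversities must be positive")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class CampaignFixture:
    """Generated initial states, configs and ground truth for all libraries."""

    spec: FixtureSpec
    states: Dict[str, LibraryState]
    configs: Dict[str, SelectionConfig]
    truth: Dict[str, Dict[str, str]]  # library -> species id -> family name


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _random_codons(
    rng: np.random.Generator, n: int, exclude_amber: bool
) -> List[str]:
    pool = sorted(NNK_CODONS - ({"TAG"} if exclude_amber else set()))
    return [pool[i] for i in rng.integers(0, len(pool), size=n)]


def _member_dna(
    reference_codons: Sequence[str],
    n_sub: int,
    rng: np.random.Generator,
    exclude_amber: bool,
) -> List[str]:
    codons = list(reference_codons)
    if n_sub > 0:
        positions = rng.choice(len(codons), size=n_sub, replace=False)
        for pos in positions:
            new = _random_codons(rng, 1, exclude_amber)[0]
            while new == codons[pos]:
                new = _random_codons(rng, 1, exclude_amber)[0]
            codons[int(pos)] = new
    return codons


def _family_variant_pools(
    spec: FixtureSpec, design: LibraryDesign
) -> Dict[str, Dict[str, List[PeptideSpecies]]]:
    """Per sampling group, per family: the tracked member variant species.

    Family references within a group are resampled until their peptide cores
    are pairwise >= ``min_reference_distance`` apart, and members carry at
    most ``max_member_mutations`` codon substitutions, so single-linkage
    clustering at the default mismatch threshold provably recovers the
    planted partition. Groups draw independently, mirroring separated
    sampling spaces.
    """
    groups = sorted({lib.group for lib in spec.libraries})
    pools: Dict[str, Dict[str, List[PeptideSpecies]]] = {}
    for g_idx, group in enumerate(groups):
        rng = _rng(spec.seed, 0, g_idx)
        references: List[List[str]] = []
        ref_peptides: List[str] = []
        for fam in spec.families:
            while True:
                codons = _random_codons(rng, design.random_codon_count, spec.exclude_amber)
                dna = "ATG" + "".join(codons) + "TGT"
                pep = translate_display_construct(dna, design).core_peptide
                assert pep is not None
                core = pep[1:-1]  # random region only
                if all(
                    sum(a != b for a, b in zip(core, prev))
                    >= spec.min_reference_distance
                    for prev in ref_peptides
                ):
                    references.append(codons)
                    ref_peptides.append(core)
                    break
        pools[group] = {}
        for fam, ref in zip(spec.families, references):
            members: List[PeptideSpecies] = []
            seen_dna = set()
            while len(members) < fam.n_members:
                n_sub = int(rng.integers(0, fam.max_member_mutations + 1))
                codons = _member_dna(ref, n_sub, rng, spec.exclude_amber)
                dna = "ATG" + "".join(codons) + "TGT"
                if dna in seen_dna:
                    continue
                seen_dna.add(dna)
                pep = translate_display_construct(dna, design).peptide
                kin = KineticParams(
                    k_a=float(
                        10
                        ** (math.log10(fam.k_a_center) + rng.normal(0, fam.member_jitter_log10))
                    ),
                    k_d=float(
                        10
                        ** (math.log10(fam.k_d_center) + rng.normal(0, fam.member_jitter_log10))
                    ),
                )
                members.append(
                    PeptideSpecies(
                        id=f"{group}:{fam.name}.m{len(members) + 1}",
                        peptide=pep,
                        dna=dna,
                        kinetics=kin,
                        stickiness=spec.background_stickiness,
                        family_truth=fam.name,
                    )
                )
            pools[group][fam.name] = members
    return pools


def _background_bins(spec: FixtureSpec) -> List[BackgroundBin]:
    from scipy.special import ndtri

    qs = (np.arange(spec.background_bins) + 0.5) / spec.background_bins
    return [
        BackgroundBin(
            kinetics=KineticParams(
                k_a=spec.background_k_a,
                k_d=float(10 ** (spec.background_mu + spec.background_sigma * ndtri(q))),
            ),
            stickiness=spec.background_stickiness,
        )
        for q in qs
    ]


def generate_planted_library(
    spec: FixtureSpec,
    library: Union[str, int],
    design: LibraryDesign = DEFAULT_DESIGN,
) -> Tuple[LibraryState, Dict[str, str]]:
    """Round-1 pool for one library plus its ground-truth family map.

    Each family member is sampled as ``Poisson(frequency * D / n_members)``
    sequence variants; the member's round-1 copy number scales that by the
    per-sequence copy depth ``budget / D`` of the round-1 translation. The
    remaining budget is background, split equally over the lognormal kinetic
    bins. Smaller libraries therefore lose rare families entirely with
    probability ``exp(-frequency * D)``.
    """
    if isinstance(library, int):
        lib = spec.libraries[library]
    else:
        matches = [l for l in spec.libraries if l.name == library]
        if not matches:
            raise ValueError(f"unknown library {library!r}")
        lib = matches[0]
    lib_index = list(spec.libraries).index(lib)
    rng = _rng(spec.seed, 1, lib_index)
    pools = _family_variant_pools(spec, design)[lib.group]
    copies_per_sequence = lib.round1_budget / lib.diversity

    bins = _background_bins(spec)
    state = LibraryState(
        background_bins=bins, background_counts=[0] * len(bins)
    )
    truth: Dict[str, str] = {}
    planted_total = 0
    for fam in spec.families:
        lam_member = fam.frequency * lib.diversity / fam.n_members
        for member in pools[fam.name]:
            n_variants = int(rng.poisson(lam_member))
            if n_variants == 0:
                continue
            copies = int(round(n_variants * copies_per_sequence))
            if copies == 0:
                continue
            state.species[member.id] = member
            state.counts[member.id] = copies
            truth[member.id] = fam.name
            planted_total += copies
    remaining = max(lib.round1_budget - planted_total, 0)
    n_bins = spec.background_bins
    per_bin, extra = divmod(remaining, n_bins)
    state.background_counts = [
        int(per_bin + (1 if i < extra else 0)) for i in range(n_bins)
    ]
    return state, truth


def generate_campaign_fixture(
    spec: FixtureSpec = FixtureSpec(),
    design: LibraryDesign = DEFAULT_DESIGN,
    outdir: Optional[Union[str, Path]] = None,
) -> CampaignFixture:
    """Bundle round-1 states, per-library configs and ground truth.

    When ``outdir`` is given the fixture is also written to disk in the
    package's delimited formats (see :func:`write_fixture`).
    """
    states: Dict[str, LibraryState] = {}
    truth: Dict[str, Dict[str, str]] = {}
    configs: Dict[str, SelectionConfig] = {}
    for i, lib in enumerate(spec.libraries):
        state, lib_truth = generate_planted_library(spec, lib.name, design)
        states[lib.name] = state
        truth[lib.name] = lib_truth
        configs[lib.name] = SelectionConfig(
            rng_seed=(spec.seed * 1009 + i) % (2**31),
            read_depth=spec.read_depth,
        )
    fixture = CampaignFixture(spec=spec, states=states, configs=configs, truth=truth)
    if outdir is not None:
        write_fixture(fixture, outdir)
    return fixture


def sample_read_counts(
    state: LibraryState,
    depth: int,
    seed: Union[int, np.random.Generator, None] = None,
    design: LibraryDesign = DEFAULT_DESIGN,
    expand_background: bool = False,
    library: str = "",
    round_index: int = 0,
) -> ReadCountTable:
    """Multinomial sample of ``depth`` reads from the pool's fractions.

    Background-bin reads either stay aggregated under reserved
    ``__background:<bin>`` keys (fast, the default) or, with
    ``expand_background=True``, are expanded into freshly drawn random NNK
    core peptides so the table looks like real sequencing output in which
    nonbinders are a sea of singletons.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(state.counts)
    n_spec = np.array([state.counts[i] for i in ids], dtype=float)
    n_bins = np.array(state.background_counts, dtype=float)
    total = n_spec.sum() + n_bins.sum()
    if total <= 0:
        return ReadCountTable(
            counts={}, library=library, round_index=round_index, empty=True
        )
    p = np.concatenate([n_spec, n_bins]) / total
    draw = rng.multinomial(int(depth), p / p.sum())
    counts: Dict[str, int] = {}
    for sid, c in zip(ids, draw[: len(ids)]):
        if c > 0:
            pep = state.species[sid].peptide
            counts[pep] = counts.get(pep, 0) + int(c)
    bin_reads = draw[len(ids) :]
    n_background = int(bin_reads.sum())
    if n_background > 0:
        if expand_background:
            pool = sorted(NNK_CODONS - {"TAG"})
            aa = [translate_display_construct("ATG" + c + "TGT", LibraryDesign(random_codon_count=1)).peptide[1] for c in pool]
            idx = rng.integers(0, len(pool), size=(n_background, design.random_codon_count))
            arr = np.array(aa)[idx]
            for row in arr:
                pep = design.initiator_symbol + "".join(row) + ("C" if design.fixed_cys else "")
                counts[pep] = counts.get(pep, 0) + 1
        else:
            for b, c in enumerate(bin_reads):
                if c > 0:
                    counts[f"__background:{b}"] = int(c)
    return ReadCountTable(counts=counts, library=library, round_index=round_index)


# ---------------------------------------------------------------------------
# Fixture persistence (delimited text only)


def write_fixture(fixture: CampaignFixture, outdir: Union[str, Path]) -> None:
    """Write a fixture as FASTA + TSV + YAML under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = fixture.spec
    meta = {
        "seed": spec.seed,
        "rounds": spec.rounds,
        "read_depth": spec.read_depth,
        "background": {
            "mu": spec.background_mu,
            "sigma": spec.background_sigma,
            "k_a": spec.background_k_a,
            "bins": spec.background_bins,
            "stickiness": spec.background_stickiness,
        },
        "libraries": [
            {
                "name": l.name,
                "diversity": l.diversity,
                "round1_budget": l.round1_budget,
                "group": l.group,
                "parent": l.parent,
            }
            for l in spec.libraries
        ],
        "families": [
            {
                "name": f.name,
                "k_a_center": f.k_a_center,
                "k_d_center": f.k_d_center,
                "frequency": f.frequency,
                "n_members": f.n_members,
                "member_jitter_log10": f.member_jitter_log10,
                "max_member_mutations": f.max_member_mutations,
            }
            for f in spec.families
        ],
    }
    with open(outdir / "fixture.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    for lib, state in fixture.states.items():
        rows = [
            {
                "id": sid,
                "peptide": sp.peptide,
                "dna": sp.dna or "",
                "count": state.counts[sid],
                "k_a": sp.kinetics.k_a,
                "k_d": sp.kinetics.k_d,
                "stickiness": sp.stickiness,
                "family": sp.family_truth or "",
            }
            for sid, sp in sorted(state.species.items())
        ]
        pd.DataFrame(
            rows,
            columns=["id", "peptide", "dna", "count", "k_a", "k_d", "stickiness", "family"],
        ).to_csv(outdir / f"{lib}.species.tsv", sep="\t", index=False, float_format="%.17g")
        pd.DataFrame(
            {
                "bin": range(len(state.background_bins)),
                "k_a": [b.kinetics.k_a for b in state.background_bins],
                "k_d": [b.kinetics.k_d for b in state.background_bins],
                "stickiness": [b.stickiness for b in state.background_bins],
                "count": state.background_counts,
            }
        ).to_csv(outdir / f"{lib}.background.tsv", sep="\t", index=False, float_format="%.17g")
        write_constructs_fasta(
            outdir / f"{lib}.fasta",
            {sid: (sp.dna or "") + LINKER_DNA for sid, sp in sorted(state.species.items()) if sp.dna},
        )


def load_fixture(outdir: Union[str, Path]) -> CampaignFixture:
    """Reload a fixture written by :func:`write_fixture` (bit-exact)."""
    outdir = Path(outdir)
    with open(outdir / "fixture.yaml") as fh:
        meta = yaml.safe_load(fh)
    spec = FixtureSpec(
        libraries=tuple(
            LibraryScale(
                name=l["name"],
                diversity=float(l["diversity"]),
                round1_budget=int(l["round1_budget"]),
                group=l["group"],
                parent=l.get("parent"),
            )
            for l in meta["libraries"]
        ),
        families=tuple(
            FamilySpec(
                name=f["name"],
                k_a_center=float(f["k_a_center"]),
                k_d_center=float(f["k_d_center"]),
                frequency=float(f["frequency"]),
                n_members=int(f["n_members"]),
                member_jitter_log10=float(f["member_jitter_log10"]),
                max_member_mutations=int(f["max_member_mutations"]),
            )
            for f in meta["families"]
        ),
        rounds=int(meta["rounds"]),
        read_depth=int(meta["read_depth"]),
        background_mu=float(meta["background"]["mu"]),
        background_sigma=float(meta["background"]["sigma"]),
        background_k_a=float(meta["background"]["k_a"]),
        background_bins=int(meta["background"]["bins"]),
        background_stickiness=float(meta["background"]["stickiness"]),
        seed=int(meta["seed"]),
    )
    states: Dict[str, LibraryState] = {}
    truth: Dict[str, Dict[str, str]] = {}
    configs: Dict[str, SelectionConfig] = {}
    for i, lib in enumerate(spec.libraries):
        species_df = pd.read_csv(
            outdir / f"{lib.name}.species.tsv",
            sep="\t",
            keep_default_na=False,
            float_precision="round_trip",
        )
        bg_df = pd.read_csv(
            outdir / f"{lib.name}.background.tsv",
            sep="\t",
            float_precision="round_trip",
        )
        state = LibraryState(
            background_bins=[
                BackgroundBin(
                    kinetics=KineticParams(k_a=row.k_a, k_d=row.k_d),
                    stickiness=row.stickiness,
                )
                for row in bg_df.itertuples()
            ],
            background_counts=[int(c) for c in bg_df["count"]],
        )
        lib_truth: Dict[str, str] = {}
        for row in species_df.itertuples():
            sp = PeptideSpecies(
                id=row.id,
                peptide=row.peptide,
                dna=row.dna or None,
                kinetics=KineticParams(k_a=row.k_a, k_d=row.k_d),
                stickiness=row.stickiness,
                family_truth=row.family or None,
            )
            state.species[sp.id] = sp
            state.counts[sp.id] = int(row.count)
            if sp.family_truth:
                lib_truth[sp.id] = sp.family_truth
        states[lib.name] = state
        truth[lib.name] = lib_truth
        configs[lib.name] = SelectionConfig(
            rng_seed=(spec.seed * 1009 + i) % (2**31), read_depth=spec.read_depth
        )
    return CampaignFixture(spec=spec, states=states, configs=configs, truth=truth)


def run_full_study(
    spec: FixtureSpec = FixtureSpec(),
    design: LibraryDesign = DEFAULT_DESIGN,
    expand_background_reads: bool = False,
) -> Dict[str, CampaignResult]:
    """Generate the fixture and run every library's campaign."""
    fixture = generate_campaign_fixture(spec, design)
    return {
        lib.name: run_campaign(
            fixture.states[lib.name],
            fixture.configs[lib.name],
            n_rounds=spec.rounds,
            library=lib.name,
            design=design,
            expand_background_reads=expand_background_reads,
        )
        for lib in spec.libraries
    }
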