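"""Construct architecture and scale arithmetic for mRNA-display peptide libraries.

An mRNA-display library expresses macrocyclic peptides from a fixed construct:
an initiator codon reprogrammed to N-chloroacetyl-L-tyrosine, a randomised
``(NNK)_L`` region, a downstream Cys codon used for thioether macrocyclisation,
and a short Ser-Gly-Gly-Leu-Thr-Asn linker that stops frameshifted products.
This module encodes that architecture, translates construct DNA/RNA into the
displayed peptide core, and provides the combinatorial arithmetic used to plan
a selection campaign: NNK sequence-space size, ribosome and mRNA budgets under
the one-fusion-per-ribosome (monosome) assumption, diversity suppression by a
selection round, and the expected diversity of diluted daughter libraries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AVOGADRO",
    "NNK_CODONS",
    "LINKER_DNA",
    "LibraryDesign",
    "DEFAULT_DESIGN",
    "LibrarySubset",
    "TranslationBudget",
    "TranslationResult",
    "MalformedConstructError",
    "nnk_theoretical_diversity",
    "ribosome_molecules",
    "required_mrna_pmol",
    "translate_display_construct",
    "diversity_suppression",
    "derive_subset",
    "expected_unique",
    "normalize_nucleotides",
    "read_constructs_fasta",
    "write_constructs_fasta",
    "load_subset_lineage",
    "dump_subset_lineage",
]

AVOGADRO = 6.022e23  # molecules per mole

_CODON_TABLE = unambiguous_dna_by_id[1]
_FORWARD = dict(_CODON_TABLE.forward_table)
_STOPS = frozenset(_CODON_TABLE.stop_codons)  # {"TAA", "TAG", "TGA"}

#: the 32 NNK codons: N in {A,C,G,T} at positions 1-2, K in {G,T} at position 3
NNK_CODONS = frozenset(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"
)

#: DNA encoding of the Ser-Gly-Gly-Leu-Thr-Asn linker (UCC-GGC-GGA-UUA-ACU-AAC)
LINKER_DNA = "TCCGGCGGATTAACTAAC"


class MalformedConstructError(ValueError):
    """Raised when a construct sequence violates the fixed architecture."""


def normalize_nucleotides(seq: str) -> str:
    """Uppercase, strip whitespace, and map RNA U to the internal T alphabet."""
    return "".join(seq.split()).upper().replace("U", "T")


@dataclass(frozen=True)
class LibraryDesign:
    """The fixed display-construct architecture.

    Parameters
    ----------
    random_codon_count : int
        Number of NNK codons in the randomised region (15 in the study design).
    initiator_symbol : str
        One-letter token for the reprogrammed initiator residue
        (N-chloroacetyl-L-Tyr); lowercase ``y`` by default so it is
        distinguishable from genetically encoded Tyr.
    fixed_cys : bool
        Whether the downstream TGT Cys codon (macrocyclisation anchor) is part
        of the core.
    linker_peptide : str
        Residues of the C-terminal linker, decoded from :data:`LINKER_DNA`.
    """

    random_codon_count: int = 15
    initiator_symbol: str = "y"
    fixed_cys: bool = True
    linker_peptide: str = "SGGLTN"
    degenerate_alphabet: frozenset = field(default=NNK_CODONS, repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.random_codon_count, int) or self.random_codon_count < 0:
            raise ValueError("random_codon_count must be a nonnegative integer")
        if len(self.degenerate_alphabet) != 32:
            raise ValueError("NNK codon set must have exactly 32 members")
        decoded = str(Seq(LINKER_DNA).translate())
        if self.linker_peptide != decoded:
            raise ValueError(
                f"linker_peptide {self.linker_peptide!r} does not decode from "
                f"{LINKER_DNA} (= {decoded!r})"
            )

    @property
    def core_length(self) -> int:
        """Residue length of the displayed core: initiator + random + Cys."""
        return 1 + self.random_codon_count + (1 if self.fixed_cys else 0)

    @property
    def core_nt_length(self) -> int:
        """Nucleotide length of the core coding region (ATG..TGT inclusive)."""
        return 3 * (1 + self.random_codon_count + (1 if self.fixed_cys else 0))


DEFAULT_DESIGN = LibraryDesign()


@dataclass
class LibrarySubset:
    """A sampled library subset (e.g. E6..E14) in a dilution lineage.

    ``estimated_diversity`` is kept as a real number: the study's largest
    subsets exceed exact-integer comfort (1.1e14 members out of a 3.8e22
    sequence space) and the stated endpoint diversities were measured rather
    than derived, so they are stored verbatim.
    """

    name: str
    estimated_diversity: float
    parent: Optional[str] = None
    dilution_factor: float = 1.0
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.estimated_diversity <= 0:
            raise ValueError("estimated_diversity must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class TranslationBudget:
    """An in vitro translation reaction sized by volume and ribosome content."""

    volume_ul: float
    ribosome_conc_pmol_per_ul: float = 1.2

    def __post_init__(self) -> None:
        if self.volume_ul < 0:
            raise ValueError("volume must be nonnegative")
        if self.ribosome_conc_pmol_per_ul <= 0:
            raise ValueError("ribosome concentration must be positive")


def nnk_theoretical_diversity(random_codon_count: int) -> float:
    """DNA-level sequence-space size ``32**L`` of an (NNK)_L region.

    Returns an exact integer when representable in a float without loss
    (L <= 10); larger values are the correctly rounded real.
    """
    if not isinstance(random_codon_count, int) or isinstance(random_codon_count, bool):
        raise ValueError("random codon count must be an integer")
    if random_codon_count < 0:
        raise ValueError("random codon count must be nonnegative")
    return float(32**random_codon_count)


def ribosome_molecules(budget: TranslationBudget) -> float:
    """Number of ribosomes (hence displayable fusions) in the reaction."""
    return budget.volume_ul * budget.ribosome_conc_pmol_per_ul * 1e-12 * AVOGADRO


def required_mrna_pmol(budget: TranslationBudget) -> float:
    """pmol of mRNA saturating every ribosome exactly once.

    Under the monosome assumption each short mRNA engages one ribosome and
    yields one peptide-mRNA fusion, so the mRNA input must equal the ribosome
    content of the reaction.
    """
    return budget.volume_ul * budget.ribosome_conc_pmol_per_ul


def diversity_suppression(recovery_rate: float) -> float:
    """Fold-suppression of sequence diversity implied by a recovery rate.

    A round that recovers a fraction ``r`` of input molecules can retain at
    most ``r`` of the unique sequences, i.e. diversity shrinks by ``1/r``.
    """
    if not 0 < recovery_rate <= 1:
        raise ValueError("recovery_rate must be in (0, 1]")
    return 1.0 / recovery_rate


def expected_unique(diversity: float, n_sampled: float) -> float:
    """Expected unique sequences when drawing ``n_sampled`` molecules.

    Poissonization of sampling-with-replacement from ``diversity`` equally
    abundant sequences: ``D * (1 - exp(-n/D))``.
    """
    if diversity <= 0:
        raise ValueError("diversity must be positive")
    if n_sampled < 0:
        raise ValueError("sample size must be nonnegative")
    return diversity * -math.expm1(-n_sampled / diversity)


def derive_subset(
    parent: LibrarySubset,
    dilution_factor: float,
    name: Optional[str] = None,
    group: Optional[str] = None,
) -> LibrarySubset:
    """Daughter subset obtained by diluting the parent ``dilution_factor``-fold.

    At one copy per sequence in the parent pool, taking a ``1/dilution_factor``
    aliquot retains each sequence independently, so the expected daughter
    diversity is ``expected_unique(D, D / dilution_factor)``. A factor of
    exactly 1 takes the whole library and is an identity.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if dilution_factor == 1:
        child_diversity = parent.estimated_diversity
    else:
        child_diversity = expected_unique(
            parent.estimated_diversity, parent.estimated_diversity / dilution_factor
        )
    return LibrarySubset(
        name=name or f"{parent.name}/{dilution_factor:g}",
        estimated_diversity=child_diversity,
        parent=parent.name,
        dilution_factor=dilution_factor,
        group=group if group is not None else parent.group,
    )


@dataclass(frozen=True)
class TranslationResult:
    """Outcome of translating one display construct.

    ``stop_index`` is the codon index (0-based, counting the initiator as 0)
    of the first in-frame stop, or None. ``non_nnk_positions`` lists
    random-region codon indices whose codon is not a legal NNK member.
    """

    peptide: str
    codons: tuple
    stop_index: Optional[int]
    non_nnk_positions: tuple
    design: LibraryDesign = field(repr=False, default=DEFAULT_DESIGN)

    @property
    def terminated_early(self) -> bool:
        return self.stop_index is not None

    @property
    def stop_in_random_region(self) -> bool:
        return (
            self.stop_index is not None
            and 1 <= self.stop_index <= self.design.random_codon_count
        )

    @property
    def core_peptide(self) -> Optional[str]:
        """Displayed core (initiator + random region + Cys) when complete."""
        if len(self.peptide) < self.design.core_length:
            return None
        return self.peptide[: self.design.core_length]


def translate_display_construct(
    sequence: str, design: LibraryDesign = DEFAULT_DESIGN
) -> TranslationResult:
    """Translate a display construct, honouring the reprogrammed initiator.

    Standard-table translation except that the obligatory AUG start is decoded
    as the initiator token (N-chloroacetyl-Tyr). An in-frame stop terminates
    translation and is flagged; random-region codons that are not legal NNK
    members are flagged. Accepts DNA or RNA, case-insensitive, with optional
    whitespace.
    """
    seq = normalize_nucleotides(sequence)
    if len(seq) % 3 != 0:
        raise MalformedConstructError(
            f"sequence length {len(seq)} is not a multiple of 3"
        )
    if len(seq) == 0 or seq[:3] != "ATG":
        raise MalformedConstructError("construct must start with AUG")
    codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    random_region = range(1, 1 + design.random_codon_count)
    residues = [design.initiator_symbol]
    non_nnk = []
    stop_index: Optional[int] = None
    for i, codon in enumerate(codons[1:], start=1):
        if i in random_region and codon not in design.degenerate_alphabet:
            non_nnk.append(i)
        if codon in _STOPS:
            stop_index = i
            break
        try:
            residues.append(_FORWARD[codon])
        except KeyError as exc:
            raise MalformedConstructError(f"invalid codon {codon!r}") from exc
    return TranslationResult(
        peptide="".join(residues),
        codons=codons,
        stop_index=stop_index,
        non_nnk_positions=tuple(non_nnk),
        design=design,
    )


# ---------------------------------------------------------------------------
# External interfaces: FASTA for construct DNA; YAML for subset lineages.


def read_constructs_fasta(path) -> "dict[str, str]":
    """Read construct DNA from FASTA as an ordered id -> sequence mapping."""
    return {
        rec.id: normalize_nucleotides(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_constructs_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(normalize_nucleotides(s)), id=name, description="")
        for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def load_subset_lineage(path) -> "dict[str, LibrarySubset]":
    """Load a subset lineage from YAML and validate its forest structure."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    subsets = {
        entry["name"]: LibrarySubset(
            name=entry["name"],
            estimated_diversity=float(entry["estimated_diversity"]),
            parent=entry.get("parent"),
            dilution_factor=float(entry.get("dilution_factor", 1.0)),
            group=entry.get("group"),
        )
        for entry in raw
    }
    _validate_lineage(subsets)
    return subsets


def dump_subset_lineage(path, subsets: Mapping[str, LibrarySubset]) -> None:
    _validate_lineage(dict(subsets))
    payload = [
        {
            "name": s.name,
            "estimated_diversity": s.estimated_diversity,
            "parent": s.parent,
            "dilution_factor": s.dilution_factor,
            "group": s.group,
        }
        for s in subsets.values()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _validate_lineage(subsets: "dict[str, LibrarySubset]") -> None:
    for s in subsets.values():
        if s.parent is not None:
            if s.parent not in subsets:
                raise ValueError(f"{s.name}: unknown parent {s.parent!r}")
            parent = subsets[s.parent]
            if s.estimated_diversity > parent.estimated_diversity:
                raise ValueError(
                    f"{s.name}: child diversity exceeds parent {s.parent}"
                )
            if s.dilution_factor <= 1:
                raise ValueError(
                    f"{s.name}: derived subsets require dilution_factor > 1"
                )
        # forest check: walk to the root, detecting cycles
        seen = {s.name}
        node = s
        while node.parent is not None:
            if node.parent in seen:
                raise ValueError(f"lineage cycle involving {node.parent!r}")
            seen.add(node.parent)
            node = subsets[node.parent]


def enumerate_nnk_peptides(length: int) -> Iterable[str]:
    """Brute-force enumeration of NNK codon strings of ``length`` codons.

    Intended for small lengths only (32**L combinations).
    """
    for combo in itertools.product(sorted(NNK_CODONS), repeat=length):
        yield "".join(combo)
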