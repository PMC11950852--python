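"""NGS-side analysis of selection rounds.

Reads are translated into displayed peptide cores and aggregated into
per-round count tables; "positive clones" are triaged with the abundance
criterion (read fraction above a threshold, 2% by default, capped at the top
6-7 clones); clone lists are deduplicated across libraries; equal-length
cores are clustered into consensus families by single-linkage on Hamming
distance; and per-round population trajectories and kinetic scatter tables
are assembled for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .kinetics import KineticParams
from .library import DEFAULT_DESIGN, LibraryDesign, MalformedConstructError, translate_display_construct

__all__ = [
    "ReadCountTable",
    "ReadFilterStats",
    "TriageConfig",
    "Family",
    "FamilyAssignment",
    "DedupResult",
    "counts_from_reads",
    "triage_positive_clones",
    "detection_floor",
    "deduplicate_across_libraries",
    "cluster_families",
    "population_trajectories",
    "kinetic_scatter_table",
]


@dataclass
class ReadCountTable:
    """Read counts per displayed peptide for one library and round."""

    counts: Dict[str, int]
    library: str = ""
    round_index: int = 0
    empty: bool = False

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("read counts must be nonnegative")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> Dict[str, float]:
        total = self.total_reads
        return {s: c / total for s, c in self.counts.items()} if total else {}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sequence": list(self.counts), "count": list(self.counts.values())}
        )
        df.insert(0, "round", self.round_index)
        df.insert(0, "library", self.library)
        total = self.total_reads
        df["fraction"] = df["count"] / total if total else 0.0
        return df.sort_values(
            ["count", "sequence"], ascending=[False, True], ignore_index=True
        )


@dataclass
class ReadFilterStats:
    """Exclusion tallies from read-to-count conversion."""

    n_reads: int = 0
    n_bad_length: int = 0
    n_bad_start: int = 0
    n_premature_stop: int = 0
    n_short_core: int = 0
    n_non_nnk: int = 0  # kept, but tallied
    n_valid: int = 0


@dataclass(frozen=True)
class TriageConfig:
    """The positive-clone triage rule: fraction threshold plus a clone cap."""

    abundance_threshold: float = 0.02
    max_clones: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.abundance_threshold < 1.0:
            raise ValueError("abundance_threshold must be in (0, 1)")
        if self.max_clones < 1:
            raise ValueError("max_clones must be >= 1")


def counts_from_reads(
    source,
    design: LibraryDesign = DEFAULT_DESIGN,
    fmt: str = "fasta",
    library: str = "",
    round_index: int = 0,
) -> "tuple[ReadCountTable, ReadFilterStats]":
    """Translate reads and aggregate identical displayed cores.

    Reads whose frame is broken (length not a multiple of 3, missing AUG
    start), that stop before the core is complete, or that are too short for
    the full core are discarded with tallies; reads containing non-NNK
    random-region codons are kept but counted.
    """
    stats = ReadFilterStats()
    counts: Dict[str, int] = {}
    for rec in SeqIO.parse(str(source), fmt):
        stats.n_reads += 1
        try:
            result = translate_display_construct(str(rec.seq), design)
        except MalformedConstructError as exc:
            if "multiple of 3" in str(exc):
                stats.n_bad_length += 1
            else:
                stats.n_bad_start += 1
            continue
        core = result.core_peptide
        if core is None:
            if result.terminated_early:
                stats.n_premature_stop += 1
            else:
                stats.n_short_core += 1
            continue
        if result.non_nnk_positions:
            stats.n_non_nnk += 1
        stats.n_valid += 1
        counts[core] = counts.get(core, 0) + 1
    table = ReadCountTable(
        counts=counts, library=library, round_index=round_index, empty=not counts
    )
    return table, stats


def triage_positive_clones(
    table: ReadCountTable, cfg: TriageConfig = TriageConfig()
) -> List[Tuple[str, int, float]]:
    """Sequences whose read fraction strictly exceeds the threshold.

    Ranked by count descending with a lexicographic tie-break, truncated at
    ``max_clones``. Returns ``(sequence, count, fraction)`` triples.
    """
    total = table.total_reads
    if total == 0:
        return []
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = [
        (seq, count, count / total)
        for seq, count in ranked
        if count / total > cfg.abundance_threshold
    ]
    return out[: cfg.max_clones]


def detection_floor(table: ReadCountTable) -> float:
    """Abundance resolved by a single read: ``1 / total_reads``."""
    total = table.total_reads
    if total == 0:
        raise ValueError("table has no reads")
    return 1.0 / total


@dataclass
class DedupResult:
    """Cross-library exact-sequence grouping."""

    unique_sequences: List[str]
    duplicate_pairs: List[Tuple[Tuple[str, str], Tuple[str, str]]]

    @property
    def n_unique(self) -> int:
        return len(self.unique_sequences)


def deduplicate_across_libraries(
    selections: Mapping[str, Sequence[str]],
) -> DedupResult:
    """Group identical clone sequences across libraries.

    ``selections`` maps a library label to its triaged clone sequences.
    Returns the unique sequence set and every cross-library pair of
    occurrences of the same sequence, as ``((lib_a, seq), (lib_b, seq))``.
    """
    occurrences: Dict[str, List[Tuple[str, str]]] = {}
    for lib in sorted(selections):
        for seq in selections[lib]:
            occurrences.setdefault(seq, []).append((lib, seq))
    pairs = []
    for seq in sorted(occurrences):
        occ = occurrences[seq]
        for i in range(len(occ)):
            for j in range(i + 1, len(occ)):
                if occ[i][0] != occ[j][0]:
                    pairs.append((occ[i], occ[j]))
    return DedupResult(unique_sequences=sorted(occurrences), duplicate_pairs=pairs)


# ---------------------------------------------------------------------------
# Family clustering


@dataclass
class Family:
    """A cluster of related cores with a per-position consensus."""

    id: str
    member_ids: List[str]
    consensus: Tuple[frozenset, ...]

    def motif(self, wildcard: str = "X", max_set: int = 2) -> str:
        """Render the consensus: single residues, (A/B) sets, X wildcards."""
        parts = []
        for s in self.consensus:
            if len(s) == 1:
                parts.append(next(iter(s)))
            elif len(s) <= max_set:
                parts.append("(" + "/".join(sorted(s)) + ")")
            else:
                parts.append(wildcard)
        return "".join(parts)


@dataclass
class FamilyAssignment:
    families: List[Family]
    singletons: List[str]

    def family_of(self) -> Dict[str, str]:
        mapping = {m: f.id for f in self.families for m in f.member_ids}
        mapping.update({s: s for s in self.singletons})
        return mapping


def _consensus_sets(
    seqs: Sequence[str], coverage: float = 2.0 / 3.0, max_set: int = 2
) -> Tuple[frozenset, ...]:
    """Per-position smallest residue sets covering >= ``coverage`` of members.

    Residues are added in frequency order (alphabetical tie-break). A position
    needing more than ``max_set`` residues to reach coverage is a wildcard and
    reports every residue observed there.
    """
    n = len(seqs)
    out = []
    for pos in range(len(seqs[0])):
        freq: Dict[str, int] = {}
        for s in seqs:
            freq[s[pos]] = freq.get(s[pos], 0) + 1
        ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
        chosen, covered = [], 0
        for res, c in ranked:
            chosen.append(res)
            covered += c
            if covered >= coverage * n:
                break
        if covered >= coverage * n and len(chosen) <= max_set:
            out.append(frozenset(chosen))
        else:
            out.append(frozenset(freq))
    return tuple(out)


def cluster_families(
    peptides: Union[Mapping[str, str], Sequence[str]],
    max_mismatch_fraction: float = 0.5,
) -> FamilyAssignment:
    """Single-linkage Hamming clustering of equal-length cores.

    Two cores join the same family when connected through a chain of pairs
    differing at no more than ``max_mismatch_fraction * length`` positions.
    Clusters of size one are reported as singletons. The result is invariant
    under input permutation: families are ordered by (size desc,
    lexicographically smallest member).
    """
    if isinstance(peptides, Mapping):
        items = list(peptides.items())
    else:
        items = [(f"p{i}", s) for i, s in enumerate(peptides)]
    if not items:
        return FamilyAssignment(families=[], singletons=[])
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError(
            "cores must share one length (gapped alignment is out of scope)"
        )
    (length,) = lengths
    ids = [i for i, _ in items]
    seqs = [s for _, s in items]
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), length)
    threshold = max_mismatch_fraction * length
    if len(seqs) == 1:
        dist = np.zeros((1, 1))
    else:
        dist = squareform(pdist(arr.view(np.uint8), metric="hamming") * length)
    adj = csr_matrix(dist <= threshold)
    n_comp, labels = connected_components(adj, directed=False)

    clusters: Dict[int, List[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)
    # deterministic ordering regardless of input order
    ordered = sorted(
        clusters.values(), key=lambda idxs: (-len(idxs), min(seqs[i] for i in idxs))
    )
    families: List[Family] = []
    singletons: List[str] = []
    fam_no = 0
    for idxs in ordered:
        if len(idxs) == 1:
            singletons.append(ids[idxs[0]])
            continue
        fam_no += 1
        member_ids = sorted((ids[i] for i in idxs), key=lambda m: (seqs[ids.index(m)], m))
        families.append(
            Family(
                id=f"F{fam_no}",
                member_ids=member_ids,
                consensus=_consensus_sets([seqs[i] for i in idxs]),
            )
        )
    singletons.sort()
    return FamilyAssignment(families=families, singletons=singletons)


# ---------------------------------------------------------------------------
# Trajectories and kinetic tables


def population_trajectories(
    tables: Sequence[ReadCountTable],
    assignment: Optional[FamilyAssignment] = None,
    sequences: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-round abundance fractions for species and (optionally) families.

    Rows are sequences (restricted to ``sequences`` when given, otherwise the
    union over rounds) plus, when a family assignment is provided,
    ``family:<id>`` aggregate rows; columns are round indices. A sequence
    absent from a round has fraction 0.
    """
    if not tables:
        raise ValueError("need at least one round table")
    libraries = {t.library for t in tables}
    if len(libraries) != 1:
        raise ValueError(f"tables mix libraries: {sorted(libraries)}")
    tables = sorted(tables, key=lambda t: t.round_index)
    rounds = [t.round_index for t in tables]
    if len(set(rounds)) != len(rounds):
        raise ValueError("duplicate round indices")
    if sequences is None:
        universe = sorted({s for t in tables for s in t.counts})
    else:
        universe = list(sequences)
    frac_by_round = [t.fractions() for t in tables]
    data = {
        r: [fr.get(s, 0.0) for s in universe] for r, fr in zip(rounds, frac_by_round)
    }
    df = pd.DataFrame(data, index=pd.Index(universe, name="sequence"))
    if assignment is not None:
        fam_rows = {}
        for fam in assignment.families:
            members = [m for m in fam.member_ids if m in df.index]
            fam_rows[f"family:{fam.id}"] = df.loc[members].sum(axis=0)
        if fam_rows:
            df = pd.concat([df, pd.DataFrame(fam_rows).T])
    df.columns.name = "round"
    return df


def kinetic_scatter_table(
    species: Sequence[Mapping],
) -> pd.DataFrame:
    """Plot-ready table of per-species kinetics with best-binder flags.

    Each entry needs ``id``; optional ``kinetics`` (:class:`KineticParams`),
    ``family`` and ``library``. Within each library the species with the
    smallest ``K_D`` is flagged best (ties broken by lower ``k_d``, then id);
    species without kinetics are listed but excluded from the ranking.
    """
    rows = []
    for entry in species:
        kin: Optional[KineticParams] = entry.get("kinetics")
        rows.append(
            {
                "id": entry["id"],
                "k_a": kin.k_a if kin else np.nan,
                "k_d": kin.k_d if kin else np.nan,
                "K_D": kin.K_D if kin else np.nan,
                "family": entry.get("family"),
                "library": entry.get("library", ""),
                "has_kinetics": kin is not None,
            }
        )
    df = pd.DataFrame(rows)
    df["best_in_library"] = False
    for lib, group in df.groupby("library"):
        ranked = group[group["has_kinetics"]].sort_values(
            ["K_D", "k_d", "id"], kind="stable"
        )
        if len(ranked):
            df.loc[ranked.index[0], "best_in_library"] = True
    return df
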