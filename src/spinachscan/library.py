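"""Mutant library enumeration, two-fragment assembly design and chip layout.

Saturation scanning mutagenesis of an n-nt RNA enumerates, at every
position, the three possible base substitutions: one transition
(purine<->purine or pyrimidine<->pyrimidine) and two transversions.
A complete compensatory double-point-mutation (DPM) scan pairs every two
positions and applies one of the three substitution classes jointly to
both partners, giving 3*C(n,2) mutants; for a 87-nt aptamer that is
11223, against only 3*87 = 261 single-point mutants (SPMs).

Each mutant is physically built from two overlapping DNA oligonucleotides
stitched by PCR; the 5' fragment carries the T7 promoter plus pull-down
anchor and probe tags, and the two fragments share a 19-nt overlap.
Mutants are arrayed on a microfluidic chip of valved unit cells (640 by
default) with a fixed number of replicate cells per mutant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")
PURINES = frozenset("AG")

#: transition partner of each RNA base
TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}
#: Watson-Crick partner of each RNA base
WC_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


class AlphabetError(ValueError):
    """Sequence contains characters outside the allowed alphabet."""


class ReferenceMismatchError(ValueError):
    """A mutation's stated wild-type base disagrees with the reference."""


class CoordinateError(ValueError):
    """A 1-based coordinate falls outside the sequence."""


class CapacityError(ValueError):
    """Chip cannot host the requested mutants at the requested replication."""


def validate_sequence(seq: str, alphabet=RNA_ALPHABET) -> str:
    seq = str(seq).upper()
    if len(seq) == 0:
        raise AlphabetError("empty sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise AlphabetError(f"invalid bases {sorted(bad)} for alphabet {sorted(alphabet)}")
    return seq


def substitution_alternatives(base: str) -> list[str]:
    """The three substitutions at a base: transition first, then the two
    transversions in alphabetical order (fixed, reproducible emission order)."""
    transition = TRANSITION[base]
    transversions = sorted(b for b in RNA_ALPHABET if b not in (base, transition))
    return [transition] + transversions


def mutation_class(wt_base: str, alt_base: str) -> str:
    if wt_base == alt_base:
        raise ValueError("wt and alternative base are identical")
    same_family = (wt_base in PURINES) == (alt_base in PURINES)
    return "transition" if same_family else "transversion"


@dataclass(frozen=True, order=True)
class PointMutation:
    """A single base substitution at a 1-based position."""

    position: int
    wt_base: str
    alt_base: str

    def __post_init__(self):
        if self.wt_base == self.alt_base:
            raise ValueError(f"position {self.position}: wt equals alt base")

    @property
    def mut_class(self) -> str:
        return mutation_class(self.wt_base, self.alt_base)

    @property
    def label(self) -> str:
        return f"{self.wt_base}{self.position}{self.alt_base}"


@dataclass(frozen=True)
class MutantSpec:
    """A mutant: a set of substitutions plus optional deletions.

    An empty spec is the wild-type control; ``negative_control`` marks the
    empty-core control cell (no aptamer sequence at all).
    """

    id: str
    substitutions: tuple[PointMutation, ...] = ()
    deletions: tuple[int, ...] = ()
    negative_control: bool = False

    def __post_init__(self):
        subs = tuple(sorted(self.substitutions))
        dels = tuple(sorted(set(self.deletions)))
        object.__setattr__(self, "substitutions", subs)
        object.__setattr__(self, "deletions", dels)
        positions = [m.position for m in subs]
        if len(set(positions)) != len(positions):
            raise ValueError(f"{self.id}: duplicate substitution positions")
        if set(positions) & set(dels):
            raise ValueError(f"{self.id}: substitution at a deleted position")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted([m.position for m in self.substitutions] + list(self.deletions)))

    @property
    def is_wildtype(self) -> bool:
        return not self.substitutions and not self.deletions and not self.negative_control


def wildtype_spec(id: str = "WT") -> MutantSpec:
    return MutantSpec(id=id)


def negative_control_spec(id: str = "NEG") -> MutantSpec:
    return MutantSpec(id=id, negative_control=True)


def spec_label(substitutions=(), deletions=()) -> str:
    parts = [m.label for m in sorted(substitutions)]
    parts += [f"D{p}" for p in sorted(deletions)]
    return "+".join(parts) if parts else "WT"


def enumerate_spms(seq: str) -> list[MutantSpec]:
    """All single-point substitution mutants: 3 per position (one
    transition, two transversions), ordered by position then by the fixed
    base order."""
    seq = validate_sequence(seq)
    out = []
    for pos, base in enumerate(seq, start=1):
        for alt in substitution_alternatives(base):
            pm = PointMutation(pos, base, alt)
            out.append(MutantSpec(id=pm.label, substitutions=(pm,)))
    return out


def enumerate_compensatory_dpms(
    seq: str,
    pairs=None,
    pairing_map=None,
) -> list[MutantSpec]:
    """Compensatory double-point mutants: 3 per unordered position pair.

    Without a ``pairing_map`` the k-th substitution alternative (in the
    fixed per-base order) is applied to both partners — the three joint
    re-pairings of the pair.  When ``pairing_map`` (an iterable of
    Watson-Crick paired position tuples) covers a pair, the partner's
    substitution is instead chosen as the Watson-Crick complement of the
    first position's new base, so each DPM restores complementarity —
    the stem-rescue screen configuration.

    With ``pairs`` absent the complete scan over all C(n,2) pairs is
    produced: 3*C(n,2) mutants.
    """
    seq = validate_sequence(seq)
    n = len(seq)
    if pairs is None:
        pairs = itertools.combinations(range(1, n + 1), 2)
    wc_pairs = set()
    if pairing_map is not None:
        for a, b in pairing_map:
            wc_pairs.add(frozenset((a, b)))
    out = []
    for raw in pairs:
        i, j = sorted(raw)
        if i == j:
            raise ValueError(f"invalid pair ({i}, {j}): positions must differ")
        if not (1 <= i <= n and 1 <= j <= n):
            raise CoordinateError(f"pair ({i}, {j}) outside sequence of length {n}")
        alts_i = substitution_alternatives(seq[i - 1])
        alts_j = substitution_alternatives(seq[j - 1])
        for k in range(3):
            mi = PointMutation(i, seq[i - 1], alts_i[k])
            if frozenset((i, j)) in wc_pairs:
                partner = WC_PAIR[alts_i[k]]
                if partner == seq[j - 1]:
                    # complement already present: fall back to the class-matched
                    # alternative so the count stays 3 per pair
                    partner = alts_j[k]
                mj = PointMutation(j, seq[j - 1], partner)
            else:
                mj = PointMutation(j, seq[j - 1], alts_j[k])
            subs = (mi, mj)
            out.append(MutantSpec(id=spec_label(subs), substitutions=subs))
    return out


def apply_mutations(seq: str, spec: MutantSpec) -> str:
    """Apply substitutions, then remove deleted positions (1-based).

    Raises :class:`ReferenceMismatchError` when a substitution's stated
    wild-type base disagrees with the sequence — the guard against
    coordinate drift between a spec and its reference.
    """
    seq = validate_sequence(seq)
    if spec.negative_control:
        return ""
    bases = list(seq)
    n = len(bases)
    for m in spec.substitutions:
        if not (1 <= m.position <= n):
            raise CoordinateError(f"{spec.id}: position {m.position} outside 1..{n}")
        if bases[m.position - 1] != m.wt_base:
            raise ReferenceMismatchError(
                f"{spec.id}: expected {m.wt_base} at position {m.position}, "
                f"reference has {bases[m.position - 1]}"
            )
        bases[m.position - 1] = m.alt_base
    for p in spec.deletions:
        if not (1 <= p <= n):
            raise CoordinateError(f"{spec.id}: deletion position {p} outside 1..{n}")
    keep = set(range(1, n + 1)) - set(spec.deletions)
    return "".join(bases[p - 1] for p in sorted(keep))


def deletion_spec(positions, id=None) -> MutantSpec:
    """A pure deletion mutant over 1-based positions (ranges inclusive)."""
    positions = tuple(sorted(set(positions)))
    return MutantSpec(id=id or spec_label(deletions=positions), deletions=positions)


def expand_ranges(ranges) -> tuple[int, ...]:
    """Expand inclusive 1-based (start, stop) ranges to a position tuple."""
    out = []
    for start, stop in ranges:
        if stop < start:
            raise CoordinateError(f"range {start}-{stop} is reversed")
        out.extend(range(start, stop + 1))
    return tuple(out)


# ---------------------------------------------------------------------------
# Two-fragment assembly design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentTags:
    """Opaque tag strings prepended to the 5' fragment (promoter, pull-down
    anchor, detection probe); configurable, empty by default."""

    promoter: str = ""
    anchor: str = ""
    probe: str = ""

    @property
    def prefix(self) -> str:
        return self.promoter + self.anchor + self.probe


@dataclass(frozen=True)
class FragmentDesign:
    fragment5: str          # tags + 5' core up to and including the overlap
    fragment3: str          # overlap + 3' core
    overlap_len: int
    overlap_start: int      # 1-based first position of the overlap window
    mutation_placement: str | None  # '5prime' | '3prime' | 'both' | None (WT)
    tags: FragmentTags = field(default_factory=FragmentTags)

    @property
    def overlap_window(self) -> tuple[int, int]:
        return (self.overlap_start, self.overlap_start + self.overlap_len - 1)


def stitch_fragments(design: FragmentDesign) -> str:
    """Reassemble the full-length sequence from a fragment pair (the PCR
    stitch): 5' core + 3' fragment minus its shared overlap."""
    core5 = design.fragment5[len(design.tags.prefix):]
    if core5[-design.overlap_len:] != design.fragment3[: design.overlap_len]:
        raise ValueError("fragment overlap regions disagree")
    return core5 + design.fragment3[design.overlap_len:]


def design_fragments(
    mutant_seq: str,
    mutated_positions=(),
    overlap_len: int = 19,
    overlap_start: int | None = None,
    tags: FragmentTags = FragmentTags(),
) -> FragmentDesign:
    """Split a mutant sequence into two overlapping synthesis fragments.

    The overlap window is centred by default.  A mutation inside the
    overlap must be carried by both oligonucleotides (placement 'both');
    mutations confined to one side are carried by that fragment alone.
    """
    mutant_seq = validate_sequence(mutant_seq)
    n = len(mutant_seq)
    if not (0 < overlap_len < n):
        raise ValueError(f"overlap_len {overlap_len} must lie in (0, {n})")
    if overlap_start is None:
        overlap_start = (n - overlap_len) // 2 + 1
    if not (1 <= overlap_start and overlap_start + overlap_len - 1 <= n):
        raise CoordinateError("overlap window outside sequence")
    lo, hi = overlap_start, overlap_start + overlap_len - 1

    for p in mutated_positions:
        if not (1 <= p <= n):
            raise CoordinateError(f"mutation position {p} outside 1..{n}")
    in_overlap = any(lo <= p <= hi for p in mutated_positions)
    in5 = any(p < lo for p in mutated_positions)
    in3 = any(p > hi for p in mutated_positions)
    if not mutated_positions:
        placement = None
    elif in_overlap or (in5 and in3):
        placement = "both"
    elif in5:
        placement = "5prime"
    else:
        placement = "3prime"

    fragment5 = tags.prefix + mutant_seq[:hi]
    fragment3 = mutant_seq[lo - 1:]
    return FragmentDesign(
        fragment5=fragment5,
        fragment3=fragment3,
        overlap_len=overlap_len,
        overlap_start=overlap_start,
        mutation_placement=placement,
        tags=tags,
    )


# ---------------------------------------------------------------------------
# Chip layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellAssignment:
    cell: int
    row: int
    col: int
    mutant_id: str
    replicate: int
    control: str  # '', 'WT' or 'NEG'


@dataclass(frozen=True)
class ChipLayout:
    n_cells: int
    replicates: int
    n_cols: int
    assignments: tuple[CellAssignment, ...]

    @property
    def capacity(self) -> int:
        return self.n_cells // self.replicates

    @property
    def mutant_ids(self) -> list[str]:
        seen = dict.fromkeys(a.mutant_id for a in self.assignments)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell": a.cell,
                    "row": a.row,
                    "col": a.col,
                    "mutant_id": a.mutant_id,
                    "replicate": a.replicate,
                    "control": a.control,
                }
                for a in self.assignments
            ]
        )


def plan_chip_layout(
    mutants,
    n_cells: int = 640,
    replicates: int = 4,
    n_cols: int = 20,
    seed: int | None = None,
) -> ChipLayout:
    """Assign each mutant to ``replicates`` unit cells on the chip.

    Capacity is floor(n_cells / replicates); a 640-cell chip at 4
    replicates hosts 160 mutants (controls count against capacity).
    Assignment order is deterministic; with ``seed`` the cell order is
    shuffled reproducibly.
    """
    mutants = list(mutants)
    capacity = n_cells // replicates
    required = len(mutants) * replicates
    if required > n_cells:
        raise CapacityError(
            f"{len(mutants)} mutants x {replicates} replicates need {required} "
            f"cells; chip has {n_cells} (capacity {capacity} mutants)"
        )
    cells = np.arange(n_cells)
    if seed is not None:
        rng = np.random.default_rng(seed)
        cells = rng.permutation(cells)
    assignments = []
    k = 0
    for spec in mutants:
        control = "NEG" if spec.negative_control else ("WT" if spec.is_wildtype else "")
        for rep in range(1, replicates + 1):
            c = int(cells[k])
            assignments.append(
                CellAssignment(
                    cell=c,
                    row=c // n_cols,
                    col=c % n_cols,
                    mutant_id=spec.id,
                    replicate=rep,
                    control=control,
                )
            )
            k += 1
    return ChipLayout(
        n_cells=n_cells,
        replicates=replicates,
        n_cols=n_cols,
        assignments=tuple(assignments),
    )


def spm_count(n: int) -> int:
    """Closed-form SPM library size for an n-nt sequence."""
    return 3 * n


def dpm_count(n: int) -> int:
    """Closed-form complete compensatory-DPM scan size: 3*C(n,2)."""
    return 3 * math.comb(n, 2)
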