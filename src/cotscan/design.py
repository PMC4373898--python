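"""Motif-introduction design: minimal point substitutions creating a CCM.

Generalizes the experimental strategy of making a cotransin-resistant
signal anchor sensitive by introducing the conformational consensus motif
with a handful of point mutations (the aquaporin-2 construct used
F25G, F26G, G27L, Q33K). The designer searches every concrete motif
variant at every placement inside a window and returns a
minimum-cardinality substitution set; the search is exact because for a
fixed placement the required mutation set is fully determined by which
positions fail their residue class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import DEFAULT_SCHEME, ResidueClassScheme, ValidationError
from .motif import (
    ROLE_FLANK_LEFT,
    ROLE_FLANK_RIGHT,
    ROLE_PATCH1,
    ROLE_PATCH2,
    ROLE_SEPARATOR,
    CompiledMotifPattern,
    ccm_pattern_family,
    scan_sequence,
)


@dataclass(frozen=True)
class Mutation:
    """One substitution in protein numbering, e.g. F25G."""

    position: int
    from_residue: str
    to_residue: str

    def __str__(self) -> str:
        return f"{self.from_residue}{self.position}{self.to_residue}"


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation(text: str) -> Mutation:
    m = _MUTATION_RE.match(text.strip().upper())
    if m is None:
        raise ValidationError(f"cannot parse mutation {text!r} (expected e.g. F25G)")
    return Mutation(position=int(m.group(2)), from_residue=m.group(1), to_residue=m.group(3))


@dataclass(frozen=True)
class MutationSet:
    mutations: tuple[Mutation, ...]
    window: tuple[int, int]

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValidationError("duplicate positions in mutation set")

    def __len__(self) -> int:
        return len(self.mutations)

    def names(self) -> list[str]:
        return [str(m) for m in sorted(self.mutations, key=lambda m: m.position)]


def apply_mutations(sequence: str, mutations: MutationSet | Sequence[Mutation]) -> str:
    """Apply point substitutions; every from_residue must match the input."""
    muts = mutations.mutations if isinstance(mutations, MutationSet) else tuple(mutations)
    seq = list(sequence.upper())
    for m in muts:
        if not 1 <= m.position <= len(seq):
            raise ValidationError(f"mutation {m}: position outside sequence of length {len(seq)}")
        if seq[m.position - 1] != m.from_residue:
            raise ValidationError(
                f"mutation {m}: sequence has {seq[m.position - 1]} at position {m.position}"
            )
        seq[m.position - 1] = m.to_residue
    return "".join(seq)


def revert_mutations(mutations: MutationSet | Sequence[Mutation]) -> tuple[Mutation, ...]:
    muts = mutations.mutations if isinstance(mutations, MutationSet) else tuple(mutations)
    return tuple(Mutation(m.position, m.to_residue, m.from_residue) for m in muts)


_ROLE_TO_CLASS = {
    ROLE_FLANK_LEFT: "flank",
    ROLE_FLANK_RIGHT: "flank",
    ROLE_PATCH1: "small",
    ROLE_SEPARATOR: "bulky",
    ROLE_PATCH2: "small",
}

#: Single-representative substitution alphabet: one biologically minimal
#: choice per class keeps proposals small and comparable to lab practice.
DEFAULT_REPRESENTATIVES = {"small": "G", "bulky": "L", "flank": "K"}


def _representative(cls: str, scheme: ResidueClassScheme, representatives: dict[str, str]) -> str:
    rep = representatives.get(cls)
    members = getattr(scheme, cls)
    if rep is not None and rep in members:
        return rep
    return min(members)


def verify_mutation_set(
    sequence: str,
    mutations: MutationSet | Sequence[Mutation],
    window: tuple[int, int],
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
) -> bool:
    """Check that applying a user-supplied mutation set creates a motif
    match inside the window (verification mode for lab-designed sets)."""
    mutated = apply_mutations(sequence, mutations)
    return bool(scan_sequence(mutated, ccm_pattern_family(scheme), region=window))


def propose_motif_insertion(
    sequence: str,
    window: Optional[tuple[int, int]] = None,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    max_mutations: int = 4,
    allow_flank_mutations: bool = True,
    representatives: Optional[dict[str, str]] = None,
) -> Optional[MutationSet]:
    """Minimal substitution set introducing a CCM inside the window.

    Enumerates every motif variant at every placement whose span lies
    within the window; the cost of a placement is the number of positions
    whose residue fails its class. Ties break by fewest mutations, then
    leftmost match, then lexicographically smallest substitution list.
    Returns an empty set when the window already contains a match and
    ``None`` when no set of size ≤ ``max_mutations`` exists.
    ``allow_flank_mutations=False`` forbids creating flank residues, so
    placements relying on a mutated-in flank become invalid.
    """
    seq = sequence.upper()
    if not seq:
        raise ValidationError("empty sequence")
    if window is None:
        window = (1, len(seq))
    lo, hi = window
    if not (1 <= lo <= hi <= len(seq)):
        raise ValidationError(f"window {lo}..{hi} out of bounds for length {len(seq)}")
    if max_mutations < 0:
        raise ValidationError("max_mutations must be >= 0")
    reps = representatives or DEFAULT_REPRESENTATIVES
    patterns = ccm_pattern_family(scheme)
    if scan_sequence(seq, patterns, region=window):
        return MutationSet(mutations=(), window=window)

    best: Optional[tuple[int, int, tuple[str, ...], tuple[Mutation, ...]]] = None
    for pat in patterns:
        length = pat.fixed_length
        for start in range(lo, hi - length + 2):  # placement start, 1-based
            muts: list[Mutation] = []
            pos = start
            valid = True
            for (residues, rep_len, _), role in zip(pat.elements, pat.roles):
                cls = _ROLE_TO_CLASS[role]
                for k in range(rep_len):
                    current = seq[pos + k - 1]
                    if current not in residues:
                        if cls == "flank" and not allow_flank_mutations:
                            valid = False
                            break
                        muts.append(
                            Mutation(pos + k, current, _representative(cls, scheme, reps))
                        )
                if not valid:
                    break
                pos += rep_len
            if not valid or len(muts) > max_mutations:
                continue
            key = (len(muts), start, tuple(sorted(str(m) for m in muts)))
            if best is None or key < best[:3]:
                best = (*key, tuple(muts))
    if best is None:
        return None
    return MutationSet(mutations=best[3], window=window)
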