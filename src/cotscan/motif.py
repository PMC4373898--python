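"""Fuzzy residue-class motif engine.

Compiles PROSITE-dialect patterns and scans sequences for the
conformational consensus motif (CCM) found in cotransin-sensitive signal
anchor sequences: two patches of small residues (the first of two, the
second of one or two residues from {G,A,S,T,C}) separated by two or three
bulky residues and flanked on one or both sides by a large charged, large
polar or aromatic residue. On an ideal transmembrane helix the two patches
form two adjacent surface cavities (see :mod:`cotscan.helix`).

Matching is purely set-membership per position — no scoring, no PWM. All
positions are 1-based inclusive. Scanning runs N→C; overlapping alternative
parses sharing a first-patch start are collapsed to one canonical match
(shortest separator, then longest second patch, flanks merged).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import (
    DEFAULT_SCHEME,
    STANDARD_AA,
    ProteinClass,
    ResidueClassScheme,
    SignalSequenceRecord,
    SignalType,
    ValidationError,
)


class PatternSyntaxError(ValueError):
    """Raised on malformed pattern text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"position {position}: {message}")
        self.position = position


class FlankRule(str, enum.Enum):
    LEFT_REQUIRED = "left_required"
    RIGHT_REQUIRED = "right_required"
    EITHER_REQUIRED = "either_required"
    BOTH_REQUIRED = "both_required"
    NONE = "none"


# Element roles used by CCM-style patterns so matches can report spans.
ROLE_FLANK_LEFT = "flank_left"
ROLE_PATCH1 = "patch1"
ROLE_SEPARATOR = "separator"
ROLE_PATCH2 = "patch2"
ROLE_FLANK_RIGHT = "flank_right"


@dataclass(frozen=True)
class CompiledMotifPattern:
    """An ordered list of (residue-set, min_repeat, max_repeat) elements."""

    elements: tuple[tuple[frozenset, int, int], ...]
    flank_rule: FlankRule = FlankRule.NONE
    source_text: str = ""
    roles: Optional[tuple[str, ...]] = None
    scheme: Optional[ResidueClassScheme] = None

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValidationError("pattern has no elements")
        for residues, lo, hi in self.elements:
            if not (1 <= lo <= hi):
                raise ValidationError(f"bad repeat range ({lo},{hi})")
        if self.roles is not None and len(self.roles) != len(self.elements):
            raise ValidationError("roles must align with elements")

    @property
    def fixed_length(self) -> Optional[int]:
        """Total length if every repeat is fixed, else None."""
        if any(lo != hi for _, lo, hi in self.elements):
            return None
        return sum(lo for _, lo, _ in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """A located CCM occurrence; all positions 1-based inclusive.

    ``start``/``end`` span every consumed position including flanks;
    patch/separator spans are (first, last) position pairs.
    """

    start: int
    end: int
    patch1_span: tuple[int, int]
    separator_span: tuple[int, int]
    patch2_span: tuple[int, int]
    left_flank_pos: Optional[int]
    right_flank_pos: Optional[int]
    pattern_id: str

    def __post_init__(self) -> None:
        p1, sep, p2 = self.patch1_span, self.separator_span, self.patch2_span
        if not (p1[1] + 1 == sep[0] and sep[1] + 1 == p2[0]):
            raise ValidationError("match spans must be contiguous and ordered")
        if p1[1] - p1[0] + 1 != 2:
            raise ValidationError("first patch must have exactly 2 residues")
        if sep[1] - sep[0] + 1 not in (2, 3):
            raise ValidationError("separator must have 2 or 3 residues")
        if p2[1] - p2[0] + 1 not in (1, 2):
            raise ValidationError("second patch must have 1 or 2 residues")

    @property
    def patch1_start(self) -> int:
        return self.patch1_span[0]


_ELEMENT_RE = re.compile(
    r"(?P<set>\[(?P<inc>[A-Za-z]+)\]|\{(?P<exc>[A-Za-z]+)\}|(?P<any>x)|(?P<single>[A-Za-z]))"
    r"(\((?P<lo>\d+)(,(?P<hi>\d+))?\))?"
)


def compile_pattern(text: str) -> CompiledMotifPattern:
    """Compile a PROSITE-dialect pattern string.

    Grammar: elements separated by ``-``; an element is ``[ABC]`` (any of),
    ``{ABC}`` (none of, i.e. the complement over the 20 standard residues),
    ``x`` (any residue) or a bare residue letter, optionally followed by a
    repeat ``(m)`` or ``(m,n)``. A trailing ``.`` is tolerated.
    """
    text = text.strip()
    body = text[:-1] if text.endswith(".") else text
    if not body:
        raise PatternSyntaxError("empty pattern", 0)
    elements: list[tuple[frozenset, int, int]] = []
    offset = 0
    for i, chunk in enumerate(body.split("-")):
        if not chunk:
            raise PatternSyntaxError("empty element", offset)
        m = _ELEMENT_RE.fullmatch(chunk)
        if m is None:
            raise PatternSyntaxError(f"cannot parse element {chunk!r}", offset)
        if m.group("inc") is not None:
            residues = frozenset(m.group("inc").upper())
        elif m.group("exc") is not None:
            residues = STANDARD_AA - frozenset(m.group("exc").upper())
        elif m.group("any") is not None:
            residues = STANDARD_AA
        else:
            residues = frozenset(m.group("single").upper())
        unknown = (residues if m.group("exc") is None else frozenset(m.group("exc").upper())) - STANDARD_AA
        if m.group("any") is None and unknown:
            raise PatternSyntaxError(f"unknown residue letters {sorted(unknown)}", offset)
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        if lo > hi:
            raise PatternSyntaxError(f"repeat ({lo},{hi}) has m > n", offset)
        if lo < 1:
            raise PatternSyntaxError("repeat must be >= 1", offset)
        elements.append((residues, lo, hi))
        offset += len(chunk) + 1
    return CompiledMotifPattern(elements=tuple(elements), source_text=text)


def pattern_to_regex(pattern: CompiledMotifPattern) -> str:
    parts = []
    for residues, lo, hi in pattern.elements:
        cc = "." if residues == STANDARD_AA else "[" + "".join(sorted(residues)) + "]"
        rep = f"{{{lo}}}" if lo == hi else f"{{{lo},{hi}}}"
        parts.append(cc + rep)
    return "".join(parts)


def find_pattern(sequence: str, pattern: CompiledMotifPattern) -> list[tuple[int, int]]:
    """Greedy-longest occurrences of a generic compiled pattern.

    Returns 1-based inclusive (start, end) spans, one per match start,
    scanning N→C. Convenience for arbitrary PROSITE-dialect patterns; CCM
    scanning with element spans goes through :func:`scan_sequence`.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    rx = re.compile(pattern_to_regex(pattern))
    spans = []
    for start in range(len(seq)):
        m = rx.match(seq, start)
        if m is not None:
            spans.append((start + 1, m.end()))
    return spans


_FLANK_PLACEMENTS = {
    FlankRule.EITHER_REQUIRED: ("left", "right", "both"),
    FlankRule.LEFT_REQUIRED: ("left",),
    FlankRule.RIGHT_REQUIRED: ("right",),
    FlankRule.BOTH_REQUIRED: ("both",),
    FlankRule.NONE: ("none",),
}


def ccm_pattern_family(
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    flank_rule: FlankRule = FlankRule.EITHER_REQUIRED,
) -> list[CompiledMotifPattern]:
    """Enumerate the concrete CCM variants for a residue-class scheme.

    With the default either-side flank rule the family has 12 variants:
    separator length {2,3} × second-patch length {1,2} × flank placement
    {left, right, both}. Flanks are immediately adjacent to the patches.
    """
    for label in ("small", "bulky", "flank"):
        if not getattr(scheme, label):
            raise ValidationError(f"scheme {scheme.name!r}: empty {label} set")
    variants = []
    for sep_len in (2, 3):
        for p2_len in (1, 2):
            for placement in _FLANK_PLACEMENTS[flank_rule]:
                elements = []
                roles = []
                if placement in ("left", "both"):
                    elements.append((scheme.flank, 1, 1))
                    roles.append(ROLE_FLANK_LEFT)
                elements.append((scheme.small, 2, 2))
                roles.append(ROLE_PATCH1)
                elements.append((scheme.bulky, sep_len, sep_len))
                roles.append(ROLE_SEPARATOR)
                elements.append((scheme.small, p2_len, p2_len))
                roles.append(ROLE_PATCH2)
                if placement in ("right", "both"):
                    elements.append((scheme.flank, 1, 1))
                    roles.append(ROLE_FLANK_RIGHT)
                rule = {
                    "left": FlankRule.LEFT_REQUIRED,
                    "right": FlankRule.RIGHT_REQUIRED,
                    "both": FlankRule.BOTH_REQUIRED,
                    "none": FlankRule.NONE,
                }[placement]
                variants.append(
                    CompiledMotifPattern(
                        elements=tuple(elements),
                        flank_rule=rule,
                        source_text=f"ccm[{scheme.name}|sep={sep_len}|patch2={p2_len}|flank={placement}]",
                        roles=tuple(roles),
                        scheme=scheme,
                    )
                )
    return variants


def _candidate_parses(
    seq: str, patterns: Sequence[CompiledMotifPattern]
) -> dict[int, set[tuple[int, int]]]:
    """All (separator_len, patch2_len) parses keyed by 0-based patch1 start."""
    by_p1: dict[int, set[tuple[int, int]]] = {}
    n = len(seq)
    for pat in patterns:
        if pat.roles is None:
            raise ValidationError(
                f"pattern {pat.source_text!r} lacks element roles; "
                "use ccm_pattern_family or find_pattern"
            )
        length = pat.fixed_length
        if length is None or length > n:
            continue
        for offset in range(n - length + 1):
            pos = offset
            spans = {}
            ok = True
            for (residues, lo, _), role in zip(pat.elements, pat.roles):
                segment = seq[pos : pos + lo]
                if any(r not in residues for r in segment):
                    ok = False
                    break
                spans[role] = (pos, pos + lo - 1)
                pos += lo
            if not ok:
                continue
            p1 = spans[ROLE_PATCH1][0]
            sep_len = spans[ROLE_SEPARATOR][1] - spans[ROLE_SEPARATOR][0] + 1
            p2_len = spans[ROLE_PATCH2][1] - spans[ROLE_PATCH2][0] + 1
            by_p1.setdefault(p1, set()).add((sep_len, p2_len))
    return by_p1


def _canonical_match(
    seq: str,
    p1: int,
    combos: set[tuple[int, int]],
    flank_set: frozenset,
    pattern_id: str,
    shift: int,
) -> MotifMatch:
    """Collapse alternative parses at one patch1 start to one match.

    Tie-break: shortest separator first, then longest second patch; both
    adjacent flanks are reported when present. ``shift`` converts local
    0-based positions back to 1-based positions in the full sequence.
    """
    sep_len = min(s for s, _ in combos)
    p2_len = max(p for s, p in combos if s == sep_len)
    p1_span = (p1, p1 + 1)
    sep_span = (p1 + 2, p1 + 1 + sep_len)
    p2_span = (sep_span[1] + 1, sep_span[1] + p2_len)
    left = p1 - 1 if p1 - 1 >= 0 and seq[p1 - 1] in flank_set else None
    right_idx = p2_span[1] + 1
    right = right_idx if right_idx < len(seq) and seq[right_idx] in flank_set else None
    to1 = lambda i: i + 1 + shift  # noqa: E731 — local coordinate shift
    return MotifMatch(
        start=to1(left) if left is not None else to1(p1),
        end=to1(right) if right is not None else to1(p2_span[1]),
        patch1_span=(to1(p1_span[0]), to1(p1_span[1])),
        separator_span=(to1(sep_span[0]), to1(sep_span[1])),
        patch2_span=(to1(p2_span[0]), to1(p2_span[1])),
        left_flank_pos=to1(left) if left is not None else None,
        right_flank_pos=to1(right) if right is not None else None,
        pattern_id=pattern_id,
    )


def scan_sequence(
    sequence: str,
    patterns: Sequence[CompiledMotifPattern],
    region: Optional[tuple[int, int]] = None,
    verbose: bool = False,
) -> list[MotifMatch]:
    """Scan a sequence N→C for CCM matches.

    ``region`` (1-based inclusive) restricts every consumed position —
    including flanks — to that window. One canonical match is reported per
    first-patch start; ``verbose=True`` additionally reports every
    alternative (separator, patch2) parse as its own match.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    if region is not None:
        lo, hi = region
        if not (1 <= lo <= hi <= len(seq)):
            raise ValidationError(
                f"region {lo}..{hi} out of bounds for sequence of length {len(seq)}"
            )
        sub = seq[lo - 1 : hi]
        shift = lo - 1
    else:
        sub = seq
        shift = 0
    if not patterns:
        return []
    scheme = patterns[0].scheme
    if scheme is None:
        raise ValidationError("scan_sequence needs scheme-annotated CCM patterns")
    pattern_id = f"ccm:{scheme.name}"
    by_p1 = _candidate_parses(sub, patterns)
    matches = []
    for p1 in sorted(by_p1):
        if verbose:
            for sep_len, p2_len in sorted(by_p1[p1]):
                matches.append(
                    _canonical_match(
                        sub, p1, {(sep_len, p2_len)}, scheme.flank,
                        f"{pattern_id}|sep={sep_len}|patch2={p2_len}", shift,
                    )
                )
        else:
            matches.append(
                _canonical_match(sub, p1, by_p1[p1], scheme.flank, pattern_id, shift)
            )
    return matches


@dataclass(frozen=True)
class ScreenRow:
    accession: str
    matched: bool
    n_matches: int
    skipped: bool
    protein_class: ProteinClass
    signal_type: SignalType
    sensitivity_label: Optional[str] = None
    first_match: Optional[MotifMatch] = None


@dataclass
class ScreenSummary:
    """Per-category with/without-motif counts from a cohort screen."""

    rows: list[ScreenRow] = field(default_factory=list)
    n_skipped: int = 0

    def counts(
        self,
        protein_class: Optional[ProteinClass] = None,
        signal_type: Optional[SignalType] = None,
        sensitivity_label: Optional[str] = None,
    ) -> dict[str, int]:
        """with/without counts for an optional category restriction."""
        with_motif = without = 0
        for row in self.rows:
            if row.skipped:
                continue
            if protein_class is not None and row.protein_class is not protein_class:
                continue
            if signal_type is not None and row.signal_type is not signal_type:
                continue
            if sensitivity_label is not None and row.sensitivity_label != sensitivity_label:
                continue
            if row.matched:
                with_motif += 1
            else:
                without += 1
        return {"with": with_motif, "without": without}

    def by_category(self) -> dict[tuple[str, str, Optional[str]], dict[str, int]]:
        out: dict[tuple[str, str, Optional[str]], dict[str, int]] = {}
        for row in self.rows:
            if row.skipped:
                continue
            key = (row.protein_class.value, row.signal_type.value, row.sensitivity_label)
            cell = out.setdefault(key, {"with": 0, "without": 0})
            cell["with" if row.matched else "without"] += 1
        return out


def screen_cohort(
    records: Iterable[SignalSequenceRecord],
    patterns: Sequence[CompiledMotifPattern],
    margin: int = 2,
    sensitivity: Optional[dict[str, str]] = None,
) -> ScreenSummary:
    """Screen annotated signal sequences for the motif.

    Scanning is restricted to [signal_start − margin, signal_end + margin]
    (clipped to the sequence) so that flanking residues just outside the
    annotated transmembrane span still count. Records without boundaries
    are flagged skipped and counted separately. ``sensitivity`` optionally
    maps accession → label (e.g. from the SILAC classifier) so summary
    counts can be partitioned by cotransin sensitivity.
    """
    summary = ScreenSummary()
    for rec in records:
        label = sensitivity.get(rec.accession) if sensitivity else None
        if not rec.has_boundaries:
            summary.rows.append(
                ScreenRow(rec.accession, False, 0, True, rec.protein_class, rec.signal_type, label)
            )
            summary.n_skipped += 1
            continue
        lo = max(1, rec.signal_start - margin)
        hi = min(len(rec.full_sequence), rec.signal_end + margin)
        matches = scan_sequence(rec.full_sequence, patterns, region=(lo, hi))
        summary.rows.append(
            ScreenRow(
                rec.accession,
                bool(matches),
                len(matches),
                False,
                rec.protein_class,
                rec.signal_type,
                label,
                matches[0] if matches else None,
            )
        )
    return summary
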