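"""Domain types and residue constants shared by the whole pipeline.

Coordinates are 1-based inclusive throughout the package (protein residue
numbering, as in mutation names like ``F25G``); conversion to Python's
0-based slices happens only inside I/O and scanning internals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE_KD

#: The 20 standard amino acids, one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues tolerated in input sequences but never members of a residue
#: class (they can never satisfy small/bulky/flank during motif matching).
AMBIGUOUS_AA = frozenset("BZUXO")


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


class ProteinClass(str, enum.Enum):
    SECRETORY = "secretory"
    MEMBRANE = "membrane"


class SignalType(str, enum.Enum):
    SP = "SP"
    SAS = "SAS"
    UNSPECIFIED = "unspecified"


class Topology(str, enum.Enum):
    #: N-terminus cytoplasmic.
    NC = "Nc"
    #: N-terminus extracellular (ER-luminal).
    NE = "Ne"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class SignalSequenceRecord:
    """One protein's sequence plus its signal-sequence annotation.

    ``signal_start``/``signal_end`` are 1-based inclusive residue positions
    of the signal peptide (SP) or signal anchor (SAS, usually TM1). Records
    with unknown boundaries carry ``None`` and are skipped (not silently
    clamped) by region-restricted operations.
    """

    accession: str
    full_sequence: str
    protein_class: ProteinClass
    signal_type: SignalType = SignalType.UNSPECIFIED
    signal_start: Optional[int] = None
    signal_end: Optional[int] = None
    topology: Topology = Topology.UNSPECIFIED

    def __post_init__(self) -> None:
        seq = self.full_sequence.upper()
        object.__setattr__(self, "full_sequence", seq)
        if not seq:
            raise ValidationError(f"{self.accession}: empty sequence")
        bad = set(seq) - STANDARD_AA - AMBIGUOUS_AA
        if bad:
            raise ValidationError(
                f"{self.accession}: non amino-acid characters {sorted(bad)}"
            )
        if (self.signal_start is None) != (self.signal_end is None):
            raise ValidationError(
                f"{self.accession}: signal boundaries must be given together"
            )
        if self.signal_start is not None:
            if not 1 <= self.signal_start <= self.signal_end <= len(seq):
                raise ValidationError(
                    f"{self.accession}: signal boundaries "
                    f"{self.signal_start}..{self.signal_end} out of range for "
                    f"sequence of length {len(seq)}"
                )
        if self.protein_class is ProteinClass.SECRETORY and self.signal_type is SignalType.SAS:
            # Secretory proteins invariantly carry cleavable signal peptides.
            raise ValidationError(
                f"{self.accession}: a secretory protein cannot have a SAS"
            )

    @property
    def has_boundaries(self) -> bool:
        return self.signal_start is not None

    @property
    def signal_sequence(self) -> Optional[str]:
        if not self.has_boundaries:
            return None
        return self.full_sequence[self.signal_start - 1 : self.signal_end]


@dataclass(frozen=True)
class ResidueClassScheme:
    """Named residue sets parameterizing the conformational consensus motif.

    ``small`` residues form the two cavity patches, ``bulky`` residues the
    2–3-residue separator, and ``flank`` residues (large charged, large
    polar or aromatic) must border the patches on at least one side.
    """

    small: frozenset[str]
    bulky: frozenset[str]
    flank: frozenset[str]
    name: str = "custom"

    def __post_init__(self) -> None:
        for label, residues in (("small", self.small), ("bulky", self.bulky), ("flank", self.flank)):
            object.__setattr__(self, label, frozenset(residues))
            extra = frozenset(residues) - STANDARD_AA
            if extra:
                raise ValidationError(
                    f"scheme {self.name!r}: {label} set contains non-standard "
                    f"residues {sorted(extra)}"
                )
        if self.small & self.bulky:
            raise ValidationError(
                f"scheme {self.name!r}: residues {sorted(self.small & self.bulky)} "
                "cannot be both small and bulky"
            )


#: Small residues forming the motif's cavities: Gly, Ala, Ser, Thr, Cys.
SMALL_RESIDUES = frozenset("GASTC")

#: Flanking residues: charged (D,E,K,R,H) + large polar (N,Q) + aromatic (F,W,Y).
FLANK_RESIDUES = frozenset("DEKRH") | frozenset("NQ") | frozenset("FWY")

#: Default scheme — "bulky" is every standard residue that is not small.
DEFAULT_SCHEME = ResidueClassScheme(
    small=SMALL_RESIDUES,
    bulky=STANDARD_AA - SMALL_RESIDUES,
    flank=FLANK_RESIDUES,
    name="default",
)

#: Stricter alternative with a hydrophobic-only separator set.
HYDROPHOBIC_SEPARATOR_SCHEME = ResidueClassScheme(
    small=SMALL_RESIDUES,
    bulky=frozenset("LIVFMWYP"),
    flank=FLANK_RESIDUES,
    name="hydrophobic-separator",
)


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydropathy values; Kyte–Doolittle by default."""

    values: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValidationError(
                f"hydropathy scale {self.name!r} lacks residues {sorted(missing)}"
            )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.values


KYTE_DOOLITTLE = HydropathyScale(values=dict(_KYTE_DOOLITTLE_KD), name="Kyte-Doolittle")


@dataclass(frozen=True)
class SilacRatioRecord:
    """Forward (H/L) and reverse (L/H) DMSO/cotransin expression ratios.

    A missing ratio (``None``) marks a protein quantified in only one of
    the label-swap experiments; such records are classified ``incomplete``.
    """

    accession: str
    forward_ratio: Optional[float]
    reverse_ratio: Optional[float]
    protein_class: Optional[ProteinClass] = None
    signal_type: SignalType = SignalType.UNSPECIFIED

    def __post_init__(self) -> None:
        for label, value in (("forward", self.forward_ratio), ("reverse", self.reverse_ratio)):
            if value is not None and not value > 0:
                raise ValidationError(
                    f"{self.accession}: {label} ratio must be positive, got {value}"
                )

    @property
    def complete(self) -> bool:
        return self.forward_ratio is not None and self.reverse_ratio is not None


@dataclass
class DoseResponseDataset:
    """Concentration / normalized-fluorescence pairs with replicate ids.

    Concentrations in μM; responses in percent of the DMSO control.
    """

    concentration: list[float] = field(default_factory=list)
    response_percent: list[float] = field(default_factory=list)
    replicate: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.concentration) == len(self.response_percent) == len(self.replicate)):
            raise ValidationError("dose-response columns must have equal length")
        if any(c <= 0 for c in self.concentration):
            raise ValidationError("concentrations must be positive")

    def __len__(self) -> int:
        return len(self.concentration)
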