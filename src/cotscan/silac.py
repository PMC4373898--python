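"""Cotransin-sensitivity classification from SILAC label-swap ratios.

A protein is called sensitive when its DMSO/cotransin expression ratio
exceeds the threshold (default 1.65) in BOTH the forward (H/L) and reverse
(L/H) experiments — strictly: a ratio exactly at the threshold is not
sensitive. A protein whose expression rises under cotransin in both
experiments (both ratios below the reciprocal threshold) is called
up-regulated. Everything else is resistant; a protein quantified in only
one experiment is incomplete.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import ProteinClass, SignalType, SilacRatioRecord, ValidationError

LABEL_SENSITIVE = "sensitive"
LABEL_RESISTANT = "resistant"
LABEL_UP_REGULATED = "up_regulated"
LABEL_INCOMPLETE = "incomplete"
LABELS = (LABEL_SENSITIVE, LABEL_RESISTANT, LABEL_UP_REGULATED, LABEL_INCOMPLETE)

DEFAULT_THRESHOLD = 1.65


@dataclass(frozen=True)
class SensitivityCall:
    label: str
    threshold_used: float


def classify_protein(record: SilacRatioRecord, threshold: float = DEFAULT_THRESHOLD) -> SensitivityCall:
    """Call one protein sensitive / resistant / up-regulated / incomplete."""
    if not threshold > 1:
        raise ValidationError(f"threshold must be > 1, got {threshold}")
    if not record.complete:
        return SensitivityCall(LABEL_INCOMPLETE, threshold)
    f, r = record.forward_ratio, record.reverse_ratio
    if f > threshold and r > threshold:
        return SensitivityCall(LABEL_SENSITIVE, threshold)
    if f < 1 / threshold and r < 1 / threshold:
        return SensitivityCall(LABEL_UP_REGULATED, threshold)
    return SensitivityCall(LABEL_RESISTANT, threshold)


@dataclass
class ClassificationSummary:
    """Per-(class × signal-type × label) counts plus per-record calls."""

    calls: dict[str, SensitivityCall] = field(default_factory=dict)
    counts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD

    @property
    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def count(
        self,
        label: str,
        protein_class: Optional[ProteinClass] = None,
        signal_type: Optional[SignalType] = None,
    ) -> int:
        total = 0
        for (cls, styp), counter in self.counts.items():
            if protein_class is not None and cls != protein_class.value:
                continue
            if signal_type is not None and styp != signal_type.value:
                continue
            total += counter[label]
        return total

    def labels(self) -> dict[str, str]:
        return {acc: call.label for acc, call in self.calls.items()}


def classify_table(
    records: Iterable[SilacRatioRecord], threshold: float = DEFAULT_THRESHOLD
) -> ClassificationSummary:
    """Classify a whole ratio table; cell counts sum to the record count."""
    summary = ClassificationSummary(threshold=threshold)
    for rec in records:
        call = classify_protein(rec, threshold)
        summary.calls[rec.accession] = call
        cls = rec.protein_class.value if rec.protein_class is not None else "unspecified"
        key = (cls, rec.signal_type.value)
        summary.counts.setdefault(key, Counter())[call.label] += 1
    return summary


def ratios_from_intensities(
    heavy: Sequence[float],
    light: Sequence[float],
    median_center: bool = False,
) -> np.ndarray:
    """Form per-protein H/L ratios from channel intensities.

    ``median_center=True`` divides all ratios by their cohort median —
    the standard SILAC normalization under the assumption that most
    proteins are unaffected. It makes the downstream calls invariant to a
    constant rescaling of either channel (e.g. unequal loading).
    """
    heavy = np.asarray(heavy, dtype=float)
    light = np.asarray(light, dtype=float)
    if heavy.shape != light.shape:
        raise ValidationError("channel intensity arrays must have equal length")
    if np.any(heavy <= 0) or np.any(light <= 0):
        raise ValidationError("intensities must be positive")
    ratios = heavy / light
    if median_center:
        ratios = ratios / np.median(ratios)
    return ratios
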