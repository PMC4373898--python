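"""Enrichment statistics and signal-sequence property profiles.

The central test is Fisher's exact test on the 2×2 table of motif presence
× cotransin sensitivity among signal anchor sequences. The two-sided
p-value follows the probability-mass rule: with margins fixed, sum the
hypergeometric probabilities of every table at most as probable as the
observed one. (Conventions for two-sided Fisher tests differ; this is the
common one and is stated explicitly for that reason.)

Property profiles (GRAVY hydropathy, signal-sequence length) are binned
frequency distributions expressed in percent of each cohort, with
half-open bins [edge, edge + width).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import HydropathyScale, KYTE_DOOLITTLE, SignalType, ValidationError
from .motif import ScreenSummary
from .silac import LABEL_SENSITIVE


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows sensitive/non-sensitive, columns motif present/absent."""

    a: int  # sensitive, with motif
    b: int  # sensitive, without motif
    c: int  # non-sensitive, with motif
    d: int  # non-sensitive, without motif

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValidationError("contingency counts must be non-negative")
        if sum(cells) == 0:
            raise ValidationError("contingency table is all-zero")


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    odds_ratio: float  # sample odds ratio ad/bc; inf when bc = 0


def fisher_exact(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table.
    The odds ratio is the sample value ad/bc (infinite on zero
    denominator, nan for a doubly degenerate 0/0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    # Degenerate margin: only one table possible, p = 1.
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        p = 1.0
    else:
        log_denom = _log_comb(n, c1)

        def log_p(x: int) -> float:
            return _log_comb(r1, x) + _log_comb(r2, c1 - x) - log_denom

        lo, hi = max(0, c1 - r2), min(r1, c1)
        lp_obs = log_p(a)
        # 1e-7 relative slack absorbs round-off when comparing equal masses,
        # the same guard scipy uses.
        total = 0.0
        for x in range(lo, hi + 1):
            lp = log_p(x)
            if lp <= lp_obs + 1e-7:
                total += math.exp(lp)
        p = min(total, 1.0)
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return FisherResult(p_two_sided=p, odds_ratio=odds)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def gravy(sequence: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathicity: mean per-residue hydropathy.

    ``X`` (unknown residue) is excluded from both numerator and
    denominator; any other residue missing from the scale is an error.
    """
    seq = sequence.upper()
    if not seq:
        raise ValidationError("empty sequence")
    values = []
    for r in seq:
        if r == "X":
            continue
        if r not in scale:
            raise ValidationError(f"residue {r!r} not in hydropathy scale {scale.name!r}")
        values.append(scale[r])
    if not values:
        raise ValidationError("sequence contains only X residues")
    return float(np.mean(values))


@dataclass
class FrequencyProfile:
    """Binned frequencies in percent of the cohort; sums to 100."""

    bin_edges: np.ndarray  # len(frequencies) + 1, half-open [edge, edge+width)
    frequencies: np.ndarray  # percent per bin
    cohort_label: str = ""
    n_values: int = 0
    n_out_of_range: int = 0

    @property
    def out_of_range(self) -> bool:
        return self.n_out_of_range > 0


def frequency_profile(
    values: Sequence[float],
    bin_width: float,
    value_range: tuple[float, float],
    rescale: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
    cohort_label: str = "",
) -> FrequencyProfile:
    """Bin values into half-open classes and convert to percent.

    ``rescale`` is an explicit linear map ((in_lo, in_hi), (out_lo, out_hi))
    applied before binning — e.g. GRAVY values on [−4.5, 4.5] mapped to the
    0–100 display scale. Values outside ``value_range`` are counted in the
    boundary bins and flagged via ``n_out_of_range``; nothing is dropped,
    so percentages always sum to 100.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    lo, hi = value_range
    if not hi > lo:
        raise ValidationError("value range must satisfy hi > lo")
    data = np.asarray(values, dtype=float)
    if data.size == 0:
        raise ValidationError("no values to profile")
    if rescale is not None:
        (in_lo, in_hi), (out_lo, out_hi) = rescale
        if in_hi == in_lo:
            raise ValidationError("degenerate rescale input interval")
        data = out_lo + (data - in_lo) * (out_hi - out_lo) / (in_hi - in_lo)
    edges = np.arange(lo, hi + bin_width, bin_width, dtype=float)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    n_out = int(np.sum((data < lo) | (data >= edges[-1])))
    clipped = np.clip(data, lo, np.nextafter(edges[-1], -np.inf))
    idx = np.floor((clipped - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return FrequencyProfile(
        bin_edges=edges,
        frequencies=100.0 * counts / data.size,
        cohort_label=cohort_label,
        n_values=int(data.size),
        n_out_of_range=n_out,
    )


#: Default GRAVY display rescaling: Kyte–Doolittle range onto 0–100.
GRAVY_RESCALE = ((-4.5, 4.5), (0.0, 100.0))


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable2x2
    p_two_sided: float
    odds_ratio: float


def enrichment_report(
    screen: ScreenSummary,
    sensitive_label: str = LABEL_SENSITIVE,
    signal_type: SignalType = SignalType.SAS,
) -> EnrichmentResult:
    """Motif × sensitivity enrichment among signal anchor sequences.

    Builds the 2×2 table (sensitive with/without motif, non-sensitive
    with/without) from a cohort screen whose rows carry sensitivity
    labels, restricted to the given signal type, and attaches the Fisher
    result. Rows without a sensitivity label are an error — the screen
    and the classification must cover the same cohort.
    """
    relevant = [r for r in screen.rows if not r.skipped and r.signal_type is signal_type]
    if not relevant:
        raise ValidationError(f"no screened records with signal type {signal_type.value}")
    unlabeled = [r.accession for r in relevant if r.sensitivity_label is None]
    if unlabeled:
        raise ValidationError(
            f"{len(unlabeled)} screened records lack sensitivity labels "
            f"(e.g. {unlabeled[0]}); screen and classification cohorts mismatch"
        )
    a = b = c = d = 0
    for row in relevant:
        if row.sensitivity_label == sensitive_label:
            a, b = (a + 1, b) if row.matched else (a, b + 1)
        else:
            c, d = (c + 1, d) if row.matched else (c, d + 1)
    table = ContingencyTable2x2(a, b, c, d)
    result = fisher_exact(table)
    return EnrichmentResult(table=table, p_two_sided=result.p_two_sided, odds_ratio=result.odds_ratio)
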