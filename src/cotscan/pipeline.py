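"""End-to-end pipeline: classify → motif screen → enrichment → profiles.

Produces a single report whose every number is recomputable from the
inputs plus the provenance block (config, seed, package version, input
hashes). Stages degrade gracefully: with only a ratio table the report
contains the classification section and marks the screen skipped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Any, Optional, Sequence

from .core import (
    DEFAULT_SCHEME,
    ResidueClassScheme,
    SignalSequenceRecord,
    SilacRatioRecord,
    ValidationError,
)
from .motif import ccm_pattern_family, screen_cohort
from .silac import DEFAULT_THRESHOLD, classify_table
from .stats import GRAVY_RESCALE, enrichment_report, frequency_profile, gravy


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and row context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineReport:
    classification: Optional[dict] = None
    screen: Optional[dict] = None
    enrichment: Optional[dict] = None
    profiles: Optional[dict] = None
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "screen": self.screen,
            "enrichment": self.enrichment,
            "profiles": self.profiles,
            "skipped": self.skipped,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = ["cotscan pipeline report", "=" * 24]
        if self.classification:
            c = self.classification
            lines.append(
                f"classification (threshold {c['threshold']}): "
                f"{c['total']} proteins"
            )
            for key, counts in sorted(c["counts"].items()):
                lines.append(f"  {key}: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
        if self.screen:
            s = self.screen
            lines.append(
                f"motif screen: {s['n_with_motif']} with / {s['n_without_motif']} without"
                f" (skipped {s['n_skipped']})"
            )
        if self.enrichment:
            e = self.enrichment
            lines.append(
                "enrichment (SAS): table "
                f"({e['table']['a']},{e['table']['b']},{e['table']['c']},{e['table']['d']}), "
                f"p={e['p_two_sided']:.3g}, OR={e['odds_ratio']}"
            )
        for stage, reason in self.skipped.items():
            lines.append(f"[skipped] {stage}: {reason}")
        return "\n".join(lines)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _package_version() -> str:
    try:
        return metadata.version("cotscan")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline(
    ratios: Optional[Sequence[SilacRatioRecord]] = None,
    sequences: Optional[Sequence[SignalSequenceRecord]] = None,
    threshold: float = DEFAULT_THRESHOLD,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    margin: int = 2,
    provenance: Optional[dict[str, Any]] = None,
    input_paths: Optional[dict[str, str]] = None,
) -> PipelineReport:
    """Run classification, motif screen, enrichment and property profiles.

    Either input may be omitted; dependent stages are then marked skipped.
    """
    report = PipelineReport()
    prov: dict[str, Any] = {
        "package_version": _package_version(),
        "threshold": threshold,
        "scheme": {
            "name": scheme.name,
            "small": sorted(scheme.small),
            "bulky": sorted(scheme.bulky),
            "flank": sorted(scheme.flank),
        },
        "margin": margin,
    }
    if provenance:
        prov.update(provenance)
    if input_paths:
        prov["input_hashes"] = {
            name: _hash_file(Path(p)) for name, p in input_paths.items() if Path(p).exists()
        }
    report.provenance = prov

    labels: Optional[dict[str, str]] = None
    if ratios is not None:
        try:
            summary = classify_table(ratios, threshold)
        except ValidationError as exc:
            raise PipelineStageError("classify", str(exc)) from exc
        labels = summary.labels()
        report.classification = {
            "threshold": threshold,
            "total": summary.total,
            "counts": {f"{cls}/{styp}": dict(ctr) for (cls, styp), ctr in summary.counts.items()},
        }
    else:
        report.skipped["classify"] = "no ratio table supplied"

    screen = None
    if sequences is not None:
        try:
            patterns = ccm_pattern_family(scheme)
            screen = screen_cohort(sequences, patterns, margin=margin, sensitivity=labels)
        except ValidationError as exc:
            raise PipelineStageError("screen", str(exc)) from exc
        totals = screen.counts()
        report.screen = {
            "n_with_motif": totals["with"],
            "n_without_motif": totals["without"],
            "n_skipped": screen.n_skipped,
            "by_category": {
                "/".join(str(k) for k in key): counts
                for key, counts in screen.by_category().items()
            },
            "matches": [
                {
                    "accession": r.accession,
                    "start": r.first_match.start,
                    "end": r.first_match.end,
                    "patch1": list(r.first_match.patch1_span),
                    "separator": list(r.first_match.separator_span),
                    "patch2": list(r.first_match.patch2_span),
                }
                for r in screen.rows
                if r.matched and r.first_match is not None
            ],
        }
    else:
        report.skipped["screen"] = "no sequences supplied"

    if screen is not None and labels is not None:
        try:
            enr = enrichment_report(screen)
            report.enrichment = {
                "table": {"a": enr.table.a, "b": enr.table.b, "c": enr.table.c, "d": enr.table.d},
                "p_two_sided": enr.p_two_sided,
                "odds_ratio": (
                    enr.odds_ratio if enr.odds_ratio == enr.odds_ratio and enr.odds_ratio != float("inf")
                    else str(enr.odds_ratio)
                ),
            }
        except ValidationError as exc:
            report.skipped["enrich"] = str(exc)
    else:
        report.skipped.setdefault("enrich", "needs both ratios and sequences")

    if sequences is not None:
        try:
            report.profiles = _profiles(sequences, labels)
        except ValidationError as exc:
            raise PipelineStageError("profile", str(exc)) from exc
    else:
        report.skipped["profile"] = "no sequences supplied"
    return report


def _profiles(
    sequences: Sequence[SignalSequenceRecord], labels: Optional[dict[str, str]]
) -> dict:
    """GRAVY and length frequency profiles per (class, sensitivity) cohort."""
    groups: dict[str, list[SignalSequenceRecord]] = {}
    for rec in sequences:
        if not rec.has_boundaries:
            continue
        label = labels.get(rec.accession, "unlabelled") if labels else "all"
        groups.setdefault(f"{rec.protein_class.value}/{label}", []).append(rec)
    out = {}
    for name, recs in sorted(groups.items()):
        signal_seqs = [r.signal_sequence for r in recs]
        gravies = [gravy(s) for s in signal_seqs]
        lengths = [float(len(s)) for s in signal_seqs]
        gp = frequency_profile(gravies, 4.0, (0.0, 100.0), rescale=GRAVY_RESCALE, cohort_label=name)
        lp = frequency_profile(lengths, 4.0, (0.0, 50.0), cohort_label=name)
        out[name] = {
            "n": len(recs),
            "gravy_percent": [round(v, 6) for v in gp.frequencies.tolist()],
            "length_percent": [round(v, 6) for v in lp.frequencies.tolist()],
            "gravy_bin_edges": gp.bin_edges.tolist(),
            "length_bin_edges": lp.bin_edges.tolist(),
        }
    return out
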