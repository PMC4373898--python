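"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython; tabular files are tab-separated UTF-8 with a
required header and "." as the decimal mark. Round-trips are lossless:
ratio values are written with :class:`repr` precision so read(write(x)) is
bit-for-bit identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DoseResponseDataset,
    ProteinClass,
    SignalSequenceRecord,
    SignalType,
    SilacRatioRecord,
    Topology,
    ValidationError,
)

PathLike = Union[str, Path]

ANNOTATION_COLUMNS = ["accession", "class", "signal_type", "signal_start", "signal_end", "topology"]
RATIO_COLUMNS = ["accession", "forward_ratio", "reverse_ratio"]
DOSE_RESPONSE_COLUMNS = ["concentration", "replicate", "percent"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(accession, sequence)`` pairs.

    Sequences are upper-cased and whitespace-stripped; an entry with an
    empty sequence raises :class:`FormatError` naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not rec.id:
            raise FormatError(f"{path}: FASTA entry with empty header")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(path: PathLike, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=accession, description="") for accession, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


_TOPOLOGY_ALIASES = {
    "nc": Topology.NC,
    "ne": Topology.NE,
    "n/s": Topology.UNSPECIFIED,
    "ns": Topology.UNSPECIFIED,
    "unspecified": Topology.UNSPECIFIED,
    "": Topology.UNSPECIFIED,
}

_SIGNAL_TYPE_ALIASES = {
    "sp": SignalType.SP,
    "sas": SignalType.SAS,
    "n/s": SignalType.UNSPECIFIED,
    "ns": SignalType.UNSPECIFIED,
    "unspecified": SignalType.UNSPECIFIED,
    "": SignalType.UNSPECIFIED,
}


def _parse_signal_type(text: object) -> SignalType:
    key = "" if text is None or (isinstance(text, float) and math.isnan(text)) else str(text).strip().lower()
    try:
        return _SIGNAL_TYPE_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unknown signal type {text!r}") from None


def _parse_topology(text: object) -> Topology:
    key = "" if text is None or (isinstance(text, float) and math.isnan(text)) else str(text).strip().lower()
    try:
        return _TOPOLOGY_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unknown topology {text!r}") from None


def read_annotation_table(
    path: PathLike, sequences: Optional[dict[str, str]] = None
) -> list[SignalSequenceRecord]:
    """Read a signal-sequence annotation TSV into typed records.

    ``sequences`` maps accession to full sequence (e.g. from
    :func:`read_fasta`); if omitted, a poly-X placeholder long enough for
    the annotated boundaries is used so the table can be inspected alone.
    Coordinate violations raise :class:`ValidationError` with the 1-based
    data-row number; nothing is clamped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        accession = str(row["accession"])
        try:
            start = int(row["signal_start"])
            end = int(row["signal_end"])
            if sequences is not None:
                if accession not in sequences:
                    raise ValidationError(f"{accession}: no sequence provided")
                seq = sequences[accession]
            else:
                seq = "X" * max(end, 1)
            records.append(
                SignalSequenceRecord(
                    accession=accession,
                    full_sequence=seq,
                    protein_class=ProteinClass(str(row["class"]).strip().lower()),
                    signal_type=_parse_signal_type(row["signal_type"]),
                    signal_start=start,
                    signal_end=end,
                    topology=_parse_topology(row["topology"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_annotation_table(path: PathLike, records: Iterable[SignalSequenceRecord]) -> None:
    rows = [
        {
            "accession": r.accession,
            "class": r.protein_class.value,
            "signal_type": r.signal_type.value if r.signal_type is not SignalType.UNSPECIFIED else "n/s",
            "signal_start": r.signal_start,
            "signal_end": r.signal_end,
            "topology": r.topology.value if r.topology is not Topology.UNSPECIFIED else "n/s",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_ratio(text: object, label: str, context: str) -> Optional[float]:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return None
    s = str(text).strip()
    if s in ("", "NA", "nan"):
        return None
    value = float(s)
    if not value > 0:
        raise ValidationError(f"{context}: {label} ratio must be positive, got {value}")
    return value


def read_ratio_table(path: PathLike) -> list[SilacRatioRecord]:
    """Read a SILAC label-swap ratio TSV.

    Required columns: accession, forward_ratio (DMSO/cotransin as H/L),
    reverse_ratio (DMSO/cotransin as L/H). Optional: class, signal_type.
    A missing ratio flags the record incomplete; a non-positive ratio is a
    validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(RATIO_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    has_class = "class" in df.columns
    has_type = "signal_type" in df.columns
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        context = f"{path}: row {i}"
        try:
            protein_class = None
            if has_class:
                raw = row["class"]
                if raw is not None and not (isinstance(raw, float) and math.isnan(raw)) and str(raw).strip():
                    protein_class = ProteinClass(str(raw).strip().lower())
            records.append(
                SilacRatioRecord(
                    accession=str(row["accession"]),
                    forward_ratio=_parse_ratio(row["forward_ratio"], "forward", context),
                    reverse_ratio=_parse_ratio(row["reverse_ratio"], "reverse", context),
                    protein_class=protein_class,
                    signal_type=_parse_signal_type(row["signal_type"]) if has_type else SignalType.UNSPECIFIED,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{context}: {exc}") from exc
    return records


def write_ratio_table(path: PathLike, records: Iterable[SilacRatioRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "accession": r.accession,
                "forward_ratio": "" if r.forward_ratio is None else repr(r.forward_ratio),
                "reverse_ratio": "" if r.reverse_ratio is None else repr(r.reverse_ratio),
                "class": "" if r.protein_class is None else r.protein_class.value,
                "signal_type": r.signal_type.value if r.signal_type is not SignalType.UNSPECIFIED else "n/s",
            }
        )
    pd.DataFrame(rows, columns=RATIO_COLUMNS + ["class", "signal_type"]).to_csv(
        path, sep="\t", index=False
    )


def read_dose_response_table(path: PathLike) -> DoseResponseDataset:
    """Read a cytometry dose-response TSV (concentration, replicate, percent)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DOSE_RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return DoseResponseDataset(
        concentration=[float(v) for v in df["concentration"]],
        response_percent=[float(v) for v in df["percent"]],
        replicate=[int(v) for v in df["replicate"]],
    )


def write_dose_response_table(path: PathLike, dataset: DoseResponseDataset) -> None:
    pd.DataFrame(
        {
            "concentration": [repr(v) for v in dataset.concentration],
            "replicate": dataset.replicate,
            "percent": [repr(v) for v in dataset.response_percent],
        }
    ).to_csv(path, sep="\t", index=False)


def join_sequences(
    fasta_records: Sequence[tuple[str, str]],
    annotations: Sequence[SignalSequenceRecord],
) -> list[SignalSequenceRecord]:
    """Attach real sequences to annotation rows; re-validates coordinates."""
    sequences = dict(fasta_records)
    joined = []
    for rec in annotations:
        if rec.accession not in sequences:
            raise ValidationError(f"{rec.accession}: annotated but absent from FASTA")
        joined.append(
            SignalSequenceRecord(
                accession=rec.accession,
                full_sequence=sequences[rec.accession],
                protein_class=rec.protein_class,
                signal_type=rec.signal_type,
                signal_start=rec.signal_start,
                signal_end=rec.signal_end,
                topology=rec.topology,
            )
        )
    return joined
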