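"""Shared readers and writers: FASTA, GFF3 and ITC isotherm CSV.

All in-memory coordinates in this package are 0-based, half-open.
GFF3 files follow the format convention (1-based, inclusive); the
converters here are the single place where that translation happens.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "Feature",
    "read_gff3",
    "write_gff3",
    "ISOTHERM_COLUMNS",
]

ISOTHERM_COLUMNS = ["injection", "volume_uL", "heat_ucal", "ratio", "ndh_kcal_per_mol"]


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, preserving order and descriptions.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record: {rec.id!r}")
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path) -> None:
    """Write records (SeqRecords or (id, sequence) pairs), wrapped at 60 columns."""
    recs = []
    for rec in records:
        if isinstance(rec, tuple):
            rec = SeqRecord(Seq(rec[1]), id=rec[0], description="")
        recs.append(rec)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)


@dataclass
class Feature:
    """One GFF3 feature, held with 0-based half-open coordinates."""

    seqid: str
    type: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"
    source: str = "ta3scan"
    score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _fmt_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features: Sequence[Feature], path, pragmas: Sequence[str] = ()) -> None:
    """Write features as GFF3 (coordinates converted to 1-based inclusive)."""
    lines = ["##gff-version 3"]
    lines.extend(pragmas)
    for f in features:
        start1 = f.start + 1
        if start1 < 1:
            raise ValueError("coordinate < 1 after 1-based conversion")
        score = "." if f.score is None else f"{f.score:g}"
        lines.append(
            "\t".join(
                [
                    f.seqid,
                    f.source,
                    f.type,
                    str(start1),
                    str(f.end),
                    score,
                    f.strand,
                    ".",
                    _fmt_attributes(f.attributes),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> tuple[list[Feature], list[str]]:
    """Parse a GFF3 file back into Features (0-based half-open) and pragmas."""
    features: list[Feature] = []
    pragmas: list[str] = []
    text = Path(path).read_text()
    for line in _io.StringIO(text):
        line = line.rstrip("\r\n")
        if not line:
            continue
        if line.startswith("##gff-version"):
            continue
        if line.startswith("#"):
            pragmas.append(line)
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        seqid, source, ftype, start, end, score, strand, _phase, attrs = cols
        attributes = {}
        if attrs not in (".", ""):
            for item in attrs.split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attributes[key] = value
        features.append(
            Feature(
                seqid=seqid,
                source=source,
                type=ftype,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                score=None if score == "." else float(score),
                attributes=attributes,
            )
        )
    return features, pragmas
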