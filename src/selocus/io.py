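"""File I/O: FASTA sequences and TSV tables.

All tabular interchange is tab-separated with a header row (no quoting
ambiguity); sequences travel as plain single-record-per-accession FASTA.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fertility import FertilityRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "read_fertility",
    "write_distribution",
]

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTNRYSWKMBDHV")  # IUPAC nucleotide codes


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs.

    IDs are preserved verbatim and must be unique; sequences are normalised
    to uppercase (logged when lowercase input is seen) and validated against
    the IUPAC nucleotide alphabet.  An empty file is an error.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record ID {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if raw != raw.upper():
            logger.info("%s: normalising lowercase bases in %s", path, rec.id)
        seq = raw.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: illegal characters {sorted(bad)} in record {rec.id!r}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as 60-column-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def _open_tsv(path: Path, required: Sequence[str]) -> tuple[list[dict], list[str]]:
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        extra = [c for c in header if c not in required]
        if extra:
            logger.warning("%s: ignoring extra columns %s", path, extra)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append({"_lineno": lineno, **dict(zip(header, row))})
    return rows, header


def read_counts(path: str | Path) -> dict[str, dict[str, int]]:
    """Read segregation counts: columns cross_id, class, count.

    Returns ``{cross_id: {genotype class: count}}``.
    """
    path = Path(path)
    rows, _ = _open_tsv(path, ["cross_id", "class", "count"])
    out: dict[str, dict[str, int]] = {}
    for row in rows:
        lineno = row["_lineno"]
        try:
            count = int(row["count"])
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: count {row['count']!r} is not an integer"
            ) from None
        if count < 0:
            raise ValueError(f"{path}: line {lineno}: negative count {count}")
        cross = out.setdefault(row["cross_id"], {})
        key = row["class"]
        if key in cross:
            raise ValueError(
                f"{path}: line {lineno}: duplicate class {key!r} for cross "
                f"{row['cross_id']!r}"
            )
        cross[key] = count
    return out


def read_fertility(path: str | Path) -> list[FertilityRecord]:
    """Read fertility measurements: columns plant_id, stained_fraction, n_pollen."""
    path = Path(path)
    rows, _ = _open_tsv(path, ["plant_id", "stained_fraction", "n_pollen"])
    records = []
    for row in rows:
        lineno = row["_lineno"]
        try:
            fraction = float(row["stained_fraction"])
            n_pollen = int(row["n_pollen"])
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: malformed numeric field") from None
        try:
            records.append(
                FertilityRecord(
                    plant_id=row["plant_id"],
                    stained_fraction=fraction,
                    n_pollen=n_pollen,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_distribution(
    classes: Mapping[str, float], n: int | None, path: str | Path
) -> None:
    """Write a genotype-class distribution as TSV (class, probability[, expected_count])."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        header = ["class", "probability"]
        if n is not None:
            header.append("expected_count")
        writer.writerow(header)
        for key in sorted(classes):
            row = [key, f"{classes[key]:.10g}"]
            if n is not None:
                row.append(f"{classes[key] * n:.10g}")
            writer.writerow(row)
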