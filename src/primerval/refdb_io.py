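"""Reference-database, lineage-table and primer-table I/O.

A reference database is a nucleotide FASTA plus a per-record lineage table.
Two lineage dialects are accepted: ``record_id<TAB>rank=name;rank=name;...``
and a seven-column fixed-rank layout (``record_id`` then phylum, class,
order, family, genus, species; empty cell = unannotated). Sequences are
uppercased on read and U is mapped to T, since rDNA entries in public
databases mix cases and RNA alphabets.

Records that fail structural validation are *reported with machine-readable
reason codes*, never silently dropped, mirroring how database-format
conversion losses are accounted for upstream of an in silico PCR run.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO

from .iupac import VALID_CODES, is_iupac
from .taxonomy import CANONICAL_RANKS, Lineage, taxon_at, UNANNOTATED

# reason codes used in exclusion reports
REASON_NO_LINEAGE = "no_lineage"
REASON_NO_SEQUENCE = "no_sequence"
REASON_EMPTY_SEQUENCE = "empty_sequence"
REASON_INVALID_CHARACTER = "invalid character"
REASON_INCOMPLETE_LINEAGE = "lineage_not_prefix_complete"
REASON_WRONG_PHYLUM = "non_target_phylum"


@dataclass(frozen=True)
class ReferenceRecord:
    """One database sequence with its taxonomic lineage."""

    record_id: str
    sequence: str
    lineage: Lineage
    source_tag: str = ""

    def validation_error(self) -> str | None:
        """Reason string if the record violates a structural invariant."""
        if not self.sequence:
            return REASON_EMPTY_SEQUENCE
        bad = set(self.sequence) - VALID_CODES
        if bad:
            return f"{REASON_INVALID_CHARACTER} {sorted(bad)[0]!r}"
        if not self.lineage.is_prefix_complete("family"):
            return REASON_INCOMPLETE_LINEAGE
        return None

    @property
    def is_valid(self) -> bool:
        return self.validation_error() is None


@dataclass(frozen=True)
class Reject:
    """A record excluded from analysis, with a machine-readable reason."""

    record_id: str
    reason: str


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse IUPAC primer sequences (both 5'->3') with the
    minimum and maximum allowed inter-primer amplicon length in bp
    (primer footprints excluded)."""

    name: str
    forward: str
    reverse: str
    min_len: int
    max_len: int

    def __post_init__(self):
        for side, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not (10 <= len(seq) <= 30):
                raise ValueError(
                    f"primer {self.name!r}: {side} length {len(seq)} "
                    "outside [10, 30]"
                )
            bad = [i for i, c in enumerate(seq) if c not in VALID_CODES]
            if bad:
                raise ValueError(
                    f"primer {self.name!r}: non-IUPAC character "
                    f"{seq[bad[0]]!r} at position {bad[0] + 1} of {side}"
                )
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(
                f"primer {self.name!r}: invalid length bounds "
                f"min_len={self.min_len}, max_len={self.max_len}"
            )


# ---------------------------------------------------------------------------
# lineage tables

def _parse_lineage_cell(cell: str) -> Lineage:
    ranks = {}
    for part in cell.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed lineage entry {part!r}")
        rank, name = part.split("=", 1)
        ranks[rank.strip()] = name.strip()
    return Lineage(ranks)


def read_lineage_table(source: str | Path | TextIO) -> dict[str, Lineage]:
    """Read a lineage TSV in either supported dialect.

    Returns a map record_id -> Lineage. Duplicate ids raise ValueError.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    try:
        lineages: dict[str, Lineage] = {}
        for line_no, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            rid = fields[0].strip()
            if line_no == 1 and rid.lower() in {"record_id", "id"}:
                continue  # optional header
            if rid in lineages:
                raise ValueError(f"duplicate record_id {rid!r} in lineage table")
            if len(fields) == 2:
                lineages[rid] = _parse_lineage_cell(fields[1])
            elif len(fields) == 7:
                ranks = {
                    rank: cell.strip()
                    for rank, cell in zip(CANONICAL_RANKS, fields[1:])
                    if cell.strip()
                }
                lineages[rid] = Lineage(ranks)
            else:
                raise ValueError(
                    f"line {line_no}: expected 2 or 7 tab-separated fields, "
                    f"got {len(fields)}"
                )
        return lineages
    finally:
        if close:
            handle.close()


def write_lineage_table(records: Iterable[ReferenceRecord],
                        path: str | Path) -> None:
    """Write lineages in the ``rank=name;...`` dialect (sorted ranks kept in
    canonical order by Lineage itself)."""
    with open(path, "w") as out:
        for rec in records:
            cell = ";".join(f"{r}={n}" for r, n in rec.lineage.ranks.items())
            out.write(f"{rec.record_id}\t{cell}\n")


# ---------------------------------------------------------------------------
# reference databases

def _clean_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_reference_db(
    fasta_source: str | Path | TextIO,
    lineage_source: str | Path | TextIO | Mapping[str, Lineage],
) -> tuple[list[ReferenceRecord], list[Reject]]:
    """Read a FASTA + lineage table into ReferenceRecords.

    Every FASTA entry with a lineage yields one record (still subject to the
    structural filter in :func:`filter_records`); entries lacking a lineage or
    containing invalid characters are returned as :class:`Reject` objects with
    reason codes rather than silently dropped. Duplicate FASTA ids raise.
    """
    if isinstance(lineage_source, dict):
        lineages = lineage_source
    else:
        lineages = read_lineage_table(lineage_source)

    records: list[ReferenceRecord] = []
    rejects: list[Reject] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(fasta_source, "fasta"):
        rid = entry.id
        if not rid:
            raise ValueError(f"malformed FASTA: empty header {entry.description!r}")
        if rid in seen:
            raise ValueError(f"duplicate record_id {rid!r} in FASTA")
        seen.add(rid)
        seq = _clean_sequence(str(entry.seq))
        if rid not in lineages:
            rejects.append(Reject(rid, REASON_NO_LINEAGE))
            continue
        if not seq:
            rejects.append(Reject(rid, REASON_EMPTY_SEQUENCE))
            continue
        if not is_iupac(seq):
            bad = sorted(set(seq) - VALID_CODES)[0]
            rejects.append(Reject(rid, f"{REASON_INVALID_CHARACTER} {bad!r}"))
            continue
        records.append(ReferenceRecord(rid, seq, lineages[rid],
                                       source_tag=entry.description))
    for rid in lineages:
        if rid not in seen:
            rejects.append(Reject(rid, REASON_NO_SEQUENCE))
    return records, rejects


def write_reference_db(records: Sequence[ReferenceRecord],
                       fasta_path: str | Path,
                       lineage_path: str | Path) -> None:
    """Write records as FASTA + lineage TSV (round-trips with
    :func:`read_reference_db` on record_id, sequence and lineage)."""
    with open(fasta_path, "w") as out:
        for rec in records:
            out.write(f">{rec.record_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                out.write(seq[i:i + 70] + "\n")
    write_lineage_table(records, lineage_path)


def filter_records(
    records: Sequence[ReferenceRecord],
    target_phylum: str | None = None,
) -> tuple[list[ReferenceRecord], list[Reject]]:
    """Apply the pre-analysis exclusion filter.

    Excludes records failing structural validation (empty or non-IUPAC
    sequence, lineage not prefix-complete below family) and, when
    ``target_phylum`` is given, records annotated to a different phylum.
    kept + excluded always partition the input.
    """
    if not records:
        raise ValueError("filter_records requires a non-empty record list")
    kept: list[ReferenceRecord] = []
    excluded: list[Reject] = []
    for rec in records:
        err = rec.validation_error()
        if err is not None:
            excluded.append(Reject(rec.record_id, err))
            continue
        if target_phylum is not None:
            phylum = taxon_at(rec.lineage, "phylum")
            if phylum is not UNANNOTATED and phylum != target_phylum:
                excluded.append(Reject(rec.record_id, REASON_WRONG_PHYLUM))
                continue
        kept.append(rec)
    if not kept:
        warnings.warn("filter_records: no records survived the filter")
    return kept, excluded


def write_exclusion_report(excluded: Iterable[Reject],
                           path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(["record_id", "reason"])
        for rej in excluded:
            writer.writerow([rej.record_id, rej.reason])


# ---------------------------------------------------------------------------
# primer tables

def read_primer_table(source: str | Path | TextIO) -> list[PrimerPair]:
    """Read a primer TSV with columns name, forward, reverse, min_len,
    max_len. Validation errors name the offending primer and position."""
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"name", "forward", "reverse", "min_len", "max_len"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"primer table must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        pairs = []
        for row in reader:
            pairs.append(PrimerPair(
                name=row["name"].strip(),
                forward=row["forward"].strip().upper().replace("U", "T"),
                reverse=row["reverse"].strip().upper().replace("U", "T"),
                min_len=int(row["min_len"]),
                max_len=int(row["max_len"]),
            ))
        return pairs
    finally:
        if close:
            handle.close()


def load_default_primer_panel() -> list[PrimerPair]:
    """The packaged panel of 15 published 18S rDNA primer pairs for nematode
    metabarcoding, with their literature amplicon-length bounds."""
    from importlib.resources import files

    source = files("primerval.data").joinpath("primer_panel_18s.tsv")
    with source.open() as handle:
        return read_primer_table(handle)
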