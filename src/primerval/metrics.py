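"""Primer-performance statistics: coverage, taxonomic resolution, specificity.

Coverage is the fraction of reference-database sequences amplified at all.
Resolution at a rank is computed over *unique metabarcodes*: the designated
amplicons of all amplified records are grouped by exact metabarcode string,
and a group is resolved at a rank when every member lineage carries the same
taxon name there. Groups containing a member unannotated at the queried rank
are, by default, excluded from both numerator and denominator at that rank
(annotation gaps should not penalise a primer); the alternative of counting
them as unresolved is available via ``incomplete``.

Specificity is measured on a mixed-phylum database after retaining one
sequence per species (seeded random choice, to avoid over-represented model
species dominating the count): the fraction of amplified sequences belonging
to the target phylum, together with the number of distinct target species
amplified.
"""

from __future__ import annotations

import csv
import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import taxonomy
from .insilico_pcr import AmplificationResult
from .refdb_io import ReferenceRecord
from .taxonomy import Lineage, UNANNOTATED, taxon_at

#: default seed for the one-sequence-per-species draw; recorded in run
#: manifests so specificity runs are reproducible by construction.
DEFAULT_DEDUP_SEED = 20240405

# incomplete-group policies for resolution()
EXCLUDE = "exclude"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class MetabarcodeGroup:
    """One unique metabarcode and the records/taxa that produce it."""

    metabarcode: str
    members: tuple[tuple[str, Lineage], ...]  # (record_id, lineage)

    def __post_init__(self):
        if not self.members:
            raise ValueError("MetabarcodeGroup requires at least one member")

    @property
    def lineages(self) -> list[Lineage]:
        return [lin for _, lin in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EvaluationReport:
    """One primer's evaluation row: coverage, amplicon-length summary and
    per-rank resolution (None where undefined)."""

    primer_name: str
    coverage: float
    mean_len: float | None
    min_len_obs: int | None
    max_len_obs: int | None
    resolution_species: float | None
    resolution_genus: float | None
    resolution_family: float | None
    n_amplified: int
    n_total: int


def coverage(result: AmplificationResult) -> float:
    """Fraction of database records with at least one hit."""
    if result.n_total == 0:
        raise ValueError("coverage undefined on an empty database")
    return result.n_amplified / result.n_total


def group_metabarcodes(result: AmplificationResult,
                       records: Sequence[ReferenceRecord]
                       ) -> list[MetabarcodeGroup]:
    """Group designated metabarcodes by exact string.

    The groups partition the amplified records; group sizes sum to
    n_amplified. Sorted by metabarcode for determinism.
    """
    by_id = {rec.record_id: rec for rec in records}
    buckets: dict[str, list[tuple[str, Lineage]]] = {}
    for rid, hit in result.designated.items():
        if rid not in by_id:
            raise KeyError(f"hit references unknown record {rid!r}")
        buckets.setdefault(hit.metabarcode, []).append((rid, by_id[rid].lineage))
    return [
        MetabarcodeGroup(bc, tuple(sorted(members)))
        for bc, members in sorted(buckets.items())
    ]


def resolution(groups: Sequence[MetabarcodeGroup], rank: str,
               incomplete: str = EXCLUDE) -> float | None:
    """Fraction of unique metabarcodes resolved at ``rank``.

    Each group counts once regardless of size. With the default
    ``incomplete=EXCLUDE`` policy, groups whose verdict is 'incomplete' enter
    neither numerator nor denominator; with ``incomplete=UNRESOLVED`` they
    count in the denominator only. Returns None (with a warning) when the
    denominator is empty.
    """
    if not groups:
        raise ValueError("resolution requires at least one metabarcode group")
    if incomplete not in (EXCLUDE, UNRESOLVED):
        raise ValueError(f"unknown incomplete policy {incomplete!r}")
    num = den = 0
    for group in groups:
        verdict = taxonomy.same_taxon_at(group.lineages, rank)
        if verdict == taxonomy.INCOMPLETE:
            if incomplete == UNRESOLVED:
                den += 1
            continue
        den += 1
        if verdict == taxonomy.AGREE:
            num += 1
    if den == 0:
        warnings.warn(
            f"resolution at rank {rank!r} undefined: every group is "
            "incomplete at this rank"
        )
        return None
    return num / den


def dedup_one_per_species(records: Sequence[ReferenceRecord],
                          seed: int = DEFAULT_DEDUP_SEED
                          ) -> list[ReferenceRecord]:
    """Retain one seeded-random sequence per distinct species name.

    Records unannotated at species level are kept as their own singletons
    (keyed by record_id). Output order follows the input; same seed and input
    give the same selection.
    """
    rng = random.Random(seed)
    by_species: dict[object, list[ReferenceRecord]] = {}
    for rec in records:
        sp = taxon_at(rec.lineage, "species")
        key = ("species", sp) if sp is not UNANNOTATED else ("record", rec.record_id)
        by_species.setdefault(key, []).append(rec)
    chosen: set[str] = set()
    for key in sorted(by_species, key=str):
        chosen.add(rng.choice(by_species[key]).record_id)
    return [rec for rec in records if rec.record_id in chosen]


def specificity(amplified_records: Sequence[ReferenceRecord],
                target_phylum: str) -> tuple[float | None, int]:
    """Specificity = amplified target-phylum records / all amplified records.

    ``amplified_records`` are the amplified sequences of an
    already-deduplicated (one per species) database. Also returns the number
    of distinct target species amplified. Returns (None, 0) with a warning
    when nothing amplified.
    """
    if not amplified_records:
        warnings.warn("specificity undefined: no amplified records")
        return None, 0
    n_target = 0
    target_species: set[str] = set()
    for rec in amplified_records:
        if taxon_at(rec.lineage, "phylum") == target_phylum:
            n_target += 1
            sp = taxon_at(rec.lineage, "species")
            if sp is not UNANNOTATED:
                target_species.add(sp)
    return n_target / len(amplified_records), len(target_species)


def build_report(result: AmplificationResult,
                 records: Sequence[ReferenceRecord],
                 incomplete: str = EXCLUDE) -> EvaluationReport:
    """Assemble one evaluation row for a primer over a database.

    Length summaries are over designated hits and exclude primer footprints.
    With zero amplification, coverage is 0 and resolutions/lengths are None.
    """
    cov = coverage(result)
    if result.n_amplified == 0:
        return EvaluationReport(result.primer.name, cov, None, None, None,
                                None, None, None, 0, result.n_total)
    lens = [result.designated[rid].amplicon_len
            for rid in result.amplified_ids]
    groups = group_metabarcodes(result, records)
    return EvaluationReport(
        primer_name=result.primer.name,
        coverage=cov,
        mean_len=sum(lens) / len(lens),
        min_len_obs=min(lens),
        max_len_obs=max(lens),
        resolution_species=resolution(groups, "species", incomplete),
        resolution_genus=resolution(groups, "genus", incomplete),
        resolution_family=resolution(groups, "family", incomplete),
        n_amplified=result.n_amplified,
        n_total=result.n_total,
    )


# ---------------------------------------------------------------------------
# output

def _fmt(value, digits):
    return "NA" if value is None else f"{value:.{digits}f}"


def write_report_tsv(reports: Iterable[EvaluationReport],
                     path: str | Path, full_precision: bool = True) -> None:
    """Evaluation table; display rounding is 2 decimals for fractions and 1
    for lengths unless ``full_precision``."""
    fd, ld = (6, 3) if full_precision else (2, 1)
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(["primer", "coverage", "mean_len", "min_len_obs",
                         "max_len_obs", "resolution_species",
                         "resolution_genus", "resolution_family",
                         "n_amplified", "n_total"])
        for rep in reports:
            writer.writerow([
                rep.primer_name, _fmt(rep.coverage, fd),
                _fmt(rep.mean_len, ld),
                "NA" if rep.min_len_obs is None else rep.min_len_obs,
                "NA" if rep.max_len_obs is None else rep.max_len_obs,
                _fmt(rep.resolution_species, fd),
                _fmt(rep.resolution_genus, fd),
                _fmt(rep.resolution_family, fd),
                rep.n_amplified, rep.n_total,
            ])


def write_specificity_tsv(rows: Iterable[tuple[str, float | None, int]],
                          path: str | Path) -> None:
    """rows: (primer_name, specificity fraction or None, n target species)."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(["primer", "specificity", "n_target_species"])
        for name, frac, n_sp in rows:
            writer.writerow([name, _fmt(frac, 6), n_sp])
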