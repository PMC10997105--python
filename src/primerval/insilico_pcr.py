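"""The in silico PCR engine.

Amplification of a template by a primer pair is modelled as in ecoPCR-style
tools: find every window matching the forward primer and every window
matching the reverse complement of the reverse primer, on both strands, with
at most ``max_mismatches`` mismatches *per primer* (not summed), and keep
every pair whose inter-primer distance lies within the pair's length bounds.
A mismatch is a position at which the IUPAC base sets of primer and template
do not intersect; matching is ungapped (no indels) and a template N never
adds a mismatch. The extracted metabarcode is the inter-primer region
excluding both primer footprints, oriented 5'->3' relative to the forward
primer. There is no thermodynamic model and no special treatment of 3'
mismatches here; 3'-end weighting belongs to the primer-refinement scan.

Coordinates are 0-based half-open on the forward strand of the stored
sequence; human-facing tables convert to 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .iupac import encode_masks, reverse_complement
from .refdb_io import PrimerPair, ReferenceRecord

DEFAULT_MAX_MISMATCHES = 3


@dataclass(frozen=True)
class AmpliconHit:
    """One in silico amplification event on a template sequence.

    ``fwd_*``/``rev_*`` are the forward- and reverse-primer footprints as
    0-based half-open intervals on the forward strand of the stored
    sequence; on strand '-' the forward primer binds the right-hand interval
    (rev_end <= fwd_start).
    """

    record_id: str
    strand: str  # '+' or '-'
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    mismatches_fwd: int
    mismatches_rev: int
    metabarcode: str

    @property
    def amplicon_len(self) -> int:
        return len(self.metabarcode)


def iupac_mismatches(primer: str, window: str) -> int:
    """Number of positions where the IUPAC sets of primer and window are
    disjoint. Both strings must have equal length; matching is ungapped."""
    if len(primer) != len(window):
        raise ValueError(
            f"primer length {len(primer)} != window length {len(window)}"
        )
    pm = encode_masks(primer)
    wm = encode_masks(window)
    return int(np.count_nonzero((pm & wm) == 0))


def _site_scan(seq_masks: np.ndarray, primer_masks: np.ndarray,
               max_mismatches: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised scan: mismatch count of every window of len(primer).

    Returns (starts, mismatch_counts) of windows within budget, ascending.
    """
    m = len(primer_masks)
    n_windows = len(seq_masks) - m + 1
    if n_windows <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    mism = np.zeros(n_windows, dtype=np.int16)
    for j in range(m):
        mism += (seq_masks[j:j + n_windows] & primer_masks[j]) == 0
    keep = np.flatnonzero(mism <= max_mismatches)
    return keep, mism[keep].astype(int)


def find_binding_sites(sequence: str, primer: str,
                       max_mismatches: int = DEFAULT_MAX_MISMATCHES
                       ) -> list[tuple[int, int, int]]:
    """All (start, end, mismatches) windows of ``sequence`` matching
    ``primer`` within the mismatch budget, in ascending start order."""
    if len(primer) >= len(sequence):
        return []
    starts, mism = _site_scan(encode_masks(sequence), encode_masks(primer),
                              max_mismatches)
    m = len(primer)
    return [(int(s), int(s) + m, int(k)) for s, k in zip(starts, mism)]


def _amplify_one_strand(seq: str, seq_masks: np.ndarray, pair: PrimerPair,
                        max_mismatches: int) -> list[tuple]:
    """Hits on the given oriented sequence: (f_start, f_end, r_start, r_end,
    mm_f, mm_r, metabarcode), coordinates in the oriented frame."""
    f_masks = encode_masks(pair.forward)
    r_rc_masks = encode_masks(reverse_complement(pair.reverse))
    f_starts, f_mm = _site_scan(seq_masks, f_masks, max_mismatches)
    r_starts, r_mm = _site_scan(seq_masks, r_rc_masks, max_mismatches)
    if len(f_starts) == 0 or len(r_starts) == 0:
        return []
    lf, lr = len(pair.forward), len(pair.reverse)
    hits = []
    for fs, fmm in zip(f_starts, f_mm):
        fe = int(fs) + lf
        lo = np.searchsorted(r_starts, fe + pair.min_len)
        hi = np.searchsorted(r_starts, fe + pair.max_len, side="right")
        for idx in range(int(lo), int(hi)):
            rs = int(r_starts[idx])
            hits.append((int(fs), fe, rs, rs + lr, int(fmm), int(r_mm[idx]),
                         seq[fe:rs]))
    return hits


def amplify(record: ReferenceRecord | str, pair: PrimerPair,
            max_mismatches: int = DEFAULT_MAX_MISMATCHES,
            record_id: str = "") -> list[AmpliconHit]:
    """Enumerate every amplification of a template by a primer pair.

    Both strands are scanned; strand '-' hits are reported in forward-strand
    coordinates with the metabarcode oriented 5'->3' relative to the forward
    primer (i.e. as read on the '-' strand).
    """
    if isinstance(record, ReferenceRecord):
        seq, rid = record.sequence, record.record_id
    else:
        seq, rid = record, record_id
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    hits: list[AmpliconHit] = []
    masks = encode_masks(seq)
    for fs, fe, rs, re_, mf, mr, bc in _amplify_one_strand(
            seq, masks, pair, max_mismatches):
        hits.append(AmpliconHit(rid, "+", fs, fe, rs, re_, mf, mr, bc))
    rc = reverse_complement(seq)
    n = len(seq)
    for fs, fe, rs, re_, mf, mr, bc in _amplify_one_strand(
            rc, encode_masks(rc), pair, max_mismatches):
        # map oriented coords [s, e) back to forward strand: [n-e, n-s)
        hits.append(AmpliconHit(rid, "-", n - fe, n - fs, n - re_, n - rs,
                                mf, mr, bc))
    hits.sort(key=lambda h: (h.fwd_start, h.rev_start, h.strand))
    return hits


def designate_hit(hits: Sequence[AmpliconHit]) -> AmpliconHit:
    """The single hit used by the metrics when a record amplifies more than
    once: shortest amplicon, ties broken by smallest fwd_start then strand
    '+' before '-'. Mimics preferential amplification of shorter fragments
    while staying deterministic."""
    if not hits:
        raise ValueError("designate_hit requires at least one hit")
    return min(hits, key=lambda h: (h.amplicon_len, h.fwd_start,
                                    0 if h.strand == "+" else 1))


@dataclass
class AmplificationResult:
    """Per-record hits of one primer pair over a reference database."""

    primer: PrimerPair
    max_mismatches: int
    hits: dict[str, list[AmpliconHit]]
    n_total: int
    designated: dict[str, AmpliconHit] = field(default_factory=dict)

    @property
    def amplified_ids(self) -> list[str]:
        return sorted(self.designated)

    @property
    def n_amplified(self) -> int:
        return len(self.designated)

    def is_amplified(self, record_id: str) -> bool:
        return record_id in self.designated


def amplify_db(records: Sequence[ReferenceRecord], pair: PrimerPair,
               max_mismatches: int = DEFAULT_MAX_MISMATCHES
               ) -> AmplificationResult:
    """Run the engine over a whole database.

    Returns per-record hit lists, the per-record amplified status, and the
    designated hit per amplified record for metric use.
    """
    hits: dict[str, list[AmpliconHit]] = {}
    designated: dict[str, AmpliconHit] = {}
    for rec in records:
        rec_hits = amplify(rec, pair, max_mismatches)
        hits[rec.record_id] = rec_hits
        if rec_hits:
            designated[rec.record_id] = designate_hit(rec_hits)
    return AmplificationResult(pair, max_mismatches, hits, len(records),
                               designated)


# ---------------------------------------------------------------------------
# output

def write_amplicon_table(result: AmplificationResult,
                         path: str | Path) -> None:
    """Amplicon TSV, all hits, 1-based inclusive coordinates."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(["record_id", "primer", "strand",
                         "fwd_start", "fwd_end", "rev_start", "rev_end",
                         "mm_fwd", "mm_rev", "amplicon_len", "metabarcode"])
        for rid in sorted(result.hits):
            for h in result.hits[rid]:
                writer.writerow([
                    rid, result.primer.name, h.strand,
                    h.fwd_start + 1, h.fwd_end, h.rev_start + 1, h.rev_end,
                    h.mismatches_fwd, h.mismatches_rev,
                    h.amplicon_len, h.metabarcode,
                ])


def write_metabarcode_fasta(result: AmplificationResult,
                            path: str | Path) -> None:
    """FASTA of the designated metabarcode per amplified record."""
    with open(path, "w") as out:
        for rid in result.amplified_ids:
            out.write(f">{rid}\n{result.designated[rid].metabarcode}\n")
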