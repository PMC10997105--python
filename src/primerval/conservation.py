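"""Per-position conservation of primer-matching regions (sequence logos).

For every designated amplification the template region under a primer
footprint is collected, oriented 5'->3' as the primer reads, and summarised
as a position frequency matrix with per-position information content

    info_i = 2 - H_i,    H_i = -sum_b f_ib * log2(f_ib)   (0*log0 = 0),

in bits: 0 when the four nucleotides are equally likely, 2 for a perfectly
conserved position. No small-sample correction is applied by default, which
keeps the exact 0-2 range semantics; the classic e_n correction is available
behind a flag for parity with logo-rendering tools. Template ambiguity codes
inside matched windows are dropped from the affected position's counts.

The matrix TSV is the contract; stacked-letter rendering is an optional
matplotlib output.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .insilico_pcr import AmplificationResult
from .iupac import reverse_complement
from .refdb_io import ReferenceRecord

BASES = ("A", "C", "G", "T")
FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class ConservationMatrix:
    """Position frequency matrix with information content per position.

    freq has shape (L, 4) over (A, C, G, T); rows sum to 1 except at
    positions where every window carried an ambiguity code (NaN row).
    """

    freq: np.ndarray
    info: np.ndarray
    n_sequences: int
    counts: np.ndarray

    def __post_init__(self):
        valid = ~np.isnan(self.info)
        if valid.any():
            if not np.allclose(self.freq[valid].sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("frequency rows must sum to 1")
            if (self.info[valid] < -1e-12).any() or (self.info[valid] > 2 + 1e-12).any():
                raise ValueError("information content out of the [0, 2] range")

    def __len__(self) -> int:
        return self.freq.shape[0]


def collect_primer_windows(records: Sequence[ReferenceRecord],
                           result: AmplificationResult,
                           primer_side: str,
                           flank: int = 0) -> list[str]:
    """Template windows under one primer's footprint, one per designated hit.

    Windows are oriented 5'->3' as the primer reads (the reverse side of a
    '+'-strand hit is the reverse complement of the template slice, and
    symmetrically on '-'). With ``flank > 0`` each window is extended by
    ``flank`` template bases on both sides; hits whose template does not
    extend far enough are skipped so all windows share one length.

    ``records`` should already be reduced to one sequence per species when
    the windows feed a specificity-style logo.
    """
    if primer_side not in (FORWARD, REVERSE):
        raise ValueError(f"primer_side must be 'forward' or 'reverse', "
                         f"got {primer_side!r}")
    by_id = {rec.record_id: rec for rec in records}
    windows: list[str] = []
    for rid in result.amplified_ids:
        if rid not in by_id:
            continue  # record filtered out (e.g. by dedup)
        hit = result.designated[rid]
        seq = by_id[rid].sequence
        # footprint on the forward strand of the stored sequence
        if primer_side == FORWARD:
            start, end = hit.fwd_start, hit.fwd_end
            # the forward primer reads 5'->3' along the hit strand
            as_stored = hit.strand == "+"
        else:
            start, end = hit.rev_start, hit.rev_end
            # the reverse primer reads 5'->3' against the hit strand
            as_stored = hit.strand == "-"
        lo, hi = start - flank, end + flank
        if lo < 0 or hi > len(seq):
            continue
        window = seq[lo:hi]
        windows.append(window if as_stored else reverse_complement(window))
    return windows


def conservation_matrix(windows: Sequence[str],
                        small_sample_correction: bool = False
                        ) -> ConservationMatrix:
    """Position frequency matrix and per-position information content.

    All windows must share one length; ambiguity codes are dropped from the
    counts of the position where they occur. With
    ``small_sample_correction`` the e_n = 3 / (2 ln2 n_i) term is subtracted
    from the information content (clamped at 0).
    """
    if not windows:
        raise ValueError("conservation_matrix requires at least one window")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("all windows must have equal length")
    counts = np.zeros((length, 4), dtype=np.int64)
    base_index = {b: i for i, b in enumerate(BASES)}
    for window in windows:
        for i, ch in enumerate(window):
            j = base_index.get(ch)
            if j is not None:  # ambiguity codes dropped per position
                counts[i, j] += 1
    totals = counts.sum(axis=1)
    freq = np.full((length, 4), np.nan)
    info = np.full(length, np.nan)
    for i in range(length):
        if totals[i] == 0:
            continue
        f = counts[i] / totals[i]
        freq[i] = f
        h = -sum(p * math.log2(p) for p in f if p > 0)
        bits = 2.0 - h
        if small_sample_correction:
            bits = max(0.0, bits - 3.0 / (2.0 * math.log(2) * totals[i]))
        info[i] = bits
    return ConservationMatrix(freq=freq, info=info,
                              n_sequences=len(windows), counts=counts)


def write_matrix_tsv(matrix: ConservationMatrix, path: str | Path) -> None:
    """`position, A, C, G, T, bits, n` with 1-based positions."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(["position", "A", "C", "G", "T", "bits", "n"])
        for i in range(len(matrix)):
            row = [i + 1]
            row += ["NA" if np.isnan(v) else f"{v:.6f}" for v in matrix.freq[i]]
            bits = matrix.info[i]
            row.append("NA" if np.isnan(bits) else f"{bits:.6f}")
            row.append(int(matrix.counts[i].sum()))
            writer.writerow(row)


def plot_logo(matrix: ConservationMatrix, ax=None, title: str = ""):
    """Render a simple stacked-letter logo (letter heights = freq * bits)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.45 * len(matrix) + 1, 2.5))
    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    for i in range(len(matrix)):
        if np.isnan(matrix.info[i]):
            continue
        order = np.argsort(matrix.freq[i])
        y = 0.0
        for j in order:
            h = matrix.freq[i, j] * matrix.info[i]
            if h <= 0:
                continue
            ax.text(i + 1, y + h / 2, BASES[j], ha="center", va="center",
                    fontsize=8 + 10 * h, color=colors[BASES[j]],
                    fontweight="bold")
            y += h
    ax.set_xlim(0.5, len(matrix) + 0.5)
    ax.set_ylim(0, 2)
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    return ax
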