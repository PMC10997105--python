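"""Primer-refinement scan: target vs non-target variability around a primer.

The scan aligns the template windows matched by an existing primer in the
target and non-target partitions (including a flank on each side, default 10
bases) and scores every position by

    delta = H_nontarget - H_target = info_target - info_nontarget,

the excess Shannon entropy of the non-target partition. A good
discriminating position is conserved in the target (low entropy) and
variable outside it (high entropy), so higher delta is better, and positions
near the 3' end — where a mismatch is most disruptive to polymerase
extension — are up-weighted by a linear ramp (1.0 at the 5' end to 3.0 at
the 3' end by default).

``propose_variants`` enumerates bounded shifts of the primer footprint along
the scanned region and bounded re-specifications of primer positions to the
target-consensus IUPAC code, scoring each candidate by estimated target
coverage and the weighted-delta sum over its footprint. It is a defined,
reproducible refinement procedure, not a reconstruction of any particular
published optimisation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .conservation import ConservationMatrix, conservation_matrix
from .insilico_pcr import iupac_mismatches, DEFAULT_MAX_MISMATCHES
from .iupac import CODE_FOR_SET, IUPAC_SETS

DEFAULT_FLANK = 10
DEFAULT_WEIGHT_RANGE = (1.0, 3.0)
#: minimum within-target base frequency for inclusion in a consensus code
DEFAULT_CONSENSUS_MIN_FREQ = 0.05


@dataclass(frozen=True)
class VariabilityScan:
    """Per-position target/non-target conservation around a primer.

    Positions run -flank .. primer_len + flank - 1 relative to the primer's
    5' end (offset 0 = first primer base).
    """

    primer_len: int
    flank: int
    offsets: np.ndarray
    target: ConservationMatrix
    nontarget: ConservationMatrix
    three_prime_weight: np.ndarray
    target_windows: tuple[str, ...]

    @property
    def delta(self) -> np.ndarray:
        """nontarget entropy - target entropy (= target info - nontarget
        info), in bits; NaN where either partition has no counts."""
        return self.target.info - self.nontarget.info

    @property
    def weighted_delta(self) -> np.ndarray:
        return self.delta * self.three_prime_weight

    def ranked_positions(self) -> list[int]:
        """Offsets sorted by weighted delta, best discriminator first
        (NaN positions last, then by offset for determinism)."""
        wd = self.weighted_delta
        keys = [(-(wd[i]) if not np.isnan(wd[i]) else np.inf, int(self.offsets[i]))
                for i in range(len(self.offsets))]
        order = sorted(range(len(keys)), key=lambda i: keys[i])
        return [int(self.offsets[i]) for i in order]


def variability_scan(target_windows: Sequence[str],
                     nontarget_windows: Sequence[str],
                     flank: int = DEFAULT_FLANK,
                     weight_range: tuple[float, float] = DEFAULT_WEIGHT_RANGE,
                     ) -> VariabilityScan:
    """Score per-position variability of target vs non-target windows.

    Both window sets must be aligned to the same primer anchor and have equal
    length primer_len + 2*flank (as produced by
    :func:`primerval.conservation.collect_primer_windows` with ``flank``).
    """
    if not target_windows:
        raise ValueError("empty target partition")
    if not nontarget_windows:
        raise ValueError("empty non-target partition")
    width = len(target_windows[0])
    if len(nontarget_windows[0]) != width:
        raise ValueError(
            "target and non-target windows must share one length "
            f"({width} vs {len(nontarget_windows[0])})"
        )
    primer_len = width - 2 * flank
    if primer_len < 1:
        raise ValueError(f"flank {flank} too large for window width {width}")
    target = conservation_matrix(target_windows)
    nontarget = conservation_matrix(nontarget_windows)
    lo, hi = weight_range
    weights = np.linspace(lo, hi, width)
    offsets = np.arange(-flank, primer_len + flank)
    return VariabilityScan(primer_len=primer_len, flank=flank,
                           offsets=offsets, target=target,
                           nontarget=nontarget, three_prime_weight=weights,
                           target_windows=tuple(target_windows))


def consensus_code(freq_row: np.ndarray,
                   min_freq: float = DEFAULT_CONSENSUS_MIN_FREQ) -> str | None:
    """Minimal IUPAC code covering the bases with frequency >= min_freq.

    Bounds degeneracy inflation: rare bases (below the cutoff) are not
    folded into the code. None when the position has no counts.
    """
    if np.isnan(freq_row).any():
        return None
    bases = frozenset(b for b, f in zip("ACGT", freq_row) if f >= min_freq)
    if not bases:
        bases = frozenset([("ACGT")[int(np.argmax(freq_row))]])
    return CODE_FOR_SET[bases]


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str
    shift: int
    n_edits: int
    coverage_est: float
    weighted_delta: float

    @property
    def score(self) -> tuple[float, float]:
        return (self.coverage_est, self.weighted_delta)


def _candidate_sequence(scan: VariabilityScan, base_primer: str, shift: int,
                        edit_positions: tuple[int, ...],
                        min_freq: float) -> str | None:
    """Primer sequence for footprint offsets shift .. shift+L-1.

    Positions overlapping the original footprint keep the base primer's
    characters; newly covered flank positions and edited positions take the
    target-consensus code. None when a needed consensus is undefined.
    """
    length = len(base_primer)
    chars: list[str] = []
    for k in range(length):
        offset = shift + k
        idx = scan.flank + offset  # index into scan matrices
        if k in edit_positions or not (0 <= offset < scan.primer_len):
            code = consensus_code(scan.target.freq[idx], min_freq)
            if code is None:
                return None
            chars.append(code)
        else:
            chars.append(base_primer[offset])
    return "".join(chars)


def propose_variants(scan: VariabilityScan, base_primer: str,
                     max_shift: int = 0, max_edits: int = 0,
                     max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                     min_freq: float = DEFAULT_CONSENSUS_MIN_FREQ
                     ) -> list[PrimerCandidate]:
    """Ranked primer variants from bounded shifts and consensus edits.

    Candidates are every shift in [-max_shift, max_shift] combined with <=
    max_edits positions re-specified to the target-consensus IUPAC code.
    Each is scored by (target coverage estimate, weighted-delta sum over the
    footprint), compared lexicographically; ties break toward fewer edits,
    then lexicographically smaller sequence. With max_shift = max_edits = 0
    the sole candidate is the base primer itself.
    """
    if len(base_primer) != scan.primer_len:
        raise ValueError(
            f"base primer length {len(base_primer)} does not match the "
            f"scanned footprint length {scan.primer_len}"
        )
    if max_shift > scan.flank:
        raise ValueError(f"max_shift {max_shift} exceeds flank {scan.flank}")
    length = len(base_primer)
    wd = scan.weighted_delta
    seen: dict[str, PrimerCandidate] = {}
    for shift in range(-max_shift, max_shift + 1):
        for k in range(max_edits + 1):
            for edits in combinations(range(length), k):
                seq = _candidate_sequence(scan, base_primer, shift, edits,
                                          min_freq)
                if seq is None:
                    continue
                idx = slice(scan.flank + shift, scan.flank + shift + length)
                footprint_wd = float(np.nansum(wd[idx]))
                matched = sum(
                    1 for w in scan.target_windows
                    if iupac_mismatches(seq, w[idx]) <= max_mismatches
                )
                cand = PrimerCandidate(
                    sequence=seq, shift=shift, n_edits=k,
                    coverage_est=matched / len(scan.target_windows),
                    weighted_delta=footprint_wd,
                )
                prev = seen.get(seq)
                if prev is None or (cand.score, -cand.n_edits) > (
                        prev.score, -prev.n_edits):
                    seen[seq] = cand
    ranked = sorted(
        seen.values(),
        key=lambda c: (-c.coverage_est, -c.weighted_delta, c.n_edits,
                       c.sequence),
    )
    return ranked


# ---------------------------------------------------------------------------
# output

def write_scan_tsv(scan: VariabilityScan, path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(["offset", "target_bits", "nontarget_bits", "delta",
                         "weight", "weighted_delta"])
        delta, wd = scan.delta, scan.weighted_delta
        for i, off in enumerate(scan.offsets):
            row = [int(off)]
            for v in (scan.target.info[i], scan.nontarget.info[i],
                      delta[i], scan.three_prime_weight[i], wd[i]):
                row.append("NA" if np.isnan(v) else f"{v:.6f}")
            writer.writerow(row)


def write_candidates_tsv(candidates: Sequence[PrimerCandidate],
                         path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(["primer_sequence", "shift", "edits", "coverage_est",
                         "score"])
        for c in candidates:
            writer.writerow([c.sequence, c.shift, c.n_edits,
                             f"{c.coverage_est:.6f}",
                             f"{c.weighted_delta:.6f}"])
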