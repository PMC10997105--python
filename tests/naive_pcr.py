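"""Independent brute-force in silico PCR oracle used by the tests.

Deliberately naive: per-position IUPAC set intersection over every window
and every forward/reverse site pairing, on both strands, with its own IUPAC
tables. Shares no code with the package's scanning engine.
"""

SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
        "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
        "D": "H", "H": "D", "N": "N"}


def revcomp(seq):
    return "".join(COMP[c] for c in reversed(seq))


def mismatches(primer, window):
    assert len(primer) == len(window)
    return sum(1 for p, w in zip(primer, window) if not (SETS[p] & SETS[w]))


def sites(seq, primer, max_mm):
    """All (start, end, mm) windows within budget, with early exit."""
    m = len(primer)
    found = []
    for i in range(len(seq) - m + 1):
        mm = 0
        for p, w in zip(primer, seq[i:i + m]):
            if not (SETS[p] & SETS[w]):
                mm += 1
                if mm > max_mm:
                    break
        else:
            found.append((i, i + m, mm))
    return found


def amplify(seq, forward, reverse, min_len, max_len, max_mm):
    """Exhaustive pairing of site lists on both strands.

    Returns a list of tuples (strand, fwd_start, fwd_end, rev_start,
    rev_end, mm_fwd, mm_rev, metabarcode) in forward-strand coordinates,
    metabarcode read 5'->3' from the forward primer.
    """
    hits = []
    for strand, template in (("+", seq), ("-", revcomp(seq))):
        f_sites = sites(template, forward, max_mm)
        r_sites = sites(template, revcomp(reverse), max_mm)
        n = len(template)
        for fs, fe, fmm in f_sites:
            for rs, re_, rmm in r_sites:
                gap = rs - fe
                if min_len <= gap <= max_len:
                    bc = template[fe:rs]
                    if strand == "+":
                        hits.append((strand, fs, fe, rs, re_, fmm, rmm, bc))
                    else:
                        hits.append((strand, n - fe, n - fs, n - re_, n - rs,
                                     fmm, rmm, bc))
    return hits
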