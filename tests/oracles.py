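"""Independent brute-force oracles used to validate the fast paths.

Everything here is deliberately naive and self-contained: the matchers
enumerate every (start, spacer, orientation) combination with per-character
set membership, and the exact test enumerates all 2x2 tables with the
observed margins in exact rational arithmetic. None of it shares code with
the implementation under test.
"""

from fractions import Fraction
from math import comb

# Independent IUPAC table (do not import from the package).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
         "D": "H", "H": "D", "N": "N"}


def revcomp(s):
    return "".join(_COMP[c] for c in reversed(s.upper()))


def _window_matches(window, pattern):
    if len(window) != len(pattern):
        return False
    return all(base in IUPAC[p] for base, p in zip(window, pattern))


def naive_consensus_hits(seq, pattern, strand_mode="both_strands"):
    """All (start, end, strand) for a consensus pattern; palindromes once."""
    seq = seq.upper()
    w = len(pattern)
    out = []
    for i in range(len(seq) - w + 1):
        if _window_matches(seq[i:i + w], pattern):
            out.append((i, i + w, "+"))
    if strand_mode == "both_strands" and pattern != revcomp(pattern):
        rc = revcomp(pattern)
        for i in range(len(seq) - w + 1):
            if _window_matches(seq[i:i + w], rc):
                out.append((i, i + w, "-"))
    return sorted(out)


def naive_dyad_hits(seq, core5, core3, smin, smax):
    """All (start, end, strand, spacer) for a spaced dyad.

    Spacer bases must be plain ACGT. Self-reverse-complementary dyads are
    scanned forward only.
    """
    seq = seq.upper()
    orientations = [(core5, core3, "+")]
    if core5 != revcomp(core3):
        orientations.append((revcomp(core3), revcomp(core5), "-"))
    out = []
    for c5, c3, strand in orientations:
        for spacer in range(smin, smax + 1):
            w = len(c5) + spacer + len(c3)
            for i in range(len(seq) - w + 1):
                window = seq[i:i + w]
                if (_window_matches(window[:len(c5)], c5)
                        and _window_matches(window[len(c5) + spacer:], c3)
                        and all(b in "ACGT"
                                for b in window[len(c5):len(c5) + spacer])):
                    out.append((i, i + w, strand, spacer))
    return sorted(out)


# Tie inclusion rule shared with the implementation's declared contract:
# tables whose point probability is within a relative 1e-7 of the observed
# one count as ties. Exact integer arithmetic here, floats there.
_TIE_NUM, _TIE_DEN = 10**7 + 1, 10**7


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration in exact rationals."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    lo, hi = max(0, col1 - row2), min(col1, row1)
    weights = {x: comb(row1, x) * comb(row2, col1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(w for w in weights.values()
                if w * _TIE_DEN <= w_obs * _TIE_NUM)
    return float(Fraction(total, comb(n, col1)))


def fisher_greater_exact(a, b, c, d):
    """One-sided (set A enriched) Fisher p by exact enumeration."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    hi = min(col1, row1)
    total = sum(comb(row1, x) * comb(row2, col1 - x) for x in range(a, hi + 1))
    return float(Fraction(total, comb(n, col1)))
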