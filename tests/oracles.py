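"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the ORF oracle walks
raw strings instead of indexing codons, and the alignment oracles are
plain linear-gap dynamic programs.
"""

import numpy as np

from coldadapt.sequence_io import STOP_CODONS, reverse_complement


def orf_oracle(seq: str, min_len: int = 30, max_len: int = 300):
    """Six-frame enumeration of ATG..first-stop spans within bounds."""
    found = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(L - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            stop_at = None
            while j + 3 <= L:
                if s[j : j + 3] in STOP_CODONS:
                    stop_at = j
                    break
                j += 3
            if stop_at is None:
                continue
            span = stop_at + 3 - i
            if not min_len <= span <= max_len:
                continue
            if strand == "+":
                found.add((i + 1, i + span, "+"))
            else:
                found.add((L - (i + span) + 1, L - i, "-"))
    return found


def nw_oracle(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Global alignment score by exhaustive DP with linear gaps."""
    n, m = len(a), len(b)
    F = np.zeros((n + 1, m + 1))
    F[:, 0] = gap * np.arange(n + 1)
    F[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            F[i, j] = max(F[i - 1, j - 1] + s, F[i - 1, j] + gap, F[i, j - 1] + gap)
    return F[n, m]


def sw_oracle(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Local alignment score by exhaustive DP with linear gaps."""
    n, m = len(a), len(b)
    F = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            F[i, j] = max(
                0.0, F[i - 1, j - 1] + s, F[i - 1, j] + gap, F[i, j - 1] + gap
            )
            best = max(best, F[i, j])
    return best
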