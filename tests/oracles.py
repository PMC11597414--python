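"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive: exhaustive enumeration, textbook
dynamic programming, direct counting.  None of it shares code with the
package.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable


# ---------------------------------------------------------------------------
# Needleman-Wunsch (linear-ish gap handled as open/extend affine)
# ---------------------------------------------------------------------------

def nw_score(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -2.0, gap_extend: float = -0.5) -> float:
    """Affine-gap global alignment score (Gotoh three-matrix DP)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# NG86 pathway / site counting
# ---------------------------------------------------------------------------

def ng86_pair_oracle(c1: str, c2: str, code: int = 5):
    """(S_sites, N_sites, Sd, Nd) for one codon pair, by direct enumeration."""
    table = CodonTable.unambiguous_dna_by_id[code]
    stops = set(table.stop_codons)
    aa = dict(table.forward_table)

    def sites(codon):
        s = 0.0
        for pos in range(3):
            syn = valid = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if alt in stops:
                    continue
                valid += 1
                if aa[alt] == aa[codon]:
                    syn += 1
            if valid:
                s += syn / valid
        return s, 3.0 - s

    s1 = sites(c1)
    s2 = sites(c2)
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    all_paths = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops:
                ok = False
                break
            if aa[nxt] == aa[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((ok, sd, nd))
    valid_paths = [(sd, nd) for ok, sd, nd in all_paths if ok]
    if not valid_paths:
        valid_paths = [(sd, nd) for _, sd, nd in all_paths]
    sd = sum(x for x, _ in valid_paths) / len(valid_paths) if diffs else 0.0
    nd = sum(y for _, y in valid_paths) / len(valid_paths) if diffs else 0.0
    return ((s1[0] + s2[0]) / 2, (s1[1] + s2[1]) / 2, sd, nd)


# ---------------------------------------------------------------------------
# Nussinov maximum pairing by exhaustive enumeration (n <= ~16)
# ---------------------------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    """Maximum non-crossing base pairs via memoized interval recursion."""
    s = seq.upper()

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i < 1:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + 1, j + 1):
            if (s[i], s[k]) in _PAIRS and k - i > min_loop:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(s) - 1) if s else 0


# ---------------------------------------------------------------------------
# circular breakpoint distance
# ---------------------------------------------------------------------------

def breakpoints_oracle(a: list[str], b: list[str]) -> int:
    """Adjacencies of circular order a missing from circular order b."""
    n = len(a)
    adj_a = {(a[i], a[(i + 1) % n]) for i in range(n)}
    m = len(b)
    adj_b = {(b[i], b[(i + 1) % m]) for i in range(m)}
    return len(adj_a - adj_b)


# ---------------------------------------------------------------------------
# sliding-window scans
# ---------------------------------------------------------------------------

def g_windows_oracle(seq: str, lo: int, hi: int, min_frac: float):
    """All qualifying G-rich windows (start, length, fraction)."""
    out = []
    s = seq.upper()
    for length in range(lo, hi + 1):
        for i in range(len(s) - length + 1):
            frac = s[i: i + length].count("G") / length
            if frac >= min_frac:
                out.append((i, length, frac))
    return out


def motif_best_oracle(seq: str, element: str):
    """(identity, offset, orientation) of the best ungapped element match."""
    comp = str.maketrans("ACGT", "TGCA")
    s = seq.upper()
    q = element.upper()
    best = (-1.0, None, None)
    for orient in ("+", "-"):
        t = s if orient == "+" else s.translate(comp)[::-1]
        for off in range(len(t) - len(q) + 1):
            ident = sum(x == y for x, y in zip(q, t[off: off + len(q)])) / len(q)
            pos = off if orient == "+" else len(s) - off - len(q)
            cand = (ident, pos, orient)
            if cand[0] > best[0]:
                best = cand
    return best
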