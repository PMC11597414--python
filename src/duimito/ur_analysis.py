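"""Unassigned-region (UR) extraction and control-region characterization.

URs are the maximal intergenic spans of an annotated mitogenome.  The
largest UR (LUR) of each genome is the prime candidate for the main
control region, and principal URs (> 150 nt) are screened for
control-region hallmarks: elevated A+T content, tandem repeats, G-rich
strings, sequence similarity to known control-region elements (TAS,
CSB1, mTF1, mt3, mt4) and fold-back secondary structure.

The tandem-repeat finder is a simplified re-implementation of the
Benson-style algorithm: k-mer recurrence proposes candidate periods,
match runs locate candidate arrays, and each array is verified by
dynamic programming against its own period-p consensus with
match/mismatch/indel weights (defaults 2/7/7) and a minimum alignment
score of 50.  Exact agreement with the original tool is not promised.

Secondary structure uses Nussinov base-pair maximization (Watson-Crick
plus G:T wobble, minimum loop 3) rather than thermodynamic folding; the
output is an inventory of stems, not a minimum-free-energy structure.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .composition import composition
from .genome_io import MitoGenome

__all__ = [
    "URRecord",
    "RepeatHit",
    "GString",
    "MotifHit",
    "FoldStem",
    "FoldResult",
    "URConfig",
    "extract_urs",
    "ur_fraction",
    "find_tandem_repeats",
    "g_string_scan",
    "motif_similarity",
    "fold_inventory",
    "homopolymer_runs",
    "characterize_urs",
    "load_elements",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class RepeatHit:
    start: int
    end: int  # UR-local, half-open; spans the whole tandem array
    period: int
    copy_number: float  # one decimal
    consensus: str
    score: int
    percent_matches: float


@dataclass
class GString:
    start: int
    length: int
    g_fraction: float


@dataclass
class MotifHit:
    element: str
    ur_start: int
    orientation: str  # + | -
    identity: float
    matched: str


@dataclass
class FoldStem:
    stem5_start: int
    stem5_end: int
    stem3_start: int
    stem3_end: int
    n_pairs: int
    loop_len: int


@dataclass
class FoldResult:
    max_pairs: int = 0
    stems: list[FoldStem] = field(default_factory=list)
    labels: set[str] = field(default_factory=set)


@dataclass
class URRecord:
    genome_id: str
    flank5: str | None
    flank3: str | None
    start: int
    end: int  # genome coords, wrap-aware (end < start spans the origin)
    length: int
    sequence: str
    at_content: float | None
    is_principal: bool
    is_lur: bool = False
    lur_tie: bool = False
    repeats: list[RepeatHit] | None = None
    g_strings: list[GString] | None = None
    motifs: list[MotifHit] | None = None
    fold: FoldResult | None = None
    homopolymers: list[tuple[str, int, int]] | None = None  # (base, start, run length)


@dataclass
class URConfig:
    """Every threshold of the UR protocol in one place."""

    min_principal: int = 150
    trf_match: int = 2
    trf_mismatch: int = 7
    trf_indel: int = 7
    trf_min_score: int = 50
    trf_max_period: int = 500
    trf_min_copies: float = 1.8
    gstring_min_len: int = 18
    gstring_max_len: int = 23
    gstring_min_fraction: float = 0.8
    motif_min_identity: float = 0.5
    fold_max_len: int = 3500
    fold_window: int = 1000
    fold_step: int = 500
    fold_min_stem: int = 5
    fold_min_loop: int = 3
    homopolymer_min: int = 8


# ---------------------------------------------------------------------------
# UR extraction
# ---------------------------------------------------------------------------

def extract_urs(genome: MitoGenome, min_principal: int = 150) -> list[URRecord]:
    """Maximal spans not covered by any feature, in genome order.

    On circular genomes the gap spanning the origin is one UR.  Flanks
    name the nearest features in genome order.  ``is_lur`` marks the
    single longest UR; ties go to the first in genome order with
    ``lur_tie`` set.
    """
    L = genome.length
    cover = np.zeros(L, dtype=np.int16)
    for f in genome.features:
        if f.wraps():
            cover[f.start:] += 1
            cover[: f.end] += 1
        else:
            cover[f.start: f.end] += 1
    if (cover > 1).any():
        warnings.warn(f"{genome.id}: overlapping annotations over "
                      f"{(cover > 1).sum()} nt; overlap excluded from URs")
    if not genome.features:
        warnings.warn(f"{genome.id}: featureless genome; single UR covers everything")
        rec = URRecord(genome.id, None, None, 0, L, L, genome.sequence,
                       composition(genome.sequence).at_content, L > min_principal,
                       is_lur=True)
        return [rec]
    uncovered = cover == 0
    if not uncovered.any():
        return []
    # runs of uncovered positions
    runs: list[tuple[int, int]] = []
    i = 0
    while i < L:
        if uncovered[i]:
            j = i
            while j < L and uncovered[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if genome.topology == "circular" and len(runs) > 1 \
            and runs[0][0] == 0 and runs[-1][1] == L:
        first = runs.pop(0)
        s, _ = runs.pop()
        runs.append((s, first[1]))  # wraps origin
    records: list[URRecord] = []
    for s, e in runs:
        seq = genome.span_seq(s, e)
        length = e - s if e >= s else L - s + e
        records.append(URRecord(genome.id, _flank5(genome, s), _flank3(genome, e % L),
                                s, e, length, seq,
                                composition(seq).at_content, length > min_principal))
    records.sort(key=lambda r: r.start)
    if records:
        best = max(r.length for r in records)
        ties = [r for r in records if r.length == best]
        ties[0].is_lur = True
        if len(ties) > 1:
            ties[0].lur_tie = True
            warnings.warn(f"{genome.id}: LUR length tie; first in genome order flagged")
    return records


def _flank5(genome: MitoGenome, pos: int) -> str | None:
    """Gene whose end is nearest upstream of ``pos`` (circular)."""
    L = genome.length
    best, best_d = None, None
    for f in genome.features:
        d = (pos - f.end) % L
        if best_d is None or d < best_d:
            best, best_d = f.gene, d
    return best


def _flank3(genome: MitoGenome, pos: int) -> str | None:
    L = genome.length
    best, best_d = None, None
    for f in genome.features:
        d = (f.start - pos) % L
        if best_d is None or d < best_d:
            best, best_d = f.gene, d
    return best


def ur_fraction(genomes: MitoGenome | list[MitoGenome]) -> dict[str, float]:
    """Percent of each genome that is unassigned, to one decimal."""
    if isinstance(genomes, MitoGenome):
        genomes = [genomes]
    out = {}
    for g in genomes:
        total = sum(r.length for r in extract_urs(g))
        out[g.id] = round(100.0 * total / g.length, 1)
    return out


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def _candidate_periods(s: str, max_period: int, kmer: int = 5,
                       max_candidates: int = 24) -> list[int]:
    votes: Counter[int] = Counter()
    last: dict[str, list[int]] = {}
    for i in range(len(s) - kmer + 1):
        w = s[i: i + kmer]
        if w in last:
            for prev in last[w][-3:]:
                d = i - prev
                if 1 <= d <= max_period:
                    votes[d] += 1
            last[w].append(i)
        else:
            last[w] = [i]
    ranked = [d for d, v in votes.most_common() if v >= 2]
    return sorted(ranked[:max_candidates])


def _match_segments(w: np.ndarray, min_seg: float) -> list[tuple[int, int]]:
    """Maximal positive-scoring runs of the shifted-match profile."""
    segs: list[tuple[int, int]] = []
    cur = 0.0
    start = None
    best = 0.0
    best_end = None
    for idx in range(len(w)):
        v = float(w[idx])
        if start is None:
            if v <= 0:
                continue
            start, cur, best, best_end = idx, 0.0, 0.0, None
        cur += v
        if cur > best:
            best, best_end = cur, idx
        if cur < 0:
            if best >= min_seg and best_end is not None:
                segs.append((start, best_end + 1))
            start = None
    if start is not None and best >= min_seg and best_end is not None:
        segs.append((start, best_end + 1))
    return segs


def _consensus(array: str, period: int) -> str:
    cols: list[Counter] = [Counter() for _ in range(period)]
    for i, ch in enumerate(array):
        cols[i % period][ch] += 1
    return "".join(c.most_common(1)[0][0] for c in cols)


def _phased_consensus(window: str, anchor_start: int, anchor_end: int,
                      period: int) -> str:
    """Majority consensus over the whole window in the anchor's phase.

    Voting over the full window lets every copy of a candidate array
    weigh in even when the anchor segment covers only part of it; the
    few flank positions per column are outvoted.  Anchor positions vote
    first so ties resolve toward the seeded array.
    """
    cols: list[Counter] = [Counter() for _ in range(period)]
    order = list(range(anchor_start, min(anchor_end, len(window)))) + \
        [k for k in range(len(window)) if k < anchor_start or k >= anchor_end]
    for k in order:
        cols[(k - anchor_start) % period][window[k]] += 1
    return "".join(c.most_common(1)[0][0] if c else "A" for c in cols)


def _align_to_tandem(window: str, consensus: str, match: int, mismatch: int,
                     indel: int) -> tuple[float, float, tuple[int, int], str]:
    """Local DP of a window against the unrolled period-p consensus.

    Local alignment bridges small mutation clusters inside one array
    (each costs a few mismatches) but terminates across stretches of
    unrelated sequence.  Returns (score, percent_matches, window span of
    the aligned array).
    """
    p = len(consensus)
    reps = len(window) // p + 2
    unroll = consensus * reps
    n, m = len(window), len(unroll)
    a = np.frombuffer(window.encode(), dtype=np.uint8)
    u = np.frombuffer(unroll.encode(), dtype=np.uint8)
    sub = np.where(u[None, :] == a[:, None], float(match), float(-mismatch))
    dp = np.zeros((n + 1, m + 1), dtype=np.float64)
    idx = np.arange(m, dtype=np.float64)
    for i in range(1, n + 1):
        tmp = np.maximum(dp[i - 1, :-1] + sub[i - 1], dp[i - 1, 1:] - indel)
        tmp = np.maximum(tmp, 0.0)
        # exact left-gap scan: cur[j] = max(tmp[k] - indel*(j-k)) clamped at 0
        cur = np.maximum.accumulate(tmp + indel * idx) - indel * idx
        dp[i, 1:] = np.maximum(cur, 0.0)
    i, j = np.unravel_index(int(np.argmax(dp)), dp.shape)
    score = float(dp[i, j])
    matches = aligned = 0
    end_i, end_j = i, j
    eps = 1e-6
    while i > 0 and j > 0 and dp[i, j] > 0:
        v = dp[i, j]
        if abs(v - (dp[i - 1, j - 1] + sub[i - 1, j - 1])) < eps:
            aligned += 1
            matches += window[i - 1] == unroll[j - 1]
            i, j = i - 1, j - 1
        elif abs(v - (dp[i, j - 1] - indel)) < eps:
            j -= 1
        elif abs(v - (dp[i - 1, j] - indel)) < eps:
            i -= 1
        else:
            break
    pct = matches / aligned if aligned else 0.0
    lo, hi = int(i), int(end_i)
    j_lo, j_hi = int(j), int(end_j)
    pcons = len(consensus)
    # re-vote the consensus from the aligned span only: the seeding
    # consensus can carry flank characters, which would let the boundary
    # extension creep into the flank
    if hi - lo >= pcons:
        cols: list[Counter] = [Counter() for _ in range(pcons)]
        for k in range(lo, hi):
            cols[(j_lo + (k - lo)) % pcons][window[k]] += 1
        refined = "".join(c.most_common(1)[0][0] if c else consensus[t]
                          for t, c in enumerate(cols))
    else:
        refined = consensus
    # boundary extension: local alignment trims mutated array edges; walk
    # outward over exact matches, bridging an isolated mismatch only when
    # the next three positions all match (two adjacent mismatches stop)
    hi = _edge_walk(window, hi, j_hi, refined, +1)
    lo = _edge_walk(window, lo - 1, j_lo - 1, refined, -1)
    return score, pct, (lo, hi), refined


def _edge_walk(window: str, k: int, phase: int, cons: str, step: int) -> int:
    p = len(cons)
    n = len(window)
    bound = k if step > 0 else k + 1
    while 0 <= k < n:
        if window[k] == cons[phase % p]:
            bound = k + 1 if step > 0 else k
            k += step
            phase += step
            continue
        nxt = [k + step * t for t in range(1, 4)]
        if all(0 <= x < n and window[x] == cons[(phase + (x - k)) % p]
               for x in nxt):
            k += step
            phase += step
            continue
        break
    return bound


def find_tandem_repeats(seq: str, match: int = 2, mismatch: int = 7,
                        indel: int = 7, min_score: int = 50,
                        max_period: int = 500, min_copies: float = 1.8,
                        max_array: int = 3000) -> list[RepeatHit]:
    """Locate tandem repeat arrays in ``seq``.

    Candidate periods come from k-mer recurrence distances; arrays are
    called from positive runs of the period-shifted match profile and
    verified by DP against their period-p consensus.  Hits below
    ``min_score`` or ``min_copies`` copies are dropped; overlapping hits
    keep the best score (ties: smaller period).
    """
    s = seq.upper()
    L = len(s)
    hits: list[RepeatHit] = []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    for p in _candidate_periods(s, min(max_period, L // 2)):
        if 2 * p > L:
            continue
        eq = arr[:-p] == arr[p:]
        w = np.where(eq, float(match), float(-mismatch))
        segs = _match_segments(w, min_seg=5 * match)
        segs.sort(key=lambda t: t[0] - t[1])  # longest first
        for seg_s, seg_e in segs[:4]:
            if any(h.start <= seg_s and seg_e + p <= h.end and p % h.period == 0
                   for h in hits):
                continue  # harmonic of an already-verified array
            win_s = max(0, seg_s - p)
            win_e = min(L, seg_e + 2 * p)
            window = s[win_s:win_e][:max_array + 3 * p]
            cons = _phased_consensus(window, seg_s - win_s,
                                     min(seg_e + p, L) - win_s, p)
            score, pct, (lo, hi), refined = _align_to_tandem(window, cons, match,
                                                             mismatch, indel)
            if refined != cons:
                # one refinement pass: a seed consensus with single-vote
                # columns from a mutated copy truncates the alignment
                s2, p2, (l2, h2), refined2 = _align_to_tandem(
                    window, refined, match, mismatch, indel)
                if s2 > score:
                    score, pct, (lo, hi), cons = s2, p2, (l2, h2), refined
                    refined = refined2
            q = _internal_period(cons)  # collapse harmonics (period 2p -> p)
            copy = round((hi - lo) / q, 1)
            if score >= min_score and copy >= min_copies:
                hits.append(RepeatHit(win_s + lo, win_s + hi, q, copy,
                                      cons[:q], int(round(score)), round(pct, 3)))
    # resolve overlaps: best score wins, except that a competitive hit at a
    # harmonically smaller period supersedes its multiple
    hits.sort(key=lambda h: (-h.score, h.period, h.start))
    kept: list[RepeatHit] = []
    for h in hits:
        placed = False
        for idx, k in enumerate(kept):
            if _overlap(h, k) >= 0.5 * min(h.end - h.start, k.end - k.start):
                if h.period < k.period and k.period % h.period == 0 \
                        and h.score >= 0.7 * k.score:
                    kept[idx] = h
                placed = True
                break
        if not placed:
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def _overlap(a: RepeatHit, b: RepeatHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _internal_period(cons: str) -> int:
    """Smallest divisor q of the period that explains the consensus
    (self-identity at lag q >= 0.9); the period itself otherwise."""
    p = len(cons)
    for q in range(1, p // 2 + 1):
        if p % q:
            continue
        same = sum(cons[i] == cons[i - q] for i in range(q, p))
        if same / (p - q) >= 0.9:
            return q
    return p


# ---------------------------------------------------------------------------
# G-strings
# ---------------------------------------------------------------------------

def g_string_scan(seq: str, len_range: tuple[int, int] = (18, 23),
                  min_fraction: float = 0.8) -> list[GString]:
    """All windows of length in ``len_range`` with G fraction >= threshold,
    merged to maximal non-overlapping hits (best fraction kept; ties to the
    longer, then leftmost window)."""
    s = seq.upper()
    lo, hi = len_range
    acc = np.concatenate([[0], np.cumsum(np.frombuffer(s.encode(), np.uint8) == ord("G"))])
    windows: list[GString] = []
    for length in range(lo, hi + 1):
        for i in range(0, len(s) - length + 1):
            frac = (acc[i + length] - acc[i]) / length
            if frac >= min_fraction:
                windows.append(GString(i, length, float(frac)))
    if not windows:
        return []
    windows.sort(key=lambda w: w.start)
    clusters: list[list[GString]] = [[windows[0]]]
    cluster_end = windows[0].start + windows[0].length
    for w in windows[1:]:
        if w.start < cluster_end:
            clusters[-1].append(w)
            cluster_end = max(cluster_end, w.start + w.length)
        else:
            clusters.append([w])
            cluster_end = w.start + w.length
    out = []
    for cl in clusters:
        best = max(cl, key=lambda w: (w.g_fraction, w.length, -w.start))
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# motif similarity
# ---------------------------------------------------------------------------

def load_elements(path: str | Path | None = None) -> dict[str, str]:
    """Load the control-region element library (FASTA, name = first header word).

    The shipped default library contains synthetic stand-in sequences for
    TAS, CSB1, mTF1, mt3 and mt4; replace it with curated sequences for
    real-data work.
    """
    if path is None:
        ref = resources.files("duimito.data").joinpath("control_region_elements.synthetic.fasta")
        with ref.open() as fh:
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def motif_similarity(seq: str, element_seq: str, element: str = "custom",
                     min_identity: float = 0.5) -> MotifHit | None:
    """Best ungapped sliding-window identity of ``element_seq`` against both
    orientations of ``seq``; returns the hit only when identity exceeds
    ``min_identity``.  Ties: leftmost, forward orientation first."""
    if len(element_seq) < 8:
        raise ValueError("element shorter than 8 nt")
    q = element_seq.upper()
    s = seq.upper()
    if len(s) < len(q):
        return None
    best: MotifHit | None = None
    for orient, target in (("+", s), ("-", s.translate(_COMPLEMENT)[::-1])):
        qa = np.frombuffer(q.encode(), np.uint8)
        ta = np.frombuffer(target.encode(), np.uint8)
        for off in range(len(target) - len(q) + 1):
            ident = float(np.mean(ta[off: off + len(q)] == qa))
            pos = off if orient == "+" else len(s) - off - len(q)
            if best is None or ident > best.identity:
                best = MotifHit(element, pos, orient, ident,
                                s[pos: pos + len(q)])
    if best is not None and best.identity > min_identity:
        return best
    return None


# ---------------------------------------------------------------------------
# secondary structure (Nussinov)
# ---------------------------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _nussinov(seq: str, min_loop: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(seq)
    a = np.frombuffer(seq.encode(), np.uint8)
    A, T, G, C = ord("A"), ord("T"), ord("G"), ord("C")
    x, y = a[:, None], a[None, :]
    P = (((x == A) & (y == T)) | ((x == T) & (y == A))
         | ((x == G) & (y == C)) | ((x == C) & (y == G))
         | ((x == G) & (y == T)) | ((x == T) & (y == G)))
    dp = np.zeros((n, n), dtype=np.int32)
    for l in range(1, n):
        i = np.arange(0, n - l)
        j = i + l
        best = dp[i + 1, j].copy()
        np.maximum(best, dp[i, j - 1], out=best)
        if l > min_loop:
            np.maximum(best, dp[i + 1, j - 1] + P[i, j], out=best)
        for k in range(1, l):
            np.maximum(best, dp[i, i + k] + dp[i + k + 1, j], out=best)
        dp[i, j] = best
    return dp, P


def _traceback_pairs(dp: np.ndarray, P: np.ndarray, min_loop: int) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    n = dp.shape[0]
    if n == 0:
        return pairs
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 1:
            continue
        if j - i > min_loop and P[i, j] and dp[i, j] == dp[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(1, j - i):
            if dp[i, j] == dp[i, i + k] + dp[i + k + 1, j]:
                stack.append((i, i + k))
                stack.append((i + k + 1, j))
                break
    return sorted(pairs)


def _stems_from_pairs(pairs: list[tuple[int, int]], min_stem: int) -> list[FoldStem]:
    pair_set = set(pairs)
    stems: list[FoldStem] = []
    seen: set[tuple[int, int]] = set()
    for (i, j) in pairs:
        if (i, j) in seen or (i - 1, j + 1) in pair_set:
            continue
        k = 0
        while (i + k, j - k) in pair_set:
            seen.add((i + k, j - k))
            k += 1
        if k >= min_stem:
            inner_i, inner_j = i + k - 1, j - k + 1
            loop = inner_j - inner_i - 1
            nested = any(inner_i < a < b < inner_j for a, b in pairs)
            stems.append(FoldStem(i, i + k, j - k + 1, j + 1, k,
                                  loop if not nested else -1))
    return stems


def fold_inventory(seq: str, max_len: int = 3500, window: int = 1000,
                   step: int = 500, min_stem: int = 5,
                   min_loop: int = 3) -> FoldResult:
    """Base-pair-maximization fold inventory.

    Sequences above ``window`` nt are folded in overlapping windows and
    the stem inventories pooled; ``max_pairs`` is then the best single
    window.  Labels: ``stem_loop`` when at least one stem of
    ``min_stem`` contiguous pairs exists; ``hairpin`` additionally when
    some stem has >= 10 pairs closing a clean loop of <= 10 nt.
    """
    s = seq.upper()
    if len(s) > max_len:
        s = s[:max_len]
        warnings.warn(f"sequence truncated to fold_max_len={max_len}")
    result = FoldResult()
    if len(s) < 2 * min_stem + min_loop:
        return result
    windows = [(0, len(s))] if len(s) <= window else [
        (w, min(w + window, len(s)))
        for w in range(0, max(1, len(s) - window + step), step)
    ]
    for ws, we in windows:
        sub = s[ws:we]
        dp, P = _nussinov(sub, min_loop)
        mp = int(dp[0, len(sub) - 1]) if len(sub) > 1 else 0
        result.max_pairs = max(result.max_pairs, mp)
        pairs = _traceback_pairs(dp, P, min_loop)
        for st in _stems_from_pairs(pairs, min_stem):
            shifted = FoldStem(st.stem5_start + ws, st.stem5_end + ws,
                               st.stem3_start + ws, st.stem3_end + ws,
                               st.n_pairs, st.loop_len)
            if not any(shifted.stem5_start == k.stem5_start
                       and shifted.stem3_end == k.stem3_end for k in result.stems):
                result.stems.append(shifted)
    if result.stems:
        result.labels.add("stem_loop")
        if any(st.n_pairs >= 10 and 0 <= st.loop_len <= 10 for st in result.stems):
            result.labels.add("hairpin")
    return result


# ---------------------------------------------------------------------------
# homopolymers + composite protocol
# ---------------------------------------------------------------------------

def homopolymer_runs(seq: str, min_len: int = 8) -> list[tuple[str, int, int]]:
    """(base, start, length) for every homopolymer run >= min_len."""
    out = []
    s = seq.upper()
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        if j - i >= min_len and s[i] in "ACGT":
            out.append((s[i], i, j - i))
        i = j
    return out


def characterize_urs(genome: MitoGenome, elements: dict[str, str] | None = None,
                     config: URConfig | None = None) -> list[URRecord]:
    """Full control-region screening protocol for one genome.

    Extraction, composition, tandem repeats, G-strings, element motifs
    and homopolymer runs are computed for every UR; the fold inventory is
    computed for principal URs only (the candidate control regions).
    """
    cfg = config or URConfig()
    if elements is None:
        elements = load_elements()
    records = extract_urs(genome, cfg.min_principal)
    for r in records:
        r.repeats = find_tandem_repeats(
            r.sequence, cfg.trf_match, cfg.trf_mismatch, cfg.trf_indel,
            cfg.trf_min_score, cfg.trf_max_period, cfg.trf_min_copies)
        r.g_strings = g_string_scan(
            r.sequence, (cfg.gstring_min_len, cfg.gstring_max_len),
            cfg.gstring_min_fraction)
        r.motifs = []
        for name, eseq in elements.items():
            hit = motif_similarity(r.sequence, eseq, name, cfg.motif_min_identity)
            if hit is not None:
                r.motifs.append(hit)
        r.homopolymers = homopolymer_runs(r.sequence, cfg.homopolymer_min)
        if r.is_principal:
            r.fold = fold_inventory(r.sequence, cfg.fold_max_len, cfg.fold_window,
                                    cfg.fold_step, cfg.fold_min_stem, cfg.fold_min_loop)
        else:
            r.fold = FoldResult()
    return records
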