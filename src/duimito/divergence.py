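"""F/M orthologue divergence: alignment, p-distances, NG86 dN/dS,
cox2 modification scanning and hydropathy-based transmembrane scanning.

The dN/dS estimator is the Nei–Gojobori (1986) counting method: per-codon
synonymous/nonsynonymous site fractions averaged over the two sequences,
observed differences resolved by averaging over all minimal mutational
pathways that avoid stop codons, and a Jukes–Cantor correction
``d = -(3/4) ln(1 - (4/3) p)`` applied to the proportions.  This is a
counting method, not a maximum-likelihood codon model: estimates agree
with ML in regime (e.g. omega < 1 under purifying selection) but not
digit-for-digit.

Site-counting convention: candidate changes that would create a stop
codon are excluded from the per-position denominator and the position is
renormalized to contribute exactly one site, so N + S = 3 x (codons
compared) holds as an identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

__all__ = [
    "PairwiseAlignment",
    "DivergenceRecord",
    "DnDsRecord",
    "Cox2ModReport",
    "TmhSegment",
    "global_align",
    "write_alignment_fasta",
    "p_distance",
    "p_distance_ungapped",
    "ng86_dnds",
    "cox2_mod_scan",
    "tmh_scan",
    "translate_cds",
    "jukes_cantor",
    "KYTE_DOOLITTLE",
]

DEFAULT_CODE = 5

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

_NT = frozenset("ACGT")
_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class CodonFrameError(ValueError):
    """Raised for untranslatable coding sequences (internal stop etc.)."""


@dataclass
class PairwiseAlignment:
    seq_a: str
    seq_b: str
    mode: str  # nt | aa | codon
    score: float
    aligned_columns: int = 0

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        self.aligned_columns = len(self.seq_a)


@dataclass
class DivergenceRecord:
    gene: str
    p_nt: float | None = None
    p_aa: float | None = None
    sites_compared: int = 0
    gap_excluded: int = 0
    defined: bool = True


@dataclass
class DnDsRecord:
    gene: str
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float | None
    ps: float | None
    dn: float | None
    ds: float | None
    omega: float | None
    codons_compared: int


@dataclass
class Cox2ModReport:
    kind: str  # none | insertion | extension_3prime | duplication
    length_nt: int = 0
    length_codons: int = 0
    position: tuple[int, int] | None = None  # alignment columns
    tmh_in_modified_region: int = 0


@dataclass
class TmhSegment:
    start: int
    end: int  # protein coords, 0-based half-open
    mean_hydropathy: float


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _nt_aligner(params: dict | None) -> Align.PairwiseAligner:
    p = {"match": 1.0, "mismatch": -1.0, "open": -2.0, "extend": -0.5}
    if params:
        p.update(params)
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = p["match"]
    al.mismatch_score = p["mismatch"]
    al.open_gap_score = p["open"]
    al.extend_gap_score = p["extend"]
    return al


def _aa_aligner(params: dict | None) -> Align.PairwiseAligner:
    p = {"open": -11.0, "extend": -1.0}
    if params:
        p.update(params)
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = p["open"]
    al.extend_gap_score = p["extend"]
    return al


def translate_cds(seq: str, code: int = DEFAULT_CODE,
                  trim_incomplete: bool = True) -> str:
    """Translate a CDS; trims a trailing partial codon and terminal stop.

    Raises :class:`CodonFrameError` naming the codon index on an internal
    stop.
    """
    s = seq.upper()
    if trim_incomplete:
        s = s[: len(s) - len(s) % 3]
    if len(s) % 3:
        raise CodonFrameError("CDS length is not a codon multiple")
    table = CodonTable.unambiguous_dna_by_id[code]
    aas = []
    n = len(s) // 3
    for i in range(n):
        codon = s[3 * i: 3 * i + 3]
        if codon in table.stop_codons:
            if i == n - 1:
                break  # terminal stop trimmed
            raise CodonFrameError(f"internal stop codon at codon index {i}")
        aas.append(table.forward_table.get(codon, "X"))
    return "".join(aas)


def global_align(a: str, b: str, mode: str = "nt",
                 params: dict | None = None, code: int = DEFAULT_CODE) -> PairwiseAlignment:
    """Needleman-Wunsch optimal global alignment.

    ``nt``: match 1 / mismatch -1 / gap open -2 / extend -0.5.
    ``aa``: BLOSUM62 with affine gaps.
    ``codon``: align the translations, then thread the nucleotides back so
    every gap run is a codon multiple.
    """
    if not a or not b:
        raise ValueError("empty input sequence")
    if mode == "nt":
        aligner = _nt_aligner(params)
        best = aligner.align(a.upper(), b.upper())[0]
        return PairwiseAlignment(str(best[0]), str(best[1]), "nt", best.score)
    if mode == "aa":
        aligner = _aa_aligner(params)
        best = aligner.align(a.upper(), b.upper())[0]
        return PairwiseAlignment(str(best[0]), str(best[1]), "aa", best.score)
    if mode == "codon":
        a = a.upper()[: len(a) - len(a) % 3]
        b = b.upper()[: len(b) - len(b) % 3]
        pa, pb = translate_cds(a, code, trim_incomplete=False), translate_cds(b, code, trim_incomplete=False)
        aa_al = global_align(pa, pb, mode="aa", params=params)
        sa, sb = _thread_codons(aa_al.seq_a, a), _thread_codons(aa_al.seq_b, b)
        return PairwiseAlignment(sa, sb, "codon", aa_al.score)
    raise ValueError(f"unknown alignment mode {mode!r}")


def write_alignment_fasta(al: PairwiseAlignment, path: str,
                          ids: tuple[str, str] = ("seq_a", "seq_b")) -> None:
    """Write a pairwise alignment as aligned FASTA."""
    with open(path, "w") as fh:
        fh.write(f">{ids[0]}\n{al.seq_a}\n>{ids[1]}\n{al.seq_b}\n")


def _thread_codons(aligned_aa: str, nt: str) -> str:
    out = []
    k = 0
    for ch in aligned_aa:
        if ch == "-":
            out.append("---")
        else:
            out.append(nt[k: k + 3])
            k += 3
    return "".join(out)


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def p_distance(al: PairwiseAlignment, gene: str = "",
               deletion: str = "pairwise") -> DivergenceRecord:
    """Uncorrected proportion of differing compared columns.

    Columns containing a gap or an ambiguity character in either sequence
    are excluded.  For a pairwise alignment ``pairwise`` and ``complete``
    deletion coincide; the option is kept for interface symmetry.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    alphabet = _NT if al.mode in ("nt", "codon") else _AA
    compared = mismatch = 0
    for x, y in zip(al.seq_a, al.seq_b):
        if x in alphabet and y in alphabet:
            compared += 1
            if x != y:
                mismatch += 1
    rec = DivergenceRecord(gene, sites_compared=compared,
                           gap_excluded=al.aligned_columns - compared)
    if compared == 0:
        rec.defined = False
        return rec
    p = mismatch / compared
    if al.mode == "aa":
        rec.p_aa = p
    else:
        rec.p_nt = p
    return rec


def p_distance_ungapped(a: str, b: str) -> float:
    """Hamming p-distance of two equal-length unaligned sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length; align first")
    compared = mismatch = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _NT and y in _NT:
            compared += 1
            mismatch += x != y
    if compared == 0:
        raise ValueError("no comparable sites")
    return mismatch / compared


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; undefined for p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


class _Code:
    """Cached sense-codon translation and per-codon site fractions."""

    _cache: dict[int, "_Code"] = {}

    def __init__(self, code: int) -> None:
        table = CodonTable.unambiguous_dna_by_id[code]
        self.stops = frozenset(table.stop_codons)
        self.aa = dict(table.forward_table)
        self.sense = sorted(self.aa)
        self.sites: dict[str, tuple[float, float]] = {}
        for codon in self.sense:
            s = 0.0
            for pos in range(3):
                syn = valid = 0
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1:]
                    if alt in self.stops:
                        continue
                    valid += 1
                    syn += self.aa[alt] == self.aa[codon]
                s += syn / valid if valid else 0.0
            self.sites[codon] = (s, 3.0 - s)

    @classmethod
    def get(cls, code: int) -> "_Code":
        if code not in cls._cache:
            cls._cache[code] = cls(code)
        return cls._cache[code]


def _pathway_counts(c1: str, c2: str, code: _Code) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal mutational
    pathways; pathways passing through a stop codon are excluded unless
    every pathway does."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        syn = non = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in code.stops:
                valid = False
                break
            if code.aa[nxt] == code.aa[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        paths.append((valid, syn, non))
    usable = [(s, n) for v, s, n in paths if v] or [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def ng86_dnds(al: PairwiseAlignment | tuple[str, str], gene: str = "",
              code: int = DEFAULT_CODE) -> DnDsRecord:
    """Nei-Gojobori dN/dS on an in-frame codon alignment.

    Accepts a codon-mode :class:`PairwiseAlignment` or a raw pair of
    equal-length in-frame coding sequences.  Codon columns containing a
    gap, an ambiguity or a stop codon are skipped.
    """
    if isinstance(al, PairwiseAlignment):
        if al.mode != "codon":
            raise ValueError("ng86_dnds requires a codon-mode alignment")
        sa, sb = al.seq_a, al.seq_b
    else:
        sa, sb = al
        if len(sa) != len(sb) or len(sa) % 3:
            raise ValueError("raw input must be two equal-length in-frame sequences")
        sa, sb = sa.upper(), sb.upper()
    ct = _Code.get(code)
    s_sites = n_sites = sd = nd = 0.0
    codons = 0
    for i in range(0, len(sa) - len(sa) % 3, 3):
        ca, cb = sa[i:i + 3], sb[i:i + 3]
        if len(ca) < 3 or not (set(ca) <= _NT and set(cb) <= _NT):
            continue
        if ca in ct.stops or cb in ct.stops:
            continue
        codons += 1
        s1, n1 = ct.sites[ca]
        s2, n2 = ct.sites[cb]
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        dsd, dnd = _pathway_counts(ca, cb, ct)
        sd += dsd
        nd += dnd
    ps = sd / s_sites if s_sites > 0 else None
    pn = nd / n_sites if n_sites > 0 else None
    ds = jukes_cantor(ps) if ps is not None else None
    dn = jukes_cantor(pn) if pn is not None else None
    omega = dn / ds if dn is not None and ds not in (None, 0.0) else None
    return DnDsRecord(gene, n_sites, s_sites, nd, sd, pn, ps, dn, ds, omega, codons)


# ---------------------------------------------------------------------------
# cox2 modification scan
# ---------------------------------------------------------------------------

def _ungapped_identity_scan(query: str, target: str) -> list[tuple[int, float]]:
    """Identity of ``query`` at every ungapped offset within ``target``."""
    hits = []
    for off in range(0, len(target) - len(query) + 1):
        window = target[off: off + len(query)]
        ident = sum(a == b for a, b in zip(query, window)) / len(query)
        hits.append((off, ident))
    return hits


def _scan_one(seq: str, reference: str, code: int,
              min_event_codons: int) -> Cox2ModReport:
    prot = translate_cds(seq, code)
    ref_prot = translate_cds(reference, code)
    # duplication: two disjoint ungapped copies of the reference protein
    if len(prot) >= int(1.8 * len(ref_prot)):
        hits = sorted(_ungapped_identity_scan(ref_prot, prot),
                      key=lambda h: -h[1])
        if hits and hits[0][1] > 0.5:
            first = hits[0][0]
            disjoint = [h for h in hits
                        if abs(h[0] - first) >= len(ref_prot) and h[1] > 0.5]
            if disjoint:
                return Cox2ModReport("duplication", len(ref_prot) * 3, len(ref_prot),
                                     (min(first, disjoint[0][0]),
                                      max(first, disjoint[0][0]) + len(ref_prot)))
    al = global_align(ref_prot, prot, mode="aa")
    ref_cols = [i for i, ch in enumerate(al.seq_a) if ch != "-"]
    ref_last = ref_cols[-1] if ref_cols else -1
    # runs of input-only columns
    runs: list[tuple[int, int]] = []
    i = 0
    n = al.aligned_columns
    while i < n:
        if al.seq_a[i] == "-" and al.seq_b[i] != "-":
            j = i
            while j < n and al.seq_a[j] == "-" and al.seq_b[j] != "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    ext = [(s, e) for s, e in runs if s > ref_last]
    ins = [(s, e) for s, e in runs if s <= ref_last and e - s >= min_event_codons]
    segments = tmh_scan(prot) if len(prot) >= 19 else []

    def _tmh_in(start_col: int, end_col: int) -> int:
        # map alignment columns to protein coordinates of the input
        prot_pos = 0
        pstart = pend = None
        for col in range(n):
            if al.seq_b[col] != "-":
                if col == start_col:
                    pstart = prot_pos
                prot_pos += 1
                if col == end_col - 1:
                    pend = prot_pos
        if pstart is None or pend is None:
            return 0
        return sum(1 for s in segments if s.start < pend and s.end > pstart)

    if ext and sum(e - s for s, e in ext) >= min_event_codons:
        s, e = ext[0][0], ext[-1][1]
        codons_n = sum(en - st for st, en in ext)
        return Cox2ModReport("extension_3prime", codons_n * 3, codons_n,
                             (s, e), _tmh_in(s, e))
    if ins:
        s, e = max(ins, key=lambda r: r[1] - r[0])
        return Cox2ModReport("insertion", (e - s) * 3, e - s, (s, e),
                             _tmh_in(s, e))
    return Cox2ModReport("none")


def cox2_mod_scan(f_cox2: str, m_cox2: str, reference_cox2: str,
                  code: int = DEFAULT_CODE,
                  min_event_codons: int = 30) -> dict[str, Cox2ModReport]:
    """Scan F and M cox2 sequences against a reference for modifications.

    Detected events: an internal run of >= ``min_event_codons``
    non-reference codons (insertion), a comparable run beyond the
    reference 3' terminus (extension_3prime), or two disjoint copies of
    the reference (duplication).  The threshold separates genuine
    modifications (smallest recurrent events are ~100 codons) from
    ordinary indels.
    """
    return {
        "F": _scan_one(f_cox2, reference_cox2, code, min_event_codons),
        "M": _scan_one(m_cox2, reference_cox2, code, min_event_codons),
    }


# ---------------------------------------------------------------------------
# transmembrane-helix scan
# ---------------------------------------------------------------------------

def tmh_scan(protein: str, window: int = 19, cutoff: float = 1.6) -> list[TmhSegment]:
    """Kyte-Doolittle sliding-window transmembrane-helix candidates.

    Windows of ``window`` residues with mean hydropathy above ``cutoff``
    are candidates; overlapping candidates merge into one segment.
    """
    p = protein.upper()
    if len(p) < window:
        raise ValueError(f"protein shorter than window ({window})")
    vals = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in p]
    acc = [0.0]
    for v in vals:
        acc.append(acc[-1] + v)
    spans: list[list[int]] = []
    for i in range(len(p) - window + 1):
        mean = (acc[i + window] - acc[i]) / window
        if mean > cutoff:
            if spans and i <= spans[-1][1]:
                spans[-1][1] = i + window
            else:
                spans.append([i, i + window])
    return [TmhSegment(s, e, (acc[e] - acc[s]) / (e - s)) for s, e in spans]
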