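"""Circular gene-order comparison: duplications, losses, transpositions and
breakpoint distance.

Orders are canonicalized by rotation to cox1 (or the lexicographic
minimum when cox1 is absent).  Reflection is *not* identified with the
original: in these genomes all genes are on the forward strand, so
orientation is meaningful.  Breakpoint distance counts the circular,
orientation-respecting adjacencies of one order that are missing from
the other, computed on the shared single-copy gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .genome_io import MitoGenome

__all__ = ["GeneOrder", "RearrangementReport", "gene_order_of",
           "compare_orders", "conserved_clusters", "order_to_string",
           "order_from_string"]


@dataclass
class GeneOrder:
    genome_id: str
    order: tuple[str, ...]  # duplicate copies carry an "@n" multiplicity marker
    strands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.strands:
            self.strands = tuple("+" for _ in self.order)

    def __eq__(self, other: object) -> bool:  # rotation-equivalent orders compare equal
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return _canonical_rotation(list(self.order)) == _canonical_rotation(list(other.order))

    def __hash__(self) -> int:
        return hash(tuple(_canonical_rotation(list(self.order))))


@dataclass
class RearrangementReport:
    shared: list[str]
    duplicated_in_a: list[str]
    duplicated_in_b: list[str]
    absent_in_a: list[str]
    absent_in_b: list[str]
    transposed: list[str]
    breakpoint_distance: int | None
    transposed_exact: bool = True


def _canonical_rotation(order: list[str]) -> list[str]:
    if not order:
        return []
    if "cox1" in order:
        k = order.index("cox1")
    else:
        target = min(order)
        k = order.index(target)
    return order[k:] + order[:k]


def gene_order_of(genome: MitoGenome) -> GeneOrder:
    """Gene symbols in genome-start order, canonically rotated.

    Duplicated symbols get multiplicity markers (``trnK``, ``trnK@2``,
    ...) in genome order.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    counts: dict[str, int] = {}
    labels = []
    strands = []
    for f in feats:
        n = counts.get(f.gene, 0) + 1
        counts[f.gene] = n
        labels.append(f.gene if n == 1 else f"{f.gene}@{n}")
        strands.append(f.strand)
    order = _canonical_rotation(labels)
    if labels and order != labels:
        k = labels.index(order[0])
        strands = strands[k:] + strands[:k]
    return GeneOrder(genome.id, tuple(order), tuple(strands))


def order_to_string(order: GeneOrder) -> str:
    """Serialize as ``gene1,gene2,...`` (multiplicity markers kept)."""
    return ",".join(order.order)


def order_from_string(text: str, genome_id: str = "") -> GeneOrder:
    return GeneOrder(genome_id,
                     tuple(x.strip() for x in text.strip().split(",") if x.strip()))


def _base(label: str) -> str:
    return label.split("@")[0]


def _adjacencies(order: list[str]) -> set[tuple[str, str]]:
    n = len(order)
    return {(order[i], order[(i + 1) % n]) for i in range(n)} if n > 1 else set()


def _project(order: tuple[str, ...], keep: set[str]) -> list[str]:
    return [_base(x) for x in order if _base(x) in keep]


def _rotation_identical(a: list[str], b: list[str]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    doubled = "," + ",".join(a + a) + ","
    return ("," + ",".join(b) + ",") in doubled


def breakpoint_distance(a: list[str], b: list[str]) -> int:
    """Adjacencies of circular order ``a`` absent from circular order ``b``."""
    return len(_adjacencies(a) - _adjacencies(b))


def compare_orders(a: GeneOrder, b: GeneOrder) -> RearrangementReport:
    """Multiset gene-content differences plus breakpoint/transposition analysis.

    Transposition search is exact for up to two moved genes (every case a
    single-gene move can explain); beyond that a greedy removal is
    reported with ``transposed_exact=False``.
    """
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for x in a.order:
        count_a[_base(x)] = count_a.get(_base(x), 0) + 1
    for x in b.order:
        count_b[_base(x)] = count_b.get(_base(x), 0) + 1
    shared = sorted(set(count_a) & set(count_b))
    dup_a = sorted(g for g, n in count_a.items() if n > 1)
    dup_b = sorted(g for g, n in count_b.items() if n > 1)
    absent_a = sorted(set(count_b) - set(count_a))
    absent_b = sorted(set(count_a) - set(count_b))
    single = {g for g in shared if count_a[g] == 1 and count_b[g] == 1}
    if not single:
        return RearrangementReport(shared, dup_a, dup_b, absent_a, absent_b, [], None)
    pa = _project(a.order, single)
    pb = _project(b.order, single)
    dist = breakpoint_distance(pa, pb)
    transposed: list[str] = []
    exact = True
    if dist > 0:
        found = None
        for r in (1, 2):
            for combo in combinations(sorted(single), r):
                qa = [g for g in pa if g not in combo]
                qb = [g for g in pb if g not in combo]
                if _rotation_identical(qa, qb):
                    found = list(combo)
                    break
            if found:
                break
        if found is not None:
            transposed = found
        else:
            exact = False
            # greedy: repeatedly drop the gene that lowers the distance most
            qa, qb = pa[:], pb[:]
            while breakpoint_distance(qa, qb) > 0 and len(qa) > 3:
                best_g, best_d = None, breakpoint_distance(qa, qb)
                for g in list(qa):
                    ra = [x for x in qa if x != g]
                    rb = [x for x in qb if x != g]
                    d = breakpoint_distance(ra, rb)
                    if d < best_d:
                        best_g, best_d = g, d
                if best_g is None:
                    break
                transposed.append(best_g)
                qa = [x for x in qa if x != best_g]
                qb = [x for x in qb if x != best_g]
    return RearrangementReport(shared, dup_a, dup_b, absent_a, absent_b,
                               transposed, dist, exact)


def conserved_clusters(a: GeneOrder, b: GeneOrder) -> list[list[str]]:
    """Maximal gene runs contiguous and co-oriented in both circular orders.

    Computed on the shared single-copy set; the cluster partition of that
    set is returned in the order of ``a``.
    """
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for x in a.order:
        count_a[_base(x)] = count_a.get(_base(x), 0) + 1
    for x in b.order:
        count_b[_base(x)] = count_b.get(_base(x), 0) + 1
    single = {g for g in count_a if count_a.get(g) == 1 and count_b.get(g) == 1}
    pa = _project(a.order, single)
    pb = _project(b.order, single)
    if not pa:
        return []
    succ_b = {pb[i]: pb[(i + 1) % len(pb)] for i in range(len(pb))} if len(pb) > 1 else {}
    n = len(pa)
    breaks = [i for i in range(n) if succ_b.get(pa[i]) != pa[(i + 1) % n]]
    if not breaks:
        return [pa]
    clusters = []
    for idx in range(len(breaks)):
        start = (breaks[idx] + 1) % n
        end = breaks[(idx + 1) % len(breaks)]
        run = []
        i = start
        while True:
            run.append(pa[i])
            if i == end:
                break
            i = (i + 1) % n
        clusters.append(run)
    return clusters
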