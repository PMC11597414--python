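"""Base composition, AT/GC skew and start/stop-codon tabulation.

Skews follow the strand-asymmetry convention
``AT skew = (A - T) / (A + T)`` and ``GC skew = (G - C) / (G + C)``.
Ambiguity codes are excluded from all counts and denominators, so a skew
can be undefined (``None``) rather than silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .genome_io import MitoGenome

__all__ = [
    "CompositionRecord",
    "CodonUsageReport",
    "composition",
    "composition_by_class",
    "codon_usage",
]

#: NCBI translation table 5 (invertebrate mitochondrial) is the default code.
DEFAULT_CODE = 5


@dataclass
class CompositionRecord:
    scope: str
    a: int
    t: int
    g: int
    c: int
    at_content: float | None
    at_skew: float | None
    gc_skew: float | None

    @property
    def total(self) -> int:
        return self.a + self.t + self.g + self.c


@dataclass
class GeneCodonUsage:
    gene: str
    start_codon: str
    stop_codon: str
    incomplete_stop: bool


@dataclass
class CodonUsageReport:
    per_gene: list[GeneCodonUsage] = field(default_factory=list)
    n_pcg: int = 0
    #: fraction of PCGs starting ATA/ATT/ATG (IUPAC D excludes C)
    atd_fraction: float | None = None
    #: fraction of PCGs starting with any ATN start
    atn_fraction: float | None = None


def composition(seq: str, scope: str = "sequence") -> CompositionRecord:
    """Counts and skews over the unambiguous bases of ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    at = a + t
    gc = g + c
    at_content = at / (at + gc) if at + gc else None
    at_skew = (a - t) / at if at else None
    gc_skew = (g - c) / gc if gc else None
    if at + gc == 0:
        warnings.warn(f"{scope}: no unambiguous bases; composition undefined")
    return CompositionRecord(scope, a, t, g, c, at_content, at_skew, gc_skew)


def composition_by_class(genome: MitoGenome) -> list[CompositionRecord]:
    """One record per scope: whole genome, then PCG / rRNA / tRNA concatenates.

    Scopes with no features are omitted with a warning.
    """
    records = [composition(genome.sequence, "genome")]
    for cls, scope in (("PCG", "PCGs"), ("rRNA", "rRNAs"), ("tRNA", "tRNAs")):
        parts = [genome.feature_seq(f) for f in genome.features if f.cls == cls]
        if not parts:
            warnings.warn(f"{genome.id}: no {cls} features; {scope} scope omitted")
            continue
        records.append(composition("".join(parts), scope))
    return records


def _stop_codons(code: int) -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[code]
    return frozenset(table.stop_codons)


def codon_usage(genome: MitoGenome, code: int = DEFAULT_CODE) -> CodonUsageReport:
    """Start/stop codon per protein-coding gene plus ATD/ATN start fractions.

    A CDS whose length is not a codon multiple and that ends in ``T`` or
    ``TA`` is flagged as an incomplete stop (completed by transcript
    polyadenylation).  CDSs shorter than 6 nt are skipped with a warning.
    """
    stops = _stop_codons(code)
    report = CodonUsageReport()
    for f in genome.features:
        if f.cls != "PCG":
            continue
        seq = genome.feature_seq(f)
        if f.codon_start > 1:
            seq = seq[f.codon_start - 1:]
        if len(seq) < 6:
            warnings.warn(f"{genome.id}:{f.gene}: CDS shorter than 6 nt skipped")
            continue
        start = seq[:3]
        rem = len(seq) % 3
        if rem == 0:
            stop = seq[-3:]
            incomplete = False
            if stop not in stops:
                warnings.warn(f"{genome.id}:{f.gene}: terminal codon {stop} is not a stop")
        else:
            tail = seq[-rem:]
            incomplete = tail in ("T", "TA")
            stop = tail
            if not incomplete:
                warnings.warn(f"{genome.id}:{f.gene}: frame remainder {tail!r} "
                              "is not a recognizable incomplete stop")
        report.per_gene.append(GeneCodonUsage(f.gene, start, stop, incomplete))
    report.n_pcg = len(report.per_gene)
    if report.n_pcg:
        atd = sum(1 for g in report.per_gene if g.start_codon in ("ATA", "ATT", "ATG"))
        atn = sum(1 for g in report.per_gene
                  if g.start_codon.startswith("AT") and len(g.start_codon) == 3)
        report.atd_fraction = atd / report.n_pcg
        report.atn_fraction = atn / report.n_pcg
    return report
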