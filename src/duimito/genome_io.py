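"""Read, write and normalize annotated mitochondrial genomes.

This module provides the shared data model for the whole package: a
:class:`MitoGenome` is a (usually circular) DNA sequence with an ordered
list of :class:`GeneFeature` annotations and a sex-type label (F or M for
the two mitochondrial lineages of a doubly-uniparental-inheritance
species).

Coordinate conventions
----------------------
Internally every feature is 0-based, half-open.  GenBank flat files and
the tab-delimited feature-table format use 1-based inclusive coordinates;
the conversion happens only at the file boundary.  On circular genomes a
feature may span the origin, encoded as ``end < start``; all span
arithmetic is modulo the genome length.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation

__all__ = [
    "GeneFeature",
    "MitoGenome",
    "CompletenessReport",
    "PCG_SYMBOLS",
    "TRNA_SYMBOLS",
    "RRNA_SYMBOLS",
    "ALL_SYMBOLS",
    "normalize_gene_name",
    "read_genbank",
    "write_genbank",
    "read_feature_table",
    "write_feature_table",
    "genome_to_json",
    "genome_from_json",
    "extract_gene_seq",
    "check_completeness",
    "write_gene_fasta",
]

PCG_SYMBOLS = frozenset(
    ["cox1", "cox2", "cox3", "cob", "atp6", "atp8",
     "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6"]
)
TRNA_SYMBOLS = frozenset(
    ["trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
     "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
     "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY"]
)
RRNA_SYMBOLS = frozenset(["rrnS", "rrnL"])
ALL_SYMBOLS = PCG_SYMBOLS | TRNA_SYMBOLS | RRNA_SYMBOLS

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_AA3_TO_TRN = {
    "ALA": "trnA", "CYS": "trnC", "ASP": "trnD", "GLU": "trnE",
    "PHE": "trnF", "GLY": "trnG", "HIS": "trnH", "ILE": "trnI",
    "LYS": "trnK", "MET": "trnM", "ASN": "trnN", "PRO": "trnP",
    "GLN": "trnQ", "ARG": "trnR", "THR": "trnT", "VAL": "trnV",
    "TRP": "trnW", "TYR": "trnY",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeFormatError(ValueError):
    """Raised when an input file cannot be parsed as a single annotated genome."""


@dataclass
class GeneFeature:
    """One annotated gene on a mitogenome.

    ``end < start`` encodes an origin-spanning feature on a circular
    genome.  ``cls`` is one of ``PCG``, ``tRNA``, ``rRNA``.
    """

    gene: str
    cls: str
    start: int
    end: int
    strand: str = "+"
    incomplete_stop: bool = False
    codon_start: int = 1

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start
        return genome_length - self.start + self.end

    def wraps(self) -> bool:
        return self.end < self.start


@dataclass
class MitoGenome:
    """A circular (or linear) annotated mitochondrial genome."""

    id: str
    species: str
    sex_type: str  # "F", "M" or "unknown"
    topology: str  # "circular" or "linear"
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        self.features.sort(key=lambda f: f.start)
        for f in self.features:
            if not (0 <= f.start < len(self.sequence)) or not (0 <= f.end <= len(self.sequence)):
                raise ValueError(f"feature {f.gene} outside genome bounds")
            if f.wraps() and self.topology != "circular":
                raise ValueError(f"origin-spanning feature {f.gene} on a linear genome")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def span_seq(self, start: int, end: int) -> str:
        """Sequence of a (possibly origin-spanning) span, forward strand."""
        if end >= start:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    def feature_seq(self, feat: GeneFeature) -> str:
        s = self.span_seq(feat.start, feat.end)
        return revcomp(s) if feat.strand == "-" else s

    def rotate(self, k: int) -> "MitoGenome":
        """Return a copy with the origin moved forward by ``k`` nucleotides."""
        if self.topology != "circular":
            raise ValueError("only circular genomes can be rotated")
        L = self.length
        k %= L
        seq = self.sequence[k:] + self.sequence[:k]
        feats = [
            GeneFeature(f.gene, f.cls, (f.start - k) % L, (f.end - k) % L,
                        f.strand, f.incomplete_stop, f.codon_start)
            for f in self.features
        ]
        # a feature whose shifted end lands exactly on 0 is contiguous to the new end
        for f in feats:
            if f.end == 0:
                f.end = L
        return MitoGenome(self.id, self.species, self.sex_type, self.topology,
                          seq, feats, self.source)


@dataclass
class CompletenessReport:
    n_pcg: int
    n_trna: int
    n_rrna: int
    missing: list[str]
    duplicated: list[str]
    is_complete: bool


# ---------------------------------------------------------------------------
# gene-name normalization
# ---------------------------------------------------------------------------

def _load_synonyms() -> dict[str, str]:
    with resources.files("duimito.data").joinpath("gene_synonyms.yaml").open() as fh:
        table = yaml.safe_load(fh)
    lookup: dict[str, str] = {}
    for canonical, raws in table.items():
        lookup[_canon_key(canonical)] = canonical
        for raw in raws:
            lookup[_canon_key(str(raw))] = canonical
    for sym in ALL_SYMBOLS:
        lookup.setdefault(_canon_key(sym), sym)
    return lookup


def _canon_key(name: str) -> str:
    return re.sub(r"[\s_\-]+", "", name.strip().lower())


_SYNONYMS: dict[str, str] | None = None


def _synonyms() -> dict[str, str]:
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    return _SYNONYMS


def normalize_gene_name(raw: str, cls_hint: str | None = None,
                        seen: set[str] | None = None) -> tuple[str, str]:
    """Map a raw annotation name to the canonical vocabulary.

    Returns ``(symbol, cls)``.  Ambiguous serine/leucine tRNAs lacking an
    anticodon qualifier are assigned the first unseen identity (S1 before
    S2, L1 before L2) with a warning.  Unknown names are kept as
    ``unknown:<raw>`` with ``cls`` from the hint (default PCG).
    """
    key = _canon_key(raw)
    lookup = _synonyms()
    symbol = lookup.get(key)
    if symbol is None:
        # generic tRNA-Ser / tRNA-Leu without anticodon
        m = re.match(r"trna?(ser|leu|s|l)\d?$", key)
        if m:
            base = "trnS" if m.group(1) in ("ser", "s") else "trnL"
            seen = seen if seen is not None else set()
            symbol = base + ("1" if base + "1" not in seen else "2")
            warnings.warn(f"ambiguous tRNA name {raw!r}: assigned {symbol}")
        else:
            m3 = re.match(r"trna?([a-z]{3})$", key)
            if m3 and m3.group(1).upper() in _AA3_TO_TRN:
                symbol = _AA3_TO_TRN[m3.group(1).upper()]
    if symbol is None:
        warnings.warn(f"unmappable gene name {raw!r}; kept as unknown")
        cls = cls_hint or "PCG"
        return f"unknown:{raw}", cls
    if symbol in PCG_SYMBOLS:
        cls = "PCG"
    elif symbol in TRNA_SYMBOLS:
        cls = "tRNA"
    else:
        cls = "rRNA"
    return symbol, cls


def symbol_class(symbol: str) -> str:
    if symbol in PCG_SYMBOLS:
        return "PCG"
    if symbol in TRNA_SYMBOLS:
        return "tRNA"
    if symbol in RRNA_SYMBOLS:
        return "rRNA"
    return "unknown"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sex_from_filename(path: str | Path) -> str:
    stem = Path(path).stem
    if re.search(r"(^|[_\-.])F$", stem):
        return "F"
    if re.search(r"(^|[_\-.])M$", stem):
        return "M"
    return "unknown"


def read_genbank(path: str | Path, sex_field: str = "sex") -> MitoGenome:
    """Read a single-record GenBank flat file into a :class:`MitoGenome`.

    Sex type is taken from the ``/<sex_field>`` qualifier of the source
    feature when present, otherwise from a ``_F`` / ``_M`` filename
    suffix, otherwise ``unknown``.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise GenomeFormatError(f"cannot parse {path} as a single GenBank record: {exc}") from exc

    topology = rec.annotations.get("topology", "circular")
    species = rec.annotations.get("organism", "") or rec.id
    sex = "unknown"
    L = len(rec.seq)
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    for f in rec.features:
        if f.type == "source":
            if sex_field in f.qualifiers:
                val = f.qualifiers[sex_field][0].strip().upper()
                if val in ("F", "M"):
                    sex = val
            if "organism" in f.qualifiers:
                species = f.qualifiers["organism"][0]
            continue
        if f.type not in ("CDS", "tRNA", "rRNA"):
            continue
        raw = (f.qualifiers.get("gene") or f.qualifiers.get("product")
               or f.qualifiers.get("note") or ["?"])[0]
        cls_hint = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}[f.type]
        symbol, cls = normalize_gene_name(raw, cls_hint, seen)
        seen.add(symbol)
        if cls != cls_hint and not symbol.startswith("unknown:"):
            cls = cls_hint
        parts = f.location.parts
        if len(parts) > 1 and int(parts[0].end) == L and int(parts[-1].start) == 0:
            start, end = int(parts[0].start), int(parts[-1].end)  # origin-spanning
        else:
            start, end = int(f.location.start), int(f.location.end)
        strand = "-" if f.location.strand == -1 else "+"
        codon_start = int(f.qualifiers.get("codon_start", ["1"])[0])
        span = end - start if end >= start else L - start + end
        incomplete = cls == "PCG" and span % 3 != 0
        feats.append(GeneFeature(symbol, cls, start, end, strand, incomplete, codon_start))
    if sex == "unknown":
        sex = _sex_from_filename(path)
    return MitoGenome(rec.id, species, sex, topology, str(rec.seq), feats,
                      source=rec.id)


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Write a genome as a single GenBank record (sex in /sex of source)."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description=f"{genome.species} {genome.sex_type} mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    rec.annotations["organism"] = genome.species
    src = SeqFeature(SimpleLocation(0, genome.length), type="source")
    src.qualifiers["organism"] = [genome.species]
    src.qualifiers["sex"] = [genome.sex_type]
    rec.features.append(src)
    L = genome.length
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps():
            loc = CompoundLocation([SimpleLocation(f.start, L, strand),
                                    SimpleLocation(0, f.end, strand)])
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}.get(f.cls, "misc_feature")
        sf = SeqFeature(loc, type=ftype)
        sf.qualifiers["gene"] = [f.gene]
        if f.codon_start != 1:
            sf.qualifiers["codon_start"] = [str(f.codon_start)]
        rec.features.append(sf)
    SeqIO.write([rec], str(path), "genbank")


def read_feature_table(fasta_path: str | Path, table_path: str | Path,
                       sex_type: str | None = None) -> MitoGenome:
    """Read FASTA + tab-delimited feature table (gene, class, start, end, strand).

    Table coordinates are 1-based inclusive; ``end < start`` rows encode
    origin-spanning features.
    """
    rec = SeqIO.read(str(fasta_path), "fasta")
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    with open(table_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, cls, start, end, strand = line.split("\t")[:5]
            symbol, norm_cls = normalize_gene_name(gene, cls, seen)
            seen.add(symbol)
            s1, e1 = int(start), int(end)
            feats.append(GeneFeature(symbol, cls if cls in ("PCG", "tRNA", "rRNA") else norm_cls,
                                     s1 - 1, e1, strand))
    sex = sex_type or _sex_from_filename(fasta_path)
    return MitoGenome(rec.id, rec.description.split(None, 1)[-1] or rec.id, sex,
                      "circular", str(rec.seq), feats, source=rec.id)


def write_feature_table(genome: MitoGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene\tclass\tstart\tend\tstrand (1-based inclusive)\n")
        for f in genome.features:
            fh.write(f"{f.gene}\t{f.cls}\t{f.start + 1}\t{f.end}\t{f.strand}\n")


def genome_to_json(genome: MitoGenome) -> str:
    return json.dumps(asdict(genome), indent=1)


def genome_from_json(text: str) -> MitoGenome:
    d = json.loads(text)
    feats = [GeneFeature(**f) for f in d.pop("features")]
    return MitoGenome(features=feats, **d)


def write_gene_fasta(genome: MitoGenome, genes: Iterable[str], path: str | Path) -> None:
    """Write extracted gene sequences to FASTA."""
    recs = []
    for g in genes:
        seq = extract_gene_seq(genome, g)
        recs.append(SeqRecord(Seq(seq), id=f"{genome.id}|{g}", description=""))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def extract_gene_seq(genome: MitoGenome, gene: str, occurrence: int = 1) -> str:
    """Forward-strand sequence of the ``occurrence``-th copy of ``gene``.

    Reverse-complemented for minus-strand features; wrap-aware on circular
    genomes.
    """
    hits = [f for f in genome.features if f.gene == gene]
    if len(hits) < occurrence:
        raise KeyError(f"gene {gene!r} occurrence {occurrence} not present in {genome.id}")
    return genome.feature_seq(hits[occurrence - 1])


def check_completeness(genome: MitoGenome) -> CompletenessReport:
    """Count PCG/tRNA/rRNA identities against the canonical 13+22+2 set.

    Serine and leucine tRNAs are distinct identities; duplications do not
    break completeness.
    """
    present: dict[str, int] = {}
    for f in genome.features:
        present[f.gene] = present.get(f.gene, 0) + 1
    n_pcg = sum(1 for s in PCG_SYMBOLS if s in present)
    n_trna = sum(1 for s in TRNA_SYMBOLS if s in present)
    n_rrna = sum(1 for s in RRNA_SYMBOLS if s in present)
    missing = sorted(s for s in ALL_SYMBOLS if s not in present)
    duplicated = sorted(s for s, n in present.items() if n > 1 and s in ALL_SYMBOLS)
    is_complete = n_pcg == 13 and n_rrna == 2 and n_trna == 22
    return CompletenessReport(n_pcg, n_trna, n_rrna, missing, duplicated, is_complete)
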