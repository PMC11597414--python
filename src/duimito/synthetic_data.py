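"""Synthetic annotated F/M mitogenome pairs and clade scenarios with
planted truth.

The generator emulates the structure of venerid DUI mitogenomes: a
circular genome of roughly 15-25 kb carrying 13 protein-coding genes,
2 rRNAs and 22 tRNAs, all on the forward strand, with AT-rich
intergenic unassigned regions (URs) into which control-region hallmarks
are planted (tandem repeats, G-strings, element motifs, an inverted
repeat so every principal UR can fold).  F and M genomes derive from a
common ancestor by codon-aware substitution: proposals falling in a
protein-coding gene are rejected when they would create a stop codon
and accepted with probability ``omega`` when nonsynonymous, which
creates a genuine dN/dS signal without a full codon-model simulator.
Divergence is controlled by realized p-distance (substitutions are
applied until the F/M hamming fraction hits the target), not by a
rate-time parameterization, so parameter-recovery checks are exact by
construction.

Every random draw flows from the mandatory config seed; identical
configs give byte-identical genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable

from .genome_io import GeneFeature, MitoGenome
from .ur_analysis import load_elements

__all__ = ["URPlan", "SimConfig", "SimTruth", "GENE_TEMPLATE",
           "simulate_pair", "simulate_clade", "simulate_gene_pair", "SEP"]

SEP = "__"
DEFAULT_CODE = 5

#: canonical gene template: (symbol, class, default length in nt).
#: All forward strand; PCG lengths are codon multiples incl. the stop.
GENE_TEMPLATE: list[tuple[str, str, int]] = [
    ("cox1", "PCG", 1536), ("nad1", "PCG", 903), ("nad2", "PCG", 978),
    ("trnC", "tRNA", 64), ("trnY", "tRNA", 66), ("cox2", "PCG", 690),
    ("trnP", "tRNA", 67), ("trnL1", "tRNA", 66), ("rrnL", "rRNA", 1260),
    ("atp8", "PCG", 159), ("nad4", "PCG", 1377), ("trnH", "tRNA", 64),
    ("trnE", "tRNA", 68), ("trnS2", "tRNA", 70), ("atp6", "PCG", 699),
    ("nad3", "PCG", 354), ("nad5", "PCG", 1713), ("trnF", "tRNA", 66),
    ("trnW", "tRNA", 68), ("trnR", "tRNA", 66), ("trnM", "tRNA", 65),
    ("trnD", "tRNA", 66), ("nad6", "PCG", 480), ("trnL2", "tRNA", 66),
    ("trnG", "tRNA", 66), ("trnQ", "tRNA", 67), ("trnK", "tRNA", 64),
    ("trnV", "tRNA", 66), ("cox3", "PCG", 780), ("trnA", "tRNA", 64),
    ("trnS1", "tRNA", 68), ("rrnS", "rRNA", 822), ("nad4l", "PCG", 297),
    ("trnI", "tRNA", 66), ("trnT", "tRNA", 64), ("trnN", "tRNA", 66),
    ("cob", "PCG", 1140),
]


class SimConfigError(ValueError):
    """Raised for infeasible simulation plans."""


@dataclass
class URPlan:
    """One planted unassigned region, inserted after gene ``after``."""

    after: str
    length: int
    at: float = 0.72
    #: (unit length, copies, per-copy identity) for each planted tandem array
    repeats: list[tuple[int, float, float]] = field(default_factory=list)
    #: (length, G fraction) of a planted G-string
    g_string: tuple[int, float] | None = None
    #: (element name, target identity) motif plants from the element library
    motifs: list[tuple[str, float]] = field(default_factory=list)
    #: (stem length, loop length) inverted repeat so the UR can fold
    hairpin: tuple[int, int] | None = (12, 6)


def _default_ur_plan() -> list[URPlan]:
    return [
        URPlan("nad1", 550, at=0.76, repeats=[(30, 2.4, 0.95)]),
        URPlan("nad5", 1200, at=0.72, repeats=[(25, 2.0, 1.0)],
               g_string=(20, 1.0),
               motifs=[("TAS", 0.9), ("CSB1", 0.85), ("mTF1", 0.8)]),
        URPlan("cob", 160, at=0.70, hairpin=(10, 5)),
    ]


@dataclass
class SimConfig:
    seed: int
    species: str = "Synthetica exempli"
    nt_divergence: float = 0.2
    #: per-gene omega map; missing genes use ``omega_default``
    omega: dict[str, float] = field(default_factory=dict)
    omega_default: float = 0.1
    #: uniform scale on PCG/rRNA lengths (desk-size runs use < 1)
    scale: float = 1.0
    at_bias: float = 0.68
    ur_plan: list[URPlan] = field(default_factory=_default_ur_plan)
    #: ops applied to the M genome: ("move", gene[, after]), ("duplicate",
    #: gene[, after]), ("delete", gene)
    rearrangement_plan: list[tuple] = field(default_factory=list)
    #: extra filler appended to the M LUR (F/M length asymmetry)
    m_extra_ur: int = 400
    #: ("insertion"|"extension_3prime", "F"|"M", codons|nt)
    cox2_mod: tuple[str, str, int] | None = None
    code: int = DEFAULT_CODE


@dataclass
class SimTruth:
    realized_divergence: float
    omega: dict[str, float]
    #: per planted UR: flank gene, UR start/length, plant coordinates (UR-local)
    ur_truth: list[dict]
    rearranged: list[tuple]
    tree_newick: str
    scenario: str
    labels: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])


_BASES = np.array(list("ATGC"))


def _filler(rng: np.random.Generator, n: int, at: float) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_base_probs(at)))


def _sense_codons(code: int) -> tuple[list[str], dict[str, str]]:
    table = CodonTable.unambiguous_dna_by_id[code]
    return sorted(table.forward_table), dict(table.forward_table)


_HYDROPHILIC = set("KNDEQRS")


def _random_pcg(rng: np.random.Generator, n_nt: int, at: float, code: int,
                hydrophilic: bool = False) -> str:
    """Random CDS: ATG start, sampled sense codons, TAA stop."""
    sense, aa = _sense_codons(code)
    if hydrophilic:
        sense = [c for c in sense if aa[c] in _HYDROPHILIC]
    probs = np.array([np.prod([_base_probs(at)["ATGC".index(b)] for b in c])
                      for c in sense])
    probs /= probs.sum()
    n_codons = n_nt // 3
    middle = rng.choice(len(sense), size=max(0, n_codons - 2), p=probs)
    return "ATG" + "".join(sense[i] for i in middle) + "TAA"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _mutate_copy(rng: np.random.Generator, s: str, identity: float) -> str:
    out = list(s)
    for i in range(len(out)):
        if rng.random() > identity:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _build_g_string(length: int, fraction: float) -> str:
    """G-string whose full window is the best-scoring scan window: non-G
    bases sit in the interior shared by all sub-windows."""
    n_other = length - int(round(length * fraction))
    if n_other == 0:
        return "G" * length
    s = ["G"] * length
    lo, hi = 4, length - 5
    slots = np.linspace(lo, hi, n_other).round().astype(int)
    for pos in slots:
        s[int(pos)] = "A"
    return "".join(s)


def _build_ur(rng: np.random.Generator, plan: URPlan,
              elements: dict[str, str], min_principal: int = 150) -> tuple[str, dict]:
    seq = list(_filler(rng, plan.length, plan.at))
    truth: dict = {"after": plan.after, "length": plan.length,
                   "repeats": [], "g_string": None, "motifs": [], "hairpin": None}
    cursor = 5

    def _place(fragment: str, what: str, meta: dict) -> None:
        nonlocal cursor
        if cursor + len(fragment) + 5 > plan.length:
            raise SimConfigError(
                f"UR after {plan.after} too short for planted {what}")
        seq[cursor: cursor + len(fragment)] = list(fragment)
        meta["start"] = cursor
        meta["end"] = cursor + len(fragment)
        cursor += len(fragment) + int(rng.integers(8, 20))

    def _guard(positions: list[tuple[int, str]]) -> None:
        # make the plant maximal: adjacent flank bases must not continue it
        for off, exp in positions:
            if 0 <= off < plan.length and seq[off] in exp:
                seq[off] = next(b for b in "ACGT" if b not in exp)

    for unit_len, copies, identity in plan.repeats:
        unit = _filler(rng, unit_len, plan.at)
        n_full = int(copies)
        frag = unit
        for _ in range(n_full - 1):
            frag += _mutate_copy(rng, unit, identity)
        partial = int(round((copies - n_full) * unit_len))
        if partial:
            frag += _mutate_copy(rng, unit[:partial], identity)
        meta = {"period": unit_len, "copies": round(copies, 1), "unit": unit}
        _place(frag, "repeat", meta)
        _guard([(meta["start"] - 1, unit[-1]), (meta["start"] - 2, unit[-2]),
                (meta["end"], unit[len(frag) % unit_len]),
                (meta["end"] + 1, unit[(len(frag) + 1) % unit_len])])
        truth["repeats"].append(meta)
    if plan.g_string is not None:
        glen, gfrac = plan.g_string
        frag = _build_g_string(glen, gfrac)
        meta = {"length": glen, "fraction": round(sum(c == "G" for c in frag) / glen, 3)}
        _place(frag, "g_string", meta)
        _guard([(meta["start"] - 1, "G"), (meta["end"], "G")])
        truth["g_string"] = meta
    for name, identity in plan.motifs:
        if name not in elements:
            raise SimConfigError(f"unknown control-region element {name!r}")
        el = elements[name]
        n_mut = int(round((1 - identity) * len(el)))
        frag = list(el)
        pos_mut = rng.choice(len(el), size=n_mut, replace=False) if n_mut else []
        for p in pos_mut:
            frag[p] = rng.choice([b for b in "ACGT" if b != frag[p]])
        meta = {"element": name,
                "identity": 1 - len(pos_mut) / len(el)}
        _place("".join(frag), "motif", meta)
        truth["motifs"].append(meta)
    if plan.hairpin is not None and plan.length > min_principal:
        stem, loop = plan.hairpin
        arm = _filler(rng, stem, 0.5)
        frag = arm + _filler(rng, loop, plan.at) + _revcomp(arm)
        meta = {"stem": stem, "loop": loop}
        _place(frag, "hairpin", meta)
        truth["hairpin"] = meta
    return "".join(seq), truth


@dataclass
class _Block:
    name: str
    cls: str  # PCG | tRNA | rRNA | UR
    seq: str


def _scaled_template(scale: float) -> list[tuple[str, str, int]]:
    out = []
    for sym, cls, length in GENE_TEMPLATE:
        if cls in ("PCG", "rRNA") and scale != 1.0:
            length = max(90, int(round(length * scale / 3)) * 3)
        out.append((sym, cls, length))
    return out


def _build_ancestor(rng: np.random.Generator, cfg: SimConfig,
                    elements: dict[str, str]) -> tuple[list[_Block], list[dict]]:
    plan_by_gene = {}
    for p in cfg.ur_plan:
        plan_by_gene.setdefault(p.after, []).append(p)
    blocks: list[_Block] = []
    ur_truth: list[dict] = []
    for sym, cls, length in _scaled_template(cfg.scale):
        if cls == "PCG":
            seq = _random_pcg(rng, length, cfg.at_bias, cfg.code)
        else:
            seq = _filler(rng, length, cfg.at_bias)
        blocks.append(_Block(sym, cls, seq))
        for p in plan_by_gene.get(sym, []):
            ur_seq, truth = _build_ur(rng, p, elements)
            blocks.append(_Block(f"UR:{sym}", "UR", ur_seq))
            ur_truth.append(truth)
    unknown = set(plan_by_gene) - {sym for sym, _, _ in GENE_TEMPLATE}
    if unknown:
        raise SimConfigError(f"ur_plan names unknown genes: {sorted(unknown)}")
    return blocks, ur_truth


def _assemble(blocks: list[_Block]) -> tuple[str, list[GeneFeature]]:
    seq_parts = []
    feats = []
    pos = 0
    for b in blocks:
        if b.cls != "UR":
            feats.append(GeneFeature(b.name, b.cls, pos, pos + len(b.seq)))
        seq_parts.append(b.seq)
        pos += len(b.seq)
    return "".join(seq_parts), feats


# ---------------------------------------------------------------------------
# codon-aware substitution engine
# ---------------------------------------------------------------------------

class _CodingMap:
    """Per-position coding context: frame anchor and per-gene omega."""

    def __init__(self, blocks: list[_Block], omega: dict[str, float],
                 omega_default: float, code: int) -> None:
        seq_len = sum(len(b.seq) for b in blocks)
        self.anchor = np.full(seq_len, -1, dtype=np.int64)  # codon start or -1
        self.omega = np.zeros(seq_len)
        table = CodonTable.unambiguous_dna_by_id[code]
        self.stops = frozenset(table.stop_codons)
        self.aa = dict(table.forward_table)
        pos = 0
        for b in blocks:
            if b.cls == "PCG":
                w = omega.get(b.name, omega_default)
                for k in range(0, len(b.seq) - 3):
                    self.anchor[pos + k] = pos + 3 * (k // 3)
                self.anchor[pos + len(b.seq) - 3: pos + len(b.seq)] = -2  # stop frozen
                self.omega[pos: pos + len(b.seq)] = w
            pos += len(b.seq)

    def propose(self, rng: np.random.Generator, seq: list[str], pos: int) -> bool:
        """Apply one substitution proposal in place; True when accepted."""
        old = seq[pos]
        new = "ACGT"[int(rng.integers(4))]
        if new == old:
            return False
        a = self.anchor[pos]
        if a >= 0:
            codon = seq[a] + seq[a + 1] + seq[a + 2]
            off = pos - a
            alt = codon[:off] + new + codon[off + 1:]
            if alt in self.stops:
                return False
            if self.aa.get(alt) != self.aa.get(codon) \
                    and rng.random() > self.omega[pos]:
                return False
        elif self.anchor[pos] == -2:
            return False
        seq[pos] = new
        return True


def _evolve_pair(rng: np.random.Generator, anc: str, cmap: _CodingMap,
                 target_p: float, max_iter_factor: int = 400) -> tuple[str, str, float]:
    L = len(anc)
    f, m = list(anc), list(anc)
    target = int(round(target_p * L))
    diff = 0
    it = 0
    limit = max_iter_factor * max(target, 1)
    while diff < target:
        it += 1
        if it > limit:
            raise SimConfigError(
                f"divergence target {target_p} unreachable (omega too low?)")
        genome = f if rng.random() < 0.5 else m
        pos = int(rng.integers(L))
        was_diff = f[pos] != m[pos]
        if cmap.propose(rng, genome, pos):
            now_diff = f[pos] != m[pos]
            diff += int(now_diff) - int(was_diff)
    return "".join(f), "".join(m), diff / L


def _evolve_branch(rng: np.random.Generator, seq: str, cmap: _CodingMap,
                   branch_p: float) -> str:
    L = len(seq)
    out = list(seq)
    target = int(round(branch_p * L))
    applied = 0
    it = 0
    while applied < target and it < 400 * max(target, 1):
        it += 1
        pos = int(rng.integers(L))
        if cmap.propose(rng, out, pos):
            applied += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# pair simulation
# ---------------------------------------------------------------------------

def _apply_rearrangements(blocks: list[_Block], plan: list[tuple],
                          rng: np.random.Generator) -> list[_Block]:
    blocks = list(blocks)
    for op in plan:
        kind, gene = op[0], op[1]
        idx = next((i for i, b in enumerate(blocks) if b.name == gene), None)
        if idx is None:
            raise SimConfigError(f"rearrangement names unknown gene {gene!r}")
        if kind == "delete":
            blocks.pop(idx)
            continue
        if len(op) > 2:
            tgt = next((i for i, b in enumerate(blocks) if b.name == op[2]), None)
            if tgt is None:
                raise SimConfigError(f"rearrangement target {op[2]!r} unknown")
        else:
            tgt = int(rng.integers(len(blocks)))
        if kind == "move":
            b = blocks.pop(idx)
            if tgt > idx:
                tgt -= 1
            blocks.insert(tgt + 1, b)
        elif kind == "duplicate":
            blocks.insert(tgt + 1, _Block(blocks[idx].name, blocks[idx].cls,
                                          blocks[idx].seq))
        else:
            raise SimConfigError(f"unknown rearrangement op {kind!r}")
    return blocks


def _apply_cox2_mod(blocks: list[_Block], mod: tuple[str, str, int],
                    rng: np.random.Generator, at: float, code: int) -> None:
    kind, _, size = mod
    idx = next(i for i, b in enumerate(blocks) if b.name == "cox2")
    seq = blocks[idx].seq
    if kind == "insertion":
        ins = _random_pcg(rng, (size + 2) * 3, at, code, hydrophilic=True)[3:-3]
        mid = 3 * ((len(seq) // 2) // 3)
        blocks[idx] = _Block("cox2", "PCG", seq[:mid] + ins + seq[mid:])
    elif kind == "extension_3prime":
        n_codons = max(1, size // 3)
        ext = _random_pcg(rng, (n_codons + 2) * 3, at, code, hydrophilic=True)[3:-3]
        blocks[idx] = _Block("cox2", "PCG", seq[:-3] + ext + "TAA")
    else:
        raise SimConfigError(f"unknown cox2 modification {kind!r}")


def _reslice(blocks: list[_Block], seq: str) -> list[_Block]:
    out = []
    pos = 0
    for b in blocks:
        out.append(_Block(b.name, b.cls, seq[pos: pos + len(b.seq)]))
        pos += len(b.seq)
    return out


def simulate_pair(cfg: SimConfig) -> tuple[MitoGenome, MitoGenome, SimTruth]:
    """Generate one F/M genome pair with planted truth.

    The two genomes share a simulated ancestor and differ by codon-aware
    substitutions until their hamming p-distance equals
    ``cfg.nt_divergence`` (to within 1/L), plus the configured
    rearrangements, cox2 modification and M-specific UR extension.
    """
    if not 0 <= cfg.nt_divergence <= 0.6:
        raise SimConfigError("nt_divergence must be in [0, 0.6]")
    rng = np.random.default_rng(cfg.seed)
    elements = load_elements()
    blocks, ur_truth = _build_ancestor(rng, cfg, elements)
    anc_seq, _ = _assemble(blocks)
    cmap = _CodingMap(blocks, cfg.omega, cfg.omega_default, cfg.code)
    if cfg.nt_divergence > 0:
        f_seq, m_seq, realized = _evolve_pair(rng, anc_seq, cmap, cfg.nt_divergence)
    else:
        f_seq, m_seq, realized = anc_seq, anc_seq, 0.0
    f_blocks = _reslice(blocks, f_seq)
    m_blocks = _reslice(blocks, m_seq)
    if cfg.cox2_mod is not None:
        target = f_blocks if cfg.cox2_mod[1] == "F" else m_blocks
        _apply_cox2_mod(target, cfg.cox2_mod, rng, cfg.at_bias, cfg.code)
    if cfg.m_extra_ur > 0:
        lur = max((i for i, b in enumerate(m_blocks) if b.cls == "UR"),
                  key=lambda i: len(m_blocks[i].seq), default=None)
        if lur is not None:
            m_blocks[lur] = _Block(m_blocks[lur].name, "UR",
                                   m_blocks[lur].seq + _filler(rng, cfg.m_extra_ur, cfg.at_bias))
    m_blocks = _apply_rearrangements(m_blocks, cfg.rearrangement_plan, rng)
    tag = cfg.species.replace(" ", "_")
    f_seq2, f_feats = _assemble(f_blocks)
    m_seq2, m_feats = _assemble(m_blocks)
    f_genome = MitoGenome(f"{tag}_F", cfg.species, "F", "circular", f_seq2, f_feats)
    m_genome = MitoGenome(f"{tag}_M", cfg.species, "M", "circular", m_seq2, m_feats)
    omega_map = {sym: cfg.omega.get(sym, cfg.omega_default)
                 for sym, cls, _ in GENE_TEMPLATE if cls == "PCG"}
    truth = SimTruth(realized, omega_map, ur_truth, list(cfg.rearrangement_plan),
                     f"({tag}{SEP}F:{realized / 2},{tag}{SEP}M:{realized / 2});",
                     "pair", {cfg.species: "pair"})
    return f_genome, m_genome, truth


def simulate_gene_pair(n_codons: int, omega: float, divergence: float,
                       seed: int, at: float = 0.68,
                       code: int = DEFAULT_CODE) -> tuple[str, str]:
    """One orthologous CDS pair evolved under a given omega.

    Returns two in-frame coding sequences of ``n_codons`` codons
    (including stop) whose hamming p-distance equals ``divergence`` to
    within 1/L.  Useful for dN/dS parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    block = _Block("cox1", "PCG", _random_pcg(rng, n_codons * 3, at, code))
    cmap = _CodingMap([block], {"cox1": omega}, omega, code)
    if divergence <= 0:
        return block.seq, block.seq
    a, b, _ = _evolve_pair(rng, block.seq, cmap, divergence)
    return a, b


# ---------------------------------------------------------------------------
# clade simulation
# ---------------------------------------------------------------------------

@dataclass
class _SimNode:
    branch: float
    label: str | None = None
    children: list["_SimNode"] = field(default_factory=list)


def _newick(node: _SimNode) -> str:
    if node.label is not None:
        return f"{node.label}:{node.branch}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.branch}"


def _ladder(labels: list[str], split: float, tip: float) -> _SimNode:
    if len(labels) == 1:
        return _SimNode(tip, label=labels[0])
    head = _SimNode(split, label=labels[0])
    rest = _ladder(labels[1:], split, tip)
    return _SimNode(split, children=[head, rest])


def _pair_node(species: str, tag: str, branch: float, tip: float) -> _SimNode:
    return _SimNode(branch, children=[
        _SimNode(tip, label=f"{tag}{SEP}F"),
        _SimNode(tip, label=f"{tag}{SEP}M"),
    ])


def simulate_clade(scenario: str, n_species: int = 3, seed: int = 0,
                   base_cfg: SimConfig | None = None,
                   species_split: float = 0.06, fm_split: float = 0.04,
                   gender_split: float = 0.12, masc_split: float = 0.015,
                   outgroup_depth: float = 0.25,
                   ) -> tuple[list[MitoGenome], SimTruth]:
    """Multi-species F/M genomes realizing a declared phylogenetic pattern.

    ``taxon_joining``: each species splits into F/M after speciation.
    ``gender_joining``: one ancient F/M split predates all speciations,
    and the F and M clades mirror the same species tree.
    ``masculinization``: exactly two species with a gender-joining
    history, after which the first species' M genome is replaced by a
    recent copy of its F genome.  An outgroup genome (tip label
    ``Outgroup``) is always included for rooting.

    Branch lengths are expected substitution proportions per branch.
    """
    if n_species < 2:
        raise SimConfigError("need at least 2 species")
    if scenario == "masculinization" and n_species != 2:
        raise SimConfigError("masculinization scenario requires exactly 2 species")
    if scenario not in ("taxon_joining", "gender_joining", "masculinization"):
        raise SimConfigError(f"unknown scenario {scenario!r}")
    cfg = base_cfg or SimConfig(seed=seed, scale=0.25, m_extra_ur=0)
    cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    elements = load_elements()
    blocks, _ = _build_ancestor(rng, cfg, elements)
    anc_seq, _ = _assemble(blocks)
    cmap = _CodingMap(blocks, cfg.omega, cfg.omega_default, cfg.code)
    names = [f"Sp{i + 1:02d}" for i in range(n_species)]

    if scenario == "taxon_joining":
        tips = _ladder(names, species_split, fm_split)
        root = _expand_pairs(tips, fm_split)
        labels = {n: "taxon_joining" for n in names}
    elif scenario == "gender_joining":
        f_clade = _ladder([f"{n}{SEP}F" for n in names], species_split, species_split)
        m_clade = _ladder([f"{n}{SEP}M" for n in names], species_split, species_split)
        f_clade.branch = gender_split
        m_clade.branch = gender_split
        root = _SimNode(0.0, children=[f_clade, m_clade])
        labels = {n: "gender_joining" for n in names}
    else:  # masculinization
        a, b = names
        # ancient gender split, then a's M replaced by a fresh copy of a's F
        a_pair = _SimNode(species_split, children=[
            _SimNode(masc_split, label=f"{a}{SEP}F"),
            _SimNode(masc_split, label=f"{a}{SEP}M"),
        ])
        f_clade = _SimNode(gender_split, children=[
            a_pair, _SimNode(species_split, label=f"{b}{SEP}F")])
        root = _SimNode(0.0, children=[
            f_clade, _SimNode(gender_split + species_split, label=f"{b}{SEP}M")])
        labels = {a: "masculinization_signature", b: "masculinization_signature"}

    root = _SimNode(0.0, children=[root, _SimNode(outgroup_depth, label="Outgroup")])
    seqs: dict[str, str] = {}

    def _walk(node: _SimNode, seq: str) -> None:
        seq = _evolve_branch(rng, seq, cmap, node.branch) if node.branch > 0 else seq
        if node.label is not None:
            seqs[node.label] = seq
        for child in node.children:
            _walk(child, seq)

    _walk(root, anc_seq)
    genomes = []
    for label, seq in seqs.items():
        sliced = _reslice(blocks, seq)
        full, feats = _assemble(sliced)
        if label == "Outgroup":
            genomes.append(MitoGenome("Outgroup", "Outgroup", "unknown",
                                      "circular", full, feats))
        else:
            sp, _, sex = label.rpartition(SEP)
            genomes.append(MitoGenome(label, sp, sex, "circular", full, feats))
    truth = SimTruth(0.0, {}, [], [], _newick(root) + ";", scenario, labels)
    return genomes, truth


def _expand_pairs(node: _SimNode, fm_split: float) -> _SimNode:
    """Replace species-labelled tips of a ladder with (F,M) cherries."""
    if node.label is not None:
        return _pair_node(node.label, node.label, node.branch, fm_split)
    node.children = [_expand_pairs(c, fm_split) for c in node.children]
    return node
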