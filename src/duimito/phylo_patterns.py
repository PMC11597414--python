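"""Neighbor-joining tree plumbing and F/M phylogenetic-pattern calls.

In a doubly-uniparental-inheritance clade the F and M mitogenomes of
each species can arrange themselves in characteristic ways on a rooted
tree:

* ``taxon_joining`` — the F and M genomes of a species form their own
  monophyletic pair (recent, species-specific F/M split);
* ``gender_joining`` — F genomes of different species cluster together
  and M genomes cluster separately (one ancient F/M split predating the
  speciations);
* ``masculinization_signature`` — a species' F genome clusters with both
  genomes of a related species while its own M genome attaches outside
  that clade, the footprint left when an M lineage is replaced by a
  recently derived copy of an F lineage;
* ``indeterminate`` — none of the above.

Classification is purely topological and root-dependent, so trees built
here from distance matrices must be rooted with an explicit outgroup.
Support values do not change calls.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

__all__ = ["SexTree", "PatternCall", "nj_tree", "classify_patterns",
           "pattern_summary", "parse_tip_label"]

SEP = "__"


@dataclass
class PatternCall:
    species: str
    label: str  # taxon_joining | gender_joining | masculinization_signature | indeterminate
    evidence: list[str] = field(default_factory=list)


@dataclass
class SexTree:
    """A rooted tree whose tips are labelled ``<species><sep><F|M>``."""

    tree: dendropy.Tree
    sep: str = SEP
    outgroup: str | None = None

    @classmethod
    def from_newick(cls, newick: str, sep: str = SEP,
                    outgroup: str | None = None) -> "SexTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
        st = cls(tree, sep, outgroup)
        if outgroup is not None:
            st.root_at(outgroup)
        return st

    def root_at(self, outgroup_label: str) -> None:
        node = self.tree.find_node_with_taxon_label(outgroup_label)
        if node is None:
            raise KeyError(f"outgroup tip {outgroup_label!r} not in tree")
        self.tree.is_rooted = True
        self.tree.to_outgroup_position(node, update_bipartitions=True)
        self.outgroup = outgroup_label

    def tips(self) -> dict[tuple[str, str], str]:
        """(species, sex) -> tip label, for F/M-labelled tips only."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            label = leaf.taxon.label
            parsed = parse_tip_label(label, self.sep)
            if parsed is not None:
                out[parsed] = label
        return out


def parse_tip_label(label: str, sep: str = SEP) -> tuple[str, str] | None:
    """Split ``species__F`` style labels; None for tips without an F/M tag."""
    if sep not in label:
        return None
    species, _, sex = label.rpartition(sep)
    sex = sex.strip().upper()
    if sex in ("F", "M") and species:
        return species, sex
    return None


# ---------------------------------------------------------------------------
# neighbor joining (plumbing)
# ---------------------------------------------------------------------------

def nj_tree(d: np.ndarray, labels: list[str],
            outgroup: str | None = None, sep: str = SEP) -> SexTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Negative branch lengths are clamped to zero with a warning.  The
    returned tree is rooted at ``outgroup`` when given (required before
    pattern classification).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    dm = DistanceMatrix(d, ids=labels)
    sk = _skbio_nj(dm)
    buf = io.StringIO()
    sk.write(buf)
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                             preserve_underscores=True)
    clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch lengths clamped to 0")
    st = SexTree(tree, sep=sep)
    if outgroup is not None:
        st.root_at(outgroup)
    return st


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def _sexed_leafset(node: dendropy.Node, sep: str) -> set[tuple[str, str]]:
    out = set()
    for leaf in node.leaf_iter():
        parsed = parse_tip_label(leaf.taxon.label, sep)
        if parsed is not None:
            out.add(parsed)
    return out


def _mrca(tree: dendropy.Tree, labels: list[str]) -> dendropy.Node:
    return tree.mrca(taxon_labels=labels)


def classify_patterns(st: SexTree) -> list[PatternCall]:
    """Classify the F/M pattern of every species with both tips present.

    Species missing one sex tip are skipped with a note in the returned
    summary evidence (no call is emitted for them).  Calls are emitted
    regardless of branch support.
    """
    tree = st.tree
    sep = st.sep
    tips = st.tips()
    species = sorted({sp for sp, _ in tips})
    both = [sp for sp in species
            if (sp, "F") in tips and (sp, "M") in tips]
    for sp in species:
        if sp not in both:
            warnings.warn(f"species {sp} missing one sex tip; skipped")
    calls: dict[str, PatternCall] = {}
    masc_pairs: list[tuple[str, str, str]] = []
    for sp in both:
        f_lbl, m_lbl = tips[(sp, "F")], tips[(sp, "M")]
        pair_clade = _sexed_leafset(_mrca(tree, [f_lbl, m_lbl]), sep)
        if pair_clade == {(sp, "F"), (sp, "M")}:
            calls[sp] = PatternCall(sp, "taxon_joining",
                                    [f"monophyletic pair ({f_lbl},{m_lbl})"])
            continue
        f_sister = _sexed_leafset(tree.find_node_with_taxon_label(f_lbl).parent_node, sep) \
            - {(sp, "F")}
        m_sister = _sexed_leafset(tree.find_node_with_taxon_label(m_lbl).parent_node, sep) \
            - {(sp, "M")}
        if f_sister and m_sister \
                and all(sex == "F" for _, sex in f_sister) \
                and all(sex == "M" for _, sex in m_sister):
            calls[sp] = PatternCall(sp, "gender_joining",
                                    [f"F sister: {sorted(f_sister)}",
                                     f"M sister: {sorted(m_sister)}"])
            continue
        masc = None
        for other in both:
            if other == sp:
                continue
            clade = _sexed_leafset(
                _mrca(tree, [f_lbl, tips[(other, "F")]]), sep)
            if (other, "M") in clade and (sp, "M") not in clade:
                masc = (sp, other,
                        f"clade({f_lbl},{tips[(other, 'F')]}) contains "
                        f"{tips[(other, 'M')]} but not {m_lbl}")
                break
        if masc is not None:
            calls[sp] = PatternCall(sp, "masculinization_signature", [masc[2]])
            masc_pairs.append(masc)
            continue
        calls[sp] = PatternCall(sp, "indeterminate",
                                [f"pair clade: {sorted(pair_clade)}"])
    # the conspecific partner of a masculinization pair carries the same signature
    for sp, other, ev in masc_pairs:
        if other in calls:
            calls[other] = PatternCall(other, "masculinization_signature",
                                       [f"paired with {sp}: {ev}"])
    return [calls[sp] for sp in both]


def pattern_summary(calls: list[PatternCall]) -> dict[str, list[str]]:
    """Species lists per pattern label."""
    tally: dict[str, list[str]] = {}
    for c in calls:
        tally.setdefault(c.label, []).append(c.species)
    return {k: sorted(v) for k, v in tally.items()}
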