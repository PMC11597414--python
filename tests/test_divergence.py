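"""Alignment, p-distances, NG86 dN/dS, cox2 scan and TMH scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duimito.divergence import (CodonFrameError, PairwiseAlignment,
                                cox2_mod_scan, global_align, jukes_cantor,
                                ng86_dnds, p_distance, p_distance_ungapped,
                                tmh_scan, translate_cds)
from duimito.synthetic_data import SimConfig, simulate_pair
from oracles import ng86_pair_oracle, nw_score

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestGlobalAlign:
    def test_identical_sequences_no_gaps(self):
        al = global_align("ACGTACGT", "ACGTACGT")
        assert "-" not in al.seq_a + al.seq_b
        assert al.score == 8.0

    def test_terminal_gap(self):
        al = global_align("ACGT", "ACG")
        assert al.seq_a == "ACGT" and al.seq_b == "ACG-"

    @given(dna, dna)
    @settings(max_examples=60, deadline=None)
    def test_score_matches_affine_dp_oracle(self, a, b):
        al = global_align(a, b)
        assert al.score == pytest.approx(nw_score(a, b))

    def test_codon_mode_gaps_are_codon_multiples(self):
        a = "ATGAAACCCGGGTTTTAA"
        b = "ATGAAAGGGTTTTAA"  # one codon missing
        al = global_align(a, b, mode="codon")
        assert al.aligned_columns % 3 == 0
        gap_runs = [r for r in al.seq_b.split("A") if set(r) == {"-"}]
        assert all(len(r) % 3 == 0 for r in gap_runs)

    def test_internal_stop_names_codon_index(self):
        with pytest.raises(CodonFrameError, match="codon index 1"):
            global_align("ATGTAAAAATTT", "ATGAAAAAATTT", mode="codon")


class TestPDistance:
    def test_identical_is_zero(self):
        al = PairwiseAlignment("ACGT", "ACGT", "nt", 4.0)
        assert p_distance(al).p_nt == 0.0

    def test_direct_count(self):
        al = PairwiseAlignment("ACGT", "ACGA", "nt", 2.0)
        assert p_distance(al).p_nt == pytest.approx(0.25)

    def test_gap_and_ambiguity_columns_excluded(self):
        al = PairwiseAlignment("ACGT-N", "ACTTAN", "nt", 0.0)
        rec = p_distance(al)
        assert rec.sites_compared == 4
        assert rec.gap_excluded == 2
        assert rec.p_nt == pytest.approx(0.25)

    def test_zero_compared_columns_flagged(self):
        al = PairwiseAlignment("--NN", "AA--", "nt", 0.0)
        rec = p_distance(al)
        assert not rec.defined

    @given(dna)
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_identity(self, seq):
        other = seq[::-1]
        al = global_align(seq, other)
        swapped = PairwiseAlignment(al.seq_b, al.seq_a, al.mode, al.score)
        assert p_distance(al).p_nt == pytest.approx(p_distance(swapped).p_nt)
        self_al = global_align(seq, seq)
        assert p_distance(self_al).p_nt == 0.0


class TestNG86:
    def test_identical_alignment_zero_counts(self):
        rec = ng86_dnds(("ATGAAATTT", "ATGAAATTT"))
        assert rec.nd == rec.sd == 0
        assert rec.dn == 0 or rec.dn is None
        assert rec.omega is None

    def test_two_synonymous_differences(self):
        # TTT->TTC (Phe) and GCC->GCA (Ala) are synonymous under the
        # invertebrate mitochondrial code
        rec = ng86_dnds(("TTTGCC", "TTCGCA"))
        assert rec.nd == 0 and rec.sd == pytest.approx(2.0)

    def test_site_sum_identity(self):
        rec = ng86_dnds(("ATGAAATTTCCC", "ATAAAGTTCCCA"))
        assert rec.n_sites + rec.s_sites == pytest.approx(3 * rec.codons_compared)

    def test_jc_domain_flagged(self):
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.0) == 0.0

    def test_all_sense_codon_pairs_match_oracle(self):
        from Bio.Data import CodonTable
        table = CodonTable.unambiguous_dna_by_id[5]
        sense = sorted(table.forward_table)
        for c1 in sense[::3]:          # thinned grid; the acceptance suite
            for c2 in sense[::3]:      # runs the full 61x61 comparison
                rec = ng86_dnds((c1, c2))
                s, n, sd, nd = ng86_pair_oracle(c1, c2)
                assert rec.s_sites == pytest.approx(s)
                assert rec.n_sites == pytest.approx(n)
                assert rec.sd == pytest.approx(sd)
                assert rec.nd == pytest.approx(nd)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_random_codon_pair_sites_identity(self, seed):
        from Bio.Data import CodonTable
        table = CodonTable.unambiguous_dna_by_id[5]
        sense = sorted(table.forward_table)
        r = np.random.default_rng(seed)
        a = "".join(r.choice(sense, 20))
        b = "".join(r.choice(sense, 20))
        rec = ng86_dnds((a, b))
        assert rec.n_sites + rec.s_sites == pytest.approx(3 * rec.codons_compared)


class TestCox2Scan:
    def test_identical_to_reference_is_none(self, rng):
        from duimito.synthetic_data import _random_pcg
        ref = _random_pcg(rng, 690, 0.65, 5)
        rep = cox2_mod_scan(ref, ref, ref)
        assert rep["F"].kind == "none" and rep["M"].kind == "none"

    def test_planted_insertion_and_extension(self):
        from duimito.genome_io import extract_gene_seq
        f, m, _ = simulate_pair(SimConfig(seed=5, scale=1.0, nt_divergence=0.1,
                                          cox2_mod=("insertion", "F", 86)))
        rep = cox2_mod_scan(extract_gene_seq(f, "cox2"), extract_gene_seq(m, "cox2"),
                            extract_gene_seq(m, "cox2"))
        assert rep["F"].kind == "insertion"
        assert rep["F"].length_codons == 86
        f2, m2, _ = simulate_pair(SimConfig(seed=6, scale=1.0, nt_divergence=0.1,
                                            cox2_mod=("extension_3prime", "M", 4100)))
        rep2 = cox2_mod_scan(extract_gene_seq(f2, "cox2"), extract_gene_seq(m2, "cox2"),
                             extract_gene_seq(f2, "cox2"))
        assert rep2["M"].kind == "extension_3prime"
        assert rep2["M"].length_nt == pytest.approx(4100, abs=60)
        # hydrophilic planted modifications carry no transmembrane helix
        assert rep["F"].tmh_in_modified_region == 0
        assert rep2["M"].tmh_in_modified_region == 0


class TestTmhScan:
    def test_polylysine_has_no_segment(self):
        assert tmh_scan("K" * 40) == []

    def test_polyleucine_has_exactly_one(self):
        segs = tmh_scan("L" * 25)
        assert len(segs) == 1
        assert segs[0].mean_hydropathy == pytest.approx(3.8)

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError):
            tmh_scan("LLL")

    def test_segments_merge_and_sort(self):
        prot = "K" * 30 + "L" * 25 + "K" * 30 + "I" * 25 + "K" * 10
        segs = tmh_scan(prot)
        assert len(segs) == 2
        assert segs[0].start < segs[1].start
        assert all(s.end - s.start >= 19 for s in segs)


def test_translate_trims_incomplete_stop():
    assert translate_cds("ATGAAAT") == "MK"


def test_alignment_fasta_writer(tmp_path):
    from duimito.divergence import write_alignment_fasta
    al = global_align("ACGT", "ACG")
    out = tmp_path / "al.fasta"
    write_alignment_fasta(al, out, ids=("F", "M"))
    assert out.read_text() == ">F\nACGT\n>M\nACG-\n"


def test_ungapped_p_distance_matches_alignment_for_equal_lengths(rng):
    a = "".join(rng.choice(list("ACGT"), 300))
    b = list(a)
    for i in rng.choice(300, 30, replace=False):
        b[i] = rng.choice([x for x in "ACGT" if x != b[i]])
    b = "".join(b)
    assert p_distance_ungapped(a, b) == pytest.approx(0.1)
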