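"""UR extraction, tandem repeats, G-strings, motifs and folding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duimito.genome_io import GeneFeature, MitoGenome
from duimito.synthetic_data import SimConfig, simulate_pair
from duimito.ur_analysis import (FoldResult, URConfig, characterize_urs,
                                 extract_urs, find_tandem_repeats,
                                 fold_inventory, g_string_scan,
                                 homopolymer_runs, load_elements,
                                 motif_similarity, ur_fraction)
from oracles import g_windows_oracle, max_pairs_exhaustive, motif_best_oracle


def _flat_genome(length, features):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), length))
    return MitoGenome("x", "sp", "F", "circular", seq, features)


class TestExtractUrs:
    def test_fully_covered_genome_has_no_urs(self):
        g = _flat_genome(300, [GeneFeature("cox1", "PCG", 0, 300)])
        assert extract_urs(g) == []

    def test_featureless_genome_is_one_ur(self):
        g = _flat_genome(300, [])
        with pytest.warns(UserWarning, match="featureless"):
            urs = extract_urs(g)
        assert len(urs) == 1 and urs[0].length == 300 and urs[0].is_lur

    def test_origin_gap_is_single_ur(self):
        g = _flat_genome(300, [GeneFeature("cox1", "PCG", 50, 250)])
        urs = extract_urs(g)
        assert len(urs) == 1
        ur = urs[0]
        assert (ur.start, ur.end) == (250, 50)
        assert ur.length == 100
        assert ur.flank5 == "cox1" and ur.flank3 == "cox1"

    def test_flanks_and_principal_threshold(self):
        g = _flat_genome(1000, [GeneFeature("nad1", "PCG", 0, 100),
                                GeneFeature("nad2", "PCG", 300, 400),
                                GeneFeature("trnF", "tRNA", 520, 590),
                                GeneFeature("nad5", "PCG", 590, 1000)])
        urs = extract_urs(g)
        spans = {(u.flank5, u.flank3): u for u in urs}
        assert spans[("nad1", "nad2")].length == 200
        assert spans[("nad1", "nad2")].is_principal
        assert spans[("nad2", "trnF")].length == 120
        assert not spans[("nad2", "trnF")].is_principal
        assert spans[("nad2", "trnF")].is_lur is False
        assert spans[("nad1", "nad2")].is_lur

    def test_overlapping_annotation_excluded_and_warned(self):
        g = _flat_genome(400, [GeneFeature("nad1", "PCG", 0, 200),
                               GeneFeature("nad2", "PCG", 150, 300)])
        with pytest.warns(UserWarning, match="overlap"):
            urs = extract_urs(g)
        assert len(urs) == 1 and urs[0].length == 100

    @given(st.lists(st.tuples(st.integers(0, 450), st.integers(10, 80)),
                    min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_coverage_partition_identity(self, spans):
        # non-overlapping projection: UR total + covered total == length
        L = 600
        feats = []
        pcgs = ["cox1", "cox2", "cox3", "nad1", "nad2", "nad3"]
        for i, (s, w) in enumerate(spans):
            feats.append(GeneFeature(pcgs[i], "PCG", s, min(L, s + w)))
        g = _flat_genome(L, feats)
        cover = np.zeros(L, bool)
        for s, w in spans:
            cover[s:min(L, s + w)] = True
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            urs = extract_urs(g)
        assert sum(u.length for u in urs) == L - cover.sum()


class TestUrFraction:
    def test_printed_totals_reproduce_percent(self):
        # genome of 25197 nt with 8055 nt unassigned -> 32.0%
        feats = [GeneFeature("cox1", "PCG", 0, 25197 - 8055)]
        g = _flat_genome(25197, feats)
        assert ur_fraction(g)["x"] == 32.0

    def test_no_urs_is_zero(self):
        g = _flat_genome(100, [GeneFeature("cox1", "PCG", 0, 100)])
        assert ur_fraction(g)["x"] == 0.0

    def test_featureless_is_hundred(self):
        g = _flat_genome(200, [])
        with pytest.warns(UserWarning):
            assert ur_fraction(g)["x"] == 100.0


class TestTandemRepeats:
    def test_identity_repeat_planted(self, rng):
        flank1 = "".join(rng.choice(list("ACGT"), 50))
        flank2 = "".join(rng.choice(list("ACGT"), 50))
        unit = "ACGTT"
        if flank1.endswith(unit[-1]):
            flank1 = flank1[:-1] + "G"
        if flank2.startswith(unit[0]):
            flank2 = "G" + flank2[1:]
        hits = find_tandem_repeats(flank1 + unit * 6 + flank2)
        assert len(hits) == 1
        assert hits[0].period == 5
        assert hits[0].copy_number == pytest.approx(6.0, abs=0.2)

    def test_two_planted_arrays_recovered(self):
        f, _, truth = simulate_pair(SimConfig(seed=101, scale=0.3,
                                              nt_divergence=0.0, m_extra_ur=0))
        ur = extract_urs(f)[0]  # carries a (30, 2.4) plant
        plant = truth.ur_truth[0]["repeats"][0]
        hits = find_tandem_repeats(ur.sequence)
        assert any(h.period == plant["period"]
                   and abs(h.copy_number - plant["copies"]) <= 0.1
                   for h in hits)

    def test_null_sequences_rarely_hit(self):
        fp = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            if find_tandem_repeats("".join(r.choice(list("ACGT"), 500))):
                fp += 1
        assert fp <= 1

    def test_copy_number_threshold_respected(self, rng):
        for h in find_tandem_repeats("".join(rng.choice(list("ACGT"), 800))):
            assert h.copy_number >= 1.8 and h.score >= 50


class TestGStrings:
    def test_pure_g20_in_random_flanks(self, rng):
        flanks = "".join(rng.choice(list("ACT"), 60))
        hits = g_string_scan(flanks[:30] + "G" * 20 + flanks[30:])
        assert len(hits) == 1
        assert hits[0].length == 20 and hits[0].g_fraction == 1.0

    def test_no_g_no_hits(self):
        assert g_string_scan("ATATATCCCCATAT" * 5) == []

    def test_interior_spread_22mer(self):
        # 18 G + 4 A placed so every sub-window fails the 80% cutoff
        s = list("G" * 22)
        for pos in (5, 8, 11, 14):
            s[pos] = "A"
        hits = g_string_scan("T" * 30 + "".join(s) + "T" * 30)
        assert len(hits) == 1
        assert hits[0].length == 22
        assert hits[0].g_fraction == pytest.approx(18 / 22)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=200))
    @settings(max_examples=80, deadline=None)
    def test_matches_all_windows_oracle(self, seq):
        hits = g_string_scan(seq)
        windows = g_windows_oracle(seq, 18, 23, 0.8)
        assert bool(hits) == bool(windows)
        for h in hits:
            assert (h.start, h.length, h.g_fraction) in \
                [(w[0], w[1], pytest.approx(w[2])) for w in windows]


class TestMotifs:
    def test_verbatim_plant_is_exact(self, rng):
        el = load_elements()["CSB1"]
        seq = "".join(rng.choice(list("ACGT"), 80)) + el + \
            "".join(rng.choice(list("ACGT"), 80))
        hit = motif_similarity(seq, el, "CSB1")
        assert hit.identity == 1.0 and hit.ur_start == 80

    def test_three_mismatches_identity(self, rng):
        el = "ACGTACGTAC"  # length 10
        planted = "AGGTACGTTA"  # 3 mismatches
        seq = "C" * 40 + planted + "C" * 40
        hit = motif_similarity(seq, el)
        assert hit.identity == pytest.approx(0.7)

    def test_reverse_complement_orientation(self, rng):
        el = load_elements()["mTF1"]
        rc = el.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = "".join(rng.choice(list("ACGT"), 60)) + rc + \
            "".join(rng.choice(list("ACGT"), 60))
        hit = motif_similarity(seq, el, "mTF1")
        assert hit.orientation == "-" and hit.identity == 1.0

    def test_short_element_rejected(self):
        with pytest.raises(ValueError):
            motif_similarity("ACGTACGTACGT", "ACGTA")

    @given(st.text(alphabet="ACGT", min_size=30, max_size=120),
           st.text(alphabet="ACGT", min_size=8, max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_best_identity_matches_oracle(self, seq, el):
        hit = motif_similarity(seq, el, min_identity=0.0)
        ident, _, _ = motif_best_oracle(seq, el)
        if hit is not None:
            assert hit.identity == pytest.approx(ident)
        else:
            assert ident <= 0.0 or len(seq) < len(el)


class TestFold:
    def test_unpairable_sequence(self):
        res = fold_inventory("AAAA")
        assert res.max_pairs == 0 and not res.labels

    def test_perfect_hairpin_stem(self):
        res = fold_inventory("GGGGGAAACCCCC")
        assert res.max_pairs >= 5
        assert len(res.stems) == 1
        st0 = res.stems[0]
        assert st0.n_pairs == 5 and st0.loop_len == 3
        assert res.labels == {"stem_loop"}

    def test_long_hairpin_labelled(self):
        arm = "GCGGCCGGCAGC"
        loop = "AAAAA"
        rc = arm.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        res = fold_inventory("TT" + arm + loop + rc + "TT")
        assert "hairpin" in res.labels

    @given(st.text(alphabet="ACGT", min_size=1, max_size=14))
    @settings(max_examples=150, deadline=None)
    def test_max_pairs_matches_exhaustive(self, seq):
        res = fold_inventory(seq, min_stem=1)
        assert res.max_pairs == max_pairs_exhaustive(seq)

    def test_windowing_long_sequences(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1500))
        res = fold_inventory(seq, window=600, step=300)
        assert isinstance(res, FoldResult)
        assert res.max_pairs > 0


class TestCharacterize:
    def test_planted_truth_recovered(self):
        f, _, truth = simulate_pair(SimConfig(seed=77, scale=0.3,
                                              nt_divergence=0.0, m_extra_ur=0))
        recs = characterize_urs(f)
        by_flank = {r.flank5: r for r in recs}
        for ur_truth in truth.ur_truth:
            rec = by_flank[ur_truth["after"]]
            assert rec.length == ur_truth["length"]
            if ur_truth["g_string"]:
                gs = ur_truth["g_string"]
                assert any(h.start == gs["start"] and h.length == gs["length"]
                           for h in rec.g_strings)
            for m in ur_truth["motifs"]:
                hit = next(h for h in rec.motifs if h.element == m["element"])
                assert hit.identity >= m["identity"] - 1e-9
        # principal URs all fold into something
        assert all(r.fold.labels for r in recs if r.is_principal)

    def test_homopolymer_column(self):
        runs = homopolymer_runs("ACGT" + "A" * 10 + "CGT" + "G" * 8 + "TT")
        assert ("A", 4, 10) in runs and ("G", 17, 8) in runs

    def test_paired_report_f_then_m(self):
        f, m, _ = simulate_pair(SimConfig(seed=9, scale=0.3, nt_divergence=0.1))
        f_recs = characterize_urs(f)
        m_recs = characterize_urs(m)
        # the M LUR is longer by the configured asymmetry
        f_lur = next(r for r in f_recs if r.is_lur)
        m_lur = next(r for r in m_recs if r.is_lur)
        assert m_lur.length == f_lur.length + 400
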