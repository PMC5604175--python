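"""Unit tests for pseudo-testcross linkage mapping."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from zwmap import radmap as rm
from zwmap import simpop as sp

HET, HOM, MISS = rm.HET, rm.HOM, rm.MISSING


def marker(mid, calls, scaffold="s1", pos=0, parent="P1"):
    return rm.RadMarker(mid, scaffold, pos, parent, "SNP",
                        np.asarray(calls, dtype=np.int8))


class TestAlignTags:
    def test_unique_tags_retained_multimapping_dropped(self, rng):
        sca = {"s": sp._random_seq(3000, rng)}
        dup = sca["s"][100:160]
        tags = [("t_uniq1", sca["s"][500:560]), ("t_uniq2", sca["s"][500:560]),
                ("t_multi", dup)]
        sca["s2"] = "T" * 20 + dup + "G" * 20  # second copy of dup elsewhere
        placed = rm.align_tags(tags, sca)
        assert set(placed.tag_id) == {"t_uniq1", "t_uniq2"}

    def test_single_tag_positions_dropped(self, rng):
        sca = {"s": sp._random_seq(2000, rng)}
        tags = [("lonely", sca["s"][300:360]),
                ("a", sca["s"][800:860]), ("b", sca["s"][800:860])]
        placed = rm.align_tags(tags, sca)
        assert "lonely" not in set(placed.tag_id)
        assert {"a", "b"} <= set(placed.tag_id)


class TestSegregationFilter:
    # oracle: exact central 95% interval of Binomial(150, 0.5) is [63, 87]
    def test_interval_bounds(self):
        assert int(binom.ppf(0.025, 150, 0.5)) == 63

    def test_keep_center(self):
        calls = np.array([HET] * 75 + [HOM] * 75, dtype=np.int8)
        assert rm.segregation_filter(calls)

    def test_drop_skewed(self):
        calls = np.array([HET] * 60 + [HOM] * 90, dtype=np.int8)
        assert not rm.segregation_filter(calls)

    def test_keep_inclusive_boundary(self):
        calls = np.array([HET] * 63 + [HOM] * 87, dtype=np.int8)
        assert rm.segregation_filter(calls)
        calls62 = np.array([HET] * 62 + [HOM] * 88, dtype=np.int8)
        assert not rm.segregation_filter(calls62)

    def test_missing_excluded_from_n(self):
        calls = np.array([HET] * 40 + [HOM] * 40 + [MISS] * 70, dtype=np.int8)
        assert rm.segregation_filter(calls)

    def test_no_informative_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            rm.segregation_filter(np.array([MISS, MISS], dtype=np.int8))


def _pileup(rows):
    out = []
    for chrom, pos, ref, a, c, g, t in rows:
        out.append({"chrom": chrom, "pos": pos, "ref": ref, "A": a, "C": c,
                    "G": g, "T": t, "depth": a + c + g + t, "sample": "x"})
    return pd.DataFrame(out)


class TestSelectSnpMarkers:
    def _f1s(self, pattern, pos=100):
        """F1 pileups: 'H' carries both alleles, 'A' ref-hom, 'C' alt-hom."""
        out = []
        for ch in pattern:
            if ch == "H":
                out.append(_pileup([("s1", pos, "A", 3, 3, 0, 0)]))
            elif ch == "A":
                out.append(_pileup([("s1", pos, "A", 6, 0, 0, 0)]))
            elif ch == "C":
                out.append(_pileup([("s1", pos, "A", 0, 6, 0, 0)]))
            else:
                out.append(_pileup([("s1", pos, "A", 0, 0, 0, 0)]))
        return out

    def test_boundary_band_inclusive(self):
        # P1 index exactly 0.2 eligible; P2 index 1 eligible; the informative
        # allele is then the reference, so F1 segregates het (A/C) vs hom (C/C)
        p1 = _pileup([("s1", 100, "A", 8, 2, 0, 0)])
        p2 = _pileup([("s1", 100, "A", 0, 10, 0, 0)])
        f1 = self._f1s("H" * 40 + "C" * 40)
        ms = rm.select_snp_markers(p1, p2, f1)
        assert len(ms) == 1 and ms[0].parent == "P1"

    def test_intermediate_other_parent_ineligible(self):
        p1 = _pileup([("s1", 100, "A", 5, 5, 0, 0)])
        p2 = _pileup([("s1", 100, "A", 9, 1, 0, 0)])  # index 0.1: not 0 or 1
        f1 = self._f1s("H" * 40 + "A" * 40)
        assert rm.select_snp_markers(p1, p2, f1) == []

    def test_thinning_one_per_interval(self):
        p1 = _pileup([("s1", 1000, "A", 5, 5, 0, 0), ("s1", 5000, "A", 5, 5, 0, 0)])
        p2 = _pileup([("s1", 1000, "A", 10, 0, 0, 0), ("s1", 5000, "A", 10, 0, 0, 0)])
        f1 = []
        for ch in "H" * 40 + "A" * 40:
            rows = [("s1", 1000, "A", 3, 3, 0, 0) if ch == "H" else ("s1", 1000, "A", 6, 0, 0, 0),
                    ("s1", 5000, "A", 3, 3, 0, 0) if ch == "H" else ("s1", 5000, "A", 6, 0, 0, 0)]
            f1.append(_pileup(rows))
        ms = rm.select_snp_markers(p1, p2, f1, spacing_bp=10_000)
        assert len(ms) == 1


class TestSelectPaMarkers:
    def _sites(self):
        return pd.DataFrame({"scaffold": ["s1"], "pos": [500], "parent": ["P1"]})

    def test_depth_rules(self):
        depths = np.array([[3, 4, 0, 2, 1, 0, 5, 0] * 20])  # n=160
        ms = rm.select_pa_markers(self._sites(), depths, min_informative=100)
        (m,) = ms
        expect = np.array([HET, HET, HOM, MISS, MISS, HOM, HET, HOM] * 20, dtype=np.int8)
        np.testing.assert_array_equal(m.calls, expect)

    def test_informative_boundary(self):
        # 119 informative dropped; 120 retained
        d119 = np.array([[3] * 60 + [0] * 59 + [1] * 41])
        d120 = np.array([[3] * 60 + [0] * 60 + [1] * 40])
        assert rm.select_pa_markers(self._sites(), d119) == []
        assert len(rm.select_pa_markers(self._sites(), d120)) == 1


class TestTwoPoint:
    def test_closed_form_rf_010(self):
        m1 = marker("a", [HET] * 50 + [HOM] * 50)
        m2 = marker("b", [HET] * 45 + [HOM] * 5 + [HET] * 5 + [HOM] * 45)
        st = rm.two_point(m1, m2)
        assert st.rf == pytest.approx(0.10)
        expected = 90 * math.log10(1.8) + 10 * math.log10(0.2)
        assert st.lod == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(15.98, abs=0.005)

    def test_identical_vectors(self):
        m1 = marker("a", [HET] * 50 + [HOM] * 50)
        st = rm.two_point(m1, marker("b", m1.calls))
        assert st.rf == 0.0
        assert st.lod == pytest.approx(100 * math.log10(2), abs=1e-9)

    def test_opposite_vectors_mirrored(self):
        m1 = marker("a", [HET] * 50 + [HOM] * 50)
        m2 = marker("b", [HOM] * 50 + [HET] * 50)
        st = rm.two_point(m1, m2)
        assert st.rf == 1.0
        assert st.lod == pytest.approx(100 * math.log10(2), abs=1e-9)

    def test_independent_markers_unlinked(self, rng):
        n = 1000
        m1 = marker("a", rng.integers(0, 2, n))
        m2 = marker("b", rng.integers(0, 2, n))
        st = rm.two_point(m1, m2)
        lo = binom.ppf(0.005, n, 0.5) / n
        hi = binom.isf(0.005, n, 0.5) / n
        assert lo <= st.rf <= hi
        assert st.lod < 3

    def test_missing_excluded_pairwise(self):
        m1 = marker("a", [HET, HOM, MISS, HET])
        m2 = marker("b", [HET, MISS, HOM, HOM])
        st = rm.two_point(m1, m2)
        assert st.n_informative == 2 and st.n_recombinant == 1

    def test_no_shared_informative_rejected(self):
        m1 = marker("a", [HET, MISS])
        m2 = marker("b", [MISS, HET])
        with pytest.raises(ValueError, match="informative"):
            rm.two_point(m1, m2)

    def test_matches_brute_force_counting(self, rng):
        # property: vectorised pairwise stats equal per-pair brute force
        ms = [marker(f"m{i}", rng.choice([HET, HOM, MISS], 60, p=[.45, .45, .1]))
              for i in range(8)]
        rf, lod, n_inf = rm.pairwise_rf_lod(ms)
        for i in range(8):
            for j in range(i + 1, 8):
                st = rm.two_point(ms[i], ms[j])
                assert rf[i, j] == pytest.approx(st.rf)
                assert lod[i, j] == pytest.approx(st.lod, abs=1e-9)
                assert n_inf[i, j] == st.n_informative


class TestSplitScaffolds:
    def _pair(self, rf_target, n=100, pos=(100_000, 300_000)):
        k = int(rf_target * n)
        m1 = marker("a", [HET] * (n // 2) + [HOM] * (n // 2), pos=pos[0])
        calls2 = list(m1.calls)
        for i in range(k):
            calls2[i] = 1 - calls2[i]
        m2 = marker("b", calls2, pos=pos[1])
        return [m1, m2]

    def test_cut_at_midpoint(self):
        ms = self._pair(0.4)
        pieces = rm.split_scaffolds(ms, {"s1": 500_000})
        assert [(p.start, p.end) for p in pieces] == [(0, 200_000), (200_000, 500_000)]
        assert [len(p.markers) for p in pieces] == [1, 1]
        assert pieces[1].markers[0].pos == 100_000  # shifted

    def test_low_rf_intact(self):
        pieces = rm.split_scaffolds(self._pair(0.1), {"s1": 500_000})
        assert len(pieces) == 1
        assert (pieces[0].start, pieces[0].end) == (0, 500_000)

    def test_partition_exact(self, rng):
        ms = []
        for i, pos in enumerate(sorted(rng.choice(900_000, 6, replace=False))):
            ms.append(marker(f"m{i}", rng.integers(0, 2, 80), pos=int(pos)))
        pieces = rm.split_scaffolds(ms, {"s1": 900_000})
        bounds = sorted((p.start, p.end) for p in pieces)
        assert bounds[0][0] == 0 and bounds[-1][1] == 900_000
        for (a, b), (c, d) in zip(bounds[:-1], bounds[1:]):
            assert b == c


class TestConvertRepulsion:
    def test_raw_09_becomes_01(self):
        m1 = marker("a", [HET] * 50 + [HOM] * 50)
        calls2 = 1 - m1.calls
        calls2[:5] = 1 - calls2[:5]  # rf 0.95... make raw rf 0.9:
        m2 = marker("b", [HOM] * 45 + [HET] * 5 + [HET] * 45 + [HOM] * 5)
        assert rm.two_point(m1, m2).rf == pytest.approx(0.9)
        out = rm.convert_repulsion([m1, m2], lod_schedule=(3,))
        assert rm.two_point(out[0], out[1]).rf == pytest.approx(0.1)
        assert out[1].phase == "repulsion"

    def test_double_complement_involution(self):
        calls = np.array([HET, HOM, MISS, HET], dtype=np.int8)
        np.testing.assert_array_equal(rm._complement(rm._complement(calls)), calls)

    def test_termination_no_repulsion_pairs_left(self, rng):
        # markers on one chromosome, some repulsion-coded
        src = rng.integers(0, 2, 120).astype(np.int8)
        ms = []
        for i in range(10):
            noise = rng.random(120) < 0.05
            calls = np.where(noise, 1 - src, src).astype(np.int8)
            if i % 3 == 0:
                calls = 1 - calls
            ms.append(marker(f"m{i}", calls))
        out = rm.convert_repulsion(ms)
        rf, lod, _ = rm.pairwise_rf_lod(out)
        mask = ~np.eye(len(out), dtype=bool)
        flipped = rm._flipped_lod(rf, lod, out)
        assert not ((rf > 0.5) & (flipped >= 3) & mask).any()


class TestBuildGroups:
    def test_haldane_distance(self):
        assert rm.haldane_cm(0.1) == pytest.approx(-50 * math.log(0.8), abs=1e-9)
        assert rm.haldane_cm(0.1) == pytest.approx(11.16, abs=0.005)

    def test_small_cluster_discarded(self):
        m1 = marker("a", [HET] * 30 + [HOM] * 30)
        m2 = marker("b", m1.calls.copy())
        groups = rm.build_groups_and_order([m1, m2], min_size=3)
        assert groups == []

    def test_two_chromosome_recovery(self, rng):
        cfg = sp.SimConfig(chrom_lengths=(1_000_000, 1_000_000), het_rate_p3=0.0,
                           het_rate_p4=0.0, shared_snp_rate=0.0, w_insert_len=0,
                           w_locus=("chr01", 1), n_f1=200, bulk_size=1,
                           xover_rate=0.5, seed=5)
        p3 = sp.ParentGenome("P1", (sp.Haplotype(), sp.Haplotype()), "ZW")
        p4 = sp.ParentGenome("P2", (sp.Haplotype(), sp.Haplotype()), "ZZ")
        f1 = sp.cross_f1(p3, p4, cfg, np.random.default_rng(5))
        markers = []
        for chrom in cfg.chrom_names:
            for p in np.linspace(50_000, 950_000, 6).astype(int):
                calls = np.array([i.gamete_source("maternal", chrom, int(p))
                                  for i in f1], dtype=np.int8)
                markers.append(marker(f"{chrom}:{p}", calls, scaffold=chrom,
                                      pos=int(p)))
        groups = rm.build_groups_and_order(markers)
        assert len(groups) == 2
        for g in groups:
            chroms = {m.scaffold for m in g.markers}
            assert len(chroms) == 1
            pos = [m.pos for m in g.markers]
            assert pos == sorted(pos) or pos == sorted(pos, reverse=True)
            assert g.cm == sorted(g.cm)


class TestMergeMaps:
    def _group(self, gid, scaffold_markers):
        ms, cm = [], []
        for k, (scaf, pos) in enumerate(scaffold_markers):
            ms.append(marker(f"{gid}:{k}", [HET, HOM] * 20, scaffold=scaf, pos=pos))
            cm.append(float(k * 10))
        return rm.LinkageGroup(gid, ms, cm)

    def test_unique_maxima_pairing(self):
        p1 = [self._group("P1-1", [("sA", 10), ("sB", 20)]),
              self._group("P1-2", [("sC", 10)])]
        p2 = [self._group("P2-1", [("sC", 5)]),
              self._group("P2-2", [("sA", 5), ("sB", 9)])]
        merged = rm.merge_maps(p1, p2)
        assert [m.id for m in merged] == ["chr01", "chr02"]
        assert [s for s, _ in merged[0].pieces] == ["sA", "sB"]

    def test_p2_only_scaffold_inserted(self):
        p1 = [self._group("P1-1", [("sA", 10), ("sB", 20)])]
        p2 = [self._group("P2-1", [("sA", 10), ("sX", 15), ("sB", 20)])]
        merged = rm.merge_maps(p1, p2)
        assert [s for s, _ in merged[0].pieces] == ["sA", "sX", "sB"]

    def test_every_scaffold_once(self):
        p1 = [self._group("P1-1", [("sA", 1), ("sB", 2)]),
              self._group("P1-2", [("sC", 1)])]
        p2 = [self._group("P2-1", [("sB", 1), ("sD", 2)])]
        merged = rm.merge_maps(p1, p2)
        all_scafs = [s for m in merged for s, _ in m.pieces]
        assert sorted(all_scafs) == sorted(set(all_scafs))
        assert set(all_scafs) == {"sA", "sB", "sC", "sD"}


class TestBuildPseudomolecules:
    def _merged(self, pieces):
        return [rm.MergedChromosome("chr01", pieces)]

    def test_gap_length(self, rng):
        seqs = {"a": sp._random_seq(10_000, rng), "b": sp._random_seq(20_000, rng)}
        out, agp = rm.build_pseudomolecules(self._merged([("a", "+"), ("b", "+")]), seqs)
        assert len(out["chr01"]) == 31_000
        assert out["chr01"][10_000:11_000] == "N" * 1000

    def test_single_piece_unchanged(self, rng):
        seqs = {"a": sp._random_seq(500, rng)}
        out, _ = rm.build_pseudomolecules(self._merged([("a", "+")]), seqs)
        assert out["chr01"] == seqs["a"]

    def test_reverse_orientation(self, rng):
        seqs = {"a": sp._random_seq(500, rng)}
        out, _ = rm.build_pseudomolecules(self._merged([("a", "-")]), seqs)
        assert out["chr01"] == sp.revcomp(seqs["a"])

    def test_missing_sequence_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            rm.build_pseudomolecules(self._merged([("zzz", "+")]), {})

    def test_placement_round_trip(self, rng):
        seqs = {k: sp._random_seq(int(rng.integers(200, 900)), rng)
                for k in "abc"}
        merged = self._merged([("a", "+"), ("b", "-"), ("c", "+")])
        out, agp = rm.build_pseudomolecules(merged, seqs)
        for row in agp[agp.component_type == "W"].itertuples(index=False):
            segment = out[row.object][row.object_beg - 1:row.object_end]
            src = seqs[row.component_id]
            assert segment == (src if row.orientation == "+" else sp.revcomp(src))
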