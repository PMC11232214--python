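"""Genomic context: conservation, orientation, TSS, promoters, terminators."""

import numpy as np
import pandas as pd
import pytest

from norfnet.context import (OrientationRecord, classify_conservation,
                             classify_orientation, promoter_tf_binding,
                             shared_promoter, shared_transcript_fraction,
                             terminator_between, tss_from_tifs)

ANN_COLS = ["orf_id", "chrom", "start", "end", "strand", "orf_class",
            "conservation_label", "translation_evidence"]


def _orfs(rows):
    return pd.DataFrame(rows, columns=ANN_COLS)


def _tifs(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


class TestConservation:
    def _tables(self, rfc_rows, hit_rows=()):
        rfc = pd.DataFrame(rfc_rows, columns=["orf_id", "rfc_distant1",
                                              "rfc_distant2", "mean_rfc"])
        hits = pd.DataFrame(list(hit_rows) or None,
                            columns=["orf_id", "search", "evalue",
                                     "outside_genus"])
        return rfc, hits

    def test_low_distant_rfc_is_de_novo(self):
        orfs = _orfs([("x", "c1", 0, 300, "+", "noncanonical", "other", True)])
        rfc, hits = self._tables([("x", 0.50, 0.55, 0.52)])
        assert classify_conservation(orfs, rfc, hits)["x"] == "de_novo"

    def test_high_mean_rfc_is_conserved(self):
        orfs = _orfs([("x", "c1", 0, 300, "+", "canonical", "other", True)])
        rfc, hits = self._tables([("x", 0.7, 0.9, 0.85)])
        assert classify_conservation(orfs, rfc, hits)["x"] == "conserved"

    def test_outside_genus_hit_is_conserved(self):
        orfs = _orfs([("x", "c1", 0, 300, "+", "noncanonical", "other", True)])
        rfc, hits = self._tables([("x", 0.5, 0.5, 0.5)],
                                 [("x", "tblastn", 1e-5, True)])
        assert classify_conservation(orfs, rfc, hits)["x"] == "conserved"

    def test_hit_above_evalue_cut_ignored(self):
        orfs = _orfs([("x", "c1", 0, 300, "+", "noncanonical", "other", True)])
        rfc, hits = self._tables([("x", 0.5, 0.5, 0.5)],
                                 [("x", "tblastn", 1e-3, True)])
        assert classify_conservation(orfs, rfc, hits)["x"] == "de_novo"

    def test_self_blastp_to_canonical_blocks_de_novo(self):
        orfs = _orfs([("x", "c1", 0, 300, "+", "noncanonical", "other", True)])
        rfc, hits = self._tables([("x", 0.5, 0.5, 0.5)],
                                 [("x", "self_blastp", 1e-9, True)])
        assert classify_conservation(orfs, rfc, hits)["x"] == "other"

    def test_same_strand_overlap_with_canonical_blocks_de_novo(self):
        orfs = _orfs([
            ("big", "c1", 0, 900, "+", "canonical", "other", True),
            ("x", "c1", 100, 400, "+", "noncanonical", "other", True),
        ])
        rfc, hits = self._tables([("big", 0.9, 0.9, 0.9),
                                  ("x", 0.5, 0.5, 0.5)])
        assert classify_conservation(orfs, rfc, hits)["x"] == "other"

    def test_missing_rfc_labeled_other_with_warning(self):
        orfs = _orfs([("x", "c1", 0, 300, "+", "noncanonical", "other", True)])
        rfc, hits = self._tables([])
        with pytest.warns(UserWarning):
            labels = classify_conservation(orfs, rfc, hits)
        assert labels["x"] == "other"

    def test_row_order_invariance(self):
        rows = [("a", "c1", 0, 300, "+", "noncanonical", "other", True),
                ("b", "c1", 5000, 5400, "+", "noncanonical", "other", True)]
        rfc, hits = self._tables([("a", 0.5, 0.5, 0.5), ("b", 0.9, 0.9, 0.9)])
        fwd = classify_conservation(_orfs(rows), rfc, hits)
        rev = classify_conservation(_orfs(rows[::-1]),
                                    rfc.iloc[::-1], hits)
        assert dict(fwd) == dict(rev)


class TestOrientation:
    CONS = ("cons", "chr1", 5000, 6000, "+", "canonical", "conserved", True)

    def _classify(self, dn_row):
        return classify_orientation(_orfs([self.CONS, dn_row]))[0]

    @pytest.mark.parametrize("dn,expect", [
        (("d", "chr1", 6100, 6200, "+", "noncanonical", "de_novo", True),
         "down_same"),
        (("d", "chr1", 4800, 4900, "-", "noncanonical", "de_novo", True),
         "up_opposite"),
        (("d", "chr1", 4800, 4900, "+", "noncanonical", "de_novo", True),
         "up_same"),
        (("d", "chr1", 6100, 6200, "-", "noncanonical", "de_novo", True),
         "down_opposite"),
        (("d", "chr1", 5500, 5600, "-", "noncanonical", "de_novo", True),
         "antisense_overlap"),
    ])
    def test_categories(self, dn, expect):
        rec = self._classify(dn)
        assert rec.category == expect
        assert rec.neighbor == "cons"

    def test_500_bp_boundary(self):
        # gap exactly 500 -> in range; 501 -> independent
        rec = self._classify(("d", "chr1", 6500, 6600, "+", "noncanonical",
                              "de_novo", True))
        assert rec.category == "down_same" and rec.distance == 500
        rec = self._classify(("d", "chr1", 6501, 6600, "+", "noncanonical",
                              "de_novo", True))
        assert rec.category == "independent"

    def test_other_chromosome_is_independent(self):
        rec = self._classify(("d", "chr2", 6100, 6200, "+", "noncanonical",
                              "de_novo", True))
        assert rec.category == "independent"

    def test_conflicting_neighbors_ambiguous(self):
        rows = [self.CONS,
                ("cons2", "chr1", 6300, 7300, "+", "canonical", "conserved",
                 True),
                ("d", "chr1", 6100, 6200, "+", "noncanonical", "de_novo",
                 True)]
        rec = classify_orientation(_orfs(rows))[0]
        # downstream of cons, upstream of cons2 -> conflicting categories
        assert rec.category == "ambiguous"

    def test_can_piggyback_flag(self):
        rec = OrientationRecord("d", "c", 10, "down_opposite")
        assert not rec.can_piggyback
        assert OrientationRecord("d", "c", 10, "up_same").can_piggyback


class TestTss:
    ORF = pd.Series({"orf_id": "x", "chrom": "c1", "start": 300, "end": 400,
                     "strand": "+"})

    def test_median_of_covering_tss(self):
        tifs = _tifs([("c1", 100, 500, "t1", 0, "+"),
                      ("c1", 120, 500, "t2", 0, "+"),
                      ("c1", 140, 500, "t3", 0, "+")])
        assert tss_from_tifs(self.ORF, tifs) == 120

    def test_even_count_takes_lower_middle(self):
        tifs = _tifs([("c1", 100, 500, "t1", 0, "+"),
                      ("c1", 130, 500, "t2", 0, "+")])
        assert tss_from_tifs(self.ORF, tifs) == 100

    def test_minus_strand_tss_is_end_minus_one(self):
        orf = pd.Series({"chrom": "c1", "start": 250, "end": 350,
                         "strand": "-"})
        tifs = _tifs([("c1", 200, 400, "t1", 0, "-")])
        assert tss_from_tifs(orf, tifs) == 399

    def test_no_covering_tif_missing(self):
        tifs = _tifs([("c1", 350, 500, "t1", 0, "+"),   # does not cover
                      ("c1", 100, 500, "t2", 0, "-")])  # wrong strand
        assert tss_from_tifs(self.ORF, tifs) is None


class TestPromoterBinding:
    ORF_P = pd.Series({"chrom": "c1", "start": 1200, "end": 1500,
                       "strand": "+"})

    def _track(self, pos):
        return pd.DataFrame([("c1", pos, pos + 1, "TF1", 0, ".")],
                            columns=["chrom", "start", "end", "name",
                                     "score", "strand"])

    def test_site_inside_window_bound(self):
        assert promoter_tf_binding(self.ORF_P, 1000, self._track(850)) == \
            {"TF1"}

    def test_site_201_bp_upstream_not_bound(self):
        assert promoter_tf_binding(self.ORF_P, 1000, self._track(799)) == set()

    def test_site_downstream_not_bound(self):
        assert promoter_tf_binding(self.ORF_P, 1000, self._track(1100)) == \
            set()

    def test_minus_strand_window_is_downstream_in_coordinates(self):
        orf = pd.Series({"chrom": "c1", "start": 500, "end": 800,
                         "strand": "-"})
        assert promoter_tf_binding(orf, 799, self._track(900)) == {"TF1"}
        assert promoter_tf_binding(orf, 799, self._track(700)) == set()

    def test_missing_tss_excluded(self):
        assert promoter_tf_binding(self.ORF_P, None, self._track(850)) is None


class TestSharedPromoter:
    ORFS = _orfs([
        ("cons", "chr1", 5000, 6000, "+", "canonical", "conserved", True),
        ("dn", "chr1", 6100, 6200, "+", "noncanonical", "de_novo", True),
    ])
    PAIR = OrientationRecord("dn", "cons", 100, "down_same")

    def test_joint_tif_means_shared(self):
        tifs = _tifs([("chr1", 4900, 6300, "joint", 0, "+"),
                      ("chr1", 6050, 6250, "own", 0, "+")])
        assert shared_promoter(self.PAIR, self.ORFS, tifs) is True
        assert shared_transcript_fraction(self.PAIR, self.ORFS, tifs) == \
            pytest.approx(0.5)

    def test_separate_tifs_not_shared(self):
        tifs = _tifs([("chr1", 4900, 6050, "c", 0, "+"),
                      ("chr1", 6050, 6250, "d", 0, "+")])
        assert shared_promoter(self.PAIR, self.ORFS, tifs) is False

    def test_de_novo_absent_not_shared(self):
        tifs = _tifs([("chr1", 4900, 6050, "c", 0, "+")])
        assert shared_promoter(self.PAIR, self.ORFS, tifs) is False

    def test_conserved_absent_missing(self):
        tifs = _tifs([("chr1", 6050, 6250, "d", 0, "+")])
        assert shared_promoter(self.PAIR, self.ORFS, tifs) is None

    def test_up_opposite_divergent_shared_vs_overlapping_tss(self):
        orfs = _orfs([
            ("cons", "chr1", 5000, 6000, "+", "canonical", "conserved", True),
            ("dn", "chr1", 4600, 4900, "-", "noncanonical", "de_novo", True),
        ])
        pair = OrientationRecord("dn", "cons", 100, "up_opposite")
        divergent = _tifs([("chr1", 4990, 6020, "c", 0, "+"),
                           ("chr1", 4580, 4920, "d", 0, "-")])
        assert shared_promoter(pair, orfs, divergent) is True
        # conserved isoform reaching past the de novo TSS -> not shared
        overlapping = _tifs([("chr1", 4500, 6020, "c", 0, "+"),
                             ("chr1", 4580, 4920, "d", 0, "-")])
        assert shared_promoter(pair, orfs, overlapping) is False

    def test_wrong_category_rejected(self):
        with pytest.raises(ValueError):
            shared_promoter(OrientationRecord("dn", "cons", 0,
                                              "antisense_overlap"),
                            self.ORFS, _tifs([]))


class TestTerminator:
    ORFS = TestSharedPromoter.ORFS
    PAIR = TestSharedPromoter.PAIR

    def _track(self, pos):
        return pd.DataFrame([("chr1", pos, pos + 1, "Pcf11", 0, ".")],
                            columns=["chrom", "start", "end", "name",
                                     "score", "strand"])

    def test_site_in_gap(self):
        assert terminator_between(self.PAIR, self.ORFS, self._track(6050))

    def test_site_inside_orf_body_ignored(self):
        assert not terminator_between(self.PAIR, self.ORFS, self._track(5500))

    def test_empty_track_false(self):
        empty = self._track(0).iloc[:0]
        assert not terminator_between(self.PAIR, self.ORFS, empty)


class TestSyntheticGroundTruth:
    """The classifier chain must reproduce every planted flag exactly."""

    def test_orientation_matches_truth(self, sim_default):
        sim = sim_default
        recs = classify_orientation(sim.annotation)
        got = {r.orf_id: r.category for r in recs}
        assert got == sim.truth.orientation
        partners = {r.orf_id: r.neighbor for r in recs
                    if r.category not in ("independent", "ambiguous")}
        assert partners == {k: v for k, v in sim.truth.partner.items()
                            if v is not None}

    def test_promoter_sharing_matches_truth(self, sim_default):
        sim = sim_default
        for rec in classify_orientation(sim.annotation):
            if rec.category in ("down_same", "up_same", "up_opposite"):
                got = shared_promoter(rec, sim.annotation, sim.tifs)
                assert got == sim.truth.shares_promoter[rec.orf_id], rec

    def test_terminator_matches_truth(self, sim_default):
        sim = sim_default
        for rec in classify_orientation(sim.annotation):
            if rec.category == "down_same":
                got = terminator_between(rec, sim.annotation, sim.terminators)
                assert got == sim.truth.terminator_present[rec.orf_id], rec

    def test_tf_binding_matches_truth(self, sim_default):
        sim = sim_default
        ann = sim.annotation.set_index("orf_id")
        targets = set(sim.truth.tf_targets["TF1"])
        for oid, row in ann.iterrows():
            tss = tss_from_tifs(row, sim.tifs)
            if tss is None:
                assert oid not in targets
                continue
            bound = promoter_tf_binding(row, tss, sim.tf_sites)
            assert ("TF1" in bound) == (oid in targets), oid
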