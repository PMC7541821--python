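"""Classifier rule tests: viral-ORF lexicon matching, recruitment ratio,
kNN scoring with binomial p-values, the ssDNA and bacterial rules, and
call precedence."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virlink.classify import (ContigEvidence, TrainingSet,
                              bacterial_by_orf_majority,
                              bacterial_by_reference, classify_contig,
                              knn_viral_score, recruitment_ratio, ssdna_flag,
                              viral_orf_fraction)
from virlink.sketch import DistanceRecord


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["qseqid", "orf_index", "rank", "stitle",
                                       "pident", "alignment_fraction",
                                       "subject_class"])


def nr_hit(cid, orf, rank, title):
    return (cid, orf, rank, title, 60.0, 0.9, "nr")


class TestViralOrfFraction:
    def test_half_of_orfs_viral(self):
        rows = [nr_hit("c", 0, 3, "major capsid protein"),
                nr_hit("c", 1, 3, "capsid assembly"),
                nr_hit("c", 2, 1, "hypothetical protein"),
                nr_hit("c", 3, 1, "ABC transporter")]
        assert viral_orf_fraction(hits_frame(rows), "c") == 0.5

    def test_hit_beyond_top_n_ignored(self):
        rows = [nr_hit("c", 0, 11, "capsid protein"),
                nr_hit("c", 0, 1, "hypothetical protein")]
        assert viral_orf_fraction(hits_frame(rows), "c", top_n=10) == 0.0

    def test_plural_and_wholeword_matching(self):
        # plural of a term counts; substrings inside longer words do not
        assert viral_orf_fraction(hits_frame(
            [nr_hit("c", 0, 1, "viruses of archaea")]), "c") == 1.0
        assert viral_orf_fraction(hits_frame(
            [nr_hit("c", 0, 1, "retailer-associated enzyme")]), "c") == 0.0
        assert viral_orf_fraction(hits_frame(
            [nr_hit("c", 0, 1, "T4-like tail fiber")]), "c") == 1.0

    def test_no_nr_hits_is_missing(self):
        rows = [("c", 0, 1, "x", 60.0, 0.9, "refseq_bacteria")]
        assert math.isnan(viral_orf_fraction(hits_frame(rows), "c"))

    def test_refseq_channel_does_not_count(self):
        rows = [nr_hit("c", 0, 1, "hypothetical protein"),
                ("c", 0, 1, "phage capsid", 60.0, 0.9, "refseq_bacteria")]
        assert viral_orf_fraction(hits_frame(rows), "c") == 0.0


class TestRecruitmentRatio:
    def test_symmetric_recruitment_is_zero(self):
        assert recruitment_ratio(9, 9, 10 ** 6, 10 ** 6) == 0.0

    def test_tenfold_enrichment(self):
        assert recruitment_ratio(99, 9, 10 ** 6, 10 ** 6) == pytest.approx(1.0)

    def test_zero_reads_pseudocounted(self):
        assert recruitment_ratio(0, 0, 10 ** 6, 10 ** 6) == 0.0

    def test_metagenome_size_scaling(self):
        # same counts, 10x larger virome -> per-million rate 10x smaller
        assert recruitment_ratio(9, 9, 10 ** 7, 10 ** 6) == pytest.approx(-1.0)

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            recruitment_ratio(1, 1, 0, 10 ** 6)


def grid_training():
    feats = [(1.0, 1.0)] * 10 + [(0.0, -1.0)] * 10
    labels = [True] * 10 + [False] * 10
    return TrainingSet(np.array(feats) + np.arange(20)[:, None] * 1e-4,
                       np.array(labels))


class TestKnn:
    def test_identical_to_unique_training_point(self):
        tr = TrainingSet(np.array([[1.0, 1.0], [0.0, -1.0], [0.2, -0.8]]),
                         np.array([True, False, False]))
        prob, _ = knn_viral_score((1.0, 1.0), tr, k=1)
        assert prob == 1.0

    def test_probability_is_neighbor_fraction(self):
        tr = TrainingSet(np.array([[0.0, 0.0], [0.05, 0.05], [0.1, 0.1],
                                   [5.0, 5.0], [6.0, 6.0]]),
                         np.array([True, True, False, False, False]))
        prob, _ = knn_viral_score((0.0, 0.0), tr, k=3)
        assert prob == pytest.approx(2 / 3)

    def test_binomial_tail_p_value(self):
        tr = grid_training()  # base rate 0.5
        prob, p = knn_viral_score((1.0, 1.0), tr, k=5)
        assert prob == 1.0
        assert p == pytest.approx(0.5 ** 5)

    def test_ties_at_kth_distance_renormalized(self):
        # four equidistant points, k=2: all four used
        feats = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0],
                          [3.0, 3.0], [-3.0, -3.0]])
        labels = np.array([True, True, False, False, True, False])
        tr = TrainingSet(feats, labels)
        prob, _ = knn_viral_score((0.0, 0.0), tr, k=2)
        assert prob == pytest.approx(0.5)

    def test_k_larger_than_training_rejected(self):
        tr = TrainingSet(np.array([[0.0, 0.0], [1.0, 1.0]]),
                         np.array([True, False]))
        with pytest.raises(ValueError):
            knn_viral_score((0, 0), tr, k=3)

    def test_affine_feature_rescaling_invariant(self):
        """z-scoring absorbs any affine rescaling of the raw features."""
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(40, 2))
        labels = feats[:, 0] + feats[:, 1] > 0
        tr1 = TrainingSet(feats, labels)
        tr2 = TrainingSet(feats * [10.0, 0.2] + [5.0, -3.0], labels)
        q = (0.3, -0.2)
        q2 = (0.3 * 10 + 5, -0.2 * 0.2 - 3)
        assert knn_viral_score(q, tr1, k=5) == knn_viral_score(q2, tr2, k=5)


class TestSsdnaFlag:
    def hit(self, lo, hi, e=1e-6):
        return {"aligned_start": lo, "aligned_end": hi, "evalue": e}

    def test_quarter_coverage_qualifies(self):
        assert ssdna_flag([self.hit(0, 250)], 1000) is True

    def test_below_coverage_threshold(self):
        assert ssdna_flag([self.hit(0, 150)], 1000) is False

    def test_length_cap_excludes_long_contigs(self):
        assert ssdna_flag([self.hit(0, 6000)], 12000) is False

    def test_weak_evalue_ignored(self):
        assert ssdna_flag([self.hit(0, 500, e=1e-3)], 1000) is False

    def test_overlapping_spans_merged_before_summing(self):
        # two overlapping 150bp hits cover only 200bp < 20%*1100
        hits = [self.hit(0, 150), self.hit(50, 200)]
        assert ssdna_flag(hits, 1100) is False
        assert ssdna_flag(hits + [self.hit(400, 500)], 1100) is True

    def test_negative_span_rejected(self):
        with pytest.raises(ValueError):
            ssdna_flag([self.hit(-5, 100)], 1000)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(0, 100)),
                    max_size=6))
    def test_monotone_in_added_hits(self, spans):
        hits = [self.hit(lo, lo + w) for lo, w in spans]
        base = ssdna_flag(hits, 1000)
        more = ssdna_flag(hits + [self.hit(0, 300)], 1000)
        assert more >= base  # adding a qualifying hit never flips True->False


class TestBacterialRules:
    def rec(self, a, b, d):
        return DistanceRecord(a, b, 0.5, d)

    @pytest.mark.parametrize("d,expect", [(0.04, True), (0.05, True),
                                          (0.06, False)])
    def test_reference_distance_threshold_inclusive(self, d, expect):
        recs = [self.rec("c", "bref1", d)]
        assert bacterial_by_reference(recs, {"bref1"}, "c") is expect

    def test_no_records_is_false(self):
        assert bacterial_by_reference([], {"bref1"}, "c") is False

    def test_match_to_nonreference_ignored(self):
        recs = [self.rec("c", "other_protist", 0.01)]
        assert bacterial_by_reference(recs, {"bref1"}, "c") is False

    def orf_rows(self, n_qual, n_total):
        rows = []
        for i in range(n_total):
            rows.append(nr_hit("c", i, 1, "hypothetical protein"))
            if i < n_qual:
                rows.append(("c", i, 1, "bacterial protein", 80.0, 0.9,
                             "refseq_bacteria"))
        return hits_frame(rows)

    def test_majority_with_verification(self):
        assert bacterial_by_orf_majority(self.orf_rows(3, 4), "c", "bacterial")

    def test_exact_half_is_not_majority(self):
        assert not bacterial_by_orf_majority(self.orf_rows(2, 4), "c", "bacterial")

    def test_organellar_verification_blocks(self):
        assert not bacterial_by_orf_majority(self.orf_rows(4, 4), "c", "organellar")

    def test_identity_and_coverage_thresholds(self):
        rows = hits_frame([
            nr_hit("c", 0, 1, "x"),
            ("c", 0, 1, "weak hit", 45.0, 0.9, "refseq_bacteria")])
        assert not bacterial_by_orf_majority(rows, "c", "bacterial")


class TestClassifyContig:
    def ev(self, **kw):
        return ContigEvidence("c", **kw)

    def test_external_category_two_is_viral(self):
        call = classify_contig(self.ev(external_viral_category=2))
        assert call.category == "viral"
        assert "external_viral_category" in call.basis

    def test_external_category_three_alone_is_eukaryote(self):
        call = classify_contig(self.ev(external_viral_category=3))
        assert call.category == "eukaryote"
        assert call.basis == ()

    def test_viral_beats_bacterial(self):
        call = classify_contig(self.ev(ssdna_flag=True,
                                       bacterial_by_reference=True))
        assert call.category == "viral"
        assert set(call.basis) == {"ssdna", "bacterial_by_reference"}

    def test_knn_needs_both_threshold_and_alpha(self):
        assert classify_contig(self.ev(knn_probability=1.0, knn_pvalue=0.03)
                               ).category == "viral"
        assert classify_contig(self.ev(knn_probability=1.0, knn_pvalue=0.2)
                               ).category == "eukaryote"
        assert classify_contig(self.ev(knn_probability=0.4, knn_pvalue=0.01)
                               ).category == "eukaryote"

    def test_bacterial_rules(self):
        assert classify_contig(self.ev(bacterial_by_reference=True)
                               ).category == "bacterial"
        assert classify_contig(self.ev(bacterial_by_orf_majority=True)
                               ).category == "bacterial"

    def test_default_is_eukaryote(self):
        call = classify_contig(self.ev())
        assert call.category == "eukaryote"

    def test_calls_exhaustive_and_exclusive(self):
        # every combination of boolean evidence yields exactly one category
        import itertools
        for ext, ss, br, bo in itertools.product([None, 1, 3], [True, False],
                                                 [True, False], [True, False]):
            call = classify_contig(self.ev(external_viral_category=ext,
                                           ssdna_flag=ss,
                                           bacterial_by_reference=br,
                                           bacterial_by_orf_majority=bo))
            assert call.category in {"viral", "bacterial", "eukaryote"}
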