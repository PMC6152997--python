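"""Observed-allele classification and outcome metrics."""
import warnings

import pandas as pd
import pytest

from premascan import (
    AlleleClassifier,
    ObservedAllele,
    tide_adjusted_prevalence,
)
from premascan.fixtures import allele_table_from_frame
from premascan import simulate_allele_table


@pytest.fixture()
def clf(group3_locus):
    return AlleleClassifier(
        group3_locus.locus, group3_locus.config,
        list(group3_locus.patterns),
    )


def mutate(seq, *positions):
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
    chars = list(seq)
    for i in positions:
        chars[i] = alt[chars[i]]
    return "".join(chars)


def off_arm_positions(allele, n):
    a0, a1 = allele.retained_arm_span
    out = [
        i for i in range(len(allele.resulting_sequence))
        if not a0 <= i < a1
    ]
    return out[:n]


class TestClassifyRead:
    def test_exact_predicted_deletion_is_top_mh(self, clf):
        obs = ObservedAllele(clf.predicted.resulting_sequence, 1)
        assert clf.classify(obs) == "top_mh"

    def test_two_off_arm_substitutions_tolerated(self, clf):
        seq = clf.predicted.resulting_sequence
        pos = off_arm_positions(clf.predicted, 2)
        obs = ObservedAllele(mutate(seq, *pos), 1)
        assert clf.classify(obs) == "top_mh"

    def test_three_substitutions_exceed_tolerance(self, clf):
        seq = clf.predicted.resulting_sequence
        pos = off_arm_positions(clf.predicted, 3)
        obs = ObservedAllele(mutate(seq, *pos), 1)
        assert clf.classify(obs) == "other_mutant"

    def test_substitution_on_retained_arm_disqualifies(self, clf):
        seq = clf.predicted.resulting_sequence
        arm_pos = clf.predicted.retained_arm_span[0]
        obs = ObservedAllele(mutate(seq, arm_pos), 1)
        assert clf.classify(obs) == "other_mutant"

    def test_second_pattern_allele_is_other_mmej(self, clf):
        second = clf.alleles[1]
        obs = ObservedAllele(second.resulting_sequence, 1)
        assert clf.classify(obs) == "other_mmej"

    def test_reference_with_snp_is_wildtype(self, clf):
        ref = clf.locus.sequence
        assert clf.classify(ObservedAllele(ref, 1)) == "wildtype"
        assert clf.classify(ObservedAllele(mutate(ref, 3), 1)) == "wildtype"

    def test_insertion_is_never_mmej(self, clf):
        ref = clf.locus.sequence
        cut = clf.locus.cut_index
        obs = ObservedAllele(ref[:cut] + "A" + ref[cut:], 1)
        assert clf.classify(obs) == "other_mutant"

    def test_compound_indel_descriptor_is_other_mutant(self, clf):
        cut = clf.locus.cut_index
        obs = ObservedAllele(None, 1, indel=(cut - 2, 4, "TT"))
        assert clf.classify(obs) == "other_mutant"

    def test_pure_deletion_descriptor_materialized(self, clf):
        d0, d1 = clf.predicted.deleted_span
        obs = ObservedAllele(None, 1, indel=(d0, d1 - d0, ""))
        assert clf.classify(obs) == "top_mh"

    def test_garbage_read_excluded(self, clf):
        assert clf.classify(ObservedAllele("ACGTX", 1)) == "excluded"
        assert clf.classify(ObservedAllele("A", 1)) == "excluded"

    def test_count_must_be_positive(self):
        with pytest.raises(ValueError):
            ObservedAllele("ACGT", 0)


class TestMetrics:
    @pytest.mark.parametrize(
        "top,total_mutant,expected",
        [(21, 24, 0.875), (16, 32, 0.50), (28, 39, 0.718)],
    )
    def test_subcloning_fractions(self, clf, top, total_mutant, expected):
        ref = clf.locus.sequence
        cut = clf.locus.cut_index
        table = [
            ObservedAllele(clf.predicted.resulting_sequence, top),
            ObservedAllele(ref[:cut] + "A" + ref[cut:], total_mutant - top),
            ObservedAllele(ref, 3),
        ]
        m = clf.metrics(table)
        assert m.mutant_reads == total_mutant
        assert m.top_mh_fraction == pytest.approx(expected, abs=5e-4)

    def test_fraction_ordering_invariant(self, clf):
        ref = clf.locus.sequence
        cut = clf.locus.cut_index
        table = [
            ObservedAllele(clf.predicted.resulting_sequence, 10),
            ObservedAllele(clf.alleles[1].resulting_sequence, 5),
            ObservedAllele(ref[:cut] + "G" + ref[cut:], 5),
            ObservedAllele(ref, 10),
        ]
        m = clf.metrics(table)
        assert m.top_mh_fraction <= m.mh_fraction <= 1
        assert m.top_mh_fraction == pytest.approx(0.5)
        assert m.mh_fraction == pytest.approx(0.75)
        assert m.mutagenic_efficiency == pytest.approx(2 / 3)

    def test_counts_conserved_across_classes(self, clf):
        ref = clf.locus.sequence
        table = [
            ObservedAllele(clf.predicted.resulting_sequence, 7),
            ObservedAllele(ref, 5),
            ObservedAllele("ACGTX", 2),
        ]
        m = clf.metrics(table)
        assert m.total_reads == 14
        assert m.excluded_reads == 2
        assert m.mutant_reads == 7

    def test_prema_boundary_behaviour(self, clf):
        ref = clf.locus.sequence
        cut = clf.locus.cut_index

        def table(top, others, wildtype):
            rows = [ObservedAllele(clf.predicted.resulting_sequence, top)]
            # split the rest across distinct 1 bp insertions so the top
            # allele stays modal
            for i, b in enumerate("ACGT"):
                share = others // 4 + (1 if i < others % 4 else 0)
                if share:
                    rows.append(
                        ObservedAllele(ref[:cut] + b + ref[cut:], share)
                    )
            rows.append(ObservedAllele(ref, wildtype))
            return rows

        # top fraction exactly 0.50, efficiency 21/100 > 0.2, modal top
        m = clf.metrics(table(top=10, others=10, wildtype=79))
        assert m.top_mh_fraction == pytest.approx(0.5)
        assert m.mutagenic_efficiency == pytest.approx(0.2020, abs=1e-3)
        assert m.prema

        # efficiency exactly 0.20 fails the strict inequality
        m = clf.metrics(table(top=10, others=10, wildtype=80))
        assert m.mutagenic_efficiency == pytest.approx(0.2)
        assert not m.prema
        assert not m.low_activity  # 0.20 is not *below* the threshold

    def test_zero_mutant_reads(self, clf):
        m = clf.metrics([ObservedAllele(clf.locus.sequence, 50)])
        assert m.mutant_reads == 0
        assert m.mh_fraction is None and m.top_mh_fraction is None
        assert not m.prema

    def test_simulated_table_recovers_planted_fractions(self, group3_locus):
        fractions = {
            "wildtype": 0.1, "top_mh": 0.7875,
            "other_mmej": 0.05, "other_mutant": 0.0625,
        }
        df = simulate_allele_table(group3_locus, fractions, 10_000, seed=2)
        clf = AlleleClassifier(
            group3_locus.locus, group3_locus.config,
            list(group3_locus.patterns),
        )
        m = clf.metrics(allele_table_from_frame(df))
        # 0.7875/0.9 = 0.875 of mutants; binomial sd ~ 0.0035
        assert m.top_mh_fraction == pytest.approx(0.875, abs=3 * 0.0035)
        assert m.mutagenic_efficiency == pytest.approx(0.9, abs=0.01)
        assert m.prema


class TestTideAdjustedPrevalence:
    def test_renormalizes_to_mutant_signal(self):
        df = pd.DataFrame({
            "indel_size": [0, -4, -1, -7],
            "percentage": [40.0, 27.0, 18.0, 15.0],
            "significant": [True, True, True, True],
        })
        # -4 is 27/60 of mutant signal
        assert tide_adjusted_prevalence(df, -4) == pytest.approx(0.45)

    def test_single_mutant_class_is_one(self):
        df = pd.DataFrame({"indel_size": [0, -4], "percentage": [60.0, 40.0]})
        assert tide_adjusted_prevalence(df, -4, sig_col=None) == 1.0

    def test_absent_predicted_size_warns_and_zero(self):
        df = pd.DataFrame({"indel_size": [0, -1], "percentage": [50.0, 50.0]})
        with pytest.warns(UserWarning, match="absent"):
            assert tide_adjusted_prevalence(df, -4, sig_col=None) == 0.0

    def test_insignificant_rows_ignored(self):
        df = pd.DataFrame({
            "indel_size": [0, -4, -2],
            "percentage": [50.0, 25.0, 25.0],
            "significant": [True, True, False],
        })
        assert tide_adjusted_prevalence(df, -4) == pytest.approx(1.0)
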