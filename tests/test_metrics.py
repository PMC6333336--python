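import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerqc import (
    AlleleCall,
    Classification,
    Panel,
    PanelAssignment,
    PanelStatus,
    Polarity,
    PolarisationError,
    PolarisationSource,
    breeding_rates,
    call_rate,
    clarity,
    classify,
    evaluate_marker,
    false_negative_rate,
    false_positive_rate,
    polarise_by_fnr,
    utility,
)
from conftest import make_marker, make_matrix, make_panel, random_panel_case
from oracle_utils import (
    all_polarisations,
    oracle_call_rate,
    oracle_clarity,
    oracle_fnr,
    oracle_fpr,
    oracle_min_fnr,
    oracle_utility,
)


def column_as_tuples(column):
    return {v: (c.state.value, set(c.alleles)) for v, c in column.items()}


class TestTechnicalMetrics:
    def test_ambiguous_counts_as_visible_but_not_clear(self):
        calls = (
            [AlleleCall.called("A")] * 8
            + [AlleleCall.ambiguous()]
            + [AlleleCall.missing()]
        )
        assert call_rate(calls) == pytest.approx(0.9)
        assert clarity(calls) == pytest.approx(0.8)

    def test_perfect_and_empty_columns(self):
        assert call_rate([AlleleCall.called("A")] * 10) == 1.0
        assert clarity([AlleleCall.ambiguous()] * 4) == 0.0
        assert call_rate([]) is None
        assert clarity([]) is None


class TestClassify:
    marker = make_marker(favourable="G", unfavourable="A")

    @pytest.mark.parametrize(
        "call, expected",
        [
            (AlleleCall.called("G"), Classification.QTL_POS),
            (AlleleCall.called("A"), Classification.QTL_NEG),
            (AlleleCall.called("A", "G"), Classification.CONFLICT),
            (AlleleCall.called("T"), Classification.UNINFORMATIVE),
            (AlleleCall.missing(), Classification.UNSCORED),
            (AlleleCall.ambiguous(), Classification.UNSCORED),
        ],
    )
    def test_allele_presence_classification(self, call, expected):
        assert classify(call, self.marker) == expected

    def test_unpolarised_marker_rejected(self):
        with pytest.raises(PolarisationError):
            classify(AlleleCall.called("G"),
                     make_marker(target=Polarity.UNPOLARISED))


class TestAccuracyRates:
    def test_perfect_marker_scores_zero_on_both_rates(self):
        marker = make_marker()
        calls = {f"d{i}": AlleleCall.called("G") for i in range(5)}
        calls |= {f"r{i}": AlleleCall.called("A") for i in range(10)}
        matrix = make_matrix(marker, calls)
        col = matrix.column(marker)
        fpr, _ = false_positive_rate(col, marker, {f"r{i}" for i in range(10)})
        fnr, _ = false_negative_rate(col, marker, {f"d{i}" for i in range(5)})
        assert fpr == 0.0 and fnr == 0.0

    def test_third_allele_recipient_is_a_false_positive(self):
        # a recipient carrying neither declared allele lacks the
        # unfavourable allele and so reads as QTL[+]
        marker = make_marker()
        calls = {f"r{i}": AlleleCall.called("A") for i in range(8)}
        calls |= {"r8": AlleleCall.called("T"), "r9": AlleleCall.called("T")}
        col = make_matrix(marker, calls).column(marker)
        fpr, n = false_positive_rate(col, marker, set(calls))
        assert fpr == pytest.approx(0.2) and n == 10

    def test_unscored_recipients_leave_the_denominator(self):
        marker = make_marker()
        calls = {
            "r0": AlleleCall.called("A"),
            "r1": AlleleCall.called("A"),
            "r2": AlleleCall.called("A"),
            "r3": AlleleCall.called("G"),  # the one false positive
            "r4": AlleleCall.missing(),
            "r5": AlleleCall.missing(),
        }
        col = make_matrix(marker, calls).column(marker)
        fpr, n = false_positive_rate(col, marker, set(calls))
        assert fpr == pytest.approx(0.25) and n == 4

    def test_het_donor_is_not_a_false_negative(self):
        marker = make_marker()
        donors = {
            "d0": AlleleCall.called("A", "G"),
            "d1": AlleleCall.called("G"),
            "d2": AlleleCall.called("G"),
            "d3": AlleleCall.called("G"),
            "d4": AlleleCall.called("A"),
        }
        col = make_matrix(marker, donors).column(marker)
        fnr, _ = false_negative_rate(col, marker, set(donors))
        assert fnr == pytest.approx(0.2)


class TestBreedingMetrics:
    def test_pool_equal_to_universe_reproduces_global_rates(self):
        marker = make_marker()
        calls = {f"d{i}": AlleleCall.called("G") for i in range(4)}
        calls |= {f"r{i}": AlleleCall.called("A" if i else "G")
                  for i in range(6)}
        matrix = make_matrix(marker, calls)
        panel = make_panel(donors=[f"d{i}" for i in range(4)],
                           recipients=[f"r{i}" for i in range(6)])
        col = matrix.column(marker)
        bp_fpr, bp_fnr = breeding_rates(col, marker, panel)
        fpr, _ = false_positive_rate(col, marker, panel.recipients)
        fnr, _ = false_negative_rate(col, marker, panel.donors)
        assert bp_fpr == fpr and bp_fnr == fnr

    def test_restricting_pool_can_hide_a_misclassified_recipient(self):
        marker = make_marker()
        calls = {"d0": AlleleCall.called("G"),
                 "r0": AlleleCall.called("A"),
                 "r1": AlleleCall.called("G")}  # the misclassified one
        matrix = make_matrix(marker, calls)
        panel = make_panel(donors=["d0"], recipients=["r0", "r1"],
                           pool={"d0", "r0"})
        col = matrix.column(marker)
        fpr, _ = false_positive_rate(col, marker, panel.recipients)
        bp_fpr, _ = breeding_rates(col, marker, panel)
        assert fpr == pytest.approx(0.5) and bp_fpr == 0.0

    def test_pool_without_donors_gives_undefined_bp_fnr(self):
        marker = make_marker()
        calls = {"d0": AlleleCall.called("G"), "r0": AlleleCall.called("A")}
        matrix = make_matrix(marker, calls)
        panel = make_panel(donors=["d0"], recipients=["r0"], pool={"r0"})
        _, bp_fnr = breeding_rates(matrix.column(marker), marker, panel)
        assert bp_fnr is None

    def test_utility_counts_pool_members_lacking_favourable(self):
        marker = make_marker()
        calls = {f"p{i}": AlleleCall.called("A" if i < 13 else "G")
                 for i in range(20)}
        col = make_matrix(marker, calls).column(marker)
        util, n = utility(col, marker, set(calls))
        assert util == pytest.approx(0.65) and n == 20

    def test_utility_extremes_fixed_and_absent(self):
        marker = make_marker()
        fixed = {f"p{i}": AlleleCall.called("G") for i in range(5)}
        absent = {f"p{i}": AlleleCall.called("A") for i in range(5)}
        assert utility(make_matrix(marker, fixed).column(marker), marker,
                       set(fixed))[0] == 0.0
        assert utility(make_matrix(marker, absent).column(marker), marker,
                       set(absent))[0] == 1.0


class TestPolariseByFnr:
    def test_unanimous_donors(self):
        marker = make_marker(target=Polarity.UNPOLARISED)
        calls = {f"d{i}": AlleleCall.called("G") for i in range(3)}
        calls |= {f"r{i}": AlleleCall.called("A") for i in range(3)}
        col = make_matrix(marker, calls).column(marker)
        pol = polarise_by_fnr(col, {f"d{i}" for i in range(3)})
        assert pol.favourable_allele == "G"
        assert pol.unfavourable_allele == "A"
        assert pol.source is PolarisationSource.FNR_CORRECTED
        assert not pol.tie_broken

    def test_majority_donor_allele_wins(self):
        marker = make_marker(target=Polarity.UNPOLARISED)
        calls = {f"d{i}": AlleleCall.called("G" if i < 3 else "A")
                 for i in range(5)}
        col = make_matrix(marker, calls).column(marker)
        pol = polarise_by_fnr(col, set(calls))
        assert pol.favourable_allele == "G"
        assert pol.donor_allele_frequencies["G"] == pytest.approx(0.6)

    def test_tie_broken_by_lower_fpr(self):
        marker = make_marker(target=Polarity.UNPOLARISED)
        donors = {"d0": AlleleCall.called("G"), "d1": AlleleCall.called("A")}
        # recipients mostly carry A, so favourable=G gives the lower FPR
        recipients = {f"r{i}": AlleleCall.called("A") for i in range(9)}
        recipients["r9"] = AlleleCall.called("G")
        col = make_matrix(marker, donors | recipients).column(marker)
        pol = polarise_by_fnr(col, set(donors), set(recipients))
        assert pol.favourable_allele == "G"
        assert pol.tie_broken

    def test_no_scored_donor_calls_is_an_error(self):
        marker = make_marker(target=Polarity.UNPOLARISED)
        calls = {"d0": AlleleCall.missing(), "r0": AlleleCall.called("A"),
                 "r1": AlleleCall.called("G")}
        col = make_matrix(marker, calls).column(marker)
        with pytest.raises(PolarisationError):
            polarise_by_fnr(col, {"d0"})


class TestEvaluateMarker:
    def test_perfect_diagnostic_marker_flags(self):
        from markerqc import QTLDefinition

        marker = make_marker(diagnostic=True, linkage_cM=0.0)
        calls = {"d0": AlleleCall.called("G"), "d1": AlleleCall.called("G"),
                 "r0": AlleleCall.called("A"), "r1": AlleleCall.called("A")}
        matrix = make_matrix(marker, calls)
        panel = make_panel(donors=["d0", "d1"], recipients=["r0", "r1"])
        qtl = QTLDefinition("qX", "", 1, 10**9)
        rec = evaluate_marker(marker, matrix, panel, qtl)
        assert rec.ideal_flags["fpr"] and rec.ideal_flags["fnr"]
        assert rec.ideal_flags["call_rate"] and rec.ideal_flags["clarity"]
        assert not rec.ideal_flags["utility"]  # donors carry the allele
        assert rec.polarisation_source is PolarisationSource.DECLARED

    def test_all_missing_column_has_undefined_accuracy(self):
        from markerqc import QTLDefinition

        marker = make_marker()
        calls = {v: AlleleCall.missing() for v in ("d0", "r0")}
        matrix = make_matrix(marker, calls)
        panel = make_panel(donors=["d0"], recipients=["r0"])
        rec = evaluate_marker(marker, matrix, panel,
                              QTLDefinition("qX", "", 1, 10**9))
        assert rec.call_rate == 0.0
        assert rec.fpr is None and rec.fnr is None and rec.utility is None


# ---------------------------------------------------------------------------
# properties


class TestOracleEquivalence:
    def test_every_metric_matches_brute_force_on_random_panels(self, rng):
        """Exact agreement with the naive per-sample loop on 200 panels."""
        for _ in range(200):
            matrix, panel, qtl = random_panel_case(rng)
            for marker in matrix.markers:
                col = matrix.column(marker)
                tcol = column_as_tuples(col)
                assert call_rate(col.values()) == oracle_call_rate(tcol)
                assert clarity(col.values()) == oracle_clarity(tcol)
                if not marker.is_polarised:
                    try:
                        pol = polarise_by_fnr(col, panel.donors,
                                              panel.recipients)
                    except PolarisationError:
                        continue
                    fav, unfav = pol.favourable_allele, pol.unfavourable_allele
                    marker = make_marker(marker.marker_id, fav, unfav)
                else:
                    fav = marker.favourable_allele
                    unfav = marker.unfavourable_allele
                assert false_positive_rate(col, marker, panel.recipients) == \
                    oracle_fpr(tcol, unfav, panel.recipients)
                assert false_negative_rate(col, marker, panel.donors) == \
                    oracle_fnr(tcol, fav, panel.donors)
                assert utility(col, marker, panel.pool) == \
                    oracle_utility(tcol, fav, panel.pool)
                bp_fpr, bp_fnr = breeding_rates(col, marker, panel)
                assert bp_fpr == oracle_fpr(
                    tcol, unfav, panel.recipients & panel.pool)[0]
                assert bp_fnr == oracle_fnr(
                    tcol, fav, panel.donors & panel.pool)[0]

    def test_fnr_correction_is_minimal_over_exhaustive_search(self, rng):
        for _ in range(100):
            matrix, panel, _ = random_panel_case(rng, max_markers=5)
            for marker in matrix.markers:
                col = matrix.column(marker)
                tcol = column_as_tuples(col)
                try:
                    pol = polarise_by_fnr(col, panel.donors, panel.recipients)
                except PolarisationError:
                    continue
                achieved, _ = oracle_fnr(tcol, pol.favourable_allele,
                                         panel.donors)
                best = oracle_min_fnr(tcol, panel.donors)
                assert achieved == best

    def test_polarisation_ties_resolve_deterministically(self, rng):
        for _ in range(50):
            matrix, panel, _ = random_panel_case(rng, max_markers=3)
            for marker in matrix.markers:
                col = matrix.column(marker)
                try:
                    p1 = polarise_by_fnr(col, panel.donors, panel.recipients)
                    p2 = polarise_by_fnr(col, panel.donors, panel.recipients)
                except PolarisationError:
                    continue
                assert (p1.favourable_allele, p1.unfavourable_allele) == (
                    p2.favourable_allele, p2.unfavourable_allele)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sampled_from(["called_hom", "called_het", "missing", "ambiguous"]),
        min_size=1,
        max_size=40,
    )
)
def test_clarity_never_exceeds_call_rate(states):
    calls = []
    for s in states:
        if s == "called_hom":
            calls.append(AlleleCall.called("A"))
        elif s == "called_het":
            calls.append(AlleleCall.called("A", "G"))
        elif s == "missing":
            calls.append(AlleleCall.missing())
        else:
            calls.append(AlleleCall.ambiguous())
    assert clarity(calls) <= call_rate(calls)


class TestMonotonicity:
    def test_appending_pool_member_without_favourable_never_decreases_utility(self):
        marker = make_marker()
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(1, 15))
            calls = {
                f"p{i}": AlleleCall.called(str(rng.choice(["A", "G"])))
                for i in range(n)
            }
            col = make_matrix(marker, calls).column(marker)
            before, _ = utility(col, marker, set(calls))
            calls["extra"] = AlleleCall.called("A")
            col = make_matrix(marker, calls).column(marker)
            after, _ = utility(col, marker, set(calls))
            assert after >= before

    def test_appending_donor_with_favourable_never_increases_fnr(self):
        marker = make_marker()
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(1, 15))
            calls = {
                f"d{i}": AlleleCall.called(str(rng.choice(["A", "G"])))
                for i in range(n)
            }
            col = make_matrix(marker, calls).column(marker)
            before, _ = false_negative_rate(col, marker, set(calls))
            calls["extra"] = AlleleCall.called("G")
            col = make_matrix(marker, calls).column(marker)
            after, _ = false_negative_rate(col, marker, set(calls))
            assert after <= before
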