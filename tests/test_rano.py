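"""Response-assessment rules: status classification, outcome automaton, KM/log-rank."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metseg import rano
from metseg.rano import ENLARGEMENT, INDETERMINATE, LC, LF, SHRINKAGE, STEADY


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "baseline,nadir,current,expected",
        [
            (10, 10, 6.9, SHRINKAGE),  # 31% decrease vs baseline
            (10, 6, 7.3, ENLARGEMENT),  # 21.7% increase vs nadir
            (10, 10, 8.5, STEADY),  # 15% decrease, no nadir increase
            (10, 4, 0.0, SHRINKAGE),  # disappearance (CR)
            (10, 10, 7.0, STEADY),  # exactly 30%: "more than" is strict
            (10, 10, 12.0, STEADY),  # exactly 20%: strict
            (10, 10, 12.01, ENLARGEMENT),
        ],
    )
    def test_rules(self, baseline, nadir, current, expected):
        assert rano.classify_status(baseline, nadir, current) == expected

    def test_negative_ld_rejected(self):
        with pytest.raises(ValueError):
            rano.classify_status(10, 10, -1)
        with pytest.raises(ValueError):
            rano.classify_status(0, 0, 1)


class TestAssessTimeline:
    def test_sustained_shrinkage_is_lc(self):
        tl = rano.assess_timeline([12, 8, 6, 5])
        assert tl.status_series == [SHRINKAGE, SHRINKAGE, SHRINKAGE]
        assert tl.outcome == LC and not tl.are_flag

    def test_confirmed_progression_is_lf_at_third_followup(self):
        # shrinkage at FU1, enlargement at FU2, >1 mm further increase at FU3
        tl = rano.assess_timeline([10, 6, 8, 10])
        assert tl.status_series == [SHRINKAGE, ENLARGEMENT, ENLARGEMENT]
        assert tl.outcome == LF and tl.lf_time == 3

    def test_transient_enlargement_is_are_at_fourth_followup(self):
        # steady FU1-2, enlargement FU3, decrease FU4
        tl = rano.assess_timeline([10, 9.5, 9, 12, 10])
        assert tl.status_series[:3] == [STEADY, STEADY, ENLARGEMENT]
        assert tl.outcome == LC and tl.are_flag and tl.are_time == 4

    def test_unconfirmable_final_enlargement(self):
        tl = rano.assess_timeline([10, 9, 12])
        assert tl.status_series == [STEADY, ENLARGEMENT]
        assert tl.outcome == INDETERMINATE

    def test_are_then_confirmed_progression_converts_to_lf(self):
        # enlargement, settles (ARE), enlarges again and is confirmed
        tl = rano.assess_timeline([10, 13, 10.5, 14, 16])
        assert tl.are_flag and tl.are_time == 2
        assert tl.outcome == LF and tl.lf_time == 4

    def test_steady_series(self):
        tl = rano.assess_timeline([10, 10])
        assert tl.status_series == [STEADY] and tl.outcome == LC

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            rano.assess_timeline([10])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        lds=st.lists(st.floats(1.0, 100.0), min_size=2, max_size=6),
        c=st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, lds, c):
        """Scaling LDs by c and the confirm threshold by c preserves everything."""
        base = rano.assess_timeline(lds)
        scaled = rano.assess_timeline(
            [x * c for x in lds], rano.OutcomeConfig(lf_confirm_mm=1.0 * c)
        )
        assert scaled.status_series == base.status_series
        assert scaled.outcome == base.outcome
        assert scaled.are_flag == base.are_flag


# ---------------------------------------------------------------------------
# exhaustive agreement with a direct transcription of the published rules


def transcribed_rules(lds, shrink=0.30, enlarge=0.20, confirm=1.0):
    """Independent re-statement of the outcome rules, written from the text.

    Statuses: enlargement if >20% above the nadir (smallest measurement so
    far, baseline included); else shrinkage if >30% below baseline; else
    steady. Outcome: no enlargement anywhere -> LC. For each enlargement at
    follow-up j with a subsequent scan: LD rising by more than `confirm` mm
    versus scan j -> LF (detected at j+1, scanning stops); otherwise the
    lesion is LC with ARE (detected at j+1) and scanning continues. An
    enlargement on the last scan, unconfirmed, with no LF before -> outcome
    indeterminate.
    """
    baseline = lds[0]
    statuses = []
    for j in range(1, len(lds)):
        nadir = min(lds[:j])
        if lds[j] > nadir * (1 + enlarge):
            statuses.append(ENLARGEMENT)
        elif lds[j] < baseline * (1 - shrink):
            statuses.append(SHRINKAGE)
        else:
            statuses.append(STEADY)

    outcome, are, lf_t, are_t = LC, False, None, None
    for j, s in enumerate(statuses, start=1):
        if s != ENLARGEMENT:
            continue
        if j == len(statuses):
            outcome = INDETERMINATE
            break
        if lds[j + 1] - lds[j] > confirm:
            outcome, lf_t = LF, j + 1
            break
        if not are:
            are, are_t = True, j + 1
    return statuses, outcome, are, lf_t, are_t


def test_exhaustive_agreement_with_rule_transcription():
    """Automaton vs independent transcription on a dense grid of LD series.

    The grid of follow-up values around a baseline of 10 mm realises every
    status sequence of length <= 4 over {shrinkage, steady, enlargement},
    including values on and adjacent to the 30%/20%/1 mm boundaries.
    """
    values = [0.0, 4.0, 6.5, 6.9, 7.0, 7.5, 9.0, 10.0, 11.0, 12.0, 12.5, 13.4, 15.0]
    seen = set()
    for n_fu in (1, 2, 3, 4):
        for fus in itertools.product(values, repeat=n_fu):
            lds = [10.0, *fus]
            tl = rano.assess_timeline(lds)
            statuses, outcome, are, lf_t, are_t = transcribed_rules(lds)
            assert tl.status_series == statuses, lds
            assert tl.outcome == outcome, lds
            assert tl.are_flag == are, lds
            assert (tl.lf_time, tl.are_time) == (lf_t, are_t), lds
            seen.add(tuple(statuses))
    # every status sequence of length <= 4 was actually realised
    for k in (1, 2, 3, 4):
        realised = {s for s in seen if len(s) == k}
        assert len(realised) == 3**k


class TestPerformance:
    def test_perfect_prediction(self):
        m = rano.status_performance([SHRINKAGE, STEADY], [SHRINKAGE, STEADY])
        assert m["accuracy"] == 1.0
        assert m[SHRINKAGE]["precision"] == 1.0 and m[STEADY]["recall"] == 1.0

    def test_hand_computed_binary_table(self):
        truth = [LF, LC, LC, LC]
        pred = [LC, LC, LC, LC]
        m = rano.binary_performance(pred, truth, positive=LF)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.0)
        assert m["specificity"] == pytest.approx(1.0)

    def test_undefined_ratio_is_nan(self):
        m = rano.status_performance([STEADY], [STEADY])
        assert np.isnan(m[ENLARGEMENT]["precision"])  # no predicted positives

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            rano.status_performance([], [])
        with pytest.raises(ValueError):
            rano.binary_performance([LC], [LC, LF], positive=LF)


def hand_logrank(times_a, events_a, times_b, events_b):
    """Risk-table log-rank oracle (1 df chi-square)."""
    all_t = sorted(set(list(times_a) + list(times_b)))
    O_E = 0.0
    V = 0.0
    for t in all_t:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        da = sum(1 for x, e in zip(times_a, events_a) if x == t and e)
        db = sum(1 for x, e in zip(times_b, events_b) if x == t and e)
        n, d = na + nb, da + db
        if n == 0 or d == 0:
            continue
        O_E += da - d * na / n
        if n > 1:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestKmLogrank:
    def test_identical_arms(self):
        t = [1.0, 2.0, 3.0]
        e = [True, True, False]
        res = rano.km_logrank(t, e, t, e)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_computed_four_subjects(self):
        ta, ea = [1.0, 2.0], [True, True]
        tb, eb = [3.0, 4.0], [True, True]
        res = rano.km_logrank(ta, ea, tb, eb)
        assert res["statistic"] == pytest.approx(hand_logrank(ta, ea, tb, eb), rel=1e-6)

    def test_all_censored_curve_constant_one(self):
        res = rano.km_logrank([1, 2, 3], [False] * 3, [2, 3], [False] * 2)
        assert np.allclose(res["curves"]["a"]["survival"], 1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            rano.km_logrank([], [], [1], [True])
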