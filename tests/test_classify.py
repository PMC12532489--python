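"""Window matching, validity classification, recodes and listing rules."""

from datetime import date, timedelta

import pandas as pd
import pytest

import medagree as m
from medagree.classify import (
    EXCLUDED,
    FN,
    FP,
    STANDARD_WINDOWS,
    TN,
    TP,
    WINDOW_1MO,
    ValidationError,
    canonical_status,
)

QDATE = date(2020, 6, 15)


def claim(days_before, atc="L04AB01", item="999999", pid="P00001"):
    return m.DispensingRecord(
        participant_id=pid,
        supply_date=QDATE - timedelta(days=days_before),
        atc_code=atc,
        item_code=item,
    )


class TestMatching:
    @pytest.mark.parametrize(
        "days_before, matched",
        [(30, True), (31, False), (0, True), (-1, False), (365, False)],
        ids=["on-boundary", "outside", "same-day", "day-after", "far-past"],
    )
    def test_30_day_window_boundaries_inclusive(self, single_med, report_factory, days_before, matched):
        """Supplies exactly at the window edge or on the questionnaire day
        count; anything outside (including future supplies) does not."""
        matches = m.match_dispensings(
            report_factory("current"), [claim(days_before)], single_med, WINDOW_1MO
        )
        assert (len(matches) == 1) == matched

    def test_code_and_participant_filtering(self, single_med, report_factory):
        claims = [
            claim(10),
            claim(5, atc="L04AB02"),  # wrong drug
            claim(5, pid="P00099"),  # wrong participant
        ]
        matches = m.match_dispensings(report_factory("current"), claims, single_med, WINDOW_1MO)
        assert matches == [QDATE - timedelta(days=10)]

    def test_item_code_matching_discriminates_shared_atc(self, report_factory):
        oral = m.MedicationDefinition(
            medication_id="mtx_oral", display_name="Methotrexate (oral)",
            med_class="csDMARD", prescription_only=True, question_type="four_level",
            match_mode="item_code", codes=frozenset({"162201"}),
        )
        claims = [claim(10, atc="L04AX03", item="162201"), claim(5, atc="L04AX03", item="107563")]
        matches = m.match_dispensings(
            report_factory("current", med="mtx_oral"), claims, oral, WINDOW_1MO
        )
        assert matches == [QDATE - timedelta(days=10)]

    def test_matches_sorted_ascending(self, single_med, report_factory):
        matches = m.match_dispensings(
            report_factory("current"), [claim(3), claim(25), claim(14)], single_med, WINDOW_1MO
        )
        assert matches == sorted(matches)


class TestClassification:
    @pytest.mark.parametrize(
        "status, match_offsets, stop_offset, expected",
        [
            ("current", [10], None, TP),
            ("current", [], None, FP),
            ("checked", [10], None, TP),
            ("checked", [], None, FP),
            ("never", [], None, TN),
            ("unchecked", [], None, TN),
            ("stopped", [], None, TN),
            ("never", [10], None, FN),
            ("unchecked", [10], None, FN),
            ("stopped", [20], 40, FN),  # supply after the reported stop date
            ("stopped", [40], 20, TN),  # every supply before the stop date
            ("stopped", [40, 10], 20, FN),  # any post-stop supply contradicts
            ("stopped", [10], None, FN),  # carve-out needs a stop date
            ("dont_know", [5], None, EXCLUDED),
            ("dont_know", [], None, EXCLUDED),
        ],
    )
    def test_validity_rules(self, report_factory, status, match_offsets, stop_offset, expected):
        """The complete TP/TN/FP/FN/excluded rule set, including the
        stop-date adjudication branches."""
        stop = QDATE - timedelta(days=stop_offset) if stop_offset else None
        matches = [QDATE - timedelta(days=d) for d in match_offsets]
        assert m.classify_self_report(report_factory(status, stop_date=stop), matches) == expected

    def test_never_with_dispensing_policy_switch(self, report_factory):
        matches = [QDATE - timedelta(days=10)]
        rep = report_factory("never")
        assert m.classify_self_report(rep, matches, never_with_dispensing="fn") == FN
        assert m.classify_self_report(rep, matches, never_with_dispensing="excluded") == EXCLUDED

    def test_stop_date_requires_stopped_status(self):
        with pytest.raises(ValidationError):
            m.SelfReportRecord("P1", QDATE, "etanercept", "current", stop_date=QDATE)

    def test_malformed_atc_rejected(self):
        with pytest.raises(ValidationError):
            m.DispensingRecord("P1", QDATE, "L04AB0", "999999")

    def test_status_canonicalisation(self):
        assert canonical_status(" Currently taking ") == "current"
        assert canonical_status("Don't know") == "dont_know"
        with pytest.raises(ValueError):
            canonical_status("sometimes")


class TestMonotoneMatching:
    def test_tp_nondecreasing_fp_nonincreasing_in_window(self, small_classified):
        """Matches under a window are a subset of matches under any longer
        window, so TP tallies never fall and FP tallies never rise."""
        for _, grp in small_classified.groupby("medication_id"):
            prev_tp, prev_fp = -1, float("inf")
            for w in STANDARD_WINDOWS:
                t = m.build_contingency(grp[f"validity_{w.label}"])
                assert t.tp >= prev_tp
                assert t.fp <= prev_fp
                prev_tp, prev_fp = t.tp, t.fp

    def test_partition_constant_across_windows(self, small_classified):
        """TP+TN+FP+FN+excluded equals the report count for every
        medication at every window."""
        for _, grp in small_classified.groupby("medication_id"):
            for w in STANDARD_WINDOWS:
                t = m.build_contingency(grp[f"validity_{w.label}"])
                assert t.total == len(grp)


class TestRecodes:
    def _reports(self, status_map, free_text=()):
        rows = []
        for med, status in status_map.items():
            row = {
                "participant_id": "P1", "questionnaire_date": pd.Timestamp("2020-06-15"),
                "medication_id": med, "status": status, "stop_date": pd.NaT,
            }
            for i, t in enumerate(free_text, start=1):
                row[f"free_text_{i}"] = t
            rows.append(row)
        return pd.DataFrame(rows)

    def _meds(self):
        return {
            "paracetamol": m.MedicationDefinition(
                medication_id="paracetamol", display_name="Paracetamol",
                med_class="nonopioid_analgesic", prescription_only=False,
                question_type="checkbox", match_mode="atc7", codes=frozenset({"N02BE01"})),
        }

    def test_free_text_overrides_negative_status(self):
        reports = self._reports({"paracetamol": "unchecked"}, free_text=["Panadol"])
        recodes = pd.DataFrame([{"token": "panadol", "medication_id": "paracetamol",
                                 "target_status": "checked"}])
        out, log = m.apply_recode_table(reports, recodes, self._meds())
        assert out["status"].iloc[0] == "checked"
        assert log.counts == {"paracetamol": 1}

    def test_idempotent_on_already_positive_status(self):
        reports = self._reports({"paracetamol": "checked"}, free_text=["panadol"])
        recodes = pd.DataFrame([{"token": "panadol", "medication_id": "paracetamol",
                                 "target_status": "checked"}])
        out, log = m.apply_recode_table(reports, recodes, self._meds())
        assert out["status"].iloc[0] == "checked"
        assert log.total == 0

    def test_empty_recode_table_is_identity(self):
        reports = self._reports({"paracetamol": "unchecked"}, free_text=["panadol"])
        out, log = m.apply_recode_table(reports, pd.DataFrame(columns=["token", "medication_id", "target_status"]), self._meds())
        assert out["status"].iloc[0] == "unchecked"
        assert log.total == 0

    def test_unknown_medication_in_recode_table_rejected(self):
        reports = self._reports({"paracetamol": "unchecked"})
        recodes = pd.DataFrame([{"token": "x", "medication_id": "nope", "target_status": "checked"}])
        with pytest.raises(ValidationError):
            m.apply_recode_table(reports, recodes, self._meds())


class TestListingFilter:
    def _med(self, listed_from=None, listed_to=None):
        return m.MedicationDefinition(
            medication_id="tofacitinib", display_name="Tofacitinib",
            med_class="btsDMARD", prescription_only=True, question_type="four_level",
            match_mode="atc7", codes=frozenset({"L04AA29"}),
            listed_from=listed_from, listed_to=listed_to)

    def _reports(self, dates):
        return pd.DataFrame({
            "participant_id": "P1", "questionnaire_date": pd.to_datetime(dates),
            "medication_id": "tofacitinib", "status": "current", "stop_date": pd.NaT,
        })

    def test_report_before_listing_excluded(self):
        med = self._med(listed_from=date(2015, 10, 1))
        out, dropped = m.filter_by_listing(self._reports(["2013-01-01", "2016-01-01"]), med)
        assert not dropped
        assert list(out["excluded_reason"]) == ["outside_listing_period", ""]

    def test_full_period_listing_keeps_all(self):
        out, dropped = m.filter_by_listing(self._reports(["2013-01-01", "2016-01-01"]), self._med())
        assert not dropped
        assert (out["excluded_reason"] == "").all()

    def test_no_listing_overlap_drops_medication(self):
        med = self._med(listed_from=date(2024, 1, 1))
        out, dropped = m.filter_by_listing(
            self._reports(["2013-01-01"]), med,
            study_start=date(2012, 1, 1), study_end=date(2023, 6, 30))
        assert dropped and len(out) == 0

    def test_listing_exclusions_present_in_pipeline(self, small_classified):
        sub = small_classified[small_classified["medication_id"] == "tofacitinib"]
        pre_listing = sub["questionnaire_date"] < pd.Timestamp("2015-10-01")
        assert (sub.loc[pre_listing, "validity_3mo"] == EXCLUDED).all()
        assert (sub.loc[pre_listing, "excluded_reason"] == "outside_listing_period").all()
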