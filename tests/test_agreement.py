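"""Kappa, diagnostic metrics, window selection and banding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

import medagree as m
from medagree.agreement import (
    EmptyTableError,
    load_reference_counts,
    recompute_reference_metrics,
    round_half_up,
)
from medagree.classify import STANDARD_WINDOWS, WINDOW_1MO, WINDOW_3MO, WINDOW_6MO, WINDOW_12MO


def table(tp=0, tn=0, fp=0, fn=0, excluded=0):
    return m.ContingencyTable(tp=tp, tn=tn, fp=fp, fn=fn, excluded=excluded)


def expanded_kappa(t):
    """Independent oracle: Cohen's kappa from the expanded per-report
    label lists via scikit-learn."""
    self_report = [1] * t.tp + [0] * t.tn + [1] * t.fp + [0] * t.fn
    claims = [1] * t.tp + [0] * t.tn + [0] * t.fp + [1] * t.fn
    return cohen_kappa_score(self_report, claims)


class TestKappa:
    def test_perfect_agreement(self):
        assert m.cohens_kappa(table(tp=10, tn=10)).value == 1.0

    def test_independence_is_zero(self):
        assert m.cohens_kappa(table(tp=10, tn=10, fp=10, fn=10)).value == pytest.approx(0.0)

    def test_all_negative_perfect_table(self):
        # both raters constant and agreeing: kappa 1 by convention
        assert m.cohens_kappa(table(tn=50)).value == 1.0

    def test_degenerate_margin_flagged_undefined(self):
        est = m.cohens_kappa(table(tn=5, fn=5))
        assert not est.defined and np.isnan(est.value)

    def test_swap_symmetry(self):
        a = m.cohens_kappa(table(tp=7, tn=40, fp=3, fn=9)).value
        b = m.cohens_kappa(table(tp=40, tn=7, fp=9, fn=3)).value
        assert a == pytest.approx(b, abs=1e-15)

    def test_matches_expanded_label_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            t = table(*(int(x) for x in rng.integers(1, 200, size=4)))
            assert m.cohens_kappa(t).value == pytest.approx(expanded_kappa(t), abs=1e-12)

    @given(st.integers(1, 500), st.integers(1, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, derandomize=True)
    def test_kappa_in_range(self, tp, tn, fp, fn):
        est = m.cohens_kappa(table(tp=tp, tn=tn, fp=fp, fn=fn))
        if est.defined:
            assert -1.0 - 1e-12 <= est.value <= 1.0 + 1e-12
            assert est.ci_lo <= est.value <= est.ci_hi

    @given(st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=100, derandomize=True)
    def test_kappa_one_iff_no_disagreement(self, tp, tn):
        assert m.cohens_kappa(table(tp=tp, tn=tn)).value == pytest.approx(1.0)
        est = m.cohens_kappa(table(tp=tp, tn=tn, fp=1))
        assert est.value < 1.0


class TestDiagnosticMetrics:
    def test_perfect_classifier(self):
        sens, ppv, npv = m.diagnostic_metrics(table(tp=5, tn=5))
        assert sens.value == ppv.value == npv.value == 1.0

    def test_zero_denominator_flagged_not_zero(self):
        sens, ppv, npv = m.diagnostic_metrics(table(tn=10))
        assert not sens.defined and not ppv.defined and npv.defined
        assert np.isnan(sens.value)

    def test_clopper_pearson_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(129, 147), (98, 275), (1, 30), (0, 12), (12, 12)]:
            est = m.diagnostic_metrics(table(tp=x, fn=n - x))[0]
            lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
            assert est.value == pytest.approx(x / n)
            assert est.ci_lo == pytest.approx(lo, abs=1e-12, nan_ok=True) or (x == 0 and est.ci_lo == 0.0)
            assert est.ci_hi == pytest.approx(hi, abs=1e-12, nan_ok=True) or (x == n and est.ci_hi == 1.0)


class TestContingency:
    def test_direct_tally(self):
        t = m.build_contingency(["TP", "TN", "excluded"])
        assert (t.tp, t.tn, t.fp, t.fn, t.excluded) == (1, 1, 0, 0, 1)

    def test_empty_input_raises(self):
        with pytest.raises(EmptyTableError):
            m.build_contingency([])

    def test_tallies_match_bruteforce_recount(self, small_classified):
        grp = small_classified[small_classified["medication_id"] == "methotrexate_oral"]
        t = m.build_contingency(grp["validity_3mo"])
        labels = list(grp["validity_3mo"])
        assert t.tp == labels.count("TP")
        assert t.fn == labels.count("FN")
        assert t.excluded == labels.count("excluded")


class TestWindowSelection:
    def _results(self, kappas, sens):
        out = {}
        for w in STANDARD_WINDOWS:
            t = table(tp=1, tn=1)
            r = m.compute_agreement(t)
            r.kappa = m.MetricEstimate(kappas[w.days], 0, 1)
            r.sensitivity = m.MetricEstimate(sens.get(w.days, 0.5), 0, 1)
            out[w] = r
        return out

    def test_argmax_kappa(self):
        res = self._results({30: 0.2, 90: 0.4, 182: 0.6, 365: 0.9}, {})
        assert m.select_optimal_window(res) is WINDOW_12MO

    def test_kappa_tie_broken_by_sensitivity(self):
        res = self._results({30: 0.5, 90: 0.7, 182: 0.7, 365: 0.6},
                            {90: 0.80, 182: 0.90})
        assert m.select_optimal_window(res) is WINDOW_6MO

    def test_double_tie_prefers_shortest_window_all_permutations(self):
        """With kappa and sensitivity equal everywhere the shortest window
        wins regardless of dict insertion order."""
        for perm in itertools.permutations(STANDARD_WINDOWS):
            res = self._results({w.days: 0.7 for w in STANDARD_WINDOWS},
                                {w.days: 0.8 for w in STANDARD_WINDOWS})
            res = {w: res[w] for w in perm}
            assert m.select_optimal_window(res) is WINDOW_1MO

    def test_all_undefined_raises(self):
        t = table(tn=5, fn=5)  # degenerate margin
        res = {w: m.compute_agreement(
            m.ContingencyTable(tp=0, tn=5, fp=0, fn=5, window=w)) for w in STANDARD_WINDOWS}
        with pytest.raises(ValueError):
            m.select_optimal_window(res)


class TestKappaBands:
    @pytest.mark.parametrize(
        "kappa, band",
        [(0.15, "poor"), (0.20, "poor"), (0.21, "fair"), (0.40, "fair"),
         (0.41, "moderate"), (0.60, "moderate"), (0.61, "substantial"),
         (0.63, "substantial"), (0.80, "substantial"), (0.81, "high"),
         (0.95, "high"), (-0.3, "poor")],
    )
    def test_band_boundaries(self, kappa, band):
        assert m.classify_kappa_band(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.classify_kappa_band(1.5)


class TestRounding:
    @pytest.mark.parametrize("x, expected", [(0.805, 0.81), (0.125, 0.13), (0.804999, 0.8), (0.2, 0.2)])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestPublishedReference:
    """Recomputation of the bundled published agreement table."""

    def test_reference_rows_load(self):
        ref = load_reference_counts()
        assert len(ref) == 35
        assert set(ref["med_class"]) == {
            "csDMARD", "btsDMARD", "opioid_analgesic", "nonopioid_analgesic", "glucocorticoid"}

    def test_point_estimates_reproduce_at_2dp(self):
        df = recompute_reference_metrics()
        for col in ("kappa", "sensitivity", "ppv", "npv"):
            calc = df[f"{col}_calc"].map(round_half_up)
            assert (calc == df[col]).all(), df.loc[calc != df[col], "medication_id"].tolist()

    def test_confidence_intervals_reproduce_at_2dp(self):
        df = recompute_reference_metrics()
        for col in ("kappa", "sensitivity", "ppv", "npv"):
            for side in ("lo", "hi"):
                calc = df[f"{col}_{side}_calc"].map(round_half_up)
                assert (calc == df[f"{col}_{side}"]).all(), (
                    col, side, df.loc[calc != df[f"{col}_{side}"], "medication_id"].tolist())
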