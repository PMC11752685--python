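import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cholmech import decision, descriptors, fixtures, pbtk, qsar_panel
from cholmech.compound_io import CompoundRecord
from cholmech.decision import (
    Rule,
    RuleConfig,
    apply_correction,
    classify,
    compute_metrics,
    evaluate,
    predict_batch,
    predict_compound,
    qivive_dose,
)

# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementation under test


def oracle_rule(votes, rule):
    n_pos = sum(votes)
    if rule == "OR":
        return 1 if n_pos >= 1 else 0
    if rule == "AND":
        return 1 if n_pos == len(votes) else 0
    if rule == "MAJORITY":
        return 1 if n_pos > len(votes) / 2 else 0
    raise ValueError(rule)


def oracle_confusion(y_true, y_pred):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    return tp, fp, tn, fn


def oracle_mcc(tp, fp, tn, fn):
    # 0-when-undefined convention for a vanishing denominator
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def oracle_auc(y_true, scores):
    """Pairwise Mann-Whitney AUC with half-credit for ties."""
    pos = [s for y, s in zip(y_true, scores) if y == 1]
    neg = [s for y, s in zip(y_true, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# QIVIVE dose conversion


@pytest.fixture(scope="module")
def params():
    return pbtk.build_parameters(fub=0.3, clint=15.0)


class TestQiviveDose:
    def test_zero_ic50_gives_zero_dose(self, params):
        assert qivive_dose(0.0, 300.0, params) == 0.0

    def test_fixed_point_of_definition(self, params):
        # an IC50 whose mg/L equivalent equals Css(1 mg/kg/day) maps to dose 1
        css_unit = pbtk.css_analytic(params, 1.0)
        mw = 250.0
        ic50 = css_unit * 1000.0 / mw
        assert qivive_dose(ic50, mw, params) == pytest.approx(1.0, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(ic50=st.floats(1e-4, 1e4))
    def test_linearity(self, params, ic50):
        assert qivive_dose(2 * ic50, 300.0, params) == pytest.approx(
            2 * qivive_dose(ic50, 300.0, params), rel=1e-10
        )

    def test_no_clearance_is_an_error(self):
        p = pbtk.build_parameters(fub=1.0, clint=0.0, overrides={"gfr": 0.0})
        with pytest.raises(pbtk.NoClearanceError):
            qivive_dose(1.0, 300.0, p)

    def test_simulated_css_at_qivive_dose_equals_ic50(self, params):
        """Reverse dosimetry closes the loop: dosing at the extrapolated
        dose reproduces the IC50 as the steady-state plasma level."""
        mw = 320.0
        ic50 = 5.0
        dose = qivive_dose(ic50, mw, params)
        days = min(pbtk.days_to_steady_state(params), 40)
        sim = pbtk.simulate_regimen(params, pbtk.DosingRegimen(dose, 1, days))
        assert sim.css == pytest.approx(ic50 * mw / 1000.0, rel=0.05)


class TestCorrectionFactor:
    def test_identity_and_arithmetic(self):
        assert apply_correction(7.0, 1.0) == 7.0
        assert apply_correction(10.0, 10.0) == pytest.approx(1.0)
        assert apply_correction(10.0, 10.0, invert=True) == pytest.approx(100.0)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            apply_correction(1.0, 0.0)
        with pytest.raises(ValueError):
            RuleConfig(selected=("BSEP",), k=-2.0)


# ---------------------------------------------------------------------------
# rule logic


class TestClassify:
    def test_quoted_rule_example(self):
        doses = {"A": 5.0, "B": 20.0}
        td = 10.0
        assert classify(td, doses, RuleConfig(selected=("A", "B"), rule="OR")) == 1
        assert classify(td, doses, RuleConfig(selected=("A", "B"), rule="AND")) == 0
        assert classify(td, doses, RuleConfig(selected=("A", "B"), rule="MAJORITY")) == 0

    def test_strict_inequality_tie_is_negative(self):
        config = RuleConfig(selected=("A",), rule="OR")
        assert classify(5.0, {"A": 5.0}, config) == 0

    def test_single_transporter_rules_coincide(self):
        for dose, td in [(1.0, 2.0), (2.0, 1.0)]:
            calls = {
                rule: classify(td, {"A": dose}, RuleConfig(selected=("A",), rule=rule))
                for rule in ("OR", "AND", "MAJORITY")
            }
            assert len(set(calls.values())) == 1

    def test_exhaustive_truth_tables_match_oracle(self):
        """All vote patterns for panels of 1..8 transporters match the
        brute-force rule oracle, and AND => MAJORITY => OR."""
        for n in range(1, 9):
            names = tuple(f"T{i}" for i in range(n))
            for pattern in itertools.product([False, True], repeat=n):
                # vote True <-> td strictly above that transporter's dose
                doses = {name: (0.5 if v else 2.0) for name, v in zip(names, pattern)}
                td = 1.0
                calls = {}
                for rule in ("OR", "AND", "MAJORITY"):
                    config = RuleConfig(selected=names, rule=rule)
                    calls[rule] = classify(td, doses, config)
                    assert calls[rule] == oracle_rule(pattern, rule)
                assert calls["AND"] <= calls["MAJORITY"] <= calls["OR"]

    def test_missing_transporter_dose_is_an_error(self):
        with pytest.raises(KeyError):
            classify(1.0, {"A": 0.5}, RuleConfig(selected=("A", "B"), rule="OR"))
        with pytest.raises(ValueError):
            RuleConfig(selected=(), rule="OR")


# ---------------------------------------------------------------------------
# full pipeline


class TestPredictCompound:
    def _record(self, dose_max, activity=None):
        return CompoundRecord(
            name="probe", chembl_id="X", smiles="CC(=O)Oc1ccccc1C(=O)O",
            fub=0.2, clint=10.0, dose_max=dose_max, activity=activity,
        )

    def test_engineered_unanimous_outcomes(self, oracle_panel):
        # tiny therapeutic dose -> no votes; huge -> all votes
        for dose_max, expected in [(1e-6, 0), (1e9, 1)]:
            for rule in ("OR", "AND", "MAJORITY"):
                config = RuleConfig(selected=qsar_panel.TRANSPORTERS, rule=rule)
                res = predict_compound(self._record(dose_max), oracle_panel, config)
                assert res.predicted == expected
                assert res.score == float(expected)

    def test_missing_exposure_estimate(self, oracle_panel):
        config = RuleConfig(selected=("BSEP",), rule="OR")
        with pytest.raises(ValueError, match="exposure"):
            predict_compound(self._record(None), oracle_panel, config)
        res = predict_compound(
            self._record(None), oracle_panel, config, expected_dose=500.0
        )
        assert res.td_per_kg == pytest.approx(500.0 / 70.0)

    def test_agreement_flag_tracks_activity(self, oracle_panel):
        config = RuleConfig(selected=("BSEP",), rule="OR")
        assert predict_compound(self._record(100.0), oracle_panel, config).agrees is None
        res = predict_compound(self._record(100.0, activity=1), oracle_panel, config)
        assert res.agrees is (res.predicted == 1)

    def test_batch_preserves_order(self, table60, oracle_panel):
        config = RuleConfig(selected=qsar_panel.TRANSPORTERS, rule="OR")
        results = predict_batch(table60.records[:8], oracle_panel, config)
        assert [r.compound.name for r in results] == [r.name for r in table60.records[:8]]

    def test_k_monotonicity_positive_set_grows(self, table60, oracle_panel):
        previous = set()
        for k in [0.5, 1.0, 2.0, 10.0]:
            config = RuleConfig(selected=qsar_panel.TRANSPORTERS, rule="OR", k=k)
            results = predict_batch(table60.records[:30], oracle_panel, config)
            positives = {r.compound.name for r in results if r.predicted == 1}
            assert previous <= positives
            previous = positives


# ---------------------------------------------------------------------------
# metrics


class TestMetrics:
    def test_perfect_classifier(self):
        y = [0, 1, 0, 1, 1]
        report = compute_metrics(y, y, scores=[0.1, 0.9, 0.2, 0.8, 0.7])
        assert report.accuracy == 1.0
        assert report.mcc == pytest.approx(1.0)
        assert report.auc == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_single_class_flags_auc_and_mcc_undefined(self):
        report = compute_metrics([1, 1, 1], [1, 0, 1], scores=[0.9, 0.1, 0.8])
        assert report.auc is None and report.mcc is None
        assert report.sensitivity == pytest.approx(2 / 3)
        assert report.specificity is None

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(11)
        n = 4000
        y = rng.integers(0, 2, size=n)
        scores = rng.random(n)
        report = compute_metrics(y, (scores > 0.5).astype(int), scores=scores)
        # binomial-order sampling error around 0.5
        assert abs(report.auc - 0.5) < 3.0 / np.sqrt(n)

    def test_metrics_equal_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, size=n)
            pred = rng.integers(0, 2, size=n)
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)  # force ties
            report = compute_metrics(y, pred, scores=scores)
            tp, fp, tn, fn = oracle_confusion(y, pred)
            assert (report.tp, report.fp, report.tn, report.fn) == (tp, fp, tn, fn)
            assert report.accuracy == pytest.approx((tp + tn) / n)
            if tp + fn and tn + fp:
                assert report.sensitivity == pytest.approx(tp / (tp + fn))
                assert report.specificity == pytest.approx(tn / (tn + fp))
                assert report.mcc == pytest.approx(oracle_mcc(tp, fp, tn, fn), abs=1e-12)
                assert report.auc == pytest.approx(oracle_auc(y, scores), abs=1e-12)

    def test_counts_identities_exhaustive_small_tables(self):
        grid = np.arange(0, 21)
        tp, fp, tn, fn = np.meshgrid(grid, grid, grid, grid, indexing="ij")
        out = decision.metrics_from_counts(tp, fp, tn, fn)
        n = tp + fp + tn + fn
        with np.errstate(divide="ignore", invalid="ignore"):
            np.testing.assert_allclose(
                out["accuracy"], np.where(n > 0, (tp + tn) / n, np.nan), equal_nan=True
            )
            denom = np.sqrt(
                (tp + fp).astype(float) * (tp + fn) * (tn + fp) * (tn + fn)
            )
            expected_mcc = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
        np.testing.assert_allclose(out["mcc"], expected_mcc, equal_nan=True)

    def test_counts_path_agrees_with_array_path(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            pred = rng.integers(0, 2, size=n)
            report = compute_metrics(y, pred)
            out = decision.metrics_from_counts(report.tp, report.fp, report.tn, report.fn)
            if report.mcc is not None:
                assert float(out["mcc"]) == pytest.approx(report.mcc, abs=1e-12)
            assert float(out["accuracy"]) == pytest.approx(report.accuracy)

    def test_evaluate_uses_only_labelled_results(self, table60, oracle_panel):
        config = RuleConfig(selected=qsar_panel.TRANSPORTERS, rule="OR")
        results = predict_batch(table60.records[:20], oracle_panel, config)
        report = evaluate(results)
        assert report.n == 20
        assert report.accuracy == 1.0  # oracle models reproduce planted labels
        with pytest.raises(ValueError):
            evaluate([])
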