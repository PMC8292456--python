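"""Inclusion/exclusion rules: boundaries, order, idempotence, recovery."""

import numpy as np
import pandas as pd
import pytest

from pdtraj import CohortConfig, FilterConfig, apply_filters, stratify
from pdtraj.filters import (
    filter_baseline_outliers,
    filter_cognitive_outliers,
    filter_hemoglobin,
    filter_min_visits,
)
from pdtraj.synthetic import (
    ABETA,
    ASYN,
    MOCA,
    TTAU,
    COL_GROUP,
    COL_HB,
    COL_MARKER,
    COL_SUBJECT,
    COL_TIME,
    COL_VALUE,
    TruthDynamics,
    generate_cohort,
    planted_violation_table,
)

from conftest import single_marker_config


def make_series(sid, marker, times, values, hb=np.nan, group="PD"):
    return pd.DataFrame({
        COL_SUBJECT: sid, COL_GROUP: group, COL_MARKER: marker,
        "visit_label": [f"V{i}" for i in range(len(times))],
        "age": 60.0 + np.asarray(times), COL_TIME: times, COL_VALUE: values,
        COL_HB: hb,
    })


class TestMinVisits:
    def test_visit_count_rule(self):
        df = pd.concat([
            make_series("A", ABETA, [0.0], [900.0]),
            make_series("B", ABETA, [0.0, 1.0], [900.0, 890.0]),
            make_series("C", ABETA, [0.0, 1.0, 2.0], [900.0, 890.0, 880.0]),
        ])
        out, log = filter_min_visits(df, 2)
        assert set(out[COL_SUBJECT]) == {"B", "C"}  # exactly 2 retained; >= is inclusive
        assert log == [{COL_SUBJECT: "A", COL_MARKER: ABETA,
                        "stage": "min_visits", "reason": "insufficient_visits"}]

    def test_empty_input_passes_through(self):
        out, log = filter_min_visits(pd.DataFrame(columns=[COL_SUBJECT, COL_MARKER]))
        assert out.empty and log == []


class TestHemoglobin:
    def test_strict_cutoff_and_marker_specificity(self):
        df = pd.concat([
            make_series("A", ASYN, [0.0, 1.0, 2.0], [1500.0] * 3,
                        hb=[199.9, 200.0, 100.0]),
            make_series("B", TTAU, [0.0, 1.0], [170.0, 171.0], hb=[500.0, 500.0]),
        ])
        out, log = filter_hemoglobin(df, 200.0)
        a = out[out[COL_SUBJECT] == "A"]
        assert list(a[COL_HB]) == [199.9, 100.0]  # 200.0 excluded (strict <)
        assert len(out[out[COL_SUBJECT] == "B"]) == 2  # rule is alpha-syn-specific
        assert log[0]["reason"] == "high_hemoglobin"

    def test_missing_hemoglobin_retained_with_warning(self, caplog):
        df = make_series("A", ASYN, [0.0, 1.0], [1500.0, 1490.0], hb=np.nan)
        with caplog.at_level("WARNING"):
            out, _ = filter_hemoglobin(df, 200.0)
        assert len(out) == 2
        assert "missing hemoglobin" in caplog.text

    def test_negative_hemoglobin_rejected(self):
        df = make_series("A", ASYN, [0.0, 1.0], [1500.0, 1490.0], hb=[-5.0, 80.0])
        with pytest.raises(ValueError, match="negative"):
            filter_hemoglobin(df, 200.0)

    def test_cascade_below_min_visits(self):
        df = make_series("A", ASYN, [0.0, 1.0], [1500.0, 1490.0], hb=[100.0, 300.0])
        out, log = filter_hemoglobin(df, 200.0, min_measurements=2)
        assert out.empty
        reasons = {e["reason"] for e in log}
        assert reasons == {"high_hemoglobin", "insufficient_visits_after_hemoglobin"}


class TestBaselineOutliers:
    def test_extreme_value_excluded(self):
        frames = [make_series(f"S{i:03d}", ABETA, [0.0, 1.0], [float(i), float(i)])
                  for i in range(1, 101)]
        frames.append(make_series("S999", ABETA, [0.0, 1.0], [10000.0, 9000.0]))
        df = pd.concat(frames)
        out, log = filter_baseline_outliers(df, 3.0)
        assert "S999" not in set(out[COL_SUBJECT])
        assert len(log) == 1 and log[0]["reason"] == "baseline_outlier"
        # fence check against the brute-force quartiles of the 101 baselines
        vals = np.r_[np.arange(1.0, 101.0), 10000.0]
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert 10000.0 > q3 + 3 * (q3 - q1)

    def test_identical_values_zero_iqr(self):
        frames = [make_series(f"S{i}", ABETA, [0.0, 1.0], [100.0, 100.0])
                  for i in range(6)]
        frames.append(make_series("DEV", ABETA, [0.0, 1.0], [100.5, 100.0]))
        out, log = filter_baseline_outliers(pd.concat(frames), 3.0)
        assert "DEV" not in set(out[COL_SUBJECT])  # any deviation from IQR=0 fence
        assert len(set(out[COL_SUBJECT])) == 6

    def test_value_exactly_on_fence_retained(self):
        # baselines 0,10,20,30,40 -> Q1=10, Q3=30, fence = 30 + 3*20 = 90
        vals = [0.0, 10.0, 20.0, 30.0, 90.0]
        frames = [make_series(f"S{i}", ABETA, [0.0, 1.0], [v, v])
                  for i, v in enumerate(vals)]
        out, log = filter_baseline_outliers(pd.concat(frames), 3.0)
        assert len(set(out[COL_SUBJECT])) == 5 and log == []  # "more than" is strict

    def test_fewer_than_four_values_skipped(self, caplog):
        frames = [make_series(f"S{i}", ABETA, [0.0, 1.0], [100.0 * (i + 1)] * 2)
                  for i in range(3)]
        with caplog.at_level("WARNING"):
            out, log = filter_baseline_outliers(pd.concat(frames), 3.0)
        assert len(set(out[COL_SUBJECT])) == 3 and log == []


class TestCognitiveOutliers:
    def test_planted_far_value_is_the_single_exclusion(self, rng):
        scores = rng.normal(28.0, 1.0, 200)
        scores = np.clip(scores, 24.0, 32.0)  # keep the bulk within 4 SD
        frames = [make_series(f"S{i:03d}", MOCA, [0.0, 1.0], [s, s])
                  for i, s in enumerate(scores)]
        frames.append(make_series("OUT", MOCA, [0.0, 1.0], [50.0, 50.0]))
        out, log = filter_cognitive_outliers(pd.concat(frames), 4.0)
        assert [e[COL_SUBJECT] for e in log] == ["OUT"]

    def test_exactly_four_sd_retained(self):
        # 100 baselines alternating 27/29 plus EDGE's 28: mean 28, SD (ddof=1)
        # exactly 1.0, so a follow-up of 32.0 sits exactly on mean + 4 SD.
        frames = [make_series(f"S{i:03d}", MOCA, [0.0, 1.0],
                              [27.0 + (i % 2) * 2.0] * 2) for i in range(100)]
        frames.append(make_series("EDGE", MOCA, [0.0, 1.0], [28.0, 32.0]))
        out, log = filter_cognitive_outliers(pd.concat(frames), 4.0)
        assert "EDGE" in set(out[COL_SUBJECT]) and log == []  # strict "beyond"

    def test_zero_sd_excludes_only_deviators(self):
        frames = [make_series(f"S{i}", MOCA, [0.0, 1.0], [27.0, 27.0])
                  for i in range(5)]
        dev = make_series("DEV", MOCA, [0.0, 1.0], [27.0, 27.5])
        out, log = filter_cognitive_outliers(pd.concat(frames + [dev]), 4.0)
        assert "DEV" not in set(out[COL_SUBJECT])
        assert len(set(out[COL_SUBJECT])) == 5


class TestStratify:
    def test_boundaries_and_controls(self):
        cov = pd.DataFrame({
            COL_SUBJECT: ["A", "B", "C", "D", "E"],
            COL_GROUP: ["PD", "PD", "PD", "PD", "control"],
            "moca_baseline": [26.0, 25.0, 27.0, np.nan, np.nan],
            "abeta_baseline": [700.0, 600.0, 683.45, 900.0, np.nan],
        })
        out = stratify(cov).set_index(COL_SUBJECT)
        assert out.loc["A", "cognition"] == "pdcu"   # MoCA 26 > 25
        assert out.loc["B", "cognition"] == "pdci"   # MoCA 25 is impaired
        assert out.loc["B", "abeta"] == "abeta_low"
        assert out.loc["C", "abeta"] == "abeta_high"  # cut-off value -> high
        assert out.loc["D", "cognition"] == "unclassifiable"
        assert out.loc["D", "abeta"] == "abeta_high"
        assert tuple(out.loc["E"]) == ("control", "control")


class TestFilterChain:
    def test_toy_fixture_recovers_exactly_the_planted_violations(self):
        table, expected = planted_violation_table()
        result = apply_filters(table, FilterConfig())
        got = set(result.report[[COL_SUBJECT, COL_MARKER, "reason"]]
                  .itertuples(index=False, name=None))
        assert got == expected

    def test_stage_counts_sum_to_input_minus_output(self):
        table, _ = planted_violation_table()
        result = apply_filters(table)
        s = result.summary
        assert (s["series_in"] - s["series_out"]
                == sum(s["series_excluded_by_stage"].values()))

    def test_chain_is_idempotent(self):
        table, _ = planted_violation_table()
        once = apply_filters(table)
        twice = apply_filters(once.data)
        pd.testing.assert_frame_equal(
            once.data.reset_index(drop=True), twice.data.reset_index(drop=True))
        assert twice.report.empty

    def test_zero_noise_cohort_recovers_hidden_truth_labels(self):
        cfg = CohortConfig(n_pd=80, n_control=30, seed=21,
                           noise_sd={m: 0.0 for m in CohortConfig().noise_sd},
                           high_hemoglobin_fraction=0.1, outlier_fraction=0.15,
                           cognitive_outlier_fraction=0.15, dropout_prob=0.0)
        visits, _, truth = generate_cohort(cfg)
        result = apply_filters(visits)
        planted = truth[truth["kind"] != "onset_level"]
        reason_of = {"high_hemoglobin": "high_hemoglobin",
                     "baseline_outlier": "baseline_outlier",
                     "cognitive_outlier": "cognitive_outlier"}
        expected = {(r.subject_id, r.marker, reason_of[r.kind])
                    for r in planted.itertuples()}
        got = set(result.report[[COL_SUBJECT, COL_MARKER, "reason"]]
                  .itertuples(index=False, name=None))
        assert got == expected
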