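"""Performance metrics, group summaries, Mann-Whitney, and Bland-Altman."""

import numpy as np
import pandas as pd
import pytest

from wardews import (
    Alarm,
    AlarmSource,
    ClavienDindo,
    ClinicalEvent,
    CohortAnalysis,
    CohortConfig,
    EwsSource,
    Group,
    NurseObservation,
    Parameter,
    ValidationError,
    alarm_performance,
    bland_altman_repeated,
    classify_alarms,
    ews_summary,
    generate_cohort,
    mann_whitney,
    out_of_range_summary,
    pair_nurse_sensor,
    points_distribution,
    regroup_sensitivity_analysis,
    threshold_sweep,
    window_sweep,
)
from wardews.events import assign_groups, select_eligible_events

from conftest import make_patient


def toy_population(n_events, n_with_early_alarm):
    """n single-event patients; the first k get one pre-onset alarm."""
    patients, events, alarms = [], [], []
    for i in range(n_events):
        pid = f"P{i:02d}"
        p = make_patient(
            {Parameter.HR: [75] * 96, Parameter.RR: [14] * 96},
            end_min=96 * 60,
            pid=pid,
        )
        patients.append(p)
        events.append(ClinicalEvent(pid, 4000, 4800, ClavienDindo.II))
        if i < n_with_early_alarm:
            alarms.append(Alarm(pid, 3500, AlarmSource.SENSOR_EWS, threshold=3))
    events = select_eligible_events(events, patients)
    assign_groups(patients, events)
    labelled = classify_alarms(alarms, events, patients)
    return patients, [e for e in events if e.included], labelled


class TestAlarmPerformance:
    @pytest.mark.parametrize(
        ("hits", "pct"), [(12, 80), (13, 87), (15, 100), (0, 0)]
    )
    def test_early_sensitivity_printed_percent(self, hits, pct):
        patients, included, alarms = toy_population(15, hits)
        perf = alarm_performance(alarms, included, patients)
        assert perf.sensitivity_early_pct == pct
        assert perf.n_events == 15

    def test_no_alarms(self):
        patients, included, _ = toy_population(15, 0)
        perf = alarm_performance([], included, patients)
        assert perf.tar == 0.0
        assert perf.fdr is None
        assert perf.sensitivity_early == 0.0
        assert perf.sensitivity_total == 0.0

    def test_zero_events_sensitivities_undefined(self):
        p = make_patient({Parameter.HR: [75] * 24}, end_min=24 * 60, pid="C0")
        p.group = Group.CONTROL
        a = Alarm("C0", 100, AlarmSource.SENSOR_EWS, threshold=3)
        (a,) = classify_alarms([a], [], [p])
        perf = alarm_performance([a], [], [p])
        assert perf.sensitivity_early is None
        assert perf.fdr == 100.0

    def test_counts_and_ratios_consistent(self):
        patients, included, alarms = toy_population(15, 12)
        extra = [Alarm("P00", 200, AlarmSource.SENSOR_EWS, threshold=3),
                 Alarm("P00", 4100, AlarmSource.SENSOR_EWS, threshold=3)]
        alarms = alarms + classify_alarms(extra, included, patients)
        perf = alarm_performance(alarms, included, patients)
        assert perf.n_alarms == perf.n_early_tp + perf.n_late_tp + perf.n_fp
        assert perf.fdr == pytest.approx(100.0 * perf.n_fp / perf.n_alarms)
        assert perf.tar == pytest.approx(perf.n_alarms / perf.patient_days)
        assert 0 <= perf.sensitivity_early <= perf.sensitivity_total <= 100

    def test_tar_variants(self):
        patients, included, alarms = toy_population(2, 2)
        pooled = alarm_performance(alarms, included, patients, "pooled")
        per_patient = alarm_performance(alarms, included, patients, "per_patient")
        # equal recording lengths -> the two variants coincide
        assert pooled.tar == pytest.approx(per_patient.tar)

    def test_excluded_patient_rejected(self):
        p = make_patient({Parameter.HR: [75] * 24}, end_min=24 * 60)
        p.group = Group.EXCLUDED
        with pytest.raises(ValidationError):
            alarm_performance([], [], [p])


class TestSweeps:
    def test_threshold_sweep_shape(self, small_analysis):
        res = threshold_sweep(small_analysis, 60, range(1, 10))
        assert sorted(res) == list(range(1, 10))
        for perf in res.values():
            assert perf.n_alarms == perf.n_early_tp + perf.n_late_tp + perf.n_fp

    def test_window_sweep_shape(self, small_analysis):
        res = window_sweep(small_analysis, 5, (30, 60, 120, 240))
        assert sorted(res) == [30, 60, 120, 240]

    def test_all_control_cohort_fdr_100(self):
        cfg = CohortConfig(seed=11, n_event_patients=0, n_control_patients=4,
                           recording_hours_range=(72, 96))
        analysis = CohortAnalysis.from_cohort(generate_cohort(cfg))
        res = threshold_sweep(analysis, 60, (1, 2, 3))
        assert any(p.n_alarms > 0 for p in res.values())
        for perf in res.values():
            if perf.n_alarms:
                assert perf.fdr == 100.0


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney([1.0, 2.0, 3.0] * 4, [1.0, 2.0, 3.0] * 4)
        assert p >= 0.99

    def test_symmetry(self):
        a = [1.5, 2.5, 7.0, 3.2]
        b = [2.0, 4.0, 5.5]
        ua, pa = mann_whitney(a, b)
        ub, pb = mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))
        assert pa == pytest.approx(pb)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestEwsSummary:
    def test_per_patient_arithmetic(self, table):
        # four hours engineered to score [0, 0, 3, 5]
        p = make_patient(
            {
                Parameter.HR: [70, 70, 70, 70],
                Parameter.RR: [12, 12, 12, 22],
                Parameter.SPO2: [97, 97, 90, 90],
                Parameter.AT: [37.0, 37.0, 37.0, 37.0],
            },
            end_min=240,
            pid="PE",
        )
        ctrl = make_patient(
            {
                Parameter.HR: [70] * 4,
                Parameter.RR: [12] * 4,
                Parameter.SPO2: [97] * 4,
                Parameter.AT: [37.0] * 4,
            },
            end_min=240,
            pid="PC",
        )
        events = select_eligible_events(
            [ClinicalEvent("PE", 230, 240, ClavienDindo.II)], [p, ctrl],
        )
        # relax the availability rule via a short pre-onset window
        from wardews.events import EligibilityRules

        analysis = CohortAnalysis(
            [p, ctrl], events,
            rules=EligibilityRules(min_availability_min=60,
                                   pre_onset_window_min=120),
        )
        per_patient, _ = ews_summary(analysis, 60)
        row = per_patient.set_index("patient_id").loc["PE"]
        assert row["mean_ews"] == pytest.approx(2.0)
        assert row["pct_ge3"] == pytest.approx(50.0)
        assert row["pct_ge5"] == pytest.approx(25.0)
        assert row["availability"] == pytest.approx(100.0)
        ctrl_row = per_patient.set_index("patient_id").loc["PC"]
        assert ctrl_row["mean_ews"] == 0.0
        assert ctrl_row["pct_ge3"] == 0.0

    def test_event_group_scores_higher_on_synthetic_cohort(self, small_analysis):
        _, summary = ews_summary(small_analysis, 60)
        row = summary.set_index("metric").loc["mean_ews"]
        assert row["event_median"] > row["control_median"]


class TestRegrouping:
    def test_noop_without_excluded(self, small_analysis):
        primary_pp, primary_sum = ews_summary(small_analysis, 60)
        re_pp, re_sum = regroup_sensitivity_analysis(small_analysis, 60)
        pd.testing.assert_frame_equal(
            primary_pp, re_pp.reindex(columns=primary_pp.columns)
        )
        assert re_sum["regrouped"].all()
        np.testing.assert_allclose(
            primary_sum["p_value"], re_sum["p_value"], rtol=1e-12
        )

    def test_excluded_merged_into_control(self):
        cohort = generate_cohort(
            CohortConfig(seed=21, n_event_patients=2, n_control_patients=3,
                         recording_hours_range=(72, 96))
        )
        # demote one event to class I -> its patient becomes EXCLUDED
        cohort.events[0].clavien_dindo = ClavienDindo.I
        analysis = CohortAnalysis.from_cohort(cohort)
        n_excluded = sum(p.group is Group.EXCLUDED for p in analysis.patients)
        assert n_excluded == 1
        pp, _ = ews_summary(analysis, 60)
        re_pp, _ = regroup_sensitivity_analysis(analysis, 60)
        n_ctrl = (pp["group"] == "CONTROL").sum()
        n_ctrl_re = (re_pp["group"] == "CONTROL").sum()
        assert n_ctrl_re == n_ctrl + n_excluded


class TestPointsDistribution:
    def test_fractions(self, table):
        # RR at 22 brpm (2 points) in half the windows, else 12 (0 points)
        p = make_patient(
            {
                Parameter.HR: [70] * 10,
                Parameter.RR: [22] * 5 + [12] * 5,
                Parameter.SPO2: [97] * 10,
                Parameter.AT: [37.0] * 10,
            },
            end_min=600,
            pid="PC",
        )
        analysis = CohortAnalysis([p], [])
        df = points_distribution(analysis, 60)
        df = df.set_index(["parameter", "points"])
        assert df.loc[("RR", 2), "fraction"] == pytest.approx(0.5)
        assert df.loc[("RR", 0), "fraction"] == pytest.approx(0.5)
        assert df.loc[("HR", 0), "fraction"] == pytest.approx(1.0)
        sums = df.groupby("parameter")["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_sums_to_one_on_synthetic_cohort(self, small_analysis):
        df = points_distribution(small_analysis, 60)
        sums = df.groupby(["group", "parameter"])["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0)


class TestOutOfRange:
    def test_hand_counts(self):
        # 3 of 10 windows with HR 135 alone; all others normal
        p1 = make_patient(
            {
                Parameter.HR: [135] * 3 + [80] * 7,
                Parameter.SPO2: [97] * 10,
            },
            end_min=600,
            pid="A",
        )
        # 2 of 10 windows with HR 135 and SpO2 90 together
        p2 = make_patient(
            {
                Parameter.HR: [135] * 2 + [80] * 8,
                Parameter.SPO2: [90] * 2 + [97] * 8,
            },
            end_min=600,
            pid="B",
        )
        analysis = CohortAnalysis([p1, p2], [])
        per_patient, _ = out_of_range_summary(analysis)
        per_patient = per_patient.set_index("patient_id")
        assert per_patient.loc["A", "pct_one_param_out"] == pytest.approx(30.0)
        assert per_patient.loc["A", "pct_multi_param_out"] == pytest.approx(0.0)
        assert per_patient.loc["B", "pct_one_param_out"] == pytest.approx(0.0)
        assert per_patient.loc["B", "pct_multi_param_out"] == pytest.approx(20.0)

    def test_all_normal(self):
        p = make_patient(
            {Parameter.HR: [80] * 5, Parameter.SPO2: [97] * 5},
            end_min=300,
        )
        per_patient, _ = out_of_range_summary(CohortAnalysis([p], []))
        assert per_patient["pct_one_param_out"].iloc[0] == 0.0
        assert per_patient["pct_multi_param_out"].iloc[0] == 0.0


class TestPairNurseSensor:
    def test_five_minute_window_mean(self):
        times = np.array([295, 296, 298])
        p = make_patient(
            {Parameter.HR: (times, np.array([82.0, 84.0, 86.0]))},
            end_min=400,
            nurse=[NurseObservation("P1", 300, hr=80.0)],
        )
        pairs = pair_nurse_sensor(p)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["parameter"] == "HR"
        assert row["nurse"] == 80.0
        assert row["sensor"] == pytest.approx(84.0)
        assert row["diff"] == pytest.approx(4.0)

    def test_no_sensor_data_drops_pair(self):
        times = np.array([100, 101])
        p = make_patient(
            {Parameter.HR: (times, np.array([82.0, 84.0]))},
            end_min=400,
            nurse=[NurseObservation("P1", 300, hr=80.0)],
        )
        assert pair_nurse_sensor(p).empty

    def test_sample_at_observation_time_excluded(self):
        # window is [t-5, t): a sample at exactly t is outside it
        times = np.array([300])
        p = make_patient(
            {Parameter.HR: (times, np.array([82.0]))},
            end_min=400,
            nurse=[NurseObservation("P1", 300, hr=80.0)],
        )
        assert pair_nurse_sensor(p).empty

    def test_sbp_never_paired_and_tt_maps_to_at(self):
        times = np.arange(295, 300)
        p = make_patient(
            {Parameter.AT: (times, np.full(5, 37.1))},
            end_min=400,
            nurse=[NurseObservation("P1", 300, sbp=120.0, tt=36.9)],
        )
        pairs = pair_nurse_sensor(p)
        assert list(pairs["parameter"]) == ["AT"]
        assert pairs.iloc[0]["diff"] == pytest.approx(37.1 - 36.9)

    def test_implausible_sensor_values_excluded_from_pairing(self):
        times = np.arange(295, 300)
        values = np.array([82.0, 250.0, 84.0, 250.0, 86.0])
        p = make_patient(
            {Parameter.HR: (times, values)},
            end_min=400,
            nurse=[NurseObservation("P1", 300, hr=80.0)],
        )
        pairs = pair_nurse_sensor(p)
        assert pairs.iloc[0]["sensor"] == pytest.approx(84.0)


class TestBlandAltman:
    def test_identical_differences(self):
        pairs = [("A", 2.0), ("A", 2.0), ("B", 2.0), ("B", 2.0)]
        res = bland_altman_repeated(pairs)
        assert res.bias == 2.0
        assert res.loa_low == res.loa_high == 2.0

    def test_one_pair_per_patient_reduces_to_classic(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(3.0, 2.0, size=40)
        pairs = [(f"P{i}", float(d)) for i, d in enumerate(diffs)]
        res = bland_altman_repeated(pairs)
        classic_sd = diffs.std(ddof=1)
        assert res.bias == pytest.approx(diffs.mean())
        width = res.loa_high - res.loa_low
        assert width == pytest.approx(2 * 1.96 * classic_sd, rel=1e-9)

    def test_single_patient_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman_repeated([("A", 1.0), ("A", 2.0)])

    def test_simple_variant_pools(self):
        pairs = [("A", 1.0), ("A", 2.0)]
        res = bland_altman_repeated(pairs, simple=True)
        assert res.bias == pytest.approx(1.5)
        assert res.loa_high - res.loa_low == pytest.approx(
            2 * 1.96 * np.std([1.0, 2.0], ddof=1)
        )

    def test_loa_bracket_bias(self):
        rng = np.random.default_rng(17)
        pairs = [
            (f"P{i}", float(rng.normal(1.0, 0.5) + rng.normal(0, 1.5)))
            for i in range(30)
            for _ in range(5)
        ]
        res = bland_altman_repeated(pairs)
        assert res.loa_low <= res.bias <= res.loa_high
        assert res.n_pairs == 150
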