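import numpy as np
import pytest

import movemetrics as mm
from movemetrics.data_model import MPI_NAMES, Trial, ValidationError, WindowConfig
from movemetrics.features import WindowSeries
from movemetrics.mpi import (
    aggregate_trial,
    build_cohort_table,
    compute_mpi_vector,
    default_emg_channel,
    emg_channel_group_differences,
    emg_channel_index,
    reference_axis_map,
    select_axis_of_interest,
)
from movemetrics.synthetic import DOMINANT_AXES, GeneratorConfig, generate_cohort


def _series(values):
    v = np.asarray(values, float)
    return WindowSeries(measurement="emg-mav", values=v,
                        window_times=np.arange(len(v), dtype=float))


class TestChannelConvention:
    def test_right_hand_channel_two(self):
        assert default_emg_channel("R") == 2
        assert emg_channel_index("R") == 1

    def test_left_hand_channel_six(self):
        assert default_emg_channel("L") == 6
        assert emg_channel_index("L") == 5

    def test_invalid_hand_rejected(self):
        with pytest.raises(ValidationError):
            default_emg_channel("B")


class TestAggregateTrial:
    def test_mean_default(self):
        assert aggregate_trial(_series([1, 2, 3])) == 2.0

    def test_constant_series(self):
        assert aggregate_trial(_series([4.2] * 7)) == pytest.approx(4.2)

    def test_mean_equals_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            v = rng.uniform(0, 10, size=rng.integers(2, 60))
            assert aggregate_trial(_series(v)) == pytest.approx(
                sum(v) / len(v), rel=1e-12)

    def test_alternative_reductions(self):
        assert aggregate_trial(_series([1, 2, 9]), "median") == 2.0
        assert aggregate_trial(_series([1, 2, 9]), "sum") == 12.0


class TestMpiVectorAssembly:
    def test_length_is_84(self, one_session):
        vec = compute_mpi_vector(one_session)
        assert len(vec) == 84

    def test_deterministic(self, one_session):
        v1 = compute_mpi_vector(one_session).to_series()
        v2 = compute_mpi_vector(one_session).to_series()
        assert (v1 == v2).all()

    def test_missing_trial_error_names_pair(self, one_session):
        partial = mm.SubjectSession(
            subject_id="x", group=one_session.group,
            affected_side=one_session.affected_side,
            hy_stage=one_session.hy_stage, updrs3_total=0, updrs3_brady_sub=0,
            taps_proximal=0, taps_distal=0,
            trials=[t for t in one_session.trials
                    if not (t.movement == "TT-D" and t.hand == "L")])
        with pytest.raises(ValidationError, match="TT-D"):
            compute_mpi_vector(partial)

    def test_emg_scaling_homogeneity(self, one_session):
        doubled = mm.SubjectSession(
            subject_id="x2", group=one_session.group,
            affected_side=one_session.affected_side,
            hy_stage=one_session.hy_stage, updrs3_total=0, updrs3_brady_sub=0,
            taps_proximal=0, taps_distal=0,
            trials=[Trial(movement=t.movement, hand=t.hand, emg=2.0 * t.emg,
                          acc=t.acc, gyro=t.gyro) for t in one_session.trials])
        base = compute_mpi_vector(one_session).to_series()
        scaled = compute_mpi_vector(doubled).to_series()
        for name in MPI_NAMES:
            if name.startswith("emg-mav") or name.startswith("emg-wc"):
                assert scaled[name] == pytest.approx(2 * base[name], rel=1e-6)
            elif name.startswith("emg-var"):
                assert scaled[name] == pytest.approx(4 * base[name], rel=1e-6)
            else:  # IMU untouched
                assert scaled[name] == pytest.approx(base[name], rel=1e-9)


class TestCohortTable:
    def test_table_shape_and_labels(self, small_cohort, small_cohort_table):
        table = small_cohort_table
        assert len(table) == len(small_cohort)
        assert sum(c in MPI_NAMES for c in table.columns) == 84
        assert set(table["group"]) == {"patient", "control"}
        assert not table[[c for c in table.columns if c in MPI_NAMES]].isna().any().any()

    def test_patients_below_controls_on_channel_of_interest(self):
        # directional planting recovered on emg-mav group means
        cfg = GeneratorConfig(n_controls=8, n_patients_per_stage=(3, 3, 2), seed=21)
        sessions = generate_cohort(cfg, movements=("GPP-HL",))
        table = build_cohort_table(sessions, movements=("GPP-HL",))
        pat = table[table.group == "patient"]
        ctl = table[table.group == "control"]
        for hand in ("R", "L"):
            assert pat[f"emg-mav_GPP-HL_{hand}"].mean() < \
                ctl[f"emg-mav_GPP-HL_{hand}"].mean()


class TestAxisSelection:
    @pytest.fixture(scope="class")
    def reference_sessions(self):
        cfg = GeneratorConfig(n_controls=8, n_patients_per_stage=(3, 3, 2), seed=17)
        return generate_cohort(cfg, movements=("RH-EE",))

    def test_recovers_planted_dominant_axes(self, reference_sessions):
        axis_acc, ev = select_axis_of_interest(reference_sessions, "RH-EE",
                                               "acc", "acc-ran")
        axis_gyro, _ = select_axis_of_interest(reference_sessions, "RH-EE",
                                               "gyro", "gyro-ran")
        assert axis_acc == DOMINANT_AXES["RH-EE"]["acc"]
        assert axis_gyro == DOMINANT_AXES["RH-EE"]["gyro"]
        assert ev["p_value"] < 0.05

    def test_override_short_circuits(self, reference_sessions):
        axis, ev = select_axis_of_interest(reference_sessions, "RH-EE", "acc",
                                           "acc-ran", override=2)
        assert axis == 2
        assert ev["override"]

    def test_single_group_rejected(self, reference_sessions):
        controls = [s for s in reference_sessions if s.group == "control"]
        with pytest.raises(ValidationError):
            select_axis_of_interest(controls, "RH-EE", "acc", "acc-ran")

    def test_tie_breaks_to_lowest_axis_and_flags(self, reference_sessions, monkeypatch):
        import movemetrics.mpi as mpi_mod

        monkeypatch.setattr(mpi_mod, "_aggregated_trial_value",
                            lambda session, movement, hand, measurement, axis,
                            config: 1.0 if session.group == "control" else 0.5)
        axis, ev = select_axis_of_interest(reference_sessions, "RH-EE", "acc",
                                           "acc-ran")
        assert axis == 0
        assert ev["tie"]

    def test_reference_map_covers_protocol(self):
        amap = reference_axis_map()
        assert len(amap) == 12
        assert amap[("RH-EE", "acc")] == 1
        assert amap[("RH-EE", "gyro")] == 0


class TestChannelAnalysis:
    def test_channel_of_interest_has_largest_difference(self):
        cfg = GeneratorConfig(n_controls=6, n_patients_per_stage=(2, 2, 2), seed=23)
        sessions = generate_cohort(cfg, movements=("RH-EE",))
        table = emg_channel_group_differences(sessions, "RH-EE", "R")
        assert table["abs_difference"].idxmax() == 2  # channel label 2
        table_l = emg_channel_group_differences(sessions, "RH-EE", "L")
        assert table_l["abs_difference"].idxmax() == 6
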