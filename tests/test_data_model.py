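import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from movemetrics.data_model import (
    FormatError,
    HANDS,
    MEASUREMENTS,
    MOVEMENTS,
    MPI_NAMES,
    MPIVector,
    SubjectSession,
    Trial,
    ValidationError,
    WindowConfig,
    mpi_name,
    parse_mpi_name,
    read_cohort_table,
    read_session,
    read_trial,
    validate_cohort_table,
    write_cohort_table,
    write_session,
    write_trial,
)


def _trial(movement="RH-EE", hand="R", n_emg=2000, n_imu=500, rng=None):
    rng = rng or np.random.default_rng(0)
    return Trial(movement=movement, hand=hand,
                 emg=rng.normal(size=(8, n_emg)),
                 acc=rng.normal(size=(3, n_imu)),
                 gyro=rng.normal(size=(3, n_imu)))


class TestMpiNaming:
    def test_key_set_is_full_cross_product(self):
        assert len(MPI_NAMES) == 84
        assert len(set(MPI_NAMES)) == 84
        expected = {f"{m}_{mov}_{h}" for m in MEASUREMENTS
                    for mov in MOVEMENTS for h in HANDS}
        assert set(MPI_NAMES) == expected

    def test_order_is_measurement_major(self):
        # first block: emg-mav over all movements, right hand first
        assert MPI_NAMES[0] == "emg-mav_RH-EE_R"
        assert MPI_NAMES[1] == "emg-mav_RH-EE_L"
        assert MPI_NAMES[12] == "emg-var_RH-EE_R"

    def test_parse_roundtrip(self):
        for name in MPI_NAMES:
            assert mpi_name(*parse_mpi_name(name)) == name

    @pytest.mark.parametrize("bad", ["emg-mav_RH-EE", "foo_RH-EE_R",
                                     "emg-mav_XX_R", "emg-mav_RH-EE_X"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(ValidationError):
            parse_mpi_name(bad)


class TestTrialValidation:
    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValidationError):
            Trial(movement="RH-EE", hand="R",
                  emg=np.zeros((7, 2000)), acc=np.zeros((3, 500)),
                  gyro=np.zeros((3, 500)))

    def test_unknown_movement_rejected(self):
        with pytest.raises(ValidationError):
            _trial(movement="JUMP")

    def test_too_short_for_one_window_rejected(self):
        with pytest.raises(ValidationError):
            _trial(n_emg=30)  # < 40 samples = one 200 ms window at 200 Hz

    def test_nonfinite_rejected(self):
        emg = np.zeros((8, 2000))
        emg[3, 10] = np.nan
        with pytest.raises(ValidationError):
            Trial(movement="RH-EE", hand="R", emg=emg,
                  acc=np.zeros((3, 500)), gyro=np.zeros((3, 500)))


class TestTrialIO:
    def test_wellformed_roundtrip_shape(self, tmp_path):
        trial = _trial(n_emg=2000)
        write_trial(trial, tmp_path, "t")
        back = read_trial(tmp_path, "t", "RH-EE", "R")
        assert back.n_emg == 2000

    @given(st.integers(0, 2 ** 31 - 1))
    def test_roundtrip_exact(self, tmp_path_factory, seed):
        tmp = tmp_path_factory.mktemp("trial")
        rng = np.random.default_rng(seed)
        trial = _trial(n_emg=60, n_imu=45, rng=rng)
        write_trial(trial, tmp, f"s{seed}")
        back = read_trial(tmp, f"s{seed}", trial.movement, trial.hand)
        np.testing.assert_array_equal(back.emg, trial.emg)
        np.testing.assert_array_equal(back.acc, trial.acc)
        np.testing.assert_array_equal(back.gyro, trial.gyro)
        assert back.sample_rate_emg == trial.sample_rate_emg

    def test_seven_column_file_is_format_error(self, tmp_path):
        trial = _trial()
        paths = write_trial(trial, tmp_path, "t")
        lines = paths["emg"].read_text().splitlines()
        broken = [lines[0], lines[1], ",".join(lines[2].split(",")[:7])]
        broken += [",".join(l.split(",")[:7]) for l in lines[3:]]
        paths["emg"].write_text("\n".join(broken) + "\n")
        with pytest.raises(FormatError):
            read_trial(tmp_path, "t", "RH-EE", "R")

    def test_missing_stream_is_format_error(self, tmp_path):
        trial = _trial()
        paths = write_trial(trial, tmp_path, "t")
        paths["acc"].unlink()
        with pytest.raises(FormatError):
            read_trial(tmp_path, "t", "RH-EE", "R")


class TestSessionIO:
    def test_roundtrip(self, tmp_path, one_session):
        write_session(one_session, tmp_path / "s")
        back = read_session(tmp_path / "s")
        assert back.subject_id == one_session.subject_id
        assert back.group == one_session.group
        assert len(back.trials) == len(one_session.trials)
        t0, b0 = one_session.trials[0], back.trials[0]
        np.testing.assert_array_equal(b0.emg, t0.emg)

    def test_control_with_stage_rejected(self):
        with pytest.raises(ValidationError):
            SubjectSession(subject_id="x", group="control", affected_side="R",
                           hy_stage=None, updrs3_total=0, updrs3_brady_sub=0,
                           taps_proximal=0, taps_distal=0)

    def test_duplicate_trial_rejected(self):
        t = _trial()
        with pytest.raises(ValidationError):
            SubjectSession(subject_id="x", group="control", affected_side=None,
                           hy_stage=None, updrs3_total=0, updrs3_brady_sub=0,
                           taps_proximal=0, taps_distal=0, trials=[t, t])


class TestCohortTable:
    def _table(self, n=33, rng=None):
        rng = rng or np.random.default_rng(1)
        data = {name: rng.uniform(0, 5, size=n) for name in MPI_NAMES}
        data["group"] = ["patient" if i % 2 else "control" for i in range(n)]
        data["hy_stage"] = pd.array(
            [1 + i % 3 if i % 2 else None for i in range(n)], dtype="Int64")
        data["affected_side"] = ["R" if i % 2 else None for i in range(n)]
        data["updrs3_total"] = rng.integers(0, 60, size=n)
        data["updrs3_brady_sub"] = rng.integers(0, 15, size=n)
        data["taps_proximal"] = rng.integers(5, 40, size=n)
        data["taps_distal"] = rng.integers(5, 50, size=n)
        return pd.DataFrame(data, index=pd.Index(
            [f"S{i:02d}" for i in range(n)], name="subject_id"))

    def test_write_has_one_row_per_subject(self, tmp_path):
        table = self._table(33)
        path = tmp_path / "cohort.csv"
        write_cohort_table(table, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 34  # header + 33 subjects

    def test_roundtrip_equality(self, tmp_path):
        table = self._table(12)
        path = tmp_path / "cohort.csv"
        write_cohort_table(table, path)
        back = read_cohort_table(path)
        pd.testing.assert_frame_equal(
            back[list(MPI_NAMES)], table[list(MPI_NAMES)], check_exact=True)
        assert list(back["group"]) == list(table["group"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            validate_cohort_table(self._table(5).iloc[:0])

    def test_missing_mpi_cell_rejected(self, tmp_path):
        table = self._table(5)
        table.loc["S01", "emg-mav_RH-EE_R"] = np.nan
        with pytest.raises(ValidationError):
            write_cohort_table(table, tmp_path / "x.csv")


class TestMPIVector:
    def test_exact_keys_required(self):
        values = {name: 1.0 for name in MPI_NAMES}
        assert len(MPIVector(values)) == 84
        del values[MPI_NAMES[0]]
        with pytest.raises(ValidationError):
            MPIVector(values)

    def test_negative_rejected(self):
        values = {name: 1.0 for name in MPI_NAMES}
        values[MPI_NAMES[3]] = -0.1
        with pytest.raises(ValidationError):
            MPIVector(values)


class TestWindowConfig:
    def test_defaults_give_40_sample_windows(self):
        cfg = WindowConfig()
        assert cfg.window_samples("emg", 200.0) == 40
        assert cfg.step_samples("emg", 200.0) == 30
        assert cfg.window_samples("imu", 50.0) == 40
        assert cfg.step_samples("imu", 50.0) == 30

    def test_bad_overlap_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(overlap_fraction=1.0)

    def test_file_roundtrip(self, tmp_path):
        cfg = WindowConfig(emg_cutoff_hz=15.0, overlap_fraction=0.5)
        cfg.to_file(tmp_path / "cfg.txt")
        back = WindowConfig.from_file(tmp_path / "cfg.txt")
        assert back.emg_cutoff_hz == 15.0
        assert back.overlap_fraction == 0.5
        assert back.emg_filter_order == 4
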