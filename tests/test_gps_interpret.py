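import numpy as np
import pytest

from gaitval.datamodel_io import (
    GPS_OUTCOMES,
    AnalysisConfig,
    CohortTable,
    CoverageError,
    PairingError,
    ValidationError,
)
from gaitval.gps_interpret import (
    NormativeBank,
    build_normative_bank,
    compare_gps_systems,
    find_outliers,
    gait_variable_score,
    gps_for_side,
    gps_table,
    mdc_flag,
)
from gaitval.synthetic_gait import make_template_bank, simulate_cohort
from tests.conftest import make_cycle, make_key


def _bank(offset=0.0, system="OPTO"):
    templates = make_template_bank(0).templates
    return NormativeBank(
        system=system, curves={o: templates[o] + offset for o in GPS_OUTCOMES}
    )


def _side_cycles(offsets=None, system="OPTO"):
    templates = make_template_bank(0).templates
    offsets = offsets or {}
    return [
        make_cycle(o, "left", 0, system, templates[o] + offsets.get(o, 0.0))
        for o in GPS_OUTCOMES
    ]


class TestNormativeBank:
    def test_single_subject_bank(self):
        table = CohortTable()
        key = make_key(group="AS")
        templates = make_template_bank(0).templates
        for o in GPS_OUTCOMES:
            table.add(key, make_cycle(o, "left", 0, "OPTO", templates[o]))
        bank = build_normative_bank(table, "OPTO")
        for o in GPS_OUTCOMES:
            np.testing.assert_array_equal(bank.curves[o], templates[o])

    def test_opposite_curves_cancel(self):
        table = CohortTable()
        rng = np.random.default_rng(0)
        curves = {o: rng.normal(0, 5, 101) for o in GPS_OUTCOMES}
        for sid, sign in (("A1", 1.0), ("A2", -1.0)):
            key = make_key(subject_id=sid, group="AS")
            for o in GPS_OUTCOMES:
                table.add(key, make_cycle(o, "left", 0, "OPTO", sign * curves[o]))
        bank = build_normative_bank(table, "OPTO")
        for o in GPS_OUTCOMES:
            np.testing.assert_allclose(bank.curves[o], 0.0, atol=1e-12)

    def test_reproducible_from_seeded_cohort(self):
        t1 = simulate_cohort(15, 1, 1, cycles_per_subject=1, seed=5, design="validity")
        t2 = simulate_cohort(15, 1, 1, cycles_per_subject=1, seed=5, design="validity")
        b1 = build_normative_bank(t1, "OPTO")
        b2 = build_normative_bank(t2, "OPTO")
        for o in GPS_OUTCOMES:
            np.testing.assert_array_equal(b1.curves[o], b2.curves[o])

    def test_missing_outcome_coverage_error(self):
        table = CohortTable()
        key = make_key(group="AS")
        table.add(key, make_cycle("hip_flexion", "left", 0, "OPTO"))
        with pytest.raises(CoverageError, match="ankle_flexion"):
            build_normative_bank(table, "OPTO")


class TestGaitVariableScore:
    def test_identity(self):
        c = make_cycle(samples=np.arange(101.0))
        assert gait_variable_score(c, np.arange(101.0)) == 0.0

    def test_constant_offset(self):
        c = make_cycle(samples=np.arange(101.0) + 3.0)
        assert gait_variable_score(c, np.arange(101.0)) == pytest.approx(3.0)

    def test_half_cycle_deviation(self):
        ref = np.zeros(101)
        dev = np.zeros(101)
        dev[:51] = 4.0
        c = make_cycle(samples=dev)
        assert gait_variable_score(c, ref) == pytest.approx(
            np.sqrt(51 * 16.0 / 101.0), abs=1e-12
        )

    def test_outcome_mismatch(self):
        c = make_cycle(outcome="hip_flexion")
        with pytest.raises(PairingError):
            gait_variable_score(c, np.zeros(101), reference_outcome="knee_flexion")


class TestGpsForSide:
    def test_identity_with_bank(self):
        res = gps_for_side(_side_cycles(), _bank())
        assert res.gps == pytest.approx(0.0, abs=1e-12)

    def test_uniform_offset(self):
        res = gps_for_side(_side_cycles({o: 2.5 for o in GPS_OUTCOMES}), _bank())
        assert res.gps == pytest.approx(2.5, abs=1e-9)

    def test_single_curve_offset(self):
        res = gps_for_side(_side_cycles({"hip_flexion": 3.0}), _bank())
        assert res.gps == pytest.approx(1.0, abs=1e-9)
        assert res.gvs["hip_flexion"] == pytest.approx(3.0, abs=1e-9)

    def test_missing_outcome(self):
        cycles = _side_cycles()[:-1]
        with pytest.raises(CoverageError):
            gps_for_side(cycles, _bank())

    def test_flat_enumeration_oracle(self):
        # staged GVS -> GPS equals RMS over all 9 x 101 deviations
        rng = np.random.default_rng(1)
        offsets = {o: rng.normal(0, 3) for o in GPS_OUTCOMES}
        templates = make_template_bank(0).templates
        cycles = [
            make_cycle(o, "left", 0, "OPTO", templates[o] + offsets[o] + rng.normal(0, 1, 101))
            for o in GPS_OUTCOMES
        ]
        bank = _bank()
        res = gps_for_side(cycles, bank)
        flat = np.concatenate(
            [c.samples - bank.curves[c.outcome] for c in cycles]
        )
        assert res.gps == pytest.approx(np.sqrt(np.mean(flat**2)), abs=1e-12)


class TestMdcFlags:
    def test_examples(self, config):
        assert mdc_flag(2.0, "CP", config) is True
        assert mdc_flag(0.5, "AS", config) is False
        assert mdc_flag(1.7, "OMD", config) is False  # strict inequality
        assert mdc_flag(-2.0, "OMD", config) is True  # absolute value


class TestOutliers:
    def test_quartile_example(self):
        vals = {"a": 5.0, "b": 5.2, "c": 5.1, "d": 4.9, "e": 12.0}
        assert find_outliers(vals) == ["e"]

    def test_identical_values(self):
        assert find_outliers([3.0, 3.0, 3.0, 3.0]) == []

    def test_too_few(self):
        with pytest.raises(ValidationError):
            find_outliers([1.0, 2.0, 3.0])


class TestCompareSystems:
    def test_identical_systems(self, null_cohort, config):
        banks = {
            "OPTO": build_normative_bank(null_cohort, "OPTO"),
            "IMU": build_normative_bank(null_cohort, "IMU"),
        }
        report = compare_gps_systems(null_cohort, banks, config)
        assert report.paired_overall["p_value"] == 1.0
        assert report.correlation["cc"] == pytest.approx(1.0)
        assert not report.mdc_flags["exceeds_mdc"].any()

    def test_group_separation(self, config):
        table = simulate_cohort(10, 10, 10, cycles_per_subject=2, seed=17, design="validity")
        banks = {
            "OPTO": build_normative_bank(table, "OPTO"),
            "IMU": build_normative_bank(table, "IMU"),
        }
        report = compare_gps_systems(table, banks, config)
        comp = report.group_comparison
        for system in ("OPTO", "IMU"):
            omni = comp[(comp.system == system) & (comp.comparison == "omnibus")]
            assert omni["p_value"].iloc[0] < config.alpha
            for g in ("CP", "OMD"):
                pair = comp[(comp.system == system) & (comp.comparison == f"{g} vs AS")]
                assert pair["p_value"].iloc[0] < config.alpha

    def test_outlier_attenuation(self):
        # three extreme subjects; test-system curves shrink deviations toward
        # the bank, so reference flags must cover test flags
        templates = make_template_bank(0).templates
        table = CohortTable()
        rng = np.random.default_rng(2)
        for i in range(12):
            group = "AS" if i < 4 else "CP"
            sev = 25.0 if i >= 9 else (3.0 if group == "CP" else 0.5)
            key = make_key(subject_id=f"S{i:02d}", group=group)
            for side in ("left", "right"):
                for o in GPS_OUTCOMES:
                    dev = sev * rng.normal(0, 1) / 3.0
                    opto = templates[o] + dev
                    imu = templates[o] + 0.4 * dev
                    table.add(key, make_cycle(o, side, 0, "OPTO", opto))
                    table.add(key, make_cycle(o, side, 0, "IMU", imu))
        banks = {
            "OPTO": build_normative_bank(table, "OPTO"),
            "IMU": build_normative_bank(table, "IMU"),
        }
        df = gps_table(table, banks)
        flags_opto = set(find_outliers(dict(zip(df["subject_id"], df["gps_opto"]))))
        flags_imu = set(find_outliers(dict(zip(df["subject_id"], df["gps_imu"]))))
        assert flags_opto
        assert flags_imu.issubset(flags_opto)

    def test_gps_calibration(self):
        # asymptomatic group mean near the conventional ~5 deg normal value
        table = simulate_cohort(15, 2, 2, cycles_per_subject=2, seed=23, design="validity")
        banks = {"OPTO": build_normative_bank(table, "OPTO")}
        df = gps_table(table, banks)
        as_mean = df[df.group == "AS"]["gps_opto"].mean()
        assert 4.0 <= as_mean <= 6.0
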