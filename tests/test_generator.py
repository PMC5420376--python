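import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from jointplay.curves import extract_features
from jointplay.generator import (
    CohortSpec,
    FeatureTargets,
    InfeasibleTargetError,
    LimbComplianceParams,
    ProtocolConfig,
    backbone_torque,
    closed_form_features,
    default_study_means,
    generate_cohort,
    params_from_features,
    simulate_rotation_test,
)


class TestBackboneTorque:
    def test_zero_at_neutral(self):
        p = LimbComplianceParams(neutral_angle=12.0)
        assert backbone_torque(p, 12.0) == 0.0

    def test_exponential_closed_form(self):
        p = LimbComplianceParams(scale_er=1.0, shape_er=0.05)
        assert backbone_torque(p, 20.0) == pytest.approx(math.e - 1.0, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=60.0))
    def test_odd_symmetry_with_equal_parameters(self, delta):
        p = LimbComplianceParams(scale_er=1.3, scale_ir=1.3,
                                 shape_er=0.04, shape_ir=0.04)
        assert backbone_torque(p, delta) == pytest.approx(
            -backbone_torque(p, -delta), rel=1e-12
        )

    def test_strictly_increasing(self):
        p = LimbComplianceParams(scale_er=0.8, scale_ir=1.7,
                                 shape_er=0.03, shape_ir=0.06)
        grid = np.linspace(-50, 50, 501)
        torque = backbone_torque(p, grid)
        assert np.all(np.diff(torque) > 0)

    def test_rejects_nonfinite_angle(self):
        with pytest.raises(ValueError):
            backbone_torque(LimbComplianceParams(), np.nan)


class TestSimulateRotationTest:
    def test_reversal_angle_matches_closed_form(self, symmetric_params, protocol):
        # noiseless limb S=1, beta=0.05, h=0.25, limit 5.65:
        # max ER = neutral + ln(1 + 5.4)/0.05 = ln(6.4)/0.05
        rec = simulate_rotation_test(symmetric_params, protocol, seed=0)
        expected = math.log(6.4) / 0.05
        assert rec.angle_deg.max() == pytest.approx(expected, abs=1e-9)
        assert rec.angle_deg.min() == pytest.approx(-expected, abs=1e-9)

    def test_noiseless_torque_never_exceeds_limit(self, symmetric_params, protocol):
        rec = simulate_rotation_test(symmetric_params, protocol, seed=0)
        assert np.abs(rec.torque_nm).max() <= protocol.torque_limit + 1e-9

    def test_same_seed_is_bit_identical(self, protocol):
        p = LimbComplianceParams(torque_noise_sd=0.01)
        a = simulate_rotation_test(p, protocol, seed=7)
        b = simulate_rotation_test(p, protocol, seed=7)
        assert np.array_equal(a.torque_nm, b.torque_nm)
        assert np.array_equal(a.angle_deg, b.angle_deg)

    def test_zero_hysteresis_loop_collapses(self, protocol):
        # loading and unloading branches coincide as curves
        p = LimbComplianceParams(hysteresis_offset=0.0, torque_noise_sd=0.0)
        rec = simulate_rotation_test(p, protocol, seed=0)
        up = rec.direction == 1
        down = rec.direction == -1
        order_d = np.argsort(rec.angle_deg[down])
        interp = np.interp(
            rec.angle_deg[up],
            rec.angle_deg[down][order_d],
            rec.torque_nm[down][order_d],
        )
        # tolerance: chord-vs-curve error ~ T'' * step^2 / 8 ~ 2e-5 Nm
        assert np.allclose(interp, rec.torque_nm[up], atol=5e-5)

    def test_unreachable_reversal_rejected(self, protocol):
        p = LimbComplianceParams(hysteresis_offset=6.0)
        with pytest.raises(ValueError, match="unreachable"):
            simulate_rotation_test(p, protocol, seed=0)


class TestParamsFromFeatures:
    @pytest.mark.parametrize(
        "target",
        [
            FeatureTargets(55.8, 36.4, 10.0, 0.26, 0.26, pos0=0.0),
            FeatureTargets(48.7, 28.2, 8.0, 0.32, 0.24, pos0=3.0),
            FeatureTargets(64.5, 31.3, 14.0, 0.26, 0.30, pos0=-2.5),
            FeatureTargets(44.6, 25.8, 10.0, 0.32, 0.32),  # pos0 free
        ],
    )
    def test_roundtrip_reproduces_targets(self, target, protocol):
        params = params_from_features(target, protocol, angle_step=0.05)
        feats = extract_features(simulate_rotation_test(params, protocol, seed=0))
        assert feats.max_external_rotation == pytest.approx(target.max_er, abs=0.1)
        assert feats.max_internal_rotation == pytest.approx(target.max_ir, abs=0.1)
        assert feats.play_at_zero_torque == pytest.approx(target.play, abs=0.1)
        if target.pos0 is None:
            assert params.neutral_angle == 0.0
        else:
            assert feats.position_at_zero_torque == pytest.approx(
                target.pos0, abs=0.1
            )
        assert feats.endpoint_slope_er == pytest.approx(target.slope_er, abs=0.005)
        assert feats.endpoint_slope_ir == pytest.approx(target.slope_ir, abs=0.005)

    def test_zero_play_gives_zero_hysteresis(self, protocol):
        params = params_from_features(
            FeatureTargets(40.0, 30.0, 0.0, 0.3, 0.3), protocol
        )
        assert params.hysteresis_offset == 0.0

    def test_printed_group_means_feasible_as_derivative_targets(self, protocol):
        # healthy-limb group means (max ER 48.7 deg, stiffness 1.6) admit a
        # curve when the stiffness is read as the endpoint derivative
        params = params_from_features(
            FeatureTargets(48.7, 28.2, 8.0, 1.6, 1.6),
            protocol,
            slope_kind="endpoint_derivative",
        )
        deriv = params.shape_er * (
            params.scale_er + protocol.torque_limit - params.hysteresis_offset
        )
        assert deriv == pytest.approx(1.6, rel=1e-6)

    def test_steep_window_slope_infeasible(self, protocol):
        # a monotone curve capped at 5.65 Nm cannot average 1.6 Nm/deg over
        # the ~8 deg endpoint window
        with pytest.raises(InfeasibleTargetError):
            params_from_features(FeatureTargets(48.7, 28.2, 8.0, 1.6, 1.6), protocol)

    def test_slope_below_secant_infeasible(self, protocol):
        with pytest.raises(InfeasibleTargetError):
            params_from_features(FeatureTargets(40.0, 30.0, 0.0, 0.05, 0.05), protocol)

    def test_monotonicity_of_generated_curves(self, protocol):
        # more friction -> wider extracted play; faster stiffening -> steeper slope
        base = LimbComplianceParams(torque_noise_sd=0.0)
        plays = []
        for h in (0.1, 0.3, 0.6):
            p = LimbComplianceParams(hysteresis_offset=h, torque_noise_sd=0.0)
            plays.append(
                extract_features(
                    simulate_rotation_test(p, protocol, seed=0)
                ).play_at_zero_torque
            )
        assert plays[0] < plays[1] < plays[2]
        slopes = []
        for beta in (0.03, 0.05, 0.08):
            p = LimbComplianceParams(shape_er=beta, shape_ir=beta,
                                     torque_noise_sd=0.0)
            slopes.append(
                extract_features(
                    simulate_rotation_test(p, protocol, seed=0)
                ).endpoint_slope_er
            )
        assert slopes[0] < slopes[1] < slopes[2]
        del base


class TestGenerateCohort:
    def test_study_shape(self, study_cohort):
        assert len(study_cohort.subjects) == 17
        assert len(study_cohort.recordings()) == 34
        df = study_cohort.cohort_frame()
        counts = df.groupby("group")["subject_id"].nunique().to_dict()
        assert counts == {1: 9, 2: 6, 3: 2}

    def test_determinism_bit_identical(self):
        a = generate_cohort(CohortSpec(seed=99, n_group1=2, n_group2=2, n_group3=0))
        b = generate_cohort(CohortSpec(seed=99, n_group1=2, n_group2=2, n_group3=0))
        assert a.cohort_frame().equals(b.cohort_frame())
        for ra, rb in zip(a.recordings(), b.recordings()):
            assert np.array_equal(ra.torque_nm, rb.torque_nm)

    def test_kt_nondecreasing_in_force(self, study_cohort):
        df = study_cohort.cohort_frame()
        kt = df[["kt_67", "kt_89", "kt_133", "kt_manmax"]].to_numpy()
        assert np.all(np.diff(kt, axis=1) >= -1e-12)

    def test_vas_within_group_rules(self, study_cohort):
        df = study_cohort.cohort_frame().drop_duplicates("subject_id")
        for _, row in df.iterrows():
            if row["group"] == 1:
                assert row["vas"] >= 80
            elif row["group"] == 2:
                assert 50 < row["vas"] < 80
            else:
                assert row["vas"] < 50

    def test_zero_dispersion_hits_group_means(self, protocol):
        spec = CohortSpec(seed=5, n_group1=1, n_group2=1, n_group3=0,
                          sd_rotation=0.0, sd_slope=0.0, sd_kt=0.0, sd_play=0.0,
                          torque_noise_sd=0.0)
        cohort = generate_cohort(spec)
        means = default_study_means()
        for subj in cohort.subjects:
            for limb, data in subj.limbs.items():
                m = means[(subj.group, limb)]
                f = extract_features(data.recording)
                assert f.max_external_rotation == pytest.approx(m.max_er, abs=0.2)
                assert f.max_internal_rotation == pytest.approx(m.max_ir, abs=0.2)
                assert f.play_at_zero_torque == pytest.approx(m.play, abs=0.2)
                assert f.endpoint_slope_er == pytest.approx(m.slope_er, abs=0.01)
                assert data.kt_manmax == pytest.approx(m.kt_manmax, abs=1e-9)

    def test_monte_carlo_group_mean_recovery(self):
        # group-2 healthy max ER should average 64.5 deg (within 2 SE at n=200)
        spec = CohortSpec(seed=11, n_group1=0, n_group2=200, n_group3=0)
        cohort = generate_cohort(spec)
        ers = [
            extract_features(s.limbs["healthy"].recording).max_external_rotation
            for s in cohort.subjects
        ]
        se = spec.sd_rotation / math.sqrt(len(ers))
        assert abs(np.mean(ers) - 64.5) < 2 * se

    def test_closed_forms_match_extraction_on_cohort_limb(self, study_cohort,
                                                          protocol):
        data = study_cohort.subjects[0].limbs["healthy"]
        noiseless = simulate_rotation_test(
            LimbComplianceParams(
                **{**data.params.__dict__, "torque_noise_sd": 0.0}
            ),
            protocol,
            seed=0,
        )
        f = extract_features(noiseless)
        cf = closed_form_features(data.params, protocol)
        assert f.max_external_rotation == pytest.approx(
            cf.max_external_rotation, abs=2 * data.params.angle_step
        )
        assert f.play_at_zero_torque == pytest.approx(
            cf.play_at_zero_torque, abs=2 * data.params.angle_step
        )
        assert f.endpoint_slope_er == pytest.approx(cf.endpoint_slope_er, abs=0.01)

    def test_seed_is_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            CohortSpec(seed=None)
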