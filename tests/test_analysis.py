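"""Measurement pipeline: peaks, compensated mass, regressions, fits,
ellipses and the experiment-level summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hammersim import analysis as an
from hammersim import protocols as pr
from hammersim import subject as sj
from hammersim.analysis import (
    anticipatory_offset,
    compensated_object_mass,
    confidence_ellipse,
    deadaptation_increase,
    extract_peaks,
    fit_half_gaussian,
    regress_compensation,
)
from hammersim.dynamics import ToolSpec, simulate_tool_loads
from hammersim.subject import TrialRecord


def record_from(force, disp, times):
    return TrialRecord(
        subject_id="s0", trial_index=0, block=0, phase="", condition="error_clamp",
        rotation_direction="CCW", visual_orientation=0.0, dynamics_orientation=0.0,
        probe_orientation=float("nan"), head_mass=0.7, required_peak_force=1.0,
        peak_force_mag=0.0, peak_force_dir=0.0, peak_disp_mag=0.0,
        peak_disp_angle=0.0, force_series=force, displacement_series=disp,
        times=times,
    )


class TestExtractPeaks:
    def test_single_sample(self):
        rec = record_from(np.array([[0.0, 2.0]]), np.zeros((1, 2)), np.zeros(1))
        p = extract_peaks(rec)
        assert p.peak_force_mag == 2.0
        assert p.peak_force_dir == pytest.approx(0.0)  # +y is bearing 0

    def test_first_of_equal_maxima(self):
        F = np.array([[0.0, 1.0], [0.0, 3.0], [0.0, 2.0], [0.0, 3.0]])
        rec = record_from(F, np.zeros((4, 2)), np.arange(4.0))
        assert extract_peaks(rec).peak_force_time == 1.0

    def test_all_zero_flagged(self):
        rec = record_from(np.zeros((5, 2)), np.zeros((5, 2)), np.arange(5.0))
        p = extract_peaks(rec)
        assert p.peak_force_mag == 0.0
        assert p.undefined_direction


class TestCompensatedMass:
    def test_zero_force_zero_mass(self, profile_ccw):
        assert compensated_object_mass(0.0, 0.3, profile_ccw).mass == 0.0

    def test_roundtrip_identity(self, profile_ccw):
        loads = simulate_tool_loads(ToolSpec(head_mass=0.91, rod_length=0.3), profile_ccw)
        peak = float(np.linalg.norm(loads.force, axis=1).max())
        m = compensated_object_mass(peak, 0.3, profile_ccw).mass
        assert m == pytest.approx(0.91, abs=1e-9)

    def test_linear_in_force(self, profile_ccw):
        m1 = compensated_object_mass(1.0, 0.3, profile_ccw).mass
        m2 = compensated_object_mass(2.0, 0.3, profile_ccw).mass
        assert m2 == pytest.approx(2 * m1, rel=1e-12)

    def test_percent_body_mass(self, profile_ccw):
        c = compensated_object_mass(1.0, 0.3, profile_ccw, body_mass=70.0)
        assert c.mass_pct_body == pytest.approx(100 * c.mass / 70.0)


class TestRegression:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["subject_id", "orientation", "true_mass", "compensated_mass"])

    def test_perfect_half_compensation(self):
        rows = [("s0", "training", m, 0.5 * m) for m in (0.7, 1.0, 1.3)]
        rows += [("s1", "training", m, 0.5 * m) for m in (0.7, 1.0, 1.3)]
        s = regress_compensation(self.table(rows))
        assert s.mean["training"] == pytest.approx(0.5, abs=1e-12)
        assert s.sd["training"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_compensation_zero_slope(self):
        rows = [("s0", "training", m, 0.4) for m in (0.7, 1.0, 1.3)]
        s = regress_compensation(self.table(rows))
        assert s.mean["training"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x = np.array([0.7, 1.0, 1.3])
        y = rng.normal(0.5 * x, 0.1)
        rows = [("s0", "training", xi, yi) for xi, yi in zip(x, y)]
        s = regress_compensation(self.table(rows))
        X = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert s.mean["training"] == pytest.approx(beta[0], abs=1e-12)

    def test_single_mass_level_rejected(self):
        rows = [("s0", "training", 1.0, 0.5), ("s0", "training", 1.0, 0.6)]
        with pytest.raises(ValueError):
            regress_compensation(self.table(rows))

    def test_paired_contrast(self):
        rows = []
        for k in range(4):
            for m in (0.7, 1.0, 1.3):
                rows.append((f"s{k}", "training", m, (0.55 + 0.02 * k) * m))
                rows.append((f"s{k}", "transfer", m, (0.20 + 0.02 * k) * m))
        s = regress_compensation(self.table(rows))
        t, p = s.paired_t
        wide_diff = 0.35  # identical for every subject
        assert p < 1e-6 or np.isnan(t) is False


class TestHalfGaussianFit:
    @pytest.mark.parametrize("sd", [10.0, 34.0, 60.0, 120.0])
    def test_exact_recovery_on_model_data(self, sd):
        phi = np.array([0.0, 22.5, 45.0, 90.0, 180.0])
        v = 1.0 * np.exp(-(phi**2) / (2 * sd**2))
        f = fit_half_gaussian(phi, v)
        assert f.sd == pytest.approx(sd, abs=0.1)
        assert f.amplitude == pytest.approx(1.0, abs=1e-3)
        assert not f.unidentifiable

    def test_flat_values_flagged_unidentifiable(self):
        phi = np.array([0.0, 45.0, 90.0, 180.0])
        f = fit_half_gaussian(phi, np.full(4, 0.7))
        assert f.unidentifiable

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_half_gaussian([10.0, 45.0, 90.0], [1.0, 0.5, 0.1])  # no 0 point
        with pytest.raises(ValueError):
            fit_half_gaussian([0.0, 45.0, 90.0], [0.0, 0.0, 0.0])


class TestDeadaptation:
    def test_no_probe_learning_no_increase(self, impedance):
        params = sj.exp3_cohort_params(
            motor_noise_sd=0.0, direction_noise_sd=0.0,
            deadapt_onset=0.0, deadapt_rate=0.0,
            kernel_sd_sd=0.0, deadapt_kernel_sd_sd=0.0,
        )
        cohort = sj.make_cohort(params, 1, seed=3)
        table = pr.run_experiment(pr.build_experiment(3, seed=5), cohort, seed=6)
        inc = deadaptation_increase(table)
        assert np.abs(inc.increase).max() < 0.02

    def test_training_orientation_probes_deadapt_most(self, exp3_noisefree_table):
        inc = deadaptation_increase(exp3_noisefree_table)
        by_orient = inc.set_index("orientation").increase
        assert by_orient.loc[0.0] == by_orient.max()

    def test_spreadsheet_oracle_on_constructed_table(self, impedance):
        # two-block toy table with aligned directions; the expected increase
        # is (req - clamp force) - disp/gain computed by hand
        from hammersim.analysis import _expected_force_direction, _plant_peak_gain

        req = 2.5
        gain = _plant_peak_gain(impedance, "CCW", 0.7, 1000.0)
        rows = []
        # block 0: four full-dynamics baseline trials, deficit 0.4 N
        for i in range(4):
            d = "CCW" if i % 2 == 0 else "CW"
            ed = _expected_force_direction(d, 0.0, 0.7, 1000.0)
            rows.append(dict(subject_id="s0", trial_index=i, block=0, phase="train",
                             condition="full_dynamics", rotation_direction=d,
                             visual_orientation=0.0, probe_orientation=0.0,
                             required_peak_force=req, peak_force_mag=req - 0.4,
                             peak_force_dir=ed, peak_disp_mag=0.4 * gain,
                             peak_disp_angle=ed + 180.0, head_mass=0.7))
        # block 1: probes at 45 deg then clamps showing deficit 1.0 N
        for i in range(2):
            d = "CCW" if i % 2 == 0 else "CW"
            rows.append(dict(subject_id="s0", trial_index=4 + i, block=1, phase="probe",
                             condition="zero_force", rotation_direction=d,
                             visual_orientation=45.0, probe_orientation=45.0,
                             required_peak_force=req, peak_force_mag=1.0,
                             peak_force_dir=0.0, peak_disp_mag=0.01,
                             peak_disp_angle=0.0, head_mass=0.7))
        for i in range(2):
            d = "CCW" if i % 2 == 0 else "CW"
            ed = _expected_force_direction(d, 0.0, 0.7, 1000.0)
            rows.append(dict(subject_id="s0", trial_index=6 + i, block=1,
                             phase="post_clamp", condition="error_clamp",
                             rotation_direction=d, visual_orientation=0.0,
                             probe_orientation=45.0, required_peak_force=req,
                             peak_force_mag=req - 1.0, peak_force_dir=ed,
                             peak_disp_mag=0.0, peak_disp_angle=0.0, head_mass=0.7))
        inc = deadaptation_increase(pd.DataFrame(rows), impedance)
        assert len(inc) == 1
        assert inc.increase.iloc[0] == pytest.approx(1.0 - 0.4, abs=1e-9)


class TestConfidenceEllipse:
    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(8)
        V = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.6], [0.6, 0.5]], size=40)
        e = confidence_ellipse(V, level=0.99)
        evals = np.linalg.eigvalsh(np.cov(V.T))
        expected = np.sqrt(evals[::-1] * stats.chi2.ppf(0.99, 2))
        assert np.allclose(e.axes, expected, rtol=1e-12)
        assert not e.degenerate

    def test_identical_points_degenerate(self):
        V = np.tile([0.3, 0.4], (5, 1))
        assert confidence_ellipse(V).degenerate

    def test_isotropic_axes_ratio_approaches_one(self):
        rng = np.random.default_rng(9)
        V = rng.normal(size=(20000, 2))
        e = confidence_ellipse(V)
        assert e.axes[0] / e.axes[1] == pytest.approx(1.0, abs=0.05)


class TestExperimentSummaries:
    def test_exp1_noise_free_offsets_and_association(self):
        cohort = sj.make_cohort(
            sj.exp1_cohort_params(motor_noise_sd=0.0, direction_noise_sd=0.0,
                                  prior_force_magnitude_sd=0.0),
            2, seed=1,
        )
        table = pr.run_experiment(pr.build_experiment(1, seed=2), cohort, seed=3)
        summ = an.exp1_summary(table, n_perm=200, seed=4)
        cw = summ[summ.rotation_direction == "CW"]
        ccw = summ[summ.rotation_direction == "CCW"]
        assert np.allclose(cw.mean_offset, -93.16, atol=0.1)
        assert np.allclose(ccw.mean_offset, 93.16, atol=0.1)
        assert np.allclose(summ.rho, 1.0, atol=1e-9)

    def test_offset_helper_mirror_convention(self):
        # a force exactly at the presented orientation reads 180 in the
        # mirrored display frame; at presented+90 it reads +90
        assert anticipatory_offset(0.0, 0.0) == 180.0
        assert anticipatory_offset(90.0, 0.0) == pytest.approx(90.0)

    def test_exp2_pipeline_recovers_slopes_noise_free(self):
        params = sj.exp2_cohort_params(
            motor_noise_sd=0.0, direction_noise_sd=0.0,
            compensation_asymptote_sd=0.0, kernel_sd_sd=0.0,
            prior_force_magnitude_sd=0.0,
        )
        cohort = sj.make_cohort(params, 3, seed=1)
        table = pr.run_experiment(pr.build_experiment(2, seed=2), cohort, seed=3)
        comp = an.exp2_compensation_table(table, body_mass=70.0)
        s = regress_compensation(comp)
        assert s.mean["training"] == pytest.approx(0.59, abs=0.02)
        assert s.mean["transfer"] == pytest.approx(0.22, abs=0.02)

    def test_exp4_congruent_vs_incongruent_contrast(self):
        results = {}
        for cong in (True, False):
            cohort = sj.make_cohort(
                sj.exp4_cohort_params(congruent=cong, motor_noise_sd=0.0,
                                      direction_noise_sd=0.0),
                2, seed=5,
            )
            table = pr.run_experiment(
                pr.build_experiment(4, seed=6, congruent=cong), cohort, seed=7
            )
            results[cong] = an.exp4_transfer_summary(table)
        cong, inc = results[True], results[False]
        assert np.allclose(cong.direction_change, -90.0, atol=2.0)
        assert (cong.magnitude_ratio < 0.7).all()
        assert np.allclose(inc.direction_change, 0.0, atol=2.0)
        assert np.allclose(inc.magnitude_ratio, 1.0, atol=0.02)
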