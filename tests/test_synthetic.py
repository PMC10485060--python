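"""Synthetic-trial generator: reproducibility, ground-truth closure, noise."""

import warnings

import numpy as np
import pytest

from springwalker.errors import InvalidParameterError
from springwalker.pipeline import analyze_trial, detect_gait_events
from springwalker.synthetic import (
    NoiseConfig,
    SyntheticConfig,
    generate_cohort,
    generate_trial,
)


def matched_errors(analysis, truth, field_map):
    """Per-step relative errors, records matched to generator steps."""
    ps = truth["per_step"]
    out = {name: [] for name in field_map}
    for rec in analysis.records:
        j = rec.step_index - 1
        for name, (attr, key) in field_map.items():
            want = ps[key][j]
            out[name].append((getattr(rec, attr) - want) / want)
    return {k: np.asarray(v) for k, v in out.items()}


class TestReproducibility:
    def test_same_seed_identical(self):
        cfg = SyntheticConfig(seed=11, n_strides=32)
        t1, _ = generate_trial(cfg)
        t2, _ = generate_trial(cfg)
        assert np.array_equal(t1.com_x, t2.com_x)
        assert np.array_equal(t1.grf_y["L"], t2.grf_y["L"])

    def test_different_seed_differs(self):
        t1, tr1 = generate_trial(SyntheticConfig(seed=11, n_strides=32))
        t2, tr2 = generate_trial(SyntheticConfig(seed=12, n_strides=32))
        assert not np.array_equal(t1.com_x, t2.com_x)
        # the underlying periodic gait is identical
        assert tr1["s"] == tr2["s"]

    def test_too_few_strides_rejected(self):
        with pytest.raises(InvalidParameterError):
            SyntheticConfig(n_strides=10)


class TestEventCounts:
    def test_heel_strikes_per_side(self, noiseless_trial):
        trial, truth = noiseless_trial
        ev = detect_gait_events(trial.grf_y, trial.grf_rate)
        assert len(ev.heel_strikes["L"]) == 35
        assert len(ev.heel_strikes["R"]) == 35

    def test_detected_times_match_truth(self, noiseless_trial):
        trial, truth = noiseless_trial
        ev = detect_gait_events(trial.grf_y, trial.grf_rate)
        merged = [t for t, _ in ev.merged_heel_strikes()]
        want = truth["per_step"]["hs_times"][: len(merged)]
        assert np.max(np.abs(np.array(merged) - np.array(want))) < 2e-3


class TestGroundTruthClosure:
    FIELDS = {
        "s": ("s_expt", "s"),
        "v": ("v_expt", "v"),
        "k": ("k_expt", "k"),
        "theta_dot": ("theta_dot_minus_expt", "theta_dot_minus"),
        "dt_ds": ("dt_ds_expt", "dt_ds"),
        "tau": ("tau_expt", "tau"),
    }

    def test_noiseless_per_step_recovery(self, noiseless_trial,
                                         noiseless_analysis):
        _, truth = noiseless_trial
        errs = matched_errors(noiseless_analysis, truth, self.FIELDS)
        for name, tol in [("s", 0.01), ("v", 0.01), ("k", 0.01),
                          ("theta_dot", 0.01), ("dt_ds", 0.02), ("tau", 0.01)]:
            assert np.mean(np.abs(errs[name])) < tol, name

    def test_noiseless_margin_of_stability(self, noiseless_trial,
                                           noiseless_analysis):
        _, truth = noiseless_trial
        ps = truth["per_step"]
        diffs = [rec.b_expt - ps["b"][rec.step_index - 1]
                 for rec in noiseless_analysis.records]
        assert np.mean(np.abs(diffs)) < 0.005

    def test_noiseless_double_support_regression(self, noiseless_trial,
                                                 noiseless_analysis):
        _, truth = noiseless_trial
        reg = noiseless_analysis.regression
        assert reg is not None
        assert reg.mu_expt == pytest.approx(truth["mu_true"], rel=0.01)

    def test_quasi_stiffness_fit_is_exact_without_noise(self,
                                                        noiseless_analysis):
        r2 = [rec.r2_k for rec in noiseless_analysis.records]
        assert min(r2) > 0.999


class TestNoise:
    def test_dispersion_grows_with_noise(self):
        spreads = []
        for factor in (0.0, 1.0, 2.5):
            nz = NoiseConfig(
                marker=0.0003 * factor, grf=2.0, angle=0.003 * factor,
                torque_rel=0.85 * factor,
            ) if factor else NoiseConfig.zeros()
            cfg = SyntheticConfig(seed=21, noise=nz)
            trial, truth = generate_trial(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ana = analyze_trial(trial)
            errs = matched_errors(ana, truth, {"k": ("k_expt", "k")})
            spreads.append(np.std(errs["k"]))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_default_torque_disturbance_hits_empirical_fit_band(self):
        cfg = SyntheticConfig(seed=5)
        trial, _ = generate_trial(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = analyze_trial(trial).frame()
        assert 0.6 < df.r2_k.mean() < 0.85


class TestCohort:
    def test_zero_stiffness_variance_gives_null_correlations(self):
        """Without any stiffness variation (between subjects or between
        steps) the battery sees only estimation noise and reports the
        torque-stiffness cell as non-significant."""
        from springwalker.pipeline import correlation_analysis, records_frame

        base = SyntheticConfig(seed=3, stiffness_jitter=0.0,
                               noise=NoiseConfig.zeros())
        records = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for config, trial, truth in generate_cohort(
                    base, n_subjects=4, speed_list=[1.25],
                    k_by_speed={1.25: 0.13}, k_subject_sd=0.0, k_speed_sd=0.0,
                    seed=3):
                assert config.k_true == pytest.approx(0.13)
                records.extend(analyze_trial(trial).records)
        rep = correlation_analysis(records_frame(records))
        cell = rep.cell(1.25, "T_expt")
        assert cell.n > 100
        assert not cell.significant
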