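"""HRF, design-matrix construction, serial orthogonalization, OLS fits."""

import numpy as np
import pandas as pd
import pytest

from intentprior.glm import (
    HRFSpec,
    build_design_matrix,
    canonical_hrf,
    dct_highpass_basis,
    fit_glm,
    motion_expansion,
    serial_orthogonalize,
)
from intentprior.observer import ObserverConfig, prior_trace
from intentprior.task_design import TaskConfig, assemble_session, generate_run


def _session(n_induction=6, n_testing=24, n_control=2, seeds=(1, 2)):
    d1 = generate_run(
        TaskConfig(task_type="basic", seed=seeds[0], n_induction=n_induction,
                   n_testing=n_testing, n_control=n_control)
    )
    d2 = generate_run(
        TaskConfig(task_type="superordinate", seed=seeds[1], n_induction=n_induction,
                   n_testing=n_testing, n_control=n_control)
    )
    ev = assemble_session([d1, d2])
    mods = []
    for d, cond in [(d1, "basic"), (d2, "superordinate")]:
        trials = d.task_trials()
        events = [t.intention for t in trials]
        trace = prior_trace(events, ObserverConfig(alpha=1.5), labels=d.config.intentions)
        mods.append(
            pd.DataFrame(
                {
                    "trial_index": [t.index for t in trials],
                    "evidence": [t.evidence_level for t in trials],
                    "prior": trace.prob_of(events),
                    "condition": cond,
                }
            )
        )
    total = d1.total_duration_s + d2.total_duration_s
    n_volumes = int(np.ceil(total / 2.5)) + 4
    return ev, pd.concat(mods, ignore_index=True), n_volumes


class TestCanonicalHrf:
    def test_peak_time_near_gamma_mode(self):
        # mode of the peak gamma (shape 6, scale 1) is 5 s
        h = canonical_hrf(HRFSpec())
        assert 4.5 <= np.argmax(h) * 0.1 <= 5.5

    def test_single_sign_change(self):
        h = canonical_hrf(HRFSpec())
        signs = np.sign(h[np.abs(h) > 1e-6])
        changes = np.sum(signs[1:] != signs[:-1])
        assert changes == 1  # positive lobe then undershoot

    def test_refinement_keeps_peak_time(self):
        t1 = np.argmax(canonical_hrf(HRFSpec(dt=0.1))) * 0.1
        t2 = np.argmax(canonical_hrf(HRFSpec(dt=0.05))) * 0.05
        assert abs(t1 - t2) <= 0.1

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            HRFSpec(dt=0.0)


class TestSerialOrthogonalize:
    def test_orthogonal_input_is_fixed_point(self):
        cols = [np.array([1.0, 0, 0, 0]), np.array([0, 1.0, 0, 0])]
        out = serial_orthogonalize(cols)
        np.testing.assert_allclose(out[0], cols[0])
        np.testing.assert_allclose(out[1], cols[1])

    def test_duplicate_becomes_zero(self):
        c = np.array([1.0, 2.0, -1.0])
        out = serial_orthogonalize([c, c.copy()])
        np.testing.assert_allclose(out[1], 0.0, atol=1e-12)

    def test_matches_qr_oracle(self, rng):
        X = rng.normal(size=(100, 3))
        out = np.column_stack(serial_orthogonalize(list(X.T)))
        Q, R = np.linalg.qr(X)
        oracle = Q * np.diag(R)  # unnormalized Gram-Schmidt columns
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_zero_column_skipped_with_warning(self):
        cols = [np.zeros(5), np.arange(5.0)]
        with pytest.warns(UserWarning, match="zero-norm"):
            out = serial_orthogonalize(cols)
        np.testing.assert_allclose(out[1], np.arange(5.0))


class TestBuildDesignMatrix:
    def test_sixteen_task_regressors_for_two_conditions(self):
        ev, mods, n_vol = _session()
        dm = build_design_matrix(ev, mods, tr=2.5, n_volumes=n_vol)
        assert len(dm.task_columns) == 16
        categorical = [c for c in dm.task_columns if "_x_" not in c]
        parametric = [c for c in dm.task_columns if "_x_" in c]
        assert len(categorical) == 8 and len(parametric) == 8

    def test_parametric_siblings_orthogonal(self):
        ev, mods, n_vol = _session()
        dm = build_design_matrix(ev, mods, tr=2.5, n_volumes=n_vol)
        f = dm.frame
        for cond in ("basic", "superordinate"):
            e = f[f"infer_{cond}_x_evidence"]
            p = f[f"infer_{cond}_x_prior"]
            i = f[f"infer_{cond}_x_evidence_x_prior"]
            assert abs(e @ p) < 1e-8
            assert abs(e @ i) < 1e-8
            assert abs(p @ i) < 1e-8
            # shared variance is credited to evidence: prior residual is
            # uncorrelated with the evidence column
            assert abs(np.corrcoef(e, p)[0, 1]) < 1e-8

    def test_orthogonalization_record_kept(self):
        ev, mods, n_vol = _session()
        dm = build_design_matrix(ev, mods, tr=2.5, n_volumes=n_vol)
        rec = dm.orthogonalization["infer_basic_x_evidence_x_prior"]
        assert "infer_basic_x_evidence" in rec and "infer_basic_x_prior" in rec

    def test_constant_modulator_column_vanishes(self):
        ev, mods, n_vol = _session()
        mods = mods.copy()
        mods["prior"] = 0.5  # no variance -> centered amplitudes all zero
        dm = build_design_matrix(ev, mods, tr=2.5, n_volumes=n_vol)
        np.testing.assert_allclose(dm.frame["infer_basic_x_prior"], 0.0, atol=1e-10)

    def test_events_beyond_scan_rejected(self):
        ev, mods, n_vol = _session()
        with pytest.raises(ValueError, match="beyond scan end"):
            build_design_matrix(ev, mods, tr=2.5, n_volumes=20)

    def test_missing_modulator_rejected(self):
        ev, mods, n_vol = _session()
        with pytest.raises(ValueError, match="missing modulators"):
            build_design_matrix(ev, mods.iloc[:-3], tr=2.5, n_volumes=n_vol)

    def test_highpass_columns_present(self):
        ev, mods, n_vol = _session()
        dm = build_design_matrix(ev, mods, tr=2.5, n_volumes=n_vol, highpass_s=128.0)
        n_dct = sum(c.startswith("dct_") for c in dm.frame.columns)
        assert n_dct == int(np.floor(2 * n_vol * 2.5 / 128.0))
        assert dct_highpass_basis(n_vol, 2.5, 128.0).shape == (n_vol, n_dct)

    def test_motion_expansion_shape(self, rng):
        m = rng.normal(size=(50, 6))
        assert motion_expansion(m).shape == (50, 12)


class TestFitGlm:
    def test_noiseless_inversion(self, rng):
        ev, mods, n_vol = _session()
        dm = build_design_matrix(ev, mods, tr=2.5, n_volumes=n_vol)
        beta = rng.normal(size=dm.frame.shape[1])
        y = dm.matrix @ beta
        fit = fit_glm(y, dm)
        np.testing.assert_allclose(fit.betas.to_numpy(), beta, atol=1e-8)
        # OLS normal equations: residuals orthogonal to every column
        assert np.max(np.abs(dm.matrix.T @ fit.residuals)) < 1e-8

    def test_t_statistic_closed_form(self, rng):
        X = rng.normal(size=(30, 3))
        beta = np.array([1.0, -0.5, 0.2])
        y = X @ beta + rng.normal(size=30)
        c = np.array([0.0, 1.0, 0.0])
        fit = fit_glm(y, X, contrasts=[c])
        bh = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ bh
        s2 = resid @ resid / (30 - 3)
        t_ref = (c @ bh) / np.sqrt(s2 * c @ np.linalg.solve(X.T @ X, c))
        assert fit.t_stats[0] == pytest.approx(t_ref, abs=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
        c = np.array([0.0, 1.0, 0.0])
        from scipy import stats

        rej = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.normal(size=60)
            fit = fit_glm(y, X, contrasts=[c])
            if 2 * stats.t.sf(abs(fit.t_stats[0]), fit.df) < 0.05:
                rej += 1
        assert 0.03 < rej / n_sim < 0.07

    def test_rank_deficiency_warns(self, rng):
        X = rng.normal(size=(20, 2))
        X = np.column_stack([X, X[:, 0]])
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_glm(rng.normal(size=20), X)

    def test_prewhitening_estimates_rho(self, rng):
        from intentprior.synthetic import ar1_noise

        X = np.column_stack([np.ones(500), rng.normal(size=500)])
        y = ar1_noise(500, 0.5, 1.0, rng)
        fit = fit_glm(y, X, prewhiten=True)
        assert 0.3 < fit.ar1_rho < 0.7


class TestInteractionRecovery:
    def test_interaction_contrast_power_and_specificity(self):
        from intentprior.synthetic import BoldSimConfig, simulate_bold

        ev, mods, n_vol = _session(n_induction=12, n_testing=48, n_control=4)
        dm = build_design_matrix(ev, mods, tr=2.5, n_volumes=n_vol)
        effect = {"infer_basic_x_evidence_x_prior": 1.0}
        y0 = simulate_bold(dm, effect, BoldSimConfig(
            n_volumes=n_vol + 5, noise_sd=0.0, drift_amplitude=0.0))
        fit0 = fit_glm(y0, dm)
        # noiseless: the effect loads only on the interaction column
        assert fit0.betas["infer_basic_x_evidence_x_prior"] == pytest.approx(1.0, abs=1e-6)
        assert abs(fit0.betas["infer_basic_x_evidence"]) < 1e-6
        assert abs(fit0.betas["infer_basic_x_prior"]) < 1e-6

        # power at SNR 1 (noise sd = signal sd of the interaction regressor)
        sig_sd = dm.frame["infer_basic_x_evidence_x_prior"].std()
        c = dm.contrast_vector({"infer_basic_x_evidence_x_prior": 1.0})
        from scipy import stats

        detected = 0
        n_sim = 50
        for s in range(n_sim):
            cfg = BoldSimConfig(n_volumes=n_vol + 5, noise_sd=float(sig_sd),
                                ar1_rho=0.0, drift_amplitude=0.5)
            y = simulate_bold(dm, effect, cfg, seed=s)
            fit = fit_glm(y, dm, contrasts=[c])
            if stats.t.sf(fit.t_stats[0], fit.df) < 0.05:
                detected += 1
        assert detected / n_sim >= 0.8
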