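"""PPI construction/estimation, DCM space, forward model, BIC fits, BMS."""

import numpy as np
import pytest
from scipy import linalg as sla
from scipy import stats

from intentprior import connectivity as cn
from intentprior.glm import HRFSpec, canonical_hrf
from intentprior.synthetic import (
    BoldSimConfig,
    ar1_noise,
    coupling_study,
    noise_sd_for_snr,
    simulate_coupled_rois,
)

TR = 2.5
HRF = HRFSpec(dt=0.1)


class TestFirstPC:
    def test_single_column_returns_centered_column(self, rng):
        x = rng.normal(size=50)
        pc = cn.extract_first_pc(x)
        np.testing.assert_allclose(pc, x - x.mean(), atol=1e-10)

    def test_identical_columns_give_their_mean(self, rng):
        x = rng.normal(size=50)
        pc = cn.extract_first_pc(np.column_stack([x, x]))
        centered = x - x.mean()
        np.testing.assert_allclose(pc / np.linalg.norm(pc),
                                   centered / np.linalg.norm(centered), atol=1e-10)

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(50, 5))
        pc = cn.extract_first_pc(X)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        oracle = U[:, 0] * s[0]
        agree = min(np.max(np.abs(pc - oracle)), np.max(np.abs(pc + oracle)))
        assert agree < 1e-10

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cn.extract_first_pc(np.ones((20, 3)))


class TestDeconvolution:
    def test_round_trip_correlation(self, rng):
        n_vol = 120
        n_micro = int(n_vol * TR / HRF.dt)
        neural = np.convolve(rng.normal(size=n_micro), np.ones(30) / 30, mode="same")
        bold = cn._reconvolve(neural, n_vol, TR, HRF)
        rec = cn.deconvolve_hrf(bold, HRF, ridge_lambda=1e-6, tr=TR)
        bold2 = cn._reconvolve(rec, n_vol, TR, HRF)
        assert np.corrcoef(bold, bold2)[0, 1] > 0.99

    def test_zero_input_zero_output(self):
        out = cn.deconvolve_hrf(np.zeros(60), HRF, 1e-2, TR)
        np.testing.assert_allclose(out, 0.0)

    def test_matches_primal_closed_form(self, rng):
        # K'(KK'+lam I)^-1 y must equal (K'K+lam I)^-1 K' y (push-through)
        n_vol, lam = 40, 0.5
        y = rng.normal(size=n_vol)
        K, _ = cn._conv_operator(n_vol, TR, HRF, lam)
        primal = np.linalg.solve(K.T @ K + lam * np.eye(K.shape[1]), K.T @ y)
        dual = cn.deconvolve_hrf(y, HRF, lam, TR)
        np.testing.assert_allclose(dual, primal, atol=1e-8)

    def test_negative_ridge_rejected(self):
        with pytest.raises(ValueError, match="ridge"):
            cn.deconvolve_hrf(np.zeros(30), HRF, -1.0, TR)


class TestPPIRegressor:
    def test_constant_contrast_proportional_to_resmoothed_seed(self, rng):
        n_vol = 80
        seed_bold = ar1_noise(n_vol, 0.3, 1.0, rng)
        psych = np.ones(int(n_vol * TR / HRF.dt))
        ppi = cn.build_ppi_regressor(seed_bold, psych, HRF, TR)
        resmoothed = cn._reconvolve(
            cn.deconvolve_hrf(seed_bold, HRF, 1e-2, TR), n_vol, TR, HRF
        )
        resmoothed -= resmoothed.mean()
        assert np.corrcoef(ppi, resmoothed)[0, 1] > 0.999999

    def test_sign_antisymmetry(self, rng):
        n_vol = 80
        seed_bold = ar1_noise(n_vol, 0.3, 1.0, rng)
        n_micro = int(n_vol * TR / HRF.dt)
        psych = np.where(np.arange(n_micro) % 500 < 250, 1.0, -1.0)
        a = cn.build_ppi_regressor(seed_bold, psych, HRF, TR)
        b = cn.build_ppi_regressor(seed_bold, -psych, HRF, TR)
        np.testing.assert_allclose(a, -b, atol=1e-10)

    def test_zero_contrast_rejected(self, rng):
        with pytest.raises(ValueError, match="all zero"):
            cn.build_ppi_regressor(ar1_noise(40, 0.0, 1.0, rng), np.zeros(40), HRF, TR)


class TestEstimatePPI:
    def test_exact_null_with_linear_coupling(self):
        # target exactly proportional to the seed: identical slopes in both
        # conditions, interaction numerically zero
        study = coupling_study(n_volumes=100, seed=0, modulators=("INT",))
        params0 = cn.DCMParams(A=study.params.A, B={}, C=study.params.C)
        cfg = BoldSimConfig(n_volumes=105, noise_sd=0.0)
        bold = simulate_coupled_rois(study.model, study.inputs, params0, cfg)
        target = 0.7 * bold["mpfc"].to_numpy()
        res = cn.estimate_ppi(
            target, bold["mpfc"], study.psych, HRF, TR, prewhiten=False
        )
        assert abs(res.interaction) < 1e-8
        assert res.slopes["cond_pos"] == pytest.approx(0.7, abs=1e-8)

    def test_slope_difference_equals_interaction(self, rng):
        study = coupling_study(n_volumes=80, seed=3)
        cfg = BoldSimConfig(n_volumes=85, noise_sd=0.2, seed=4)
        bold = simulate_coupled_rois(study.model, study.inputs, study.params, cfg)
        res = cn.estimate_ppi(bold["tpj"], bold["mpfc"], study.psych, HRF, TR)
        assert res.interaction == pytest.approx(
            res.slopes["cond_pos"] - res.slopes["cond_neg"], abs=1e-12
        )

    def test_modulated_coupling_detected_positive(self):
        hits = 0
        for s in range(5):
            study = coupling_study(n_volumes=285, seed=s, modulators=("INT",))
            states = cn.simulate_dcm(study.model, study.inputs, study.params)
            bold = cn.states_to_bold(states, 285, TR, HRF)
            nsd = noise_sd_for_snr(bold, snr=1.0, rho=0.3)
            rng = np.random.default_rng(1000 + s)
            vox = bold[:, [1]] + ar1_noise(285, 0.3, nsd, rng, n_cols=20)
            seed_series = cn.extract_first_pc(vox)
            target = bold[:, 2] + ar1_noise(285, 0.3, nsd, rng)
            res = cn.estimate_ppi(target, seed_series, study.psych, HRF, TR)
            hits += res.interaction > 0
        assert hits >= 4


class TestModelSpace:
    def test_five_families_nested(self):
        fams = cn.enumerate_families()
        assert len(fams) == 5
        full = set(fams[0].edges)
        for fam in fams[1:]:
            assert set(fam.edges) <= full

    def test_minimal_family_single_forward_edge(self):
        fams = cn.enumerate_families()
        assert fams[4].edges == (("prep", "mpfc"),)

    def test_forty_models_eight_per_family(self):
        models = cn.enumerate_models()
        assert len(models) == 40
        ids = [m.id for m in models]
        assert len(set(ids)) == 40
        from collections import Counter

        per_family = Counter(m.family_id for m in models)
        assert all(per_family[f] == 8 for f in range(1, 6))
        # deterministic across calls
        assert ids == [m.id for m in cn.enumerate_models()]

    def test_b_masked_by_a(self):
        for m in cn.enumerate_models():
            a = m.a_mask
            for name, b in m.b_masks.items():
                assert not np.any(b & ~a)

    def test_backward_models_target_mpfc_to_tpj(self):
        models = {m.id: m for m in cn.enumerate_models()}
        tpj, mpfc = cn.REGIONS.index("tpj"), cn.REGIONS.index("mpfc")
        # family 2 has both mPFC-TPJ edges: backward PE model modulates
        # the top-down mPFC->TPJ entry, forward PE model the TPJ->mPFC entry
        assert models["f2_m6"].b_masks["PE"][tpj, mpfc]
        assert models["f2_m2"].b_masks["PE"][mpfc, tpj]


class TestSimulateDCM:
    def _simple_inputs(self, n_steps, dt=0.1, impulse=None):
        u = np.zeros((n_steps, 2))
        if impulse is not None:
            u[impulse, 0] = 1.0
        return cn.DCMInputs(
            u_drive=u, u_mod=np.zeros((n_steps, 0)), mod_names=(), dt=dt
        )

    def test_rest_stays_at_zero(self):
        model = cn.enumerate_models()[0]
        inputs = self._simple_inputs(100)
        params = cn.DCMParams(A=-np.eye(3), B={}, C=np.zeros((3, 2)))
        Z = cn.simulate_dcm(model, inputs, params)
        np.testing.assert_allclose(Z, 0.0)

    def test_exponential_decay_closed_form(self):
        # constant input on [0, 1) s then off: z(t) = 1 - e^-t, then decay
        dt = 0.01
        n_steps = 500
        model = cn.enumerate_models()[-1]  # family 5: prep->mpfc only
        u = np.zeros((n_steps, 2))
        u[: int(1.0 / dt), 0] = 1.0
        inputs = cn.DCMInputs(u_drive=u, u_mod=np.zeros((n_steps, 0)), mod_names=(), dt=dt)
        params = cn.DCMParams(
            A=-np.eye(3), B={}, C=np.array([[1.0, 0], [0, 0], [0, 0]])
        )
        Z = cn.simulate_dcm(model, inputs, params)
        t = np.arange(1, n_steps + 1) * dt
        expected = np.where(t <= 1.0, 1 - np.exp(-t), (1 - np.exp(-1.0)) * np.exp(-(t - 1.0)))
        np.testing.assert_allclose(Z[:, 0], expected, atol=1e-6)

    def test_rk4_refinement(self):
        study = coupling_study(n_volumes=40, dt=0.1, seed=0)
        Z1 = cn.simulate_dcm(study.model, study.inputs, study.params)
        fine = coupling_study(n_volumes=40, dt=0.01, seed=0)
        # the PE modulator is random per microtime step; silence it so the
        # two grids integrate the same right-hand side
        def silence(inp):
            um = inp.u_mod.copy()
            um[:, 1:] = 0.0
            return cn.DCMInputs(u_drive=inp.u_drive, u_mod=um, mod_names=inp.mod_names, dt=inp.dt)

        Z1 = cn.simulate_dcm(study.model, silence(study.inputs), study.params)
        Z10 = cn.simulate_dcm(fine.model, silence(fine.inputs), fine.params)
        coarse_at_fine = Z10[9::10][: Z1.shape[0]]
        rel = np.max(np.abs(Z1 - coarse_at_fine)) / max(np.max(np.abs(Z10)), 1e-12)
        assert rel < 1e-3

    def test_numba_and_python_paths_agree(self):
        study = coupling_study(n_volumes=40, seed=2)
        Z1 = cn.simulate_dcm(study.model, study.inputs, study.params, use_numba=True)
        Z2 = cn.simulate_dcm(study.model, study.inputs, study.params, use_numba=False)
        np.testing.assert_allclose(Z1, Z2, atol=1e-12)

    def test_unstable_a_rejected(self):
        model = cn.enumerate_models()[0]
        inputs = self._simple_inputs(10)
        params = cn.DCMParams(A=np.eye(3) * 0.1, B={}, C=np.zeros((3, 2)))
        with pytest.raises(cn.DCMInstabilityError, match="eigenvalue"):
            cn.simulate_dcm(model, inputs, params)


class TestFitDCM:
    def test_noiseless_self_recovery(self):
        study = coupling_study(n_volumes=100, seed=0)
        cfg = BoldSimConfig(n_volumes=105, noise_sd=0.0)
        bold = simulate_coupled_rois(study.model, study.inputs, study.params, cfg)
        fit = cn.fit_dcm_bic(bold.to_numpy(), study.model, study.inputs, tr=TR, hrf=HRF)
        true = study.params
        assert fit.params.A[1, 0] == pytest.approx(true.A[1, 0], rel=0.05)
        assert fit.params.A[2, 1] == pytest.approx(true.A[2, 1], rel=0.05)
        assert fit.params.B["INT"][2, 1] == pytest.approx(true.B["INT"][2, 1], rel=0.05)
        assert fit.params.C[0, 0] == pytest.approx(true.C[0, 0], rel=0.05)

    def test_unused_free_parameter_lowers_evidence(self):
        # fit the generating (INT-only) data with the INT model and with the
        # INT+PE+PExINT model: equal fit quality, more parameters, lower BIC
        study = coupling_study(n_volumes=80, seed=1, modulators=("INT",))
        cfg = BoldSimConfig(n_volumes=85, noise_sd=0.0)
        bold = simulate_coupled_rois(study.model, study.inputs, study.params, cfg)
        models = {m.id: m for m in cn.enumerate_models()}
        fit_true = cn.fit_dcm_bic(bold.to_numpy(), models["f2_m5"], study.inputs, tr=TR, hrf=HRF)
        fit_big = cn.fit_dcm_bic(bold.to_numpy(), models["f2_m8"], study.inputs, tr=TR, hrf=HRF)
        assert fit_big.n_free > fit_true.n_free
        assert fit_true.log_evidence > fit_big.log_evidence


class TestBMS:
    def test_symmetric_evidences_give_half(self):
        L = np.zeros((30, 2))
        res = cn.bms_exceedance(L, n_samples=50_000, seed=0)
        assert res.exceedance_p[0] == pytest.approx(0.5, abs=0.02)
        assert res.exceedance_p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exceedance_sums_to_one(self, rng):
        L = rng.normal(size=(12, 6))
        res = cn.bms_exceedance(L, n_samples=50_000, seed=1)
        assert res.exceedance_p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_model_quadrature_oracle(self, rng):
        # P(r1 > r2) under Dirichlet(a1, a2) is 1 - BetaCDF(1/2; a1, a2)
        L = rng.normal(size=(15, 2)) + np.array([0.8, 0.0])
        res = cn.bms_exceedance(L, n_samples=200_000, seed=2)
        a = res.alpha
        oracle = 1.0 - stats.beta.cdf(0.5, a[0], a[1])
        assert res.exceedance_p[0] == pytest.approx(oracle, abs=0.01)

    def test_dominant_model_wins(self):
        L = np.zeros((20, 3))
        L[:, 1] = 3.0  # consistently higher evidence
        res = cn.bms_exceedance(L, n_samples=50_000, seed=3)
        assert res.exceedance_p[1] > 0.95
        assert np.all(res.alpha >= 1.0)

    def test_family_aggregation(self):
        L = np.zeros((20, 4))
        L[:, 2:] = 2.0  # family b wins
        res = cn.bms_exceedance(
            L, grouping=[0, 0, 1, 1], n_samples=50_000, seed=4
        )
        assert res.family_exceedance_p[1] > 0.9
        assert res.family_exceedance_p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_model_trivial(self):
        with pytest.warns(UserWarning, match="single model"):
            res = cn.bms_exceedance(np.zeros((5, 1)), n_samples=10_000, seed=0)
        assert res.exceedance_p[0] == 1.0

    def test_all_inf_subject_rejected(self):
        L = np.zeros((3, 2))
        L[1] = -np.inf
        with pytest.raises(ValueError, match="every model"):
            cn.bms_exceedance(L)
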