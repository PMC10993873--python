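"""DSC perfusion: concentration conversion, AIF extraction, oSVD, CBV/MTT."""

import numpy as np
import pytest

from strokefate.acquisition import (
    AcquisitionConfig,
    forward_concentration,
    gamma_variate_aif,
    simulate_dsc,
)
from strokefate.image import DscSeries, hemisphere_masks
from strokefate.perfusion import (
    compute_cbv,
    compute_mtt,
    deconvolve_perfusion,
    extract_aif,
    oscillation_index,
    osvd_deconvolve,
    signal_to_concentration,
)
from strokefate.phantom import make_phantom
from strokefate.validation import simulate_recovery_voxels


def make_series(conc, te_ms=13.0, tr_ms=164.0, s0=1000.0, bolus=180, trunc=400):
    """Signal series from a (nx,ny,nz,nt) concentration array."""
    sig = s0 * np.exp(-(te_ms / 1000.0) * conc)
    return DscSeries.from_ordinals(sig, bolus, trunc, tr_ms=tr_ms, te_ms=te_ms)


class TestSignalToConcentration:
    def test_flat_signal_gives_zero(self):
        conc = np.zeros((2, 2, 1, 450))
        out = signal_to_concentration(make_series(conc))
        assert np.allclose(out.values, 0.0)

    def test_exact_inversion(self):
        rng = np.random.default_rng(0)
        conc = np.zeros((2, 2, 1, 450))
        conc[..., 200:300] = rng.uniform(0, 30, (2, 2, 1, 100))
        out = signal_to_concentration(make_series(conc))
        assert np.allclose(out.values, conc, atol=1e-10)

    def test_simulator_roundtrip_noiseless(self):
        ph = make_phantom(seed=1).downsample((4, 4, 2))
        cfg = AcquisitionConfig(noise_sd=0.0, dsc_noise_sd=0.0)
        series, planted = simulate_dsc(ph, cfg, return_concentration=True)
        out = signal_to_concentration(series)
        brain = ph.brain_mask
        assert np.abs(out.values[brain] - planted[brain]).max() < 1e-9

    def test_empty_baseline_window_rejected(self):
        conc = np.zeros((1, 1, 1, 450))
        with pytest.raises(ValueError):
            signal_to_concentration(make_series(conc), baseline_window=(50, 20))

    def test_baseline_must_precede_bolus(self):
        conc = np.zeros((1, 1, 1, 450))
        with pytest.raises(ValueError, match="bolus"):
            signal_to_concentration(make_series(conc), baseline_window=(20, 200))

    def test_nonpositive_signal_masked(self):
        conc = np.zeros((1, 1, 1, 450))
        series = make_series(conc)
        data = series.data.copy()
        data[0, 0, 0, 210] = -5.0
        series = DscSeries.from_ordinals(data, 180, 400)
        out = signal_to_concentration(series)
        assert out.masked_frames[0, 0, 0, 210]
        assert out.values[0, 0, 0, 210] == 0.0


class TestExtractAif:
    def _conc_series(self, values, bolus=179):
        from strokefate.perfusion import ConcentrationSeries

        nt = values.shape[-1]
        return ConcentrationSeries(
            values=values,
            frame_interval_s=0.164,
            baseline_window=(19, 169),
            bolus_frame=bolus,
            truncation_frame=399,
            valid=np.ones(values.shape[:3], dtype=bool),
            masked_frames=np.zeros(values.shape, dtype=bool),
        )

    def test_single_voxel_mask_returns_that_curve(self):
        vals = np.zeros((4, 4, 1, 450))
        curve = gamma_variate_aif(450, 0.164, 179)
        vals[1, 2, 0] = curve
        conc = self._conc_series(vals)
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[1, 2, 0] = True
        aif = extract_aif(conc, mask)
        assert np.allclose(aif.curve, curve)
        assert aif.peak_frame > 179

    def test_identical_voxels_any_k(self):
        vals = np.zeros((4, 4, 1, 450))
        curve = gamma_variate_aif(450, 0.164, 179)
        vals[:, :, 0, :] = curve
        conc = self._conc_series(vals)
        mask = np.ones((4, 4, 1), dtype=bool)
        for k in (1, 5, 100):
            assert np.allclose(extract_aif(conc, mask, k=k).curve, curve)

    def test_empty_mask_rejected(self):
        conc = self._conc_series(np.zeros((2, 2, 1, 450)))
        with pytest.raises(ValueError, match="empty"):
            extract_aif(conc, np.zeros((2, 2, 1), dtype=bool))

    def test_no_post_bolus_peak_rejected(self):
        conc = self._conc_series(np.zeros((2, 2, 1, 450)))
        with pytest.raises(ValueError, match="peak"):
            extract_aif(conc, np.ones((2, 2, 1), dtype=bool))

    def test_selects_planted_arterial_voxels(self):
        """Arterial voxels (tall, early, narrow curves) win the ranking."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            ph = make_phantom(seed=seed).downsample((2, 2, 1))
            cfg = AcquisitionConfig(seed=seed)
            series = simulate_dsc(ph, cfg, timepoint="post_0.5h")
            conc = signal_to_concentration(series)
            left, _ = hemisphere_masks(ph.shape)
            aif = extract_aif(conc, left, k=5)
            arterial = ph.arterial_mask
            sel_ok = all(arterial[tuple(v)] for v in aif.source_voxels)
            hits += sel_ok
        assert hits >= 95


class TestOsvd:
    def test_impulse_aif_identity(self):
        """With a unit-impulse AIF the deconvolution returns the residue."""
        dt, L = 1.0, 64
        aif = np.zeros(L)
        aif[5] = 1.0 / dt  # discrete delta with unit integral
        r_true = np.exp(-np.arange(L) / 6.0)
        r_true[L - 5 :] = 0.0  # finite support: convolution fits the window
        c = 3.0 * dt * np.convolve(aif, r_true)[:L]
        cbf, residues, oi, cut = osvd_deconvolve(c, aif, dt=dt)
        assert cbf[0] == pytest.approx(3.0, rel=1e-6)
        # the common bolus delay cancels: the residue is recovered at lag 0
        assert np.allclose(residues[0], 3.0 * r_true, atol=1e-6)

    def test_zero_tissue_curve_gives_zero_cbf(self):
        dt, L = 1.0, 64
        aif = gamma_variate_aif(L, dt, 5)
        cbf, residues, oi, cut = osvd_deconvolve(np.zeros(L), aif, dt=dt)
        assert cbf[0] == 0.0
        assert np.allclose(residues[0], 0.0)

    def test_all_zero_aif_rejected(self):
        with pytest.raises(ValueError, match="AIF"):
            osvd_deconvolve(np.ones(64), np.zeros(64), dt=1.0)

    def test_scale_equivariance(self):
        exp = simulate_recovery_voxels(8, seed=3)
        cbf1, *_ = osvd_deconvolve(exp.conc, exp.aif, dt=exp.dt)
        cbf2, *_ = osvd_deconvolve(3.0 * exp.conc, exp.aif, dt=exp.dt)
        cbf3, *_ = osvd_deconvolve(exp.conc, 2.0 * exp.aif, dt=exp.dt)
        assert np.allclose(cbf2, 3.0 * cbf1, rtol=1e-9)
        assert np.allclose(cbf3, cbf1 / 2.0, rtol=1e-9)

    def test_selected_residues_satisfy_oi_bound(self):
        exp = simulate_recovery_voxels(100, seed=4, snr=50)
        _, residues, oi, cut = osvd_deconvolve(exp.conc, exp.aif, 0.17, dt=exp.dt)
        # Every voxel not forced to the strongest rung satisfies the bound
        forced = cut == 0.50
        assert np.all(oi[~forced] <= 0.17 + 1e-12)
        recomputed = oscillation_index(residues, residues.shape[1])
        assert np.allclose(recomputed, oi, atol=1e-12)

    def test_noiseless_recovery_within_tolerance(self):
        exp = simulate_recovery_voxels(200, seed=5)
        est, *_ = osvd_deconvolve(exp.conc, exp.aif, 0.17, dt=exp.dt)
        rel = np.abs(est - exp.cbf) / exp.cbf
        assert rel.max() < 0.05


class TestCbvMtt:
    def test_zero_concentration_zero_cbv(self):
        assert compute_cbv(np.zeros((3, 120)), truncation_index=100, dt=1.0).max() == 0

    def test_constant_concentration_rectangle(self):
        conc = np.full((1, 120), 2.5)
        cbv = compute_cbv(conc, truncation_index=101, dt=1.0)
        assert cbv[0] == pytest.approx(2.5 * 100.0)  # trapezoid over 100 s

    def test_truncation_contract_bit_exact(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 5, (10, 450))
        b = a.copy()
        b[:, 400:] = rng.uniform(50, 99, (10, 50))  # differ only past frame 400
        cbv_a = compute_cbv(a, truncation_index=400, dt=0.164)
        cbv_b = compute_cbv(b, truncation_index=400, dt=0.164)
        assert np.array_equal(cbv_a, cbv_b)

    def test_cbv_linear_in_concentration(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 5, (4, 200))
        b = rng.uniform(0, 5, (4, 200))
        s = compute_cbv(a + b, truncation_index=150, dt=1.0)
        assert np.allclose(
            s,
            compute_cbv(a, truncation_index=150, dt=1.0)
            + compute_cbv(b, truncation_index=150, dt=1.0),
        )

    def test_mtt_quotient_and_masking(self):
        cbv = np.array([[8.0, 8.0]])
        cbf = np.array([[2.0, 0.0]])
        mtt = compute_mtt(cbv, cbf)
        assert mtt[0, 0] == 4.0
        assert mtt[0, 1] == 0.0  # masked, not inf

    def test_mtt_grid_mismatch(self):
        with pytest.raises(ValueError):
            compute_mtt(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_noiseless_mtt_recovery_within_10pct(self):
        """CBV/CBF at the in-vivo frame interval matches planted MTT."""
        exp = simulate_recovery_voxels(
            40, seed=9, dt=0.164, n_frames=1024, t0_frame=30
        )
        est_cbf, *_ = osvd_deconvolve(exp.conc, exp.aif, dt=exp.dt)
        cbv = compute_cbv(exp.conc, truncation_index=1024, dt=exp.dt, aif=exp.aif)
        est_mtt = compute_mtt(cbv, est_cbf)
        assert np.all(np.abs(est_mtt - exp.mtt) / exp.mtt < 0.10)


def test_deconvolve_perfusion_maps_identity(phantom):
    """End-to-end maps: MTT = CBV/CBF holds exactly wherever CBF > 0."""
    ph = phantom.downsample((2, 2, 1))
    cfg = AcquisitionConfig(noise_sd=0.0, dsc_noise_sd=0.0)
    series = simulate_dsc(ph, cfg, timepoint="post_0.5h")
    conc = signal_to_concentration(series)
    left, _ = hemisphere_masks(ph.shape)
    aif = extract_aif(conc, left)
    pm = deconvolve_perfusion(conc, aif)
    pos = pm.cbf.data > 0
    assert np.allclose(pm.mtt.data[pos], pm.cbv.data[pos] / pm.cbf.data[pos])
    assert np.all(pm.cbv.data >= 0)
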