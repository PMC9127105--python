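"""K-space sampling, reconstruction, presets, geometry and orchestration."""

import numpy as np
import pytest

from fsesim.acquisition import (KSpaceSlice, SequenceParams, assign_lines,
                                build_slice_geometry, derive_geometry,
                                fermi_window, finalize_slice, haste_preset,
                                kspace_to_image, make_reference_volume,
                                project_slice, sample_kspace, simulate_protocol,
                                simulate_series, slice_acquisition_order,
                                slice_profile, ssfse_preset)
from fsesim.epg import T2DecayMatrix
from fsesim.anatomy import classify_tissues

from .conftest import make_toy_seq


def unit_decay(phantom, etl=64, esp=5.0):
    """Decay matrix with relaxation disabled: every foreground echo is 1."""
    fg = (phantom.labels > 0).astype(np.int32)
    return T2DecayMatrix(combo_index=fg,
                         amplitudes=np.vstack([np.zeros(etl), np.ones(etl)]),
                         echo_times_ms=(np.arange(etl) + 1) * esp,
                         spacing=phantom.spacing, origin=phantom.origin)


class TestSliceProfile:
    def test_fwhm_equals_thickness(self):
        off, w = slice_profile(3.0, fine_step_mm=0.1)
        half = w.max() / 2
        above = off[w >= half]
        fwhm = above.max() - above.min()
        assert fwhm == pytest.approx(3.0, abs=0.1)

    def test_weights_sum_to_one(self):
        _, w = slice_profile(4.0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_half_maximum_identity(self):
        """Gaussian with FWHM = t: weight(0) / weight(t/2) = 2 exactly."""
        off, w = slice_profile(3.0, fine_step_mm=0.1)
        c = w[np.argmin(np.abs(off))]
        h = w[np.argmin(np.abs(off - 1.5))]
        assert c / h == pytest.approx(2.0, rel=1e-9)

    def test_truncation_bound(self):
        off, _ = slice_profile(3.0)
        assert off.min() == pytest.approx(-4.5) and off.max() == pytest.approx(4.5)


class TestDeriveGeometry:
    def test_haste_protocol_numbers(self):
        spec = derive_geometry(haste_preset())
        assert spec.in_plane_voxel_mm == pytest.approx(1.13)
        assert spec.n_phase_lines == 404
        assert spec.scan_time_s == pytest.approx(36.0)   # 30 slices x 1.2 s

    def test_ssfse_recon_grid(self):
        seq = ssfse_preset(1.5)
        assert derive_geometry(seq).recon_shape == (512, 512)
        assert seq.zip_fill

    def test_phase_lines_rounded_to_even(self):
        seq = make_toy_seq(base_resolution=50, phase_resolution=0.7,
                           phase_oversampling=0.0, fov_mm=100,
                           effective_te_ms=50.0)
        assert derive_geometry(seq).n_phase_lines % 2 == 0


class TestPresets:
    def test_haste_values(self):
        seq = haste_preset()
        assert seq.noise_sd == 0.15
        assert seq.effective_te_ms == 90.0
        assert seq.echo_spacing_ms == 4.08
        assert seq.echo_train_length == 224
        assert seq.acceleration_factor == 2
        assert seq.n_reference_lines == 42
        assert seq.slice_gap_mm == pytest.approx(0.3)

    def test_ssfse_values(self):
        seq = ssfse_preset(1.5)
        assert seq.noise_sd == 0.01
        assert seq.echo_spacing_ms == 10.0
        assert seq.reconstruction_matrix == (512, 512)
        assert seq.slice_gap_mm == 0.0

    def test_presets_validate(self):
        for seq in (haste_preset(), ssfse_preset(1.5), ssfse_preset(3.0)):
            seq.validate()

    def test_invalid_flip_rejected(self):
        with pytest.raises(ValueError):
            make_toy_seq(refocusing_flip_deg=190.0)


class TestAssignLines:
    def test_dc_line_acquired_at_effective_te(self):
        """P = 8, TE at echo 4 -> the DC line is the 4th line acquired."""
        seq = make_toy_seq(base_resolution=8, fov_mm=32, echo_train_length=8,
                           effective_te_ms=20.0, echo_spacing_ms=5.0)
        plan = assign_lines(seq)
        assert plan.n_phase == 8 and plan.dc_index == 4
        order = list(plan.sampled)
        assert order.index(4) + 1 == 4            # 4th acquired
        assert plan.echo_of_line[order.index(4)] == 3

    def test_haste_band_and_stride(self):
        plan = assign_lines(haste_preset())
        dc = plan.dc_index
        band = set(range(dc - 21, dc + 21))
        sampled = set(int(i) for i in plan.sampled)
        assert band <= sampled | set(plan.grappa_copies)   # band fully handled
        in_band = sorted(i for i in sampled if i in band)
        assert np.all(np.diff(in_band) == 1)               # consecutive
        above = sorted(i for i in sampled if i >= dc + 21)
        assert np.all(np.diff(above) == 2)                 # stride 2 outside

    def test_line_count_within_echo_train(self):
        for seq in (haste_preset(), ssfse_preset(1.5)):
            plan = assign_lines(seq)
            assert len(plan.sampled) == len(set(map(int, plan.sampled)))
            assert len(plan.sampled) <= seq.echo_train_length

    def test_echo_train_too_short_rejected(self):
        seq = make_toy_seq(echo_train_length=16, effective_te_ms=40.0)
        with pytest.raises(ValueError, match="echo train"):
            assign_lines(seq)


class TestFermiWindow:
    def test_stated_values(self):
        w = fermi_window((64, 64))
        P = 64
        # rho = 0 at DC -> ~1; rho = 0.85 -> exactly 0.5
        assert w[P // 2, P // 2] == pytest.approx(1.0, abs=1e-8)
        rho = 0.85
        j = P // 2 + int(round(rho * P / 2))
        val = 1.0 / (1.0 + np.exp((abs(j - P // 2) / (P / 2) - 0.85) * 23.0))
        assert w[P // 2, j] == pytest.approx(val, abs=1e-12)
        direct = 1.0 / (1.0 + np.exp((0.85 - 0.85) / (1 / 23)))
        assert direct == pytest.approx(0.5)

    def test_radially_monotone_and_bounded(self):
        w = fermi_window((32, 48))
        assert w.max() <= 1.0
        center = w[16, 24:]
        assert np.all(np.diff(center) <= 1e-15)


class TestSampleAndFinalize:
    def test_identity_limit(self, small_phantom):
        """Static, noiseless, full-Fourier, relaxation-disabled acquisition
        reproduces the projected object to 1e-9 relative."""
        seq = make_toy_seq(fov_mm=128, base_resolution=32, n_slices=3,
                          effective_te_ms=85.0)       # TE at echo 17 = P/2+1
        decay = unit_decay(small_phantom)
        geom = build_slice_geometry(seq, small_phantom.world_center())
        obj = project_slice(decay, geom, 1, echo=0)
        ks = sample_kspace(decay, geom, 1, seq=seq)
        assert ks.plan.hermitian_lines.size == 0      # truly full sampling
        img = finalize_slice(ks, seq)
        assert np.max(np.abs(img - obj)) / obj.max() < 1e-9

    def test_hermitian_fill_imaginary_residual(self, small_phantom):
        """Half-Fourier of a static real object leaves a tiny imaginary part."""
        seq = make_toy_seq(fov_mm=128, base_resolution=32, n_slices=3,
                          effective_te_ms=25.0)       # early TE -> partial Fourier
        decay = unit_decay(small_phantom)
        geom = build_slice_geometry(seq, small_phantom.world_center())
        ks = sample_kspace(decay, geom, 1, seq=seq)
        assert ks.plan.hermitian_lines.size > 0
        cimg = kspace_to_image(ks.data)
        assert np.max(np.abs(cimg.imag)) < 1e-8 * np.max(np.abs(cimg))

    def test_grappa_copied_lines_identical_to_source(self, small_phantom):
        seq = make_toy_seq(fov_mm=128, base_resolution=32, n_slices=3,
                          echo_train_length=32, effective_te_ms=40.0,
                          acceleration_factor=2, n_reference_lines=8)
        decay = unit_decay(small_phantom, etl=32)
        geom = build_slice_geometry(seq, small_phantom.world_center())
        ks = sample_kspace(decay, geom, 1, seq=seq)
        assert ks.plan.grappa_copies
        for missing, src in ks.plan.grappa_copies.items():
            assert np.array_equal(ks.data[missing], ks.data[src])

    def test_projection_truncation_bound(self, small_phantom):
        """Slices farther than 1.5 x thickness from any tissue are zero."""
        seq = make_toy_seq(fov_mm=128, base_resolution=32, n_slices=40,
                          effective_te_ms=85.0)
        decay = unit_decay(small_phantom)
        geom = build_slice_geometry(seq, small_phantom.world_center())
        obj = project_slice(decay, geom, 0, echo=0)   # far outside the head
        assert np.all(obj == 0)

    def test_delta_at_dc_gives_constant_image(self):
        seq = make_toy_seq(base_resolution=16, fov_mm=64, effective_te_ms=45.0,
                          echo_train_length=16)
        k = np.zeros((16, 16), complex)
        k[8, 8] = 1.0
        ks = KSpaceSlice(data=k, sampled_mask=np.ones(16, bool),
                         plan=assign_lines(seq))
        img = finalize_slice(ks, seq)
        assert np.ptp(img) < 1e-12

    def test_noise_propagation_through_unitary_ift(self):
        """Image-domain noise SD equals the k-space SD (orthonormal FT)."""
        rng = np.random.default_rng(0)
        sd = 0.15
        vals = []
        for _ in range(100):
            k = rng.normal(0, sd, (32, 32)) + 1j * rng.normal(0, sd, (32, 32))
            vals.append(np.std(kspace_to_image(k).real))
        assert np.mean(vals) == pytest.approx(sd, rel=0.05)

    def test_zip_preserves_field_of_view(self, small_phantom):
        """ZIP doubles the grid and halves the pixel pitch; extent in mm holds."""
        seq = make_toy_seq(fov_mm=128, base_resolution=32, n_slices=3,
                          effective_te_ms=85.0)
        seq_zip = make_toy_seq(fov_mm=128, base_resolution=32, n_slices=3,
                              effective_te_ms=85.0,
                              reconstruction_matrix=(64, 64), zip_fill=True)
        decay = unit_decay(small_phantom)
        g1 = build_slice_geometry(seq, small_phantom.world_center())
        g2 = build_slice_geometry(seq_zip, small_phantom.world_center())
        assert g2.final_pitch_mm[1] == pytest.approx(g1.final_pitch_mm[1] / 2)
        i1 = finalize_slice(sample_kspace(decay, g1, 1, seq=seq), seq)
        i2 = finalize_slice(sample_kspace(decay, g2, 1, seq=seq_zip), seq_zip)
        r1 = i1[16] > 0.5 * i1.max()
        r2 = i2[32] > 0.5 * i2.max()
        w1 = r1.sum() * g1.final_pitch_mm[1]
        w2 = r2.sum() * g2.final_pitch_mm[1]
        assert abs(w1 - w2) <= 2 * g1.final_pitch_mm[1]


class TestSeriesOrchestration:
    def test_noiseless_static_runs_are_identical(self, slab_phantom, toy_props,
                                                 toy_seq):
        a = simulate_series(slab_phantom, toy_seq, motion_level="none", seed=5,
                            props=toy_props)
        b = simulate_series(slab_phantom, toy_seq, motion_level="none", seed=5,
                            props=toy_props)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.label_series, b.label_series)

    def test_corruption_cap_in_output(self, slab_phantom, toy_props):
        seq = make_toy_seq(n_slices=30)
        s = simulate_series(slab_phantom, seq, motion_level="strong", seed=9,
                            props=toy_props)
        assert s.trajectory.corrupted.sum() <= 0.05 * 30

    def test_fov_shift_moves_slice_centers(self, slab_phantom, toy_props, toy_seq):
        a = simulate_series(slab_phantom, toy_seq, motion_level="none", seed=1,
                            props=toy_props, fov_shift_mm=1.6)
        b = simulate_series(slab_phantom, toy_seq, motion_level="none", seed=1,
                            props=toy_props, fov_shift_mm=-1.6)
        diff = a.geometry.slice_positions_mm - b.geometry.slice_positions_mm
        assert np.allclose(diff, 3.2)

    def test_interleaved_slice_order(self):
        order = slice_acquisition_order(7)
        assert list(order) == [0, 2, 4, 6, 1, 3, 5]
        assert list(slice_acquisition_order(4, "sequential")) == [0, 1, 2, 3]

    def test_label_series_matches_geometry(self, slab_phantom, toy_props, toy_seq):
        s = simulate_series(slab_phantom, toy_seq, motion_level="none", seed=0,
                            props=toy_props)
        assert s.label_series.shape == (toy_seq.n_slices,) + s.geometry.final_shape
        assert set(np.unique(s.label_series)) <= set(np.unique(slab_phantom.labels))

    def test_series_save_sidecar(self, tmp_path, slab_phantom, toy_props, toy_seq):
        import yaml
        s = simulate_series(slab_phantom, toy_seq, motion_level="little", seed=2,
                            props=toy_props)
        s.save(tmp_path)
        sidecar = yaml.safe_load((tmp_path / "series.yaml").read_text())
        assert sidecar["seed"] == 2
        assert len(sidecar["corrupted_slices"]) <= 0.05 * toy_seq.n_slices


class TestProtocol:
    def test_protocol_set(self, slab_phantom, toy_props):
        seq = make_toy_seq(n_slices=4, base_resolution=16, fov_mm=64,
                          effective_te_ms=45.0, echo_train_length=16)
        series = simulate_protocol(slab_phantom, seq, seed=3, props=toy_props)
        assert len(series) == 9
        assert {s.geometry.orientation for s in series} == \
            {"sagittal", "coronal", "transverse"}
        levels = [s.trajectory.level for s in series]
        assert levels.count("little") == 6 and levels.count("moderate") == 3
        seeds = [s.seed for s in series]
        assert len(set(seeds)) == 9
        again = simulate_protocol(slab_phantom, seq, seed=3, props=toy_props)
        assert [t.seed for t in again] == seeds


class TestReferenceVolume:
    def test_isotropic_noiseless_reference(self, slab_phantom, toy_props):
        seq = make_toy_seq(base_resolution=32, fov_mm=128, effective_te_ms=85.0)
        ref = make_reference_volume(slab_phantom, seq, props=toy_props)
        pp, fp = ref.geometry.final_pitch_mm
        pitch = 128 / 32
        assert pp == pytest.approx(pitch) and fp == pytest.approx(pitch)
        dz = np.diff(ref.geometry.slice_positions_mm)
        assert np.allclose(dz, pitch)                  # contiguous thin slices
        assert ref.seq.noise_sd == 0.0
        again = make_reference_volume(slab_phantom, seq, props=toy_props)
        assert np.array_equal(ref.images, again.images)
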