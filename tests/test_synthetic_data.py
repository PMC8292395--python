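"""Unit and property tests for the cell-shape and micropattern simulator."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from cyclostretch import (
    CellMask,
    DynamicsParams,
    StretchProtocol,
    apply_substrate_strain,
    make_initial_cell,
    make_micropattern,
    preset_params,
    simulate_timecourse,
    step_cycle,
    waveform_strain,
)
from cyclostretch.errors import (
    ConfigurationError,
    DimensionError,
    DynamicsError,
    InputError,
)
from cyclostretch.synthetic_data import CONDITIONS


# ------------------------------------------------------------------ waveform


class TestWaveform:
    def test_square_holds_amplitude_in_stretch_window(self):
        p = StretchProtocol(waveform="square", amplitude=0.15)
        assert waveform_strain(p, 0.5) == pytest.approx(0.15)

    def test_zero_at_cycle_start_for_all_waveforms(self):
        for wf in ("square", "triangular", "trapezoid"):
            p = StretchProtocol(waveform=wf)
            assert waveform_strain(p, 0.0) == 0.0
            assert waveform_strain(p, p.period) == 0.0

    def test_triangular_ramp_values(self):
        # piecewise-linear ramp peaking mid-window, checked against a dense
        # numeric tabulation of the triangle
        p = StretchProtocol(waveform="triangular", amplitude=0.15, frequency=0.5)
        assert waveform_strain(p, 0.5) == pytest.approx(0.15)
        assert waveform_strain(p, 0.25) == pytest.approx(0.075)
        t = np.linspace(0, p.stretch_duration, 101)
        expected = 0.15 * (1 - np.abs(t - 0.5) / 0.5)
        np.testing.assert_allclose(waveform_strain(p, t), expected, atol=1e-12)

    def test_trapezoid_ramps_and_dwells(self):
        p = StretchProtocol(waveform="trapezoid", ramp_time=0.25)
        assert waveform_strain(p, 0.125) == pytest.approx(p.amplitude / 2)
        assert waveform_strain(p, 0.6) == pytest.approx(p.amplitude)  # dwell high
        assert waveform_strain(p, 1.5) == 0.0  # dwell low

    def test_unknown_waveform_rejected(self):
        with pytest.raises(ConfigurationError):
            StretchProtocol(waveform="sawtooth")

    @given(
        t=st.floats(0, 100),
        wf=st.sampled_from(["square", "triangular", "trapezoid"]),
    )
    def test_bounded_and_periodic(self, t, wf):
        p = StretchProtocol(waveform=wf, amplitude=0.18)
        eps = waveform_strain(p, t)
        assert 0.0 <= eps <= 0.18
        # periodicity checked away from the waveform breakpoints, where a
        # float epsilon legitimately lands on the other side of the step
        tin = t % p.period
        breakpoints = (0.0, p.ramp_time, p.stretch_duration / 2,
                       p.stretch_duration, p.stretch_duration + p.ramp_time, p.period)
        assume(min(abs(tin - b) for b in breakpoints) > 1e-6)
        assert waveform_strain(p, t + p.period) == pytest.approx(eps, abs=1e-6)


class TestProtocolInvariants:
    def test_amplitude_range_enforced(self):
        with pytest.raises(ConfigurationError):
            StretchProtocol(amplitude=0.25)
        with pytest.raises(ConfigurationError):
            StretchProtocol(amplitude=0.0)

    def test_durations_must_sum_to_period(self):
        with pytest.raises(ConfigurationError):
            StretchProtocol(stretch_duration=0.7, relax_duration=0.7, frequency=0.5)

    def test_transverse_ratio_capped(self):
        with pytest.raises(ConfigurationError):
            StretchProtocol(transverse_ratio=0.3)


# ------------------------------------------------------------- initial cell


class TestMakeInitialCell:
    def test_disc_area_matches_pi_r_squared(self, disc_mask):
        assert disc_mask.area_um2 == pytest.approx(np.pi * 25**2, rel=0.02)

    def test_disc_is_circular(self, disc_mask):
        from cyclostretch import fit_ellipse

        fit = fit_ellipse(disc_mask)
        assert fit.eccentricity < 0.01
        assert fit.theta == 0.0  # tie-break

    def test_same_seed_is_bitwise_identical(self):
        a = make_initial_cell(25, 0.2, seed=7)
        b = make_initial_cell(25, 0.2, seed=7)
        assert np.array_equal(a.pixels, b.pixels)

    def test_irregular_mask_is_valid_single_component(self):
        m = make_initial_cell(25, 0.3, seed=1)
        m.validate()

    def test_oversized_cell_rejected(self):
        with pytest.raises(DimensionError):
            make_initial_cell(radius=200, pixel_size=0.5, image_shape=(256, 256))


# ---------------------------------------------------------- substrate strain


class TestApplySubstrateStrain:
    def test_zero_strain_is_identity(self, disc_mask):
        assert apply_substrate_strain(disc_mask, 0.0, 0.0) is disc_mask

    def test_axial_extent_scales(self, disc_mask):
        from cyclostretch import fit_rectangle

        out = apply_substrate_strain(disc_mask, 0.15, 0.0)
        ax0, tr0 = fit_rectangle(disc_mask)
        ax1, tr1 = fit_rectangle(out)
        # within one pixel of the analytic scaled extent
        assert abs(ax1 - ax0 * 1.15) <= 1.01 * disc_mask.pixel_size
        assert tr1 == pytest.approx(tr0, abs=disc_mask.pixel_size)

    def test_round_trip_jaccard(self, disc_mask):
        eps_ax, eps_tr = 0.15, -0.0225
        fwd = apply_substrate_strain(disc_mask, eps_ax, eps_tr)
        back = apply_substrate_strain(fwd, 1 / (1 + eps_ax) - 1, 1 / (1 + eps_tr) - 1)
        inter = np.logical_and(back.pixels, disc_mask.pixels).sum()
        union = np.logical_or(back.pixels, disc_mask.pixels).sum()
        assert inter / union > 0.98

    def test_y_stretch_axis_scales_rows(self, disc_mask):
        mask_y = disc_mask.replace(stretch_axis="y")
        out = apply_substrate_strain(mask_y, 0.2, 0.0)
        rows = np.nonzero(out.pixels)[0]
        rows0 = np.nonzero(disc_mask.pixels)[0]
        assert (rows.max() - rows.min()) == pytest.approx(
            (rows0.max() - rows0.min()) * 1.2, abs=2
        )


# ------------------------------------------------------------------ dynamics


class TestStepCycle:
    def test_null_dynamics_returns_identical_mask(self, disc_mask):
        params = DynamicsParams(r0=0, p_T=0, p_A0=0, noise_sigma=0)
        out = step_cycle(disc_mask, params, 1, 1.0, np.random.default_rng(0))
        assert np.array_equal(out.pixels, disc_mask.pixels)

    def test_retraction_removes_target_area_fraction(self, disc_mask):
        params = DynamicsParams(r0=0.2, p_T=0, p_A0=0, noise_sigma=0)
        out = step_cycle(disc_mask, params, 1, 1.0, np.random.default_rng(0))
        removed = 1 - out.area_um2 / disc_mask.area_um2
        assert removed == pytest.approx(0.2, rel=0.05)

    def test_retraction_decay_matches_rate_law(self, disc_mask):
        # measured removed-area ratio across cycles vs the closed form
        params = DynamicsParams(r0=0.1, r_decay=1.5, p_T=0, p_A0=0, noise_sigma=0)
        rng = np.random.default_rng(0)
        c1 = step_cycle(disc_mask, params, 1, 1.0, rng)
        c2 = step_cycle(c1, params, 2, 1.0, rng)
        removed1 = disc_mask.area_um2 - c1.area_um2
        removed2 = c1.area_um2 - c2.area_um2
        # normalize by the area each retraction acted on
        ratio = (removed2 / c1.area_um2) / (removed1 / disc_mask.area_um2)
        assert ratio == pytest.approx(np.exp(-1 / 1.5), rel=0.10)

    def test_retraction_emptying_cell_raises(self, disc_mask):
        params = DynamicsParams(r0=1.0, p_T=0, p_A0=0, noise_sigma=0)
        with pytest.raises(DynamicsError):
            step_cycle(disc_mask, params, 1, 1.0, np.random.default_rng(0))

    def test_output_stays_single_component(self):
        cell = make_initial_cell(25, 0.25, seed=3)
        params = preset_params("control")
        rng = np.random.default_rng(3)
        out = step_cycle(cell, params, 1, 300.0, rng)
        out.validate()  # raises if fragmented, empty, or touching border

    def test_transverse_length_nondecreasing_under_control(self, control_bundle):
        # relaxed-state transverse extent never shrinks across checkpoints
        for _, cell_tc in control_bundle.shape_timecourse.groupby("cell_id"):
            tr = cell_tc.sort_values("time_s").transverse_length_um.to_numpy()
            assert (np.diff(tr) >= 0).all()


class TestSimulateTimecourse:
    def _protocol(self, n_cycles=3, samples=()):
        return StretchProtocol(n_cycles=n_cycles, sample_points=tuple(samples))

    def test_single_pre_stretch_frame_equals_input(self, disc_mask):
        proto = self._protocol(samples=[(1, "pre_stretch")])
        frames, truth = simulate_timecourse(
            proto, DynamicsParams(r0=0, p_T=0, p_A0=0, noise_sigma=0), disc_mask, 0
        )
        assert len(frames) == 1
        assert np.array_equal(frames[0].pixels, disc_mask.pixels)

    def test_during_stretch_is_affine_image_of_pre_stretch(self, disc_mask):
        proto = self._protocol(samples=[(1, "pre_stretch"), (1, "during_stretch")])
        params = DynamicsParams(r0=0, p_T=0, p_A0=0, noise_sigma=0)
        frames, _ = simulate_timecourse(proto, params, disc_mask, 0)
        pre = next(f for f in frames if f.phase_tag == "pre_stretch")
        during = next(f for f in frames if f.phase_tag == "during_stretch")
        expected = apply_substrate_strain(
            pre, proto.amplitude, -proto.transverse_ratio * proto.amplitude
        )
        assert np.array_equal(during.pixels, expected.pixels)

    def test_schedule_beyond_n_cycles_rejected(self, disc_mask):
        with pytest.raises(ConfigurationError):
            StretchProtocol(n_cycles=2, sample_points=((5, "pre_stretch"),))

    def test_ground_truth_mass_bookkeeping(self, disc_mask):
        # logged (protrusion - retraction) must equal the measured area change
        params = DynamicsParams(
            r0=0.05, r_decay=2.0, p_T=0.01, p_A0=0.005, p_A_tau=5, noise_sigma=0.3
        )
        proto = self._protocol(n_cycles=3)
        _, truth = simulate_timecourse(proto, params, disc_mask, seed=1)
        area = np.concatenate([[disc_mask.area_um2], truth.area_um2.to_numpy()])
        logged = (
            truth.protrusion_T_um2 + truth.protrusion_A_um2 - truth.retraction_area_um2
        ).to_numpy()
        np.testing.assert_allclose(np.diff(area), logged, rtol=0.05, atol=1e-6)

    def test_protrusion_totals_match_rate_law(self, disc_mask):
        params = DynamicsParams(r0=0, p_T=0.01, p_A0=0.004, p_A_tau=1e9, noise_sigma=0)
        proto = self._protocol(n_cycles=2)
        _, truth = simulate_timecourse(proto, params, disc_mask, seed=0)
        for _, row in truth.iterrows():
            area_before = row.area_um2 - row.protrusion_T_um2 - row.protrusion_A_um2
            expect_t = 0.01 * proto.relax_duration * area_before
            expect_a = 0.004 * proto.relax_duration * area_before
            assert row.protrusion_T_um2 == pytest.approx(expect_t, rel=0.05)
            assert row.protrusion_A_um2 == pytest.approx(expect_a, rel=0.05)

    def test_same_seed_bitwise_identical_stacks(self, disc_mask):
        proto = self._protocol(samples=[(c, "relaxation_end") for c in (1, 2, 3)])
        params = preset_params("control")
        f1, t1 = simulate_timecourse(proto, params, disc_mask, seed=11)
        f2, t2 = simulate_timecourse(proto, params, disc_mask, seed=11)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(f1, f2))
        assert t1.equals(t2)


# -------------------------------------------------------------- micropattern


class TestMakeMicropattern:
    def test_unstrained_centers_on_pitch_lattice(self, grid_pair):
        ref, _ = grid_pair
        xs = np.unique(np.round(ref.centers[:, 0], 1))
        # 6 distinct columns spaced by the 100 µm pitch
        cols = np.sort(xs)
        spacing = np.diff(cols)
        assert len(cols) == 6
        np.testing.assert_allclose(spacing, 100.0, atol=0.5)

    def test_ten_percent_strain_moves_spacing_to_110(self):
        from cyclostretch import detect_grid

        img = make_micropattern(eps_ax=0.10, seed=0)
        fit = detect_grid(img)
        assert fit.pitch_ax == pytest.approx(110.0, abs=0.5)

    def test_noiseless_round_trip_with_detector(self, grid_pair):
        from cyclostretch import measure_strain

        ref, stretched = grid_pair
        m = measure_strain(ref, stretched)
        assert m.eps_ax == pytest.approx(0.15, abs=0.005)
        assert m.eps_tr == pytest.approx(-0.0225, abs=0.005)


# ------------------------------------------------------------------- presets


class TestPresets:
    def test_all_presets_satisfy_invariants(self):
        for cond in CONDITIONS:
            p = preset_params(cond)
            assert p.condition == cond
            assert min(p.r0, p.p_T, p.p_A0) >= 0
            assert p.r_decay > 0 and p.p_A_tau > 0

    def test_nocodazole_enhances_retraction_and_transverse_protrusion(self):
        control, noc = preset_params("control"), preset_params("nocodazole")
        assert noc.r0 > control.r0
        assert noc.p_T >= control.p_T

    def test_blebbistatin_suppresses_retraction_and_transverse_protrusion(self):
        control, bleb = preset_params("control"), preset_params("blebbistatin")
        assert bleb.r0 < 0.1 * control.r0
        assert bleb.p_T < 0.1 * control.p_T
        assert bleb.p_A0 > 0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigurationError):
            preset_params("latrunculin")


# ------------------------------------------------------------ mask invariants


class TestCellMaskInvariants:
    def test_empty_mask_rejected(self):
        m = CellMask(np.zeros((32, 32), bool), 0.5)
        with pytest.raises(InputError):
            m.validate()

    def test_multi_component_rejected(self):
        px = np.zeros((32, 32), bool)
        px[5:8, 5:8] = True
        px[20:23, 20:23] = True
        with pytest.raises(InputError):
            CellMask(px, 0.5).validate()

    def test_border_touching_rejected(self):
        px = np.zeros((32, 32), bool)
        px[0:5, 10:15] = True
        with pytest.raises(InputError):
            CellMask(px, 0.5).validate()
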