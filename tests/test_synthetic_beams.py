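"""Simulator physics: apertures, horn, blur chains, flood-field erasure."""

from __future__ import annotations

import numpy as np
import pytest

from portaldose.core import GeometryError, GridSpec, flip_about_center
from portaldose.synthetic_beams import (
    BeamSpec,
    Segment,
    desk_config,
    generate_dataset,
    horn_profile,
    make_aperture,
    paper_config,
    simulate_dose,
    simulate_portal_image,
    square_beam,
)

DESK = desk_config(seed=0, noise_sd=0.0)


class TestAperture:
    def test_fully_open_segment_gives_constant_mu(self):
        grid = DESK.grid
        half = grid.side_mm / 2
        gaps = np.tile([-half, half], (DESK.n_leaf_pairs, 1))
        beam = BeamSpec(segments=[Segment(gaps, mu=100.0)], label="open")
        ap = make_aperture(beam, grid)
        assert np.all(ap == 100.0)

    def test_all_leaves_closed_gives_zero_map(self):
        gaps = np.zeros((DESK.n_leaf_pairs, 2))
        beam = BeamSpec(segments=[Segment(gaps, mu=50.0)], label="closed")
        assert not make_aperture(beam, DESK.grid).any()

    def test_80mm_square_spans_333_pixels_on_paper_pitch(self):
        # pixel-center rule: centers within +/-40 mm of the beam axis
        grid = GridSpec(1024, 0.24)
        ap = make_aperture(square_beam(80.0), grid)
        row = ap[grid.center_index]
        assert (row > 0).sum() == 333
        col = ap[:, grid.center_index]
        assert (col > 0).sum() == 333

    def test_protruding_square_clips_with_warning(self):
        with pytest.warns(UserWarning, match="protrude"):
            ap = make_aperture(square_beam(260.0), DESK.grid)
        assert np.all(ap > 0)  # fully open: the square covers the whole panel

    def test_clinical_segment_beyond_panel_is_rejected(self):
        half = DESK.grid.side_mm / 2
        gaps = np.zeros((DESK.n_leaf_pairs, 2))
        gaps[5] = [-10.0, half + 5.0]
        beam = BeamSpec(segments=[Segment(gaps, mu=10.0)], label="bad")
        with pytest.raises(GeometryError):
            make_aperture(beam, DESK.grid)

    def test_mu_weighted_sum_over_segments(self):
        gaps = np.zeros((DESK.n_leaf_pairs, 2))
        gaps[6:10] = [-20.0, 20.0]
        beam = BeamSpec(
            segments=[Segment(gaps, mu=4.0), Segment(gaps, mu=6.0)], label="two"
        )
        ap = make_aperture(beam, DESK.grid)
        assert ap.max() == pytest.approx(10.0)


class TestHorn:
    def test_zero_coeffs_give_flat_map(self):
        assert np.all(horn_profile(DESK.grid, ()) == 1.0)

    def test_center_is_exactly_one(self):
        oar = horn_profile(DESK.grid, DESK.horn_coeffs)
        c = DESK.grid.center_index
        assert oar[c, c] == 1.0

    def test_value_matches_polynomial_at_100mm(self):
        # pixel 52 columns right of the axis sits at r = 99.84 mm
        grid = DESK.grid
        c = grid.center_index
        r = 52 * grid.pixel_pitch
        expected = 1.0 + 0.03 * (r / 100.0) ** 2 + 0.01 * (r / 100.0) ** 4
        oar = horn_profile(grid, (0.03, 0.01))
        assert oar[c, c + 52] == pytest.approx(expected, rel=1e-12)

    def test_default_horn_magnitude_at_100mm(self):
        grid = DESK.grid
        oar = horn_profile(grid, DESK.horn_coeffs)
        c = grid.center_index
        val = oar[c, c + 52]  # r = 99.84 mm
        assert 1.03 <= val <= 1.05

    def test_nonpositive_horn_rejected(self):
        with pytest.raises(ValueError):
            horn_profile(DESK.grid, (-2.0,))


class TestDose:
    def test_linearity_in_mu(self):
        b1 = square_beam(100.0, mu=50.0)
        b2 = square_beam(100.0, mu=100.0)
        d1 = simulate_dose(b1, DESK).values
        d2 = simulate_dose(b2, DESK).values
        mask = d1 > 0
        assert np.max(np.abs(d2[mask] / d1[mask] - 2.0)) < 1e-12

    def test_reference_square_central_dose_is_anchored(self):
        dose = simulate_dose(square_beam(80.0, mu=100.0), DESK)
        assert dose.central_value == pytest.approx(0.008 * 100, abs=1e-12)

    def test_small_field_loses_output_to_kernel_truncation(self):
        d15 = simulate_dose(square_beam(15.0), DESK).central_value
        d100 = simulate_dose(square_beam(100.0), DESK).central_value
        assert d15 < d100

    def test_centered_square_symmetric_about_beam_axis(self):
        dose = simulate_dose(square_beam(100.0), DESK).values
        for axis in (0, 1):
            flipped = flip_about_center(dose, axis)
            assert np.max(np.abs(flipped - dose)) < 1e-12 * dose.max()


class TestPortalImage:
    def test_open_field_is_flat_after_flood_correction(self):
        grid = DESK.grid
        half = grid.side_mm / 2
        gaps = np.tile([-half, half], (DESK.n_leaf_pairs, 1))
        beam = BeamSpec(segments=[Segment(gaps, mu=100.0)], label="open")
        img = simulate_portal_image(beam, DESK).values
        assert img.max() - img.min() <= 1  # flat to quantization

    def test_same_seed_gives_identical_image(self):
        cfg = desk_config(seed=5, noise_sd=25.0)
        beam = square_beam(100.0)
        a = simulate_portal_image(beam, cfg).values
        b = simulate_portal_image(beam, cfg).values
        assert np.array_equal(a, b)

    def test_horn_erased_from_image_but_present_in_dose(self):
        """The property the TDM layer must recover: a 200 mm square's portal
        image is flat across the central 80 % of the field while the dose
        profile shows the off-axis horn."""
        beam = square_beam(200.0)
        img = simulate_portal_image(beam, DESK).values.astype(float)
        dose = simulate_dose(beam, DESK).values
        c = DESK.grid.center_index
        w = int(0.8 * 100.0 / DESK.grid.pixel_pitch)  # central 80 % of 200 mm
        img_prof = img[c, c - w : c + w + 1]
        dose_prof = dose[c, c - w : c + w + 1]
        assert img_prof.max() / img_prof[w] <= 1.005
        assert dose_prof.max() / dose_prof[w] > 1.02

    def test_portal_image_symmetric_about_beam_axis(self):
        # symmetric to the quantization step: the long-range glare kernel is
        # truncated at the panel border, whose margins differ by one pixel
        # about the beam axis, so the float field is symmetric only to ~1e-5
        img = simulate_portal_image(square_beam(100.0), DESK).values.astype(int)
        for axis in (0, 1):
            assert np.abs(flip_about_center(img, axis) - img).max() <= 1


class TestDataset:
    def test_generation_is_bitwise_deterministic(self, tiny_config):
        p1, c1 = generate_dataset(4, tiny_config, seed=1)
        p2, c2 = generate_dataset(4, tiny_config, seed=1)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.mpi.values, b.mpi.values)
            assert np.array_equal(a.ppd.values, b.ppd.values)
        for side in c1:
            assert np.array_equal(c1[side].mpi.values, c2[side].mpi.values)

    def test_calibration_set_holds_seven_squares(self, tiny_dataset):
        _, calibration = tiny_dataset
        assert sorted(calibration) == [15.0, 50.0, 80.0, 100.0, 150.0, 200.0, 260.0]
        assert all(p.beam.kind == "square" for p in calibration.values())

    def test_generated_pairs_respect_invariants(self, tiny_dataset):
        pairs, calibration = tiny_dataset
        for p in list(pairs) + list(calibration.values()):
            assert np.all(p.ppd.values >= 0)
            assert p.mpi.values.dtype == np.uint16  # hence within [0, 65535]
            assert p.mpi.grid == p.ppd.grid

    def test_clinical_beams_vary_across_samples(self, tiny_dataset):
        pairs, _ = tiny_dataset
        images = [p.mpi.values for p in pairs]
        assert not np.array_equal(images[0], images[1])

    def test_paper_preset_reproduces_acquisition_geometry(self):
        cfg = paper_config()
        assert cfg.grid.n_pixels == 1024
        assert cfg.grid.pixel_pitch == 0.24
        assert cfg.n_leaf_pairs == 80
        # 24.5 cm active area at SAD, to the printed precision
        assert round(cfg.grid.side_mm / 10) == 25 or abs(cfg.grid.side_mm - 245.0) < 1.0
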