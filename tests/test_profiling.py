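"""Sectorized radial profiling: geometry, normalization, smoothing, stacks."""

import numpy as np
import pytest

import spheroquant as sq
from spheroquant.errors import ProfileError
from spheroquant.profiling import moving_average


def section(radius_px, profile, shape=None, noise=(0.0, 0.0), seed=0, center=None):
    """Nuclear + marker section with concentration `profile` on the disk."""
    phantom = sq.SpheroidPhantom(
        radius=float(radius_px),
        pixel_size=1.0,
        center=center,
        marker_profiles={"m": profile},
    )
    img, truth = sq.make_section_image(
        phantom,
        ["m"],
        seed=seed,
        shape=shape,
        noise=sq.NoiseModel(gaussian_sigma=noise[0], poisson_scale=noise[1]),
    )
    return img[0], img[1], truth


class TestFindCenter:
    def test_centered_disk(self):
        nuc, _, truth = section(100, sq.uniform())
        cy, cx = sq.find_center(nuc)
        assert abs(cy - truth["center_px"][0]) < 1
        assert abs(cx - truth["center_px"][1]) < 1

    def test_translation_equivariance(self):
        nuc, _, t0 = section(80, sq.uniform(), shape=(400, 400))
        moved, _, t1 = section(
            80,
            sq.uniform(),
            shape=(400, 400),
            center=(t0["center_px"][0] + 30.0, t0["center_px"][1] - 20.0),
        )
        c0 = sq.find_center(nuc)
        c1 = sq.find_center(moved)
        assert c1[0] - c0[0] == pytest.approx(30.0, abs=1.0)
        assert c1[1] - c0[1] == pytest.approx(-20.0, abs=1.0)

    def test_all_zero_raises(self):
        with pytest.raises(ProfileError, match="no nuclei detected"):
            sq.find_center(np.zeros((64, 64)))


class TestSegmentEdges:
    def test_disk_edge_radii(self):
        nuc, _, truth = section(200, sq.uniform())
        geom = sq.segment_edges(nuc, truth["center_px"], n_segments=12)
        assert geom.edge_radii.shape == (12,)
        np.testing.assert_allclose(geom.edge_radii, 200.0, atol=4.0)

    def test_ellipse_edge_radii_follow_axes(self):
        # narrow (10°) sectors so the per-sector radius tracks the local
        # ellipse radius; wide sectors smear the minor-axis estimate upward
        yy, xx = np.mgrid[:500, :500]
        nuc = (((xx - 250) / 200.0) ** 2 + ((yy - 250) / 100.0) ** 2 <= 1).astype(float)
        geom = sq.segment_edges(nuc, (250.0, 250.0), n_segments=36)
        angles = (np.arange(36) + 0.5) / 36 * 2 * np.pi - np.pi
        major = geom.edge_radii[np.argmin(np.abs(np.cos(angles) - 1))]
        minor = geom.edge_radii[np.argmin(np.abs(np.sin(angles) - 1))]
        assert major / minor == pytest.approx(2.0, rel=0.05)

    def test_off_center_gives_unequal_radii(self):
        nuc, _, truth = section(150, sq.uniform())
        cy, cx = truth["center_px"]
        geom = sq.segment_edges(nuc, (cy + 60, cx), n_segments=12)
        assert geom.edge_radii.max() > geom.edge_radii.min() + 20

    def test_degenerate_sectors_flagged(self):
        # nuclei confined to the right half-plane: left sectors are empty
        nuc = np.zeros((200, 200))
        nuc[90:110, 120:180] = 1.0
        geom = sq.segment_edges(nuc, (100.0, 100.0), n_segments=12)
        assert geom.degenerate.any() and not geom.degenerate.all()


class TestRadialProfile:
    def test_uniform_marker_constant_profile(self):
        nuc, marker, truth = section(150, sq.uniform(), noise=(0.005, 500.0))
        geom = sq.segment_edges(nuc, truth["center_px"])
        prof = sq.radial_profile(marker, geom)
        assert np.all(prof.smoothed >= 0.95) and np.all(prof.smoothed <= 1.0)

    def test_outer_shell_profile_localizes_signal(self):
        nuc, marker, truth = section(150, sq.outer_shell(0.8))
        geom = sq.segment_edges(nuc, truth["center_px"])
        prof = sq.radial_profile(marker, geom)
        assert np.all(prof.smoothed[prof.bin_centers < 0.7] < 0.1)
        assert np.any(prof.smoothed[prof.bin_centers > 0.8] >= 0.5)

    def test_normalized_peak_is_exactly_one(self):
        nuc, marker, truth = section(120, sq.penetration_front(0.5), noise=(0.01, 200.0))
        geom = sq.segment_edges(nuc, truth["center_px"])
        prof = sq.radial_profile(marker, geom)
        assert np.max(prof.normalized) == 1.0
        assert np.max(prof.smoothed) <= 1.0
        assert np.all(prof.smoothed >= 0.0)

    def test_rotation_invariance(self):
        nuc, marker, truth = section(150, sq.outer_shell(0.6), noise=(0.01, 200.0))
        geom = sq.segment_edges(nuc, truth["center_px"])
        prof = sq.radial_profile(marker, geom)
        nuc_r, marker_r = np.rot90(nuc), np.rot90(marker)
        geom_r = sq.segment_edges(nuc_r, sq.find_center(nuc_r))
        prof_r = sq.radial_profile(marker_r, geom_r)
        assert np.max(np.abs(prof.smoothed - prof_r.smoothed)) < 0.05

    @pytest.mark.parametrize("profile", [sq.uniform(), sq.penetration_front(0.5)])
    def test_edge_normalization_makes_profiles_radius_invariant(self, profile):
        profs = []
        for radius in (150, 300):
            nuc, marker, truth = section(radius, profile, noise=(0.01, 200.0))
            geom = sq.segment_edges(nuc, truth["center_px"])
            profs.append(sq.radial_profile(marker, geom).smoothed)
        assert np.max(np.abs(profs[0] - profs[1])) < 0.05

    def test_sector_count_robustness(self):
        nuc, marker, truth = section(150, sq.penetration_front(0.5), noise=(0.01, 200.0))
        a = sq.radial_profile(
            marker, sq.segment_edges(nuc, truth["center_px"], n_segments=12)
        )
        b = sq.radial_profile(
            marker, sq.segment_edges(nuc, truth["center_px"], n_segments=24)
        )
        assert np.max(np.abs(a.smoothed - b.smoothed)) < 0.03

    def test_sum_statistic_scales_with_annulus_area(self):
        nuc, marker, truth = section(150, sq.uniform())
        geom = sq.segment_edges(nuc, truth["center_px"])
        prof = sq.radial_profile(marker, geom, statistic="sum")
        # for a uniform field, per-bin sums grow with radius (annulus area)
        mid = prof.averaged[40:60].mean()
        inner = prof.averaged[5:25].mean()
        assert mid > inner


class TestMovingAverage:
    def test_constant_sequence_unchanged(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(moving_average(x), x)

    def test_window_truncated_at_ends(self):
        x = np.arange(10.0)
        out = moving_average(x, 5)
        assert out[0] == pytest.approx(np.mean(x[:3]))
        assert out[-1] == pytest.approx(np.mean(x[-3:]))
        assert out[5] == pytest.approx(np.mean(x[3:8]))

    def test_variance_reduction_on_iid_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 100))
        sm = np.stack([moving_average(row) for row in x])
        ratio = x[:, 10:-10].var() / sm[:, 10:-10].var()
        assert 4.0 < ratio < 6.0


class TestZStackProfiles:
    def test_uniform_ideal_stack_representative_constant(self, uniform_phantom):
        stack, _ = sq.make_zstack(
            uniform_phantom, sq.MODALITY_PRESETS["ideal"], seed=0
        )
        zp = sq.profile_zstack(stack)
        assert np.all(zp.representative.smoothed >= 0.95)

    def test_section_areas_unimodal_over_z(self, uniform_phantom):
        stack, _ = sq.make_zstack(
            uniform_phantom, sq.MODALITY_PRESETS["ideal"], seed=0
        )
        zp = sq.profile_zstack(stack)
        areas = zp.section_areas
        peak = int(np.argmax(areas))
        assert np.all(np.diff(areas[: peak + 1]) >= -0.02 * areas.max())
        assert np.all(np.diff(areas[peak:]) <= 0.02 * areas.max())
        # representative section is the (equatorial) area maximum
        assert zp.representative_index == peak

    def test_front_stack_profile_quiet_in_core(self):
        phantom = sq.SpheroidPhantom(
            radius=250.0,
            pixel_size=4.0,
            marker_profiles={"nc": sq.penetration_front(0.4)},
        )
        stack, _ = sq.make_zstack(phantom, sq.MODALITY_PRESETS["ideal"], seed=0)
        zp = sq.profile_zstack(stack)
        rep = zp.representative
        assert np.all(rep.smoothed[rep.bin_centers < 0.5] < 0.1)

    def test_empty_stack_raises(self):
        stack = np.zeros((2, 5, 32, 32))
        with pytest.raises(ProfileError):
            sq.profile_zstack(stack)
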