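"""Ground-truth integrity of the synthetic scan/incubation generators."""

import numpy as np
import pytest

from barct.incubation_chem import chamber_rates
from barct.synthetic_data import (
    AccretionPatch,
    BarSimSpec,
    Borehole,
    GrazedRegion,
    make_bar_pair,
    make_incubation_set,
    make_ph_response_table,
    make_phantom_set,
)


class TestPhantoms:
    def test_noiseless_means_invert_the_calibration_line(self):
        phantoms = make_phantom_set([1.5, 2.5], slope=0.01, intercept=0.5, noise_sd=0.0)
        means = [v.values.mean() for v, _ in phantoms]
        assert means == pytest.approx([100.0, 200.0])

    def test_single_density_is_rejected(self):
        with pytest.raises(ValueError):
            make_phantom_set([1.5])

    def test_noisy_means_within_standard_error_bound(self):
        noise = 2.0
        phantoms = make_phantom_set([1.5, 2.5], noise_sd=noise, seed=12, shape=(20, 20, 20))
        bound = 3 * noise / np.sqrt(20**3)
        for vol, d in phantoms:
            assert abs(vol.values.mean() - (d - 0.5) / 0.01) < bound


class TestBarPair:
    def test_identity_spec_roundtrips_through_resampling(self, cal):
        """No modifications, no offset: post is pre re-gridded."""
        import scipy.ndimage as ndi

        from barct.register_partition import resample_to, threshold_carbonate

        spec = BarSimSpec(
            block_dims_cm=(0.9, 0.5, 0.3), noise_sd=0.0, texture_sd=0.0, seed=0
        )
        pre, post, truth = make_bar_pair(spec)
        back = resample_to(post, None, target=pre)
        interior = ndi.binary_erosion(threshold_carbonate(pre), iterations=2)
        np.testing.assert_allclose(back.values[interior], pre.values[interior], rtol=1e-6)
        vol_pre = threshold_carbonate(pre).sum() * pre.voxel_volume_cm3
        vol_post = threshold_carbonate(post).sum() * post.voxel_volume_cm3
        assert vol_post == pytest.approx(vol_pre, rel=0.02)

    def test_borehole_volume_matches_brute_force_voxel_count(self):
        """Truth equals an independent distance-to-axis enumeration."""
        pitch = 100.0
        spec = BarSimSpec(
            block_dims_cm=(1.0, 0.5, 0.3),
            pre_pitch_um=pitch,
            post_pitch_um=pitch,
            boreholes=[Borehole(face="x+", entry=(0.5, 0.5), radius_um=4 * pitch, length_um=50 * pitch)],
            noise_sd=0.0,
            texture_sd=0.0,
        )
        _, _, truth = make_bar_pair(spec)
        n, m = spec.block_voxels, spec.margin_voxels
        p0 = np.array([m + n[0] - 0.5, m + 0.5 * n[1], m + 0.5 * n[2]])
        d = np.array([-1.0, 0.0, 0.0])
        count = 0
        for i in range(m, m + n[0]):
            for j in range(m + n[1] // 2 - 6, m + n[1] // 2 + 7):  # window around the axis
                for k in range(m + n[2] // 2 - 6, m + n[2] // 2 + 7):
                    v = np.array([i, j, k], float) - p0
                    t = np.clip(v @ d, 0.0, 50.0)
                    if np.sum((v - t * d) ** 2) <= 16.0:
                        count += 1
        assert truth.macroboring_voxels == count
        # capsule ≈ cylinder of π·4²·50 voxels plus its rounded end
        assert truth.macroboring_voxels == pytest.approx(np.pi * 16 * 50, rel=0.10)

    def test_grazed_full_face_slab_is_exact(self):
        spec = BarSimSpec(
            block_dims_cm=(1.0, 0.5, 0.3),
            pre_pitch_um=100.0,
            post_pitch_um=100.0,
            grazed_regions=[GrazedRegion(face="z+", depth_voxels=2, footprint=(0, 1, 0, 1))],
            noise_sd=0.0,
        )
        _, _, truth = make_bar_pair(spec)
        assert truth.grazing_voxels == 100 * 50 * 2
        assert truth.grazing_volume_cm3 == pytest.approx(10000 * (100e-4) ** 3)

    def test_determinism_bit_identical(self):
        spec = BarSimSpec(block_dims_cm=(0.4, 0.3, 0.2), noise_sd=3.0, seed=21)
        a = make_bar_pair(spec)
        b = make_bar_pair(spec)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)
        assert a[2] == b[2]

    def test_voxel_conservation_on_pre_grid(self):
        spec = BarSimSpec(
            block_dims_cm=(0.6, 0.4, 0.3),
            boreholes=[Borehole(face="y+", radius_um=200, length_um=2500)],
            grazed_regions=[GrazedRegion(face="z+", depth_voxels=3, footprint=(0.2, 0.8, 0.2, 0.8))],
            accretion_patches=[AccretionPatch()],
            microboring_density_drop_frac=0.05,
        )
        _, _, truth = make_bar_pair(spec)
        assert (
            truth.remaining_voxels + truth.macroboring_voxels + truth.grazing_voxels
            == truth.block_voxels
        )
        assert truth.accretion_voxels > 0  # disjoint from the block by construction

    def test_macroboring_monotone_in_radius(self):
        vols = []
        for r in (150.0, 220.0, 300.0):
            spec = BarSimSpec(
                block_dims_cm=(0.6, 0.4, 0.3),
                boreholes=[Borehole(face="x+", radius_um=r, length_um=2500)],
            )
            vols.append(make_bar_pair(spec)[2].macroboring_volume_cm3)
        assert vols[0] < vols[1] < vols[2]

    @pytest.mark.parametrize(
        "build",
        [
            lambda: Borehole(radius_um=40.0),  # microboring scale, not a resolvable tunnel
            lambda: BarSimSpec(microboring_density_drop_frac=1.2),
            lambda: BarSimSpec(block_dims_cm=(0.0, 1.0, 1.0)),
            lambda: GrazedRegion(depth_voxels=0),
        ],
    )
    def test_invalid_specs_are_rejected(self, build):
        with pytest.raises(ValueError):
            build()

    def test_feature_outside_grid_is_rejected(self):
        spec = BarSimSpec(
            block_dims_cm=(0.5, 0.3, 0.2),
            boreholes=[Borehole(face="x+", length_um=3.0e4, radius_um=200.0)],
        )
        with pytest.raises(ValueError, match="outside"):
            make_bar_pair(spec)

    def test_accretion_on_epoxied_base_is_rejected(self):
        with pytest.raises(ValueError, match="base"):
            AccretionPatch(face="z-")


class TestIncubationSet:
    def test_zero_rates_give_zero_deltas(self):
        for r in make_incubation_set(0, 0, 0, 0):
            assert r.delta_at == pytest.approx(0.0)
            assert r.delta_o2 == pytest.approx(0.0)

    def test_noiseless_roundtrip_is_exact(self):
        recs = make_incubation_set(0.42, -0.17, 0.8, 0.5, blank_drift=-4.0)
        cr = chamber_rates(recs)
        assert cr.g_light == pytest.approx(0.42, abs=1e-12)
        assert cr.g_dark == pytest.approx(-0.17, abs=1e-12)
        assert cr.p_net == pytest.approx(0.8, abs=1e-12)
        assert cr.r_dark == pytest.approx(0.5, abs=1e-12)

    def test_noisy_replicates_recover_rate_in_expectation(self):
        noise, n = 2.0, 50
        est = [
            chamber_rates(make_incubation_set(0.42, -0.17, 0.8, 0.5, noise_sd=noise, seed=s)).g_light
            for s in range(n)
        ]
        # ΔA_T noise propagates through G = (ΔA_T/2)·mass/(SA·t); blanks add variance
        se_single = np.std(est, ddof=1) / np.sqrt(n)
        assert abs(np.mean(est) - 0.42) < 3 * se_single

    def test_nonpositive_surface_area_is_rejected(self):
        with pytest.raises(ValueError):
            make_incubation_set(0, 0, 0, 0, surface_area_cm2=0.0)


class TestPhResponseTable:
    def test_noiseless_line_crosses_zero_at_7_8(self):
        df = make_ph_response_table(intercept=-39.0, slope=5.0, n=50, noise_sd=0.0, seed=2)
        np.testing.assert_allclose(df.response, -39.0 + 5.0 * df.ph)
        assert np.interp(7.8, np.sort(df.ph), df.response[np.argsort(df.ph)]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            make_ph_response_table(0.0, 1.0, n=0)

    def test_gamma_with_nonpositive_mean_is_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_ph_response_table(intercept=-39.0, slope=5.0, n=20, noise_sd=0.1, family="gamma")

    def test_seed_reproducible(self):
        a = make_ph_response_table(-2.73, 0.35, 30, noise_sd=0.08, seed=4)
        b = make_ph_response_table(-2.73, 0.35, 30, noise_sd=0.08, seed=4)
        assert a.equals(b)
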