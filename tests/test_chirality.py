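import numpy as np
import pytest
from scipy import ndimage

from bbbq import angles, chirality, core_io, synthetic

PS = 0.645


def make_stripes(shape, angle_deg, period=8.0):
    """Sinusoidal stripes whose axial orientation is angle_deg."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    th = np.radians(angle_deg)
    s = -cols * np.sin(th) - rows * np.cos(th)
    return 0.5 + 0.4 * np.sin(2 * np.pi * s / period)


class TestOrientationField:
    @staticmethod
    def _informative(f, margin=10):
        # at stripe crests the gradient vanishes and orientation is noise;
        # check only pixels carrying real gradient signal
        ori = f.orientation[margin:-margin, margin:-margin]
        mag = f.magnitude[margin:-margin, margin:-margin]
        return ori[mag > 0.2 * mag.max()]

    def test_vertical_stripes_measure_90_degrees(self):
        # intensity varies along x only, so the texture runs vertically
        frame = make_stripes((96, 96), 90.0)
        f = chirality.orientation_field(frame, sigma_px=2.0)
        d = angles.signed_axial_diff_deg(self._informative(f), 90.0)
        assert np.abs(d).max() < 0.5

    @pytest.mark.parametrize("angle", [0.0, 30.0, 120.0])
    def test_oriented_stripes_recovered(self, angle):
        frame = make_stripes((96, 96), angle)
        f = chirality.orientation_field(frame, sigma_px=2.0)
        d = angles.signed_axial_diff_deg(self._informative(f), angle)
        assert np.abs(d).max() < 1.0

    def test_rotating_image_shifts_orientation(self):
        frame = make_stripes((128, 128), 15.0)
        rot = ndimage.rotate(frame, 30.0, reshape=False, order=3)
        f = chirality.orientation_field(rot, sigma_px=2.0)
        # ndimage.rotate(+30) turns the displayed image CCW on screen
        ori = f.orientation[40:-40, 40:-40]
        mag = f.magnitude[40:-40, 40:-40]
        d = angles.signed_axial_diff_deg(ori[mag > 0.2 * mag.max()],
                                         15.0 + 30.0)
        assert np.abs(np.median(d)) < 1.5

    def test_constant_image_zero_magnitude(self):
        f = chirality.orientation_field(np.full((64, 64), 3.0), sigma_px=2.0)
        assert np.all(f.magnitude == 0)


class TestDominantDirections:
    def test_uniform_orientation_gives_unit_resultant(self):
        field = chirality.OrientationField(
            orientation=np.full((64, 64), 45.0),
            magnitude=np.ones((64, 64)))
        roi = core_io.RoiMask(np.ones((64, 64), bool))
        res = chirality.dominant_directions(field, roi, grid_px=32,
                                            mag_quantile=0.0)
        assert res
        for r in res:
            assert r.dominant_deg == pytest.approx(45.0, abs=0.5)
            assert r.resultant_length == pytest.approx(1.0, abs=1e-6)
            assert r.reliable

    def test_crossed_populations_flagged_unreliable(self):
        ori = np.zeros((32, 32))
        ori[:, 16:] = 90.0
        field = chirality.OrientationField(ori, np.ones((32, 32)))
        roi = core_io.RoiMask(np.ones((32, 32), bool))
        res = chirality.dominant_directions(field, roi, grid_px=32,
                                            mag_quantile=0.0)
        assert len(res) == 1
        assert res[0].resultant_length < 0.05
        assert not res[0].reliable

    def test_subregion_dominants_match_generator_samples(self, ring_geometry):
        truth = synthetic.ChiralityTruth(20.0, 8.0, ring_geometry)
        stack, t2 = synthetic.gen_ring_texture(truth, (280, 280), seed=5,
                                               pixel_size=PS, block_px=24)
        f = chirality.orientation_field(stack.frame(0))
        roi = core_io.pattern_mask(ring_geometry, (280, 280), PS)
        # analyse on the generator's own block grid so each subregion sees
        # one sampled orientation
        res = chirality.dominant_directions(f, roi, grid_px=24,
                                            pixel_size=PS)
        centers = {(round(cx), round(cy)): a for (cx, cy), a in
                   zip(t2.block_centers_px, t2.sampled_angles_deg)}
        matched = diffs = 0
        for r in res:
            key = (round(r.centroid_um[0] / PS), round(r.centroid_um[1] / PS))
            for (cx, cy), a in centers.items():
                if abs(cx - key[0]) <= 4 and abs(cy - key[1]) <= 4:
                    matched += 1
                    diffs += abs(angles.signed_axial_diff_deg(r.dominant_deg, a))
                    break
        assert matched >= 10
        assert diffs / matched < 3.0

    def test_empty_roi_rejected(self):
        field = chirality.OrientationField(np.zeros((32, 32)),
                                           np.ones((32, 32)))
        with pytest.raises(ValueError):
            mask = np.zeros((32, 32), bool)
            mask[0, 0] = True  # RoiMask forbids fully empty masks
            roi = core_io.RoiMask(mask)
            roi.mask[:] = False
            chirality.dominant_directions(field, roi)


class TestBiasFromGeometry:
    def test_dominant_equal_tangent_gives_zero_bias(self, ring_geometry):
        subs = []
        for ang_deg in range(0, 360, 30):
            x = ring_geometry.center[0] + 70 * np.cos(np.radians(ang_deg))
            y = ring_geometry.center[1] + 70 * np.sin(np.radians(ang_deg))
            tan = angles.ring_tangent_deg(x, y, ring_geometry.center)
            subs.append(chirality.SubregionResult((x, y), tan, 1.0, 100))
        out = chirality.bias_from_geometry(subs, ring_geometry)
        for r in out:
            assert r.bias_deg == pytest.approx(0.0, abs=1e-9)

    def test_line_pattern_axial_arithmetic(self):
        geo = core_io.PatternGeometry("line", center=(50, 50),
                                      band_width=30.0, axis_angle=30.0)
        sub = chirality.SubregionResult((40.0, 40.0), 75.0, 1.0, 100)
        out = chirality.bias_from_geometry([sub], geo)
        assert out[0].bias_deg == pytest.approx(45.0)

    def test_centroid_at_ring_center_rejected(self, ring_geometry):
        sub = chirality.SubregionResult(ring_geometry.center, 10.0, 1.0, 100)
        with pytest.raises(ValueError):
            chirality.bias_from_geometry([sub], ring_geometry)


class TestSummarizeBias:
    @staticmethod
    def _subs(biases):
        return [chirality.SubregionResult((0, 0), 0, 1.0, 10, bias_deg=b)
                for b in biases]

    def test_constant_bias_classified_ccw(self):
        s = chirality.summarize_bias(self._subs([10.0] * 12))
        assert s.mean_bias_deg == pytest.approx(10.0)
        assert s.circ_sd_deg == pytest.approx(0.0, abs=1e-6)
        assert s.classification == "CCW"

    def test_negative_bias_classified_cw(self):
        s = chirality.summarize_bias(self._subs([-10.0] * 12))
        assert s.classification == "CW"

    def test_uniform_biases_not_significant(self):
        rng = np.random.default_rng(0)
        nonsig = 0
        for _ in range(200):
            biases = rng.uniform(-90, 90, 10_000)
            s = chirality.summarize_bias(self._subs(biases))
            nonsig += s.rayleigh_p > 0.05
        assert nonsig / 200 >= 0.90

    def test_too_few_subregions_rejected(self):
        with pytest.raises(ValueError):
            chirality.summarize_bias(self._subs([1.0, 2.0]))


class TestEndToEndProperties:
    def test_mirror_negates_bias(self, ring_geometry):
        truth = synthetic.ChiralityTruth(15.0, 6.0, ring_geometry)
        stack, _ = synthetic.gen_ring_texture(truth, (280, 280), seed=11,
                                              pixel_size=PS)
        _, fwd = chirality.analyze_pattern(stack.frame(0), ring_geometry,
                                           PS, grid_px=24)
        mirrored = stack.frame(0)[:, ::-1]
        geo_m = core_io.PatternGeometry(
            "ring", center=((280 - 1) * PS - ring_geometry.center[0],
                            ring_geometry.center[1]),
            diameter=ring_geometry.diameter,
            band_width=ring_geometry.band_width)
        _, bwd = chirality.analyze_pattern(mirrored, geo_m, PS, grid_px=24)
        assert fwd.mean_bias_deg + bwd.mean_bias_deg == pytest.approx(0.0, abs=2.0)

    def test_rotation_equivariance(self, ring_geometry):
        # rotating the image by 90 deg maps the ring onto itself (centre on
        # the diagonal), so the bias distribution must be unchanged
        truth = synthetic.ChiralityTruth(15.0, 6.0, ring_geometry)
        stack, _ = synthetic.gen_ring_texture(truth, (280, 280), seed=12,
                                              pixel_size=PS)
        _, a = chirality.analyze_pattern(stack.frame(0), ring_geometry, PS,
                                         grid_px=24)
        _, b = chirality.analyze_pattern(np.rot90(stack.frame(0)).copy(),
                                         ring_geometry, PS, grid_px=24)
        assert a.mean_bias_deg == pytest.approx(b.mean_bias_deg, abs=1.5)

    def test_resultant_length_decreases_with_dispersion(self, ring_geometry):
        means = []
        for kappa in (16.0, 8.0, 4.0, 2.0):
            truth = synthetic.ChiralityTruth(10.0, kappa, ring_geometry)
            stack, _ = synthetic.gen_ring_texture(truth, (280, 280), seed=3,
                                                  pixel_size=PS)
            subs, _ = chirality.analyze_pattern(stack.frame(0), ring_geometry,
                                                PS, grid_px=24)
            means.append(np.mean([s.resultant_length for s in subs]))
        assert all(a > b for a, b in zip(means, means[1:]))
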