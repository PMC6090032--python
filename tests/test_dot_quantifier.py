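"""Densitometry: localisation, integration, calibration, CN estimation."""

import numpy as np
import pytest

from rdnacn.dot_quantifier import (
    CalibrationError,
    estimate_cn,
    fit_calibration,
    locate_dots,
    measure_dot,
    quantify_membrane,
)
from rdnacn.membrane_sim import (
    DEFAULT_NOISE,
    NOISE_FREE,
    SIGNAL_PER_COPY_NG,
    DotSpec,
    MembraneImage,
    MembraneLayout,
    NoisePreset,
    render_membrane,
    standard_layout,
)


def _signals(cn_by_sample):
    return {sid: cn * SIGNAL_PER_COPY_NG for sid, cn in cn_by_sample.items()}


@pytest.fixture(scope="module")
def clean_membrane():
    lay = standard_layout(["a", "b"])
    img = render_membrane(lay, _signals({"a": 400, "b": 550}), NOISE_FREE, rng_seed=0)
    return lay, img


class TestLocate:
    def test_centroids_within_one_pixel_of_truth(self, clean_membrane):
        lay, img = clean_membrane
        stubs = locate_dots(img, lay)
        for stub, (_, led) in zip(stubs, img.ledger.iterrows()):
            assert abs(stub.y - led.y) <= 1 and abs(stub.x - led.x) <= 1
            assert stub.usable

    def test_displaced_dot_flagged_off_grid(self):
        # lambda dots sit in their own row; displace one by 0.6 pitch
        lay = standard_layout(["a"])
        img = render_membrane(lay, _signals({"a": 400}), NOISE_FREE, rng_seed=0)
        target = next(d for d in lay.dots if d.role == "lambda")
        y, x = lay.center(target)
        shift = int(0.6 * lay.pitch_px)
        px = img.pixels.astype(float)
        r = 3 * int(lay.dot_sigma_px) + 2
        spot = px[int(y) - r : int(y) + r + 1, int(x) - r : int(x) + r + 1].copy()
        px[int(y) - r : int(y) + r + 1, int(x) - r : int(x) + r + 1] = 0
        px[int(y) - r : int(y) + r + 1, int(x) + shift - r : int(x) + shift + r + 1] += spot
        moved = MembraneImage(px.astype(np.uint16), img.ledger, lay)
        stub = [s for s in locate_dots(moved, lay) if s.dot_id == target.dot_id][0]
        assert "off_grid" in stub.flags

    def test_blank_membrane_flags_low_signal(self):
        lay = standard_layout(["a"])
        blank = MembraneImage(
            np.full(lay.shape, 100, dtype=np.uint16), None, lay
        )
        assert all("low_signal" in s.flags for s in locate_dots(blank, lay))

    def test_shape_mismatch_rejected(self, clean_membrane):
        lay, img = clean_membrane
        cropped = MembraneImage(img.pixels[:-10], img.ledger, lay)
        with pytest.raises(ValueError, match="does not match"):
            locate_dots(cropped, lay)


class TestMeasure:
    def test_flat_image_integral_zero(self):
        lay = standard_layout(["a"])
        flat = MembraneImage(np.full(lay.shape, 500, dtype=np.uint16), None, lay)
        stubs = locate_dots(flat, lay)
        m = measure_dot(flat, stubs[0], lay)
        assert m.integral == 0.0

    def test_noise_free_integral_matches_ledger_truth(self, clean_membrane):
        lay, img = clean_membrane
        for stub in locate_dots(img, lay):
            m = measure_dot(img, stub, lay)
            truth = img.ledger.set_index("dot_id").loc[stub.dot_id, "truth"]
            assert m.integral == pytest.approx(truth, rel=1e-3)

    def test_saturated_dot_flagged_and_excluded(self):
        lay = standard_layout(["a"])
        noise = NoisePreset(background=0, gradient=0, dot_cv=0, read_noise=0, ceiling=1500)
        img = render_membrane(lay, _signals({"a": 400}), noise, rng_seed=0)
        measured = [
            measure_dot(img, s, lay, ceiling=1500)
            for s in locate_dots(img, lay)
            if s.role == "sample"
        ]
        assert all("saturated" in m.flags for m in measured)
        est = estimate_cn(
            measured,
            fit_calibration([(200, 100, 1e5), (400, 100, 2e5), (600, 100, 3e5)], []),
        )
        assert "no_usable_replicates" in est.flags
        assert np.isnan(est.cn_mean)

    def test_bad_geometry_rejected(self, clean_membrane):
        lay, img = clean_membrane
        stub = locate_dots(img, lay)[0]
        with pytest.raises(ValueError, match="annulus"):
            measure_dot(img, stub, lay, aperture_radius=20, annulus=(10, 15))


class TestCalibration:
    def test_exact_linear_standards_recover_slope(self):
        slope, intercept = 7.5, 0.0
        standards = [(cn, 100.0, intercept + slope * cn * 100.0) for cn in range(200, 800, 100)]
        curve = fit_calibration(standards, [])
        assert curve.slope == pytest.approx(slope, rel=1e-6)
        assert curve.r_squared > 1 - 1e-9

    def test_slope_unbiased_under_five_percent_noise(self, rng):
        # Monte-Carlo oracle: mean recovered slope within 1% of truth
        slope = 7.5
        slopes = []
        for _ in range(100):
            standards = [
                (cn, 100.0, slope * cn * 100.0 * (1 + 0.05 * rng.standard_normal()))
                for cn in range(200, 800, 100)
            ]
            slopes.append(fit_calibration(standards, []).slope)
        assert abs(np.mean(slopes) / slope - 1) < 0.01

    def test_degenerate_standards_rejected(self):
        with pytest.raises(CalibrationError, match="degenerate"):
            fit_calibration([(400, 100, 1e5)] * 6, [])

    def test_too_few_standards_rejected(self):
        with pytest.raises(CalibrationError, match="at least 3"):
            fit_calibration([(200, 100, 1e5), (400, 100, 2e5)], [])

    def test_negative_slope_rejected(self):
        standards = [(cn, 100.0, 1e6 - 1000 * cn) for cn in range(200, 800, 100)]
        with pytest.raises(CalibrationError, match="slope"):
            fit_calibration(standards, [])


class TestEstimation:
    def test_noise_free_cn_recovered_within_half_percent(self, clean_membrane):
        lay, img = clean_membrane
        df, _ = quantify_membrane(img, lay)
        assert df.set_index("sample_id").loc["a", "cn_mean"] == pytest.approx(400, rel=5e-3)
        assert df.set_index("sample_id").loc["b", "cn_mean"] == pytest.approx(550, rel=5e-3)

    def test_single_replicate_flagged_low_confidence(self):
        curve = fit_calibration(
            [(cn, 100.0, 7.5 * cn * 100.0) for cn in range(200, 800, 100)], []
        )
        from rdnacn.dot_quantifier import DotMeasurement

        one = [DotMeasurement("s.0", "s", "sample", 0, 0, 100.0, integral=3e5)]
        est = estimate_cn(one, curve)
        assert est.n_replicates == 1
        assert "low_confidence" in est.flags
        assert np.isnan(est.cn_se)

    def test_floor_subtraction_cancels_constant_nonspecific_signal(self):
        lay = standard_layout(["a"])
        base = render_membrane(lay, _signals({"a": 450}), NOISE_FREE, rng_seed=0,
                               nonspecific_per_ng=0.0)
        lifted = render_membrane(lay, _signals({"a": 450}), NOISE_FREE, rng_seed=0,
                                 nonspecific_per_ng=400.0)
        cn0 = quantify_membrane(base, lay)[0]["cn_mean"].iloc[0]
        cn1 = quantify_membrane(lifted, lay)[0]["cn_mean"].iloc[0]
        assert cn1 == pytest.approx(cn0, rel=2e-3)

    def test_estimates_monotone_in_true_cn_noise_free(self):
        truths = [250, 350, 450, 550, 650]
        ids = [f"s{i}" for i in range(len(truths))]
        lay = standard_layout(ids)
        img = render_membrane(lay, _signals(dict(zip(ids, truths))), NOISE_FREE, rng_seed=0)
        df, _ = quantify_membrane(img, lay)
        est = df.set_index("sample_id").loc[ids, "cn_mean"].to_numpy()
        assert (np.diff(est) > 0).all()

    def test_default_noise_bias_below_five_percent(self):
        # end-to-end recovery across 200 noisy samples
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(10)]
        lay = standard_layout(ids)
        biases = []
        for seed in range(20):
            cn_true = {sid: rng.uniform(250, 650) for sid in ids}
            img = render_membrane(lay, _signals(cn_true), DEFAULT_NOISE, rng_seed=seed)
            df, _ = quantify_membrane(img, lay)
            for _, row in df.iterrows():
                biases.append(row["cn_mean"] / cn_true[row["sample_id"]] - 1)
        assert abs(np.mean(biases)) < 0.05
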