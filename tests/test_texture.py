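"""GLCM texture metrics: quantization, windowed maps, the 160-column table.

The key check is an independent brute-force oracle: explicit pair
counting per window and literal metric sums, compared to the vectorized
implementation to 1e-10.
"""

import math

import numpy as np
import pandas as pd
import pytest

from wheatspad.bandstack import PlotImage
from wheatspad.texture import (GLCM, EmptyMapError, GLCMConfig, METRICS,
                               STATISTICS, OFFSETS, glcm_from_window,
                               glcm_metric, plot_texture_stats, quantize,
                               texture_feature_table, texture_map, TextureMap)

# ---------------------------------------------------------------------------
# brute-force oracle, written independently of the package internals


def oracle_glcm(window, direction, levels, symmetric=True):
    dr, dc = OFFSETS[direction]
    counts = {}
    h, w = window.shape
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                key = (int(window[r, c]), int(window[rr, cc]))
                counts[key] = counts.get(key, 0) + 1
                if symmetric:
                    k2 = (key[1], key[0])
                    counts[k2] = counts.get(k2, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def oracle_metric(p, metric):
    mu_i = sum(i * v for (i, j), v in p.items())
    mu_j = sum(j * v for (i, j), v in p.items())
    if metric == "Me":
        return mu_i
    if metric == "Va":
        return sum((i - mu_i) ** 2 * v for (i, j), v in p.items())
    if metric == "Ho":
        return sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    if metric == "Cn":
        return sum((i - j) ** 2 * v for (i, j), v in p.items())
    if metric == "Di":
        return sum(abs(i - j) * v for (i, j), v in p.items())
    if metric == "En":
        return -sum(v * math.log(v) for v in p.values() if v > 0)
    if metric == "Se":
        return sum(v * v for v in p.values())
    if metric == "Cr":
        sd_i = math.sqrt(sum((i - mu_i) ** 2 * v for (i, j), v in p.items()))
        sd_j = math.sqrt(sum((j - mu_j) ** 2 * v for (i, j), v in p.items()))
        if sd_i * sd_j == 0:
            return 1.0
        cov = sum(i * j * v for (i, j), v in p.items()) - mu_i * mu_j
        return cov / (sd_i * sd_j)
    raise KeyError(metric)


def oracle_stats(image, mask, direction=45, levels=64):
    """All 160-per-band stats by naive window-by-window evaluation."""
    q = np.zeros(image.shape, dtype=int)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q[mask] = np.minimum(
            np.floor(levels * (image[mask] - lo) / (hi - lo)), levels - 1)
    h, w = image.shape
    per_metric = {m: [] for m in METRICS}
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if not mask[r - 1:r + 2, c - 1:c + 2].all():
                continue
            p = oracle_glcm(q[r - 1:r + 2, c - 1:c + 2], direction, levels)
            for m in METRICS:
                per_metric[m].append(oracle_metric(p, m))
    out = {}
    for m, xs in per_metric.items():
        xs = np.asarray(xs)
        out[m] = {"MAX": xs.max(), "MIN": xs.min(), "MEAN": xs.mean(),
                  "SD": xs.std()}
    return out


def make_plot(arrays, mask=None, plot_id="p"):
    px = np.stack(arrays, axis=2) if isinstance(arrays, list) else arrays
    if px.ndim == 2:
        px = np.repeat(px[:, :, None], 5, axis=2)
    if mask is None:
        mask = np.ones(px.shape[:2], bool)
    return PlotImage(plot_id=plot_id, pixels=px.astype(float), mask=mask,
                     semantics="reflectance")


class TestQuantize:
    def test_hand_example(self):
        assert quantize(np.array([0.0, 0.5, 1.0]), 64).tolist() == [0, 32, 63]

    def test_constant_maps_to_zero(self):
        assert quantize(np.full(9, 0.7), 64).tolist() == [0] * 9

    def test_output_within_range(self):
        rng = np.random.default_rng(0)
        q = quantize(rng.normal(size=1000), 16)
        assert q.min() >= 0 and q.max() <= 15

    def test_fixed_range_mode(self):
        q = quantize(np.array([0.0, 0.25, 0.5]), 4, value_range=(0.0, 1.0))
        assert q.tolist() == [0, 1, 2]


class TestWindowGLCM:
    def test_constant_window_single_cell(self):
        g = glcm_from_window(np.zeros((3, 3), int), GLCMConfig())
        assert g.p[0, 0] == pytest.approx(1.0)
        assert g.p.sum() == pytest.approx(1.0)

    def test_checkerboard_45_diagonal(self):
        w = np.indices((3, 3)).sum(axis=0) % 2
        g = glcm_from_window(w, GLCMConfig(levels=2))
        # 45-degree neighbours share parity, hence colour
        brute = oracle_glcm(w, 45, 2)
        assert g.p[0, 0] == pytest.approx(brute[(0, 0)])
        assert g.p[1, 1] == pytest.approx(brute[(1, 1)])
        assert g.p[0, 1] == 0 and g.p[1, 0] == 0

    def test_symmetry_flag(self):
        rng = np.random.default_rng(2)
        w = rng.integers(0, 4, (3, 3))
        g = glcm_from_window(w, GLCMConfig(levels=4))
        assert np.allclose(g.p, g.p.T)


class TestMetrics:
    def test_uniform_window_values(self):
        g = glcm_from_window(np.zeros((3, 3), int), GLCMConfig())
        assert glcm_metric(g, "Cn") == 0
        assert glcm_metric(g, "Di") == 0
        assert glcm_metric(g, "Ho") == pytest.approx(1.0)
        assert glcm_metric(g, "Se") == pytest.approx(1.0)
        assert glcm_metric(g, "En") == pytest.approx(0.0)
        assert glcm_metric(g, "Cr") == 1.0   # zero-variance convention

    def test_uniform_four_cell_distribution(self):
        p = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 0), (2, 3), (3, 2)]:
            p[i, j] = 0.25
        g = GLCM(p=p, levels=4, normalized=True)
        assert glcm_metric(g, "En") == pytest.approx(-4 * 0.25 * np.log(0.25))
        assert glcm_metric(g, "Se") == pytest.approx(0.25)
        base2 = glcm_metric(g, "En", log_base=2)
        assert base2 == pytest.approx(2.0)

    def test_unnormalized_rejected(self):
        g = GLCM(p=np.ones((2, 2)), levels=2, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            glcm_metric(g, "Me")

    def test_bounds_on_random_windows(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            w = rng.integers(0, 8, (3, 3))
            g = glcm_from_window(w, GLCMConfig(levels=8))
            assert 0 < glcm_metric(g, "Ho") <= 1
            assert 0 < glcm_metric(g, "Se") <= 1
            assert glcm_metric(g, "Cn") >= 0


class TestMaps:
    def test_constant_plot_zero_contrast(self):
        plot = make_plot(np.full((8, 10), 0.4))
        tm = texture_map(plot, "R", "Cn")
        v = tm.values[np.isfinite(tm.values)]
        assert np.allclose(v, 0.0)

    def test_single_bright_pixel_localized(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        tm = texture_map(make_plot(img), "R", "Cn")
        nz_r, nz_c = np.nonzero(np.nan_to_num(tm.values) > 0)
        # affected centers are those whose within-window 45-degree pair
        # set touches (4, 4): as source pixel (r in {3,4}, c in {4,5}) or
        # as target of (5, 3) (r in {4,5}, c in {3,4})
        affected = ({(r, c) for r in (3, 4) for c in (4, 5)}
                    | {(r, c) for r in (4, 5) for c in (3, 4)})
        # map coordinates are offset by 1 (window centers)
        assert {(r + 1, c + 1) for r, c in zip(nz_r, nz_c)} == affected

    def test_plot_smaller_than_window(self):
        with pytest.raises(EmptyMapError):
            texture_map(make_plot(np.zeros((2, 5))), "R", "Cn")

    @pytest.mark.parametrize("d1,d2", [(45, 45), (135, 135), (0, 90),
                                       (90, 0)])
    def test_transpose_with_mirrored_direction(self, d1, d2):
        # transposition maps the 0-degree offset to 90 degrees and maps the
        # diagonal offsets to their own reverses, which the symmetric GLCM
        # cannot distinguish; the metric map transposes along with the image
        rng = np.random.default_rng(4)
        img = rng.uniform(size=(10, 12))
        p1 = make_plot(img)
        p2 = make_plot(img.T)
        for m in METRICS:
            a = texture_map(p1, "G", m, GLCMConfig(direction=d1)).values
            b = texture_map(p2, "G", m, GLCMConfig(direction=d2)).values
            assert np.allclose(a, b.T, atol=1e-12, equal_nan=True)

    def test_stats_examples(self):
        tm = TextureMap(np.array([[0.0, 2.0]]), "Cn", "R")
        s = plot_texture_stats(tm)
        assert s == {"MAX": 2.0, "MIN": 0.0, "MEAN": 1.0, "SD": 1.0}
        const = plot_texture_stats(TextureMap(np.full((3, 3), 5.0), "Me", "R"))
        assert const["MAX"] == const["MIN"] == const["MEAN"] == 5.0
        assert const["SD"] == 0.0


class TestOracle:
    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_brute_force_agreement_random_plots(self, direction):
        rng = np.random.default_rng(5)
        for _ in range(5):
            img = rng.uniform(size=(12, 12))
            plot = make_plot(img)
            cfg = GLCMConfig(direction=direction)
            expected = oracle_stats(img, plot.mask, direction=direction)
            for m in METRICS:
                got = plot_texture_stats(texture_map(plot, "B", m, cfg))
                for s in STATISTICS:
                    assert got[s] == pytest.approx(expected[m][s],
                                                   abs=1e-10), (m, s)

    def test_masked_plot_agreement(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(size=(12, 12))
        mask = np.ones((12, 12), bool)
        mask[:3, :5] = False
        plot = make_plot(img, mask=mask)
        expected = oracle_stats(img, mask)
        for m in METRICS:
            got = plot_texture_stats(texture_map(plot, "B", m))
            for s in STATISTICS:
                assert got[s] == pytest.approx(expected[m][s], abs=1e-10)


class TestTable:
    def test_160_columns_once_each(self, heading_plots):
        table = texture_feature_table(heading_plots[:4])
        assert table.data.shape == (4, 160)
        combos = {(m.band, m.metric, m.statistic)
                  for m in table.meta.itertuples()}
        assert len(combos) == 160

    def test_reproducible(self, heading_plots):
        a = texture_feature_table(heading_plots[:2])
        b = texture_feature_table(heading_plots[:2])
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_stripe_amplitude_monotone_contrast(self):
        import pandas as pd
        from wheatspad.synthetic import (CanopyParams, ExperimentDesign,
                                         render_plot_image)
        design = ExperimentDesign(seed=0)
        row = pd.DataFrame({"plot_id": ["p"], "stage": ["heading"],
                            "spad": [40.0]}).iloc[0]
        # per-plot min-max quantization is invariant to a pure affine
        # rescaling of the stripe pattern, so the amplitude response is
        # probed with a fixed global quantization range
        cfg = GLCMConfig(levels=256, quantization="global",
                         global_range=(0.0, 1.0))
        means_cn, means_di = [], []
        for amp in (0.0, 0.1, 0.2, 0.3):
            params = CanopyParams(noise=False, stripes=True,
                                  stripe_amp_min=amp, stripe_amp_max=amp,
                                  cover={"heading": 0.5, "flowering": 0.5,
                                         "late_filling": 0.5})
            stack, region, panels = render_plot_image(row, design, params,
                                                      seed=0)
            gain = np.array(stack.meta["true_gain"])
            offset = np.array(stack.meta["true_offset"])
            refl = stack.pixels * gain + offset
            plot = PlotImage("p", refl, region.pixel_mask(stack),
                             "reflectance")
            means_cn.append(np.nanmean(texture_map(plot, "R", "Cn",
                                                   cfg).values))
            means_di.append(np.nanmean(texture_map(plot, "R", "Di",
                                                   cfg).values))
        for m in (means_cn, means_di):
            assert all(b >= a for a, b in zip(m, m[1:]))
            assert m[-1] > m[0]   # stripes create contrast
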