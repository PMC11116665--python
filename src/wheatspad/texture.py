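"""Windowed GLCM texture maps and per-plot statistics (160 metrics).

For each band, plot pixels are min–max quantized to a fixed number of
gray levels, a gray-level co-occurrence matrix is built inside a small
sliding window (default 3×3) at a fixed offset (default 45°, i.e. pixel
pair (r, c) → (r−1, c+1)), eight Haralick-style metrics are evaluated per
window, and the per-plot MAX / MIN / MEAN / SD of each metric map are
reported: 5 bands × 8 metrics × 4 statistics = 160 texture features.

Conventions (documented, configurable where marked):

* quantization is per plot over the unmasked pixels (illumination-robust);
  a constant plot maps to level 0;
* GLCMs are symmetric and normalized (Σp = 1), as the metric formulas
  assume;
* windows straddling the plot mask are skipped, not padded — padding
  would invent texture at plot borders;
* entropy uses 0·log 0 := 0 with natural log by default (base
  configurable);
* correlation of a zero-variance (uniform) window is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .bandstack import BAND_NAMES, PlotImage

METRICS: tuple[str, ...] = ("Me", "Va", "Ho", "Cn", "Di", "En", "Se", "Cr")
STATISTICS: tuple[str, ...] = ("MAX", "MIN", "MEAN", "SD")

#: direction (degrees) -> (drow, dcol) pixel offset, image coordinates
#: (row axis points down, so 45° is the up-right neighbour).
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class EmptyMapError(ValueError):
    pass


@dataclass
class GLCMConfig:
    window: int = 3
    direction: int = 45
    levels: int = 64
    symmetric: bool = True
    normalize: bool = True
    log_base: float | None = None   # None -> natural log
    # quantization range: per-plot min-max ("plot") or a fixed global range
    quantization: str = "plot"
    global_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.direction not in OFFSETS:
            raise ValueError(f"direction must be one of {sorted(OFFSETS)}")


@dataclass
class GLCM:
    """Co-occurrence probabilities over levels × levels."""

    p: np.ndarray
    levels: int
    normalized: bool

    def marginals(self):
        """Marginal means and SDs (μi, μj, σi, σj) of the row/column sums."""
        idx = np.arange(self.levels, dtype=float)
        pi = self.p.sum(axis=1)
        pj = self.p.sum(axis=0)
        mu_i = float((idx * pi).sum())
        mu_j = float((idx * pj).sum())
        sd_i = float(np.sqrt(((idx - mu_i) ** 2 * pi).sum()))
        sd_j = float(np.sqrt(((idx - mu_j) ** 2 * pj).sum()))
        return mu_i, mu_j, sd_i, sd_j


def quantize(values: np.ndarray, levels: int,
             value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Min–max quantize to integer levels 0..levels−1.

    ``q = floor(levels * (x − lo) / (hi − lo))`` clamped to levels−1, so
    the maximum maps to the top level; a constant input maps to level 0.
    With ``value_range`` given, lo/hi are fixed instead of per-input.
    """
    x = np.asarray(values, dtype=float)
    if value_range is None:
        lo, hi = (float(np.min(x)), float(np.max(x))) if x.size else (0.0, 1.0)
    else:
        lo, hi = value_range
    if hi <= lo:
        return np.zeros(x.shape, dtype=np.int64)
    q = np.floor(levels * (x - lo) / (hi - lo)).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm_from_window(window: np.ndarray, config: GLCMConfig) -> GLCM:
    """Build the co-occurrence matrix of one quantized window.

    Counts pixel pairs at the configured direction offset; adds the
    transpose when symmetric; divides by the total count when normalized.
    """
    w = np.asarray(window)
    dr, dc = OFFSETS[config.direction]
    L = config.levels
    p = np.zeros((L, L), dtype=float)
    h, wd = w.shape
    for r in range(h):
        for c in range(wd):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < wd:
                p[w[r, c], w[r2, c2]] += 1.0
    if config.symmetric:
        p = p + p.T
    if config.normalize:
        total = p.sum()
        if total > 0:
            p = p / total
    return GLCM(p=p, levels=L, normalized=config.normalize)


def glcm_metric(g: GLCM, metric: str, log_base: float | None = None) -> float:
    """Literal evaluation of one texture formula on a normalized GLCM."""
    if not g.normalized:
        raise ValueError("glcm_metric requires a normalized GLCM")
    p = g.p
    idx = np.arange(g.levels, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    if metric == "Me":
        return float((i * p).sum())
    if metric == "Va":
        u = float((i * p).sum())
        return float(((i - u) ** 2 * p).sum())
    if metric == "Ho":
        return float((p / (1.0 + (i - j) ** 2)).sum())
    if metric == "Cn":
        return float(((i - j) ** 2 * p).sum())
    if metric == "Di":
        return float((np.abs(i - j) * p).sum())
    if metric == "En":
        nz = p[p > 0]
        e = float(-(nz * np.log(nz)).sum())
        return e / np.log(log_base) if log_base else e
    if metric == "Se":
        return float((p ** 2).sum())
    if metric == "Cr":
        mu_i, mu_j, sd_i, sd_j = g.marginals()
        denom = sd_i * sd_j
        if denom == 0:
            return 1.0
        return float(((i * j * p).sum() - mu_i * mu_j) / denom)
    raise KeyError(f"unknown metric {metric!r}; valid: {list(METRICS)}")


# ---------------------------------------------------------------------------
# vectorized texture maps


def _pair_entries(q: np.ndarray, config: GLCMConfig):
    """Per-window co-occurring level pairs for all interior window centers.

    Returns (i, j) integer arrays of shape (H−2, W−2, k) holding the k
    directed pairs inside each 3×3 window (k = 4 for diagonal offsets,
    6 for axis-aligned ones).
    """
    dr, dc = OFFSETS[config.direction]
    h, w = q.shape
    r0, c0 = max(0, -dr), max(0, -dc)
    hp, wp = h - abs(dr), w - abs(dc)
    i0 = q[r0:r0 + hp, c0:c0 + wp]
    j0 = q[r0 + dr:r0 + dr + hp, c0 + dc:c0 + dc + wp]
    bh, bw = 3 - abs(dr), 3 - abs(dc)
    iw = sliding_window_view(i0, (bh, bw)).reshape(h - 2, w - 2, bh * bw)
    jw = sliding_window_view(j0, (bh, bw)).reshape(h - 2, w - 2, bh * bw)
    return iw, jw


def _metric_maps(q: np.ndarray, valid: np.ndarray,
                 config: GLCMConfig) -> dict[str, np.ndarray]:
    """All eight metric maps at once (shared pair decomposition).

    ``valid`` marks pixels inside the plot mask; a window center produces
    a value only if its full window is valid.  Invalid centers are NaN.
    """
    if config.window != 3:
        raise NotImplementedError("vectorized maps support the 3x3 window")
    h, w = q.shape
    if h < 3 or w < 3:
        raise EmptyMapError("plot smaller than the GLCM window")
    iw, jw = _pair_entries(q, config)
    if config.symmetric:
        ii = np.concatenate([iw, jw], axis=2).astype(np.int64)
        jj = np.concatenate([jw, iw], axis=2).astype(np.int64)
    else:
        ii, jj = iw.astype(np.int64), jw.astype(np.int64)
    k = ii.shape[2]                       # entries per window, weight 1/k

    fi = ii.astype(float)
    fj = jj.astype(float)
    diff = fi - fj
    me_i = fi.mean(axis=2)
    me_j = fj.mean(axis=2)
    va_i = ((fi - me_i[..., None]) ** 2).mean(axis=2)
    va_j = ((fj - me_j[..., None]) ** 2).mean(axis=2)

    maps: dict[str, np.ndarray] = {}
    maps["Me"] = me_i
    maps["Va"] = va_i
    maps["Ho"] = (1.0 / (1.0 + diff ** 2)).mean(axis=2)
    maps["Cn"] = (diff ** 2).mean(axis=2)
    maps["Di"] = np.abs(diff).mean(axis=2)

    codes = ii * config.levels + jj
    counts = (codes[..., :, None] == codes[..., None, :]).sum(axis=3)
    # sum over cells of p^2 = (1/k^2) * sum over entries of its cell count
    maps["Se"] = counts.sum(axis=2) / (k * k)
    en = -(np.log(counts / k)).mean(axis=2)
    if config.log_base:
        en = en / np.log(config.log_base)
    maps["En"] = en

    sd = np.sqrt(va_i * va_j)
    cov = (fi * fj).mean(axis=2) - me_i * me_j
    with np.errstate(divide="ignore", invalid="ignore"):
        cr = cov / sd
    maps["Cr"] = np.where(sd > 0, cr, 1.0)

    ok = sliding_window_view(valid, (3, 3)).all(axis=(2, 3))
    for name in maps:
        maps[name] = np.where(ok, maps[name], np.nan)
    return maps


@dataclass
class TextureMap:
    values: np.ndarray     # (H-2, W-2), NaN outside valid window centers
    metric: str
    band: str


def texture_map(plot: PlotImage, band: str, metric: str,
                config: GLCMConfig | None = None) -> TextureMap:
    """Metric map over all interior window centers of one plot band."""
    config = config or GLCMConfig()
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; valid: {list(METRICS)}")
    values = plot.band(band)
    r, c = np.nonzero(plot.mask)
    if r.size == 0:
        raise EmptyMapError(f"plot {plot.plot_id}: empty mask")
    sub = values[r.min():r.max() + 1, c.min():c.max() + 1]
    msk = plot.mask[r.min():r.max() + 1, c.min():c.max() + 1]
    rng = None if config.quantization == "plot" else config.global_range
    q = quantize(sub[msk], config.levels, rng)
    qimg = np.zeros(sub.shape, dtype=np.int64)
    qimg[msk] = q
    maps = _metric_maps(qimg, msk, config)
    return TextureMap(values=maps[metric], metric=metric, band=band)


def plot_texture_stats(tmap: TextureMap) -> dict[str, float]:
    """MAX / MIN / MEAN / SD (population SD) over valid map cells."""
    v = tmap.values[np.isfinite(tmap.values)]
    if v.size == 0:
        raise EmptyMapError("texture map has no valid cells")
    return {"MAX": float(v.max()), "MIN": float(v.min()),
            "MEAN": float(v.mean()), "SD": float(v.std())}


def texture_feature_table(plots: Sequence[PlotImage],
                          config: GLCMConfig | None = None):
    """160-column texture feature table: 5 bands × 8 metrics × 4 stats."""
    from .features import FeatureTable

    config = config or GLCMConfig()
    rows = {}
    for plot in plots:
        r, c = np.nonzero(plot.mask)
        if r.size == 0:
            raise EmptyMapError(f"plot {plot.plot_id}: empty mask")
        sub_sl = (slice(r.min(), r.max() + 1), slice(c.min(), c.max() + 1))
        msk = plot.mask[sub_sl]
        rng = None if config.quantization == "plot" else config.global_range
        feats = {}
        for band in BAND_NAMES:
            sub = plot.band(band)[sub_sl]
            qimg = np.zeros(sub.shape, dtype=np.int64)
            qimg[msk] = quantize(sub[msk], config.levels, rng)
            maps = _metric_maps(qimg, msk, config)
            for metric in METRICS:
                stats = plot_texture_stats(
                    TextureMap(maps[metric], metric, band))
                for stat in STATISTICS:
                    feats[f"{band}_{metric}_{stat}"] = stats[stat]
        rows[plot.plot_id] = feats
    columns = [f"{b}_{m}_{s}" for b in BAND_NAMES for m in METRICS
               for s in STATISTICS]
    data = pd.DataFrame.from_dict(rows, orient="index")[columns]
    meta = pd.DataFrame(
        {
            "feature_type": "TF",
            "band": [c.split("_")[0] for c in columns],
            "metric": [c.split("_")[1] for c in columns],
            "statistic": [c.split("_")[2] for c in columns],
        },
        index=columns,
    )
    return FeatureTable(data, meta, label="TF")
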