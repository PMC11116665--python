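"""Synthetic winter-wheat canopy experiment generator.

Emulates the statistical structure of a plot-scale UAV multispectral
nitrogen trial so the full analysis chain (calibration → features →
selection → fusion → SVR) is testable without field data:

* a full-factorial design — 3 varieties × 4 nitrogen rates
  (0/100/200/300 kg/ha) × 3 replicates = 36 plots of 2 m × 8 m, observed
  at three reproductive stages (heading, flowering, late filling);
* per-plot SPAD values rising with nitrogen (saturating response),
  highest at flowering and collapsing at late filling (senescence),
  spanning roughly 30–55 at heading and 6–44 at late filling;
* per-plot 5-band (B, G, R, RE, NIR) imagery in digital numbers, with a
  known affine DN encoding, four grey calibration panels
  (5/10/20/40 % reflectance), row-structured canopy texture at 30 cm row
  spacing, soil background between rows (more of it at late filling) and
  multiplicative speckle.

Canopy reflectance responds to SPAD through simple logistic curves:
blue/green/red decline with SPAD (chlorophyll absorption), NIR rises
(healthy mesophyll scattering), red edge sits in between and moves little.
Row stripes are a raised-cosine vegetation-cover modulation whose
amplitude grows with SPAD (vigorous canopies throw more structured row
shadow), so texture carries SPAD information complementary to the band
means.  All randomness flows through one explicitly passed seeded
generator; identical (config, seed) reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box

from .bandstack import BAND_NAMES, DN, BandStack, CalPanel, PlotRegion

STAGES: tuple[str, ...] = ("heading", "flowering", "late_filling")
N_LEVELS_KG_HA: tuple[float, ...] = (0.0, 100.0, 200.0, 300.0)
VARIETIES: tuple[str, ...] = ("V1", "V2", "V3")


@dataclass
class ExperimentDesign:
    """Factorial layout of the trial (defaults reproduce the 36-plot design)."""

    varieties: tuple[str, ...] = VARIETIES
    n_levels: tuple[float, ...] = N_LEVELS_KG_HA
    replicates: int = 3
    stages: tuple[str, ...] = STAGES
    plot_size: tuple[float, float] = (2.0, 8.0)   # metres (across-row, along-row)
    row_spacing: float = 0.30                      # metres
    gsd: float = 0.05                              # metres / pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.varieties and self.n_levels and self.replicates >= 1
                and self.stages):
            raise ValueError("factor levels must be non-empty")
        if any(n < 0 for n in self.n_levels):
            raise ValueError("nitrogen rates must be non-negative")
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")

    @property
    def n_plots(self) -> int:
        return len(self.varieties) * len(self.n_levels) * self.replicates


def _stage_map(value, default: Mapping[str, float]) -> dict[str, float]:
    if value is None:
        return dict(default)
    return dict(value)


@dataclass
class SpadModelParams:
    """Stage-wise SPAD response model: baseline + saturating N response.

    mean SPAD(stage, N) = baseline[stage]
                          + amplitude[stage] * N / (N + half_saturation[stage])
                          + variety offset,
    plus Gaussian plot noise (truncated to the meter's [0, 60] range).

    Defaults approximate the study's stage envelopes: heading ≈ 30–55,
    flowering ≈ 31–56, late filling ≈ 6–44 with the widest spread (leaf
    senescence under low N versus sustained greenness under high N).
    """

    baseline: dict[str, float] = field(default_factory=lambda: {
        "heading": 35.0, "flowering": 37.0, "late_filling": 6.0})
    amplitude: dict[str, float] = field(default_factory=lambda: {
        "heading": 17.0, "flowering": 17.0, "late_filling": 42.0})
    half_saturation: dict[str, float] = field(default_factory=lambda: {
        "heading": 100.0, "flowering": 100.0, "late_filling": 150.0})
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "heading": 3.0, "flowering": 3.0, "late_filling": 3.0})
    variety_offsets: dict[str, float] = field(default_factory=lambda: {
        "V1": 0.0, "V2": 0.0, "V3": 0.0})
    spad_range: tuple[float, float] = (0.0, 60.0)


@dataclass
class CanopyParams:
    """Radiometric / structural parameters of the rendered plot imagery."""

    # canopy reflectance at SPAD→0 (r0) and SPAD→∞ (r1), logistic between
    refl_low_spad: tuple[float, ...] = (0.065, 0.13, 0.16, 0.19, 0.25)
    refl_high_spad: tuple[float, ...] = (0.035, 0.07, 0.035, 0.16, 0.46)
    logistic_mid: float = 25.0      # SPAD units
    logistic_scale: float = 10.0    # SPAD units
    soil_reflectance: tuple[float, ...] = (0.10, 0.14, 0.18, 0.21, 0.25)
    # mean vegetation cover per stage (senescence opens the canopy)
    cover: dict[str, float] = field(default_factory=lambda: {
        "heading": 0.85, "flowering": 0.90, "late_filling": 0.65})
    cover_jitter_sd: dict[str, float] = field(default_factory=lambda: {
        "heading": 0.03, "flowering": 0.03, "late_filling": 0.08})
    # raised-cosine stripe amplitude grows with SPAD between these bounds
    stripe_amp_min: float = 0.05
    stripe_amp_max: float = 0.30
    stripes: bool = True
    # senescence decoupling: the canopy *colour* responds to an "optical"
    # SPAD = true SPAD + noise with this SD, because leaves yellow at
    # plot-specific rates late in the season while row *structure* keeps
    # tracking biomass (true SPAD).  This is the spectral-saturation /
    # mixing problem the analysis targets.
    senescence_sd: dict[str, float] = field(default_factory=lambda: {
        "heading": 1.5, "flowering": 1.5, "late_filling": 7.0})
    # multiplicative pixel speckle (lognormal sigma) per stage
    speckle_sd: dict[str, float] = field(default_factory=lambda: {
        "heading": 0.05, "flowering": 0.05, "late_filling": 0.08})
    # per-plot illumination multiplier (lognormal sigma) per stage
    illumination_sd: dict[str, float] = field(default_factory=lambda: {
        "heading": 0.03, "flowering": 0.03, "late_filling": 0.06})
    noise: bool = True
    # DN encoding: DN = (reflectance - offset) / gain per band
    dn_gain: tuple[float, ...] = (1.8e-5, 1.9e-5, 2.0e-5, 2.1e-5, 2.2e-5)
    dn_offset: tuple[float, ...] = (-0.004, -0.005, -0.006, -0.005, -0.004)
    quantize_dn: bool = False       # round DN to integers (uint16 grid)
    panel_nominals: tuple[float, ...] = (0.05, 0.10, 0.20, 0.40)
    margin_px: int = 6              # soil margin around the plot
    panel_px: int = 6               # panel patch side length


# ---------------------------------------------------------------------------
# design + SPAD


def generate_design(config: ExperimentDesign) -> pd.DataFrame:
    """One row per (plot, stage); the default design yields 36 × 3 rows."""
    rows = []
    for stage in config.stages:
        for v in config.varieties:
            for i, n in enumerate(config.n_levels):
                for r in range(1, config.replicates + 1):
                    rows.append({
                        "plot_id": f"{v}-N{i}-R{r}",
                        "stage": stage,
                        "variety": v,
                        "n_level": float(n),
                        "replicate": r,
                    })
    return pd.DataFrame(rows)


def simulate_spad(design: pd.DataFrame, params: SpadModelParams,
                  seed: int) -> pd.DataFrame:
    """Draw per-plot SPAD for every design row (reproducible under seed).

    Raises
    ------
    ValueError
        If the deterministic stage/N means leave the meter range [0, 60].
    """
    lo, hi = params.spad_range
    rng = np.random.default_rng(seed)
    mean = np.empty(len(design))
    for i, row in enumerate(design.itertuples(index=False)):
        m = (params.baseline[row.stage]
             + params.amplitude[row.stage] * row.n_level
             / (row.n_level + params.half_saturation[row.stage])
             + params.variety_offsets.get(row.variety, 0.0))
        if not (lo <= m <= hi):
            raise ValueError(
                f"SPAD model mean {m:.2f} for stage={row.stage} "
                f"N={row.n_level} outside [{lo}, {hi}]; adjust parameters"
            )
        mean[i] = m
    sd = design["stage"].map(params.noise_sd).to_numpy(dtype=float)
    spad = np.clip(mean + rng.normal(0.0, 1.0, len(design)) * sd, lo, hi)
    out = design.copy()
    out["spad"] = spad
    return out


# ---------------------------------------------------------------------------
# imagery


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def canopy_reflectance(spad: float, params: CanopyParams) -> np.ndarray:
    """Deterministic per-band canopy reflectance as a function of SPAD."""
    r0 = np.asarray(params.refl_low_spad)
    r1 = np.asarray(params.refl_high_spad)
    t = _logistic((spad - params.logistic_mid) / params.logistic_scale)
    return r0 + (r1 - r0) * t


def stripe_amplitude(spad: float, params: CanopyParams) -> float:
    """Row-stripe cover modulation amplitude, rising with canopy vigour."""
    t = float(_logistic((spad - params.logistic_mid) / params.logistic_scale))
    return params.stripe_amp_min + (params.stripe_amp_max - params.stripe_amp_min) * t


def render_plot_image(gt_row, design: ExperimentDesign, params: CanopyParams,
                      seed: int) -> tuple[BandStack, PlotRegion, list[CalPanel]]:
    """Render one plot at one stage as a DN BandStack with panels.

    ``gt_row`` needs fields plot_id / stage / spad (a row of the ground
    truth table).  The returned polygon outlines the sown plot area; the
    four calibration panels sit in a soil strip right of the plot.
    """
    spad = float(gt_row.spad)
    stage = str(gt_row.stage)
    rng = np.random.default_rng(seed)
    gsd = design.gsd
    ph = int(round(design.plot_size[0] / gsd))   # across rows
    pw = int(round(design.plot_size[1] / gsd))   # along rows
    m = params.margin_px
    strip = params.panel_px + 2 * 2              # panel strip width incl. gaps
    h = ph + 2 * m
    w = pw + 2 * m + strip
    if ph < 1 or pw < 1:
        raise ValueError("plot does not fit the image at this gsd")

    optical_spad = spad
    if params.noise:
        optical_spad = float(np.clip(
            spad + rng.normal(0.0, params.senescence_sd[stage]), 0.0, 60.0))
    canopy = canopy_reflectance(optical_spad, params)     # (5,)
    soil = np.asarray(params.soil_reflectance)

    cover = params.cover[stage]
    if params.noise:
        cover = float(np.clip(
            cover + rng.normal(0.0, params.cover_jitter_sd[stage]), 0.2, 0.98))
    # stripes follow canopy structure, hence true SPAD (vigour), not colour
    amp = stripe_amplitude(spad, params) if params.stripes else 0.0

    period = design.row_spacing / gsd                     # pixels per row
    rr = np.arange(ph)
    veg = np.clip(cover + amp * np.cos(2.0 * np.pi * rr / period),
                  0.0, 1.0)                               # (ph,)

    refl = np.empty((h, w, 5))
    refl[:] = soil[None, None, :]
    plot_block = (veg[:, None, None] * canopy[None, None, :]
                  + (1.0 - veg)[:, None, None] * soil[None, None, :])
    refl[m:m + ph, m:m + pw, :] = plot_block

    if params.noise:
        illum = float(np.exp(rng.normal(0.0, params.illumination_sd[stage])))
        speckle = np.exp(rng.normal(0.0, params.speckle_sd[stage],
                                    size=(h, w, 5)))
        refl[:, :w - strip, :] *= illum
        refl[:, :w - strip, :] *= speckle[:, :w - strip, :]

    # calibration panels: exact nominal reflectance patches (grey in all bands)
    panels: list[CalPanel] = []
    c0 = w - strip + 2
    r = 2
    for nominal in params.panel_nominals:
        r1, c1 = r + params.panel_px, c0 + params.panel_px
        if r1 > h:
            raise ValueError("panels do not fit the image margin")
        refl[r:r1, c0:c1, :] = nominal
        panels.append(CalPanel(nominal_reflectance=nominal,
                               region=(r, r1, c0, c1)))
        r = r1 + 2

    gain = np.asarray(params.dn_gain)
    offset = np.asarray(params.dn_offset)
    dn = (refl - offset[None, None, :]) / gain[None, None, :]
    n_clipped = int(((dn < 0) | (dn > 65535)).sum())
    dn = np.clip(dn, 0, 65535)
    if params.quantize_dn:
        dn = np.round(dn)

    transform = (gsd, 0.0, 0.0, 0.0, gsd, 0.0)
    stack = BandStack(
        pixels=dn, semantics=DN, transform=transform,
        meta={
            "plot_id": str(gt_row.plot_id), "stage": stage,
            "true_gain": list(gain), "true_offset": list(offset),
            "n_clipped": n_clipped, "spad": spad,
        },
    )
    poly = box(gsd * m, gsd * m, gsd * (m + pw), gsd * (m + ph))
    region = PlotRegion(plot_id=str(gt_row.plot_id), polygon=poly)
    return stack, region, panels


def simulate_experiment(design_cfg: ExperimentDesign,
                        spad_params: SpadModelParams | None = None,
                        canopy_params: CanopyParams | None = None,
                        seed: int | None = None):
    """Full synthetic campaign: ground truth + one image per (plot, stage).

    Returns ``(ground_truth, images)`` where ``images`` maps
    (plot_id, stage) → (BandStack, PlotRegion, panels).  Per-image seeds
    are spawned deterministically from the top-level seed.
    """
    spad_params = spad_params or SpadModelParams()
    canopy_params = canopy_params or CanopyParams()
    seed = design_cfg.seed if seed is None else seed
    design = generate_design(design_cfg)
    gt = simulate_spad(design, spad_params, seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(gt))
    images = {}
    for child, row in zip(child_seeds, gt.itertuples(index=False)):
        sub = int(child.generate_state(1)[0] % (2 ** 31))
        images[(row.plot_id, row.stage)] = render_plot_image(
            row, design_cfg, canopy_params, sub)
    return gt, images
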