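"""Empirical line method (ELM) radiometric calibration.

The ELM maps sensor digital numbers to surface reflectance with one affine
relation per band, fitted by ordinary least squares on ground panels of
known reflectance: ``reflectance = gain * DN + offset``.  With noise-free
panels on a truly affine sensor the fit is exact for any two or more
distinct panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bandstack import (
    DN,
    REFLECTANCE,
    REFLECTANCE_CEILING,
    BandStack,
    CalPanel,
    N_BANDS,
    SemanticsError,
)


class CalibrationError(ValueError):
    """Insufficient or degenerate calibration-panel information."""


@dataclass
class ElmCoefficients:
    """Per-band ELM gain/offset plus panel-fit diagnostics."""

    gain: np.ndarray      # (5,) reflectance per DN, > 0
    offset: np.ndarray    # (5,) reflectance
    r_squared: np.ndarray  # (5,) panel-fit R^2
    n_panels: int

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)


def fit_elm(stack: BandStack, panels: Sequence[CalPanel],
            statistic: str = "mean") -> ElmCoefficients:
    """Fit per-band DN→reflectance lines on calibration panels.

    Parameters
    ----------
    stack : BandStack with DN semantics.
    panels : at least two panels with strictly increasing nominal
        reflectances.
    statistic : {"mean", "median"}
        Panel summary statistic; mean is standard ELM practice.

    Raises
    ------
    SemanticsError, CalibrationError
    """
    if stack.semantics != DN:
        raise SemanticsError("fit_elm requires a DN stack")
    if len(panels) < 2:
        raise CalibrationError(
            f"ELM needs at least 2 panels, got {len(panels)}"
        )
    nominal = np.array([p.nominal_reflectance for p in panels], dtype=float)
    if not np.all(np.diff(nominal) > 0):
        raise CalibrationError("panel nominal reflectances must be strictly increasing")

    if statistic == "mean":
        dn = np.stack([p.mean_dn(stack) for p in panels])  # (P, 5)
    elif statistic == "median":
        dn = np.stack([
            np.median(stack.pixels[p.region[0]:p.region[1],
                                   p.region[2]:p.region[3], :].reshape(-1, N_BANDS),
                      axis=0)
            for p in panels
        ])
    else:  # pragma: no cover - config validation
        raise ValueError(f"unknown panel statistic {statistic!r}")

    gain = np.empty(N_BANDS)
    offset = np.empty(N_BANDS)
    r2 = np.empty(N_BANDS)
    for b in range(N_BANDS):
        x = dn[:, b]
        if np.ptp(x) == 0:
            raise CalibrationError(
                f"band {stack.band_names[b]}: zero DN variance across panels"
            )
        g, o = np.polyfit(x, nominal, 1)
        fitted = g * x + o
        ss_res = float(np.sum((nominal - fitted) ** 2))
        ss_tot = float(np.sum((nominal - nominal.mean()) ** 2))
        gain[b], offset[b] = g, o
        r2[b] = 1.0 - ss_res / ss_tot
    return ElmCoefficients(gain=gain, offset=offset, r_squared=r2,
                           n_panels=len(panels))


def apply_elm(stack: BandStack, coef: ElmCoefficients) -> BandStack:
    """Convert a DN stack to reflectance: ``gain * DN + offset`` per band.

    Values outside [0, 1.2] are masked out and counted in
    ``meta["n_out_of_range"]``.
    """
    if stack.semantics != DN:
        raise SemanticsError("apply_elm requires a DN stack")
    refl = stack.pixels * coef.gain[None, None, :] + coef.offset[None, None, :]
    out_of_range = ((refl < 0) | (refl > REFLECTANCE_CEILING)).any(axis=2)
    mask = stack.mask & ~out_of_range
    meta = dict(stack.meta)
    meta["n_out_of_range"] = int((out_of_range & stack.mask).sum())
    return BandStack(
        pixels=refl,
        semantics=REFLECTANCE,
        mask=mask,
        transform=stack.transform,
        crs=stack.crs,
        meta=meta,
    )
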