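"""Spectral features: 5 band means + 25 vegetation indices (30 features).

The registry mirrors the standard five-band VI inventory for SPAD work,
organised in five classes:

* I   — the original band reflectances (B, G, R, RE, NIR);
* II  — visible-band-only indices (7);
* III — red-edge indices without NIR (5);
* IV  — NIR indices without red edge (8);
* V   — indices combining NIR and red edge (5).

Indices are evaluated on plot-mean reflectance (mean-then-index); a
config switch in the pipeline enables index-then-mean for sensitivity
checks.  A formula whose denominator vanishes yields NaN (a missing-value
sentinel), never ±inf.  ``DCabCxc`` R/G*3*RE is read with left-to-right
precedence as (R/G)·3·RE and ``ExB`` 1.4*B-G as 1.4·B − G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bandstack import BAND_NAMES, REFLECTANCE, PlotImage, SemanticsError


class EmptyPlotError(ValueError):
    pass


@dataclass(frozen=True)
class SpectralFeatureDef:
    name: str
    vi_class: str            # I..V
    formula: str             # human-readable formula string
    func: Callable           # (B, G, R, RE, NIR) -> value


def _d(num, den):
    """Safe division: zero denominator -> NaN, never inf."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out = np.where(np.isfinite(out), out, np.nan)
    return out if out.ndim else float(out)


_DEFS: list[tuple[str, str, str, Callable]] = [
    # class I: original bands
    ("B",    "I", "B",              lambda B, G, R, RE, NIR: B),
    ("G",    "I", "G",              lambda B, G, R, RE, NIR: G),
    ("R",    "I", "R",              lambda B, G, R, RE, NIR: R),
    ("RE",   "I", "RE",             lambda B, G, R, RE, NIR: RE),
    ("NIR",  "I", "NIR",            lambda B, G, R, RE, NIR: NIR),
    # class II: visible only
    ("CI",    "II", "(R-B)/R",      lambda B, G, R, RE, NIR: _d(R - B, R)),
    ("NGBDI", "II", "(G-B)/(G+B)",  lambda B, G, R, RE, NIR: _d(G - B, G + B)),
    ("RBI",   "II", "R/B",          lambda B, G, R, RE, NIR: _d(R, B)),
    ("NPCI",  "II", "(R-B)/(R+B)",  lambda B, G, R, RE, NIR: _d(R - B, R + B)),
    ("WI",    "II", "(G-B)/(R-G)",  lambda B, G, R, RE, NIR: _d(G - B, R - G)),
    ("ExB",   "II", "1.4*B-G",      lambda B, G, R, RE, NIR: 1.4 * B - G),
    ("GBI",   "II", "G/B",          lambda B, G, R, RE, NIR: _d(G, B)),
    # class III: red edge, no NIR
    ("PSRI",    "III", "(R-G)/RE",    lambda B, G, R, RE, NIR: _d(R - G, RE)),
    ("LIC3",    "III", "B/RE",        lambda B, G, R, RE, NIR: _d(B, RE)),
    ("DCabCxc", "III", "R/G*3*RE",    lambda B, G, R, RE, NIR: _d(R, G) * 3 * RE),
    ("GM1",     "III", "RE/G",        lambda B, G, R, RE, NIR: _d(RE, G)),
    ("NDREI",   "III", "(RE-G)/(RE+G)",
     lambda B, G, R, RE, NIR: _d(RE - G, RE + G)),
    # class IV: NIR, no red edge (mSR printed with RE; kept verbatim)
    ("DVI",  "IV", "NIR-R",           lambda B, G, R, RE, NIR: NIR - R),
    ("mSR",  "IV", "(NIR-B)/(RE-B)",  lambda B, G, R, RE, NIR: _d(NIR - B, RE - B)),
    ("CVI",  "IV", "NIR*R/(G*G)",     lambda B, G, R, RE, NIR: _d(NIR * R, G * G)),
    ("SIPI", "IV", "(NIR-B)/(NIR-R)", lambda B, G, R, RE, NIR: _d(NIR - B, NIR - R)),
    ("GCVI", "IV", "NIR/G-1",         lambda B, G, R, RE, NIR: _d(NIR, G) - 1),
    ("ARI3", "IV", "NIR*(1/G-1/R)",
     lambda B, G, R, RE, NIR: NIR * (_d(1.0, G) - _d(1.0, R))),
    ("BDVI", "IV", "NIR-B",           lambda B, G, R, RE, NIR: NIR - B),
    ("NDVI", "IV", "(NIR-R)/(NIR+R)", lambda B, G, R, RE, NIR: _d(NIR - R, NIR + R)),
    # class V: NIR + red edge
    ("NDRE",    "V", "(NIR-RE)/(NIR+RE)",
     lambda B, G, R, RE, NIR: _d(NIR - RE, NIR + RE)),
    ("LCI",     "V", "(NIR-RE)/(NIR+R)",
     lambda B, G, R, RE, NIR: _d(NIR - RE, NIR + R)),
    ("MTCI",    "V", "(NIR-RE)/(RE-R)",
     lambda B, G, R, RE, NIR: _d(NIR - RE, RE - R)),
    ("DATT",    "V", "(NIR-RE)/(NIR-R)",
     lambda B, G, R, RE, NIR: _d(NIR - RE, NIR - R)),
    ("mNDblue", "V", "(B-RE)/(NIR+B)",
     lambda B, G, R, RE, NIR: _d(B - RE, NIR + B)),
]

REGISTRY: dict[str, SpectralFeatureDef] = {
    name: SpectralFeatureDef(name, cls, formula, func)
    for name, cls, formula, func in _DEFS
}

CLASS_COUNTS = {"I": 5, "II": 7, "III": 5, "IV": 8, "V": 5}
assert len(REGISTRY) == 30
assert {c: sum(d.vi_class == c for d in REGISTRY.values())
        for c in CLASS_COUNTS} == CLASS_COUNTS


def band_means(plot: PlotImage) -> dict[str, float]:
    """Arithmetic mean reflectance per band over unmasked plot pixels."""
    if plot.semantics != REFLECTANCE:
        raise SemanticsError("band means require reflectance semantics")
    if plot.n_pixels == 0:
        raise EmptyPlotError(f"plot {plot.plot_id}: no unmasked pixels")
    return {name: float(plot.band(name)[plot.mask].mean())
            for name in BAND_NAMES}


def compute_vi(name: str, bm: dict[str, float]) -> float:
    """Evaluate one registry formula on band means; NaN where undefined."""
    try:
        d = REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown spectral feature {name!r}; valid: {sorted(REGISTRY)}"
        ) from None
    v = d.func(bm["B"], bm["G"], bm["R"], bm["RE"], bm["NIR"])
    return float(v) if np.isfinite(v) else float("nan")


def spectral_feature_table(plots: Sequence[PlotImage],
                           per_pixel: bool = False):
    """30-column spectral feature table (one row per plot).

    With ``per_pixel=True`` each index is evaluated per pixel and then
    averaged (index-then-mean); the default evaluates each formula on the
    plot-mean reflectances (mean-then-index).
    """
    from .features import FeatureTable

    if not plots:
        raise ValueError("need at least one plot")
    rows = {}
    for plot in plots:
        if per_pixel:
            px = {name: plot.band(name)[plot.mask].astype(float)
                  for name in BAND_NAMES}
            rows[plot.plot_id] = {
                name: float(np.nanmean(np.atleast_1d(
                    d.func(px["B"], px["G"], px["R"], px["RE"], px["NIR"]))))
                for name, d in REGISTRY.items()
            }
        else:
            bm = band_means(plot)
            rows[plot.plot_id] = {name: compute_vi(name, bm)
                                  for name in REGISTRY}
    data = pd.DataFrame.from_dict(rows, orient="index")[list(REGISTRY)]
    meta = pd.DataFrame(
        {
            "feature_type": "SF",
            "vi_class": [REGISTRY[n].vi_class for n in data.columns],
            "formula": [REGISTRY[n].formula for n in data.columns],
        },
        index=data.columns,
    )
    return FeatureTable(data, meta, label="SF")
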