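"""Monte-Carlo studies on synthetic campaigns.

Two groups:

* Boruta sanity — a planted perfect predictor among pure noise must come
  out Confirmed with the noise Rejected, and an all-noise table must
  yield (almost) no Confirmed features, at the nominal binomial level.

* Selection + fusion tendency — the headline property of the method at
  desk scale: with pure-noise features appended to the spectral and
  texture tables, the best dual-strategy model (feature selection +
  feature fusion) should match or beat the unselected single-type
  (SF-only / TF-only) models in median validation R² at every stage,
  with the largest median gain at the late-filling stage, where
  senescence and soil exposure corrupt the spectral signal most.

The study configurations use reduced forest sizes / elimination
granularity (documented in the methods note) so a 20-seed × 3-stage
campaign runs in minutes on one CPU; generator noise levels, effect
sizes and sample sizes are the package defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic
from .features import FeatureTable
from .modeling import SpadSVR, SplitSpec, SvrGrid, build_fusion_sets, split
from .pipeline import _append_noise, extract_stage_features
from .selection import (BorutaConfig, RfeConfig, boruta, make_subsets,
                        rfe)
from .texture import GLCMConfig

FUSION_LABELS = [f"{a}SF--{b}TF"
                 for a in ("C-", "CT-", "R-") for b in ("C-", "CT-", "R-")]


def _derived_seed(base: int, k: int) -> int:
    return int((base * 100003 + k * 7919 + 1) % (2 ** 31))


# ---------------------------------------------------------------------------
# Boruta sanity


def planted_predictor_study(n_seeds: int = 20, n_noise: int = 20,
                            n_samples: int = 36, base_seed: int = 0,
                            config: BorutaConfig | None = None) -> dict:
    """Plant y itself among pure-noise columns; Boruta must find it."""
    confirmed_copy = 0
    rejected_noise = []
    for s in range(n_seeds):
        seed = _derived_seed(base_seed, s)
        rng = np.random.default_rng(seed)
        y = rng.normal(40.0, 8.0, n_samples)
        X = pd.DataFrame(
            rng.normal(size=(n_samples, n_noise)),
            columns=[f"noise_{k}" for k in range(n_noise)])
        X["copy_of_y"] = y
        cfg = dataclasses.replace(config or BorutaConfig(n_estimators=50),
                                  seed=seed + 1)
        statuses = {st.name: st.status for st in boruta(X, y, cfg)}
        confirmed_copy += statuses["copy_of_y"] == "Confirmed"
        rejected_noise.append(
            np.mean([statuses[f"noise_{k}"] == "Rejected"
                     for k in range(n_noise)]))
    return {
        "n_seeds": n_seeds,
        "fraction_copy_confirmed": confirmed_copy / n_seeds,
        "mean_fraction_noise_rejected": float(np.mean(rejected_noise)),
    }


def all_noise_study(n_seeds: int = 50, n_features: int = 30,
                    n_samples: int = 36, base_seed: int = 0,
                    config: BorutaConfig | None = None) -> dict:
    """Type-I check: all-noise tables should yield no Confirmed features."""
    any_confirmed = 0
    total_confirmed = 0
    for s in range(n_seeds):
        seed = _derived_seed(base_seed, 1000 + s)
        rng = np.random.default_rng(seed)
        y = rng.normal(40.0, 8.0, n_samples)
        X = pd.DataFrame(
            rng.normal(size=(n_samples, n_features)),
            columns=[f"noise_{k}" for k in range(n_features)])
        cfg = dataclasses.replace(config or BorutaConfig(n_estimators=50),
                                  seed=seed + 1)
        n_conf = sum(st.status == "Confirmed" for st in boruta(X, y, cfg))
        any_confirmed += n_conf > 0
        total_confirmed += n_conf
    return {
        "n_seeds": n_seeds,
        "fraction_seeds_with_confirmations": any_confirmed / n_seeds,
        "false_confirmation_rate":
            total_confirmed / (n_seeds * n_features),
    }


# ---------------------------------------------------------------------------
# tendency study


@dataclass
class TendencyConfig:
    """Desk-scale study sizes; generator statistics stay at defaults."""

    n_seeds: int = 20
    n_noise_features: int = 40
    boruta: BorutaConfig = dataclasses.field(default_factory=lambda:
        BorutaConfig(max_iterations=25, n_estimators=40))
    rfe_sf: RfeConfig = dataclasses.field(default_factory=lambda:
        RfeConfig(step=2, cv_folds=3, n_estimators=25))
    rfe_tf: RfeConfig = dataclasses.field(default_factory=lambda:
        RfeConfig(step=8, cv_folds=3, n_estimators=25))
    grid: SvrGrid = dataclasses.field(default_factory=SvrGrid)


def _one_seed_runs(seed: int, cfg: TendencyConfig) -> list[dict]:
    design = synthetic.ExperimentDesign(seed=seed)
    gt, images = synthetic.simulate_experiment(design, seed=seed)
    rng = np.random.default_rng(seed + 17)
    rows = []
    for stage in design.stages:
        sf, tf, y = extract_stage_features(gt, images, stage, GLCMConfig())
        half = cfg.n_noise_features // 2
        sf = _append_noise(sf, half, rng, "SF")
        tf = _append_noise(tf, cfg.n_noise_features - half, rng, "TF")

        yv = y.to_numpy()
        b_sf = boruta(sf, yv, dataclasses.replace(cfg.boruta, seed=seed + 3))
        b_tf = boruta(tf, yv, dataclasses.replace(cfg.boruta, seed=seed + 5))
        r_sf = rfe(sf, yv, dataclasses.replace(cfg.rfe_sf, seed=seed + 7))
        r_tf = rfe(tf, yv, dataclasses.replace(cfg.rfe_tf, seed=seed + 9))
        sf_subsets = make_subsets(sf, b_sf, r_sf)
        tf_subsets = make_subsets(tf, b_tf, r_tf)
        tables = {"SF": sf, "TF": tf}
        tables.update(build_fusion_sets(sf_subsets, tf_subsets))

        cal, val = split(y.index, SplitSpec(seed=seed))
        for label, table in tables.items():
            res = SpadSVR(table.data.loc[cal], y.loc[cal].to_numpy(),
                          grid=cfg.grid, seed=seed).fit()
            m = res.evaluate(table.data.loc[val], y.loc[val].to_numpy())
            rows.append({"seed": seed, "stage": stage, "dataset_label": label,
                         "R2_val": m.r2, "RMSE_val": m.rmse,
                         "n_features": table.n_features})
    return rows


def tendency_study(base_seed: int = 0, config: TendencyConfig | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Run the selection+fusion vs single-type comparison over seeds.

    Returns the per-run table and a summary with, per stage, the median
    validation R² of the unselected SF and TF models, the best
    dual-strategy (fusion-of-selected-subsets) median, and the gain of
    the latter over the better single-type model.
    """
    cfg = config or TendencyConfig()
    rows: list[dict] = []
    for s in range(cfg.n_seeds):
        rows.extend(_one_seed_runs(_derived_seed(base_seed, 2000 + s), cfg))
    df = pd.DataFrame(rows)

    med = (df.groupby(["stage", "dataset_label"])["R2_val"]
             .median().unstack("dataset_label"))
    summary = {"per_stage": {}, "gains": {}}
    for stage in med.index:
        fusion_meds = {lab: med.loc[stage, lab] for lab in FUSION_LABELS
                       if lab in med.columns and np.isfinite(med.loc[stage, lab])}
        best_label = max(fusion_meds, key=fusion_meds.get)
        best = fusion_meds[best_label]
        single = {"SF": float(med.loc[stage, "SF"]),
                  "TF": float(med.loc[stage, "TF"])}
        gain = best - max(single.values())
        summary["per_stage"][stage] = {
            "median_R2_SF": single["SF"],
            "median_R2_TF": single["TF"],
            "best_dual_label": best_label,
            "best_dual_median_R2": float(best),
            "gain_over_best_single": float(gain),
        }
        summary["gains"][stage] = float(gain)
    summary["largest_gain_stage"] = max(summary["gains"],
                                        key=summary["gains"].get)
    return df, summary
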