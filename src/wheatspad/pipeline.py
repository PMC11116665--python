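"""End-to-end orchestration: simulate → calibrate → features → select →
model → report, driven by one config and one global seed.

Every stage writes CSV/JSON artifacts into the run directory and a
manifest records the config hash, derived seeds and row/column counts, so
re-running an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .bandstack import extract_plot
from .calibration import apply_elm, fit_elm
from .features import FeatureTable, concat_tables
from .modeling import (SplitSpec, StageData, SvrGrid, run_factorial)
from .selection import (BorutaConfig, RfeConfig, boruta, boruta_subsets,
                        make_subsets, rfe)
from .spectral import spectral_feature_table
from .texture import GLCMConfig, texture_feature_table

log = logging.getLogger("wheatspad")


@dataclass
class DataPaths:
    """Real-data inputs: per-stage imagery plus shared vector/table files.

    ``images[stage]`` is either one 5-band DN TIFF (an orthoimage whose
    coordinates match the polygons) or a directory of per-plot TIFFs
    named ``<plot_id>_<stage>.tif``.  ``ground_truth`` is a CSV with
    plot_id, stage, spad columns; ``panels`` a CSV with
    nominal_reflectance, row0, row1, col0, col1.
    """

    images: dict[str, str]
    polygons: str
    panels: str
    ground_truth: str


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run.

    Exactly one input mode is active: the synthetic block (default) or
    ``paths`` pointing at real data.
    """

    paths: DataPaths | None = None
    design: synthetic.ExperimentDesign = field(
        default_factory=synthetic.ExperimentDesign)
    spad_params: synthetic.SpadModelParams = field(
        default_factory=synthetic.SpadModelParams)
    canopy_params: synthetic.CanopyParams = field(
        default_factory=synthetic.CanopyParams)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    rfe: RfeConfig = field(default_factory=RfeConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    grid: SvrGrid = field(default_factory=SvrGrid)
    experiments: tuple[int, ...] = (1, 2, 3)
    n_noise_features: int = 0      # appended half to SF, half to TF
    seed: int = 0
    out_dir: str = "runs/default"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = {}
        mapping = {
            "synthetic": None,  # handled below
            "glcm": GLCMConfig, "boruta": BorutaConfig, "rfe": RfeConfig,
            "split": SplitSpec, "grid": SvrGrid,
        }
        if "paths" in raw and "synthetic" in raw:
            raise ValueError("config must use either `paths` (real data) "
                             "or `synthetic`, not both")
        if "paths" in raw:
            kw["paths"] = DataPaths(**raw["paths"])
        syn = raw.get("synthetic", {})
        kw["design"] = synthetic.ExperimentDesign(**syn.get("design", {}))
        kw["spad_params"] = synthetic.SpadModelParams(
            **syn.get("spad_params", {}))
        kw["canopy_params"] = synthetic.CanopyParams(
            **syn.get("canopy_params", {}))
        for key, klass in mapping.items():
            if klass is not None and key in raw:
                kw[key] = klass(**raw[key])
        for key in ("experiments", "n_noise_features", "seed", "out_dir"):
            if key in raw:
                kw[key] = tuple(raw[key]) if key == "experiments" else raw[key]
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _append_noise(table: FeatureTable, n: int, rng: np.random.Generator,
                  feature_type: str) -> FeatureTable:
    """Append pure-noise columns (standard normal), typed like the table."""
    if n <= 0:
        return table
    cols = {f"noise_{feature_type}_{k:02d}":
            rng.normal(size=len(table.data)) for k in range(n)}
    noise = pd.DataFrame(cols, index=table.data.index)
    meta = pd.DataFrame({"feature_type": feature_type, "noise": True},
                        index=noise.columns)
    return FeatureTable(pd.concat([table.data, noise], axis=1),
                        pd.concat([table.meta, meta]), label=table.label)


def _load_real_plots(paths: DataPaths, stage: str):
    """Read, calibrate and extract one stage's plots from files on disk."""
    from .bandstack import CalPanel, read_regions_geojson, read_stack

    panels_path = Path(paths.panels)
    if not panels_path.exists():
        raise FileNotFoundError(
            f"calibrate stage: panels file not found: {panels_path}")
    pdf = pd.read_csv(panels_path)
    panels = [CalPanel(float(r.nominal_reflectance),
                       (int(r.row0), int(r.row1), int(r.col0), int(r.col1)))
              for r in pdf.itertuples(index=False)]
    regions = read_regions_geojson(paths.polygons)
    img_path = Path(paths.images[stage])
    plots = []
    if img_path.is_dir():
        for region in regions:
            stack = read_stack(img_path / f"{region.plot_id}_{stage}.tif")
            refl = apply_elm(stack, fit_elm(stack, panels))
            plots.append(extract_plot(refl, region))
    else:
        stack = read_stack(img_path)
        refl = apply_elm(stack, fit_elm(stack, panels))
        plots = [extract_plot(refl, r) for r in regions]
    return plots


def extract_stage_features(gt: pd.DataFrame, images: dict, stage: str,
                           glcm: GLCMConfig):
    """Calibrate (per-image ELM), extract plots, build SF + TF tables."""
    plots = []
    sub = gt[gt["stage"] == stage]
    for row in sub.itertuples(index=False):
        stack, region, panels = images[(row.plot_id, row.stage)]
        coef = fit_elm(stack, panels)
        refl = apply_elm(stack, coef)
        plots.append(extract_plot(refl, region))
    sf = spectral_feature_table(plots).impute_median()
    tf = texture_feature_table(plots, glcm).impute_median()
    y = sub.set_index("plot_id")["spad"]
    return sf, tf, y


def select_stage(sf: FeatureTable, tf: FeatureTable, y: pd.Series,
                 boruta_cfg: BorutaConfig, rfe_cfg: RfeConfig,
                 stage_seed: int) -> StageData:
    """Run Boruta + RFE on SF, TF and the fused SFTF table for one stage."""
    stage_data = {}
    tables = {"SF": sf, "TF": tf, "SFTF": concat_tables(sf, tf, "SFTF")}
    subsets = {}
    reports = {}
    for k, (name, table) in enumerate(tables.items()):
        bc = dataclasses.replace(boruta_cfg, seed=stage_seed + 7 * k + 1)
        rc = dataclasses.replace(rfe_cfg, seed=stage_seed + 7 * k + 2)
        statuses = boruta(table, y.to_numpy(), bc)
        r = rfe(table, y.to_numpy(), rc)
        subsets[name] = make_subsets(table, statuses, r)
        reports[name] = {
            "statuses": [{"name": s.name, "status": s.status,
                          "hits": s.hits, "iterations": s.iterations}
                         for s in statuses],
            "rfe_selected": r.selected,
            "rfe_cv_rmse_path": r.detail["cv_rmse_path"],
        }
    sd = StageData(
        stage="", sf=sf, tf=tf, y=y,
        sf_subsets=subsets["SF"], tf_subsets=subsets["TF"],
        sftf_subsets=subsets["SFTF"],
    )
    sd.selection_report = reports  # type: ignore[attr-defined]
    return sd


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    rng = np.random.default_rng(seed + 101)

    if config.paths is not None:
        gt = pd.read_csv(config.paths.ground_truth)
        stage_names = list(config.paths.images)
        images = None
        log.info("ingest: %d ground-truth rows, %d stages", len(gt),
                 len(stage_names))
    else:
        log.info("simulate: %d plots x %d stages", config.design.n_plots,
                 len(config.design.stages))
        design_df = synthetic.generate_design(config.design)
        gt, images = synthetic.simulate_experiment(
            config.design, config.spad_params, config.canopy_params, seed)
        design_df.to_csv(out / "design.csv", index=False)
        stage_names = list(config.design.stages)
    gt.to_csv(out / "ground_truth.csv", index=False)

    stages: list[StageData] = []
    manifest_stages = {}
    for si, stage in enumerate(stage_names):
        if config.paths is not None:
            plots = _load_real_plots(config.paths, stage)
            sf = spectral_feature_table(plots).impute_median()
            tf = texture_feature_table(plots, config.glcm).impute_median()
            y = gt[gt["stage"] == stage].set_index("plot_id")["spad"]
        else:
            sf, tf, y = extract_stage_features(gt, images, stage,
                                               config.glcm)
        half = config.n_noise_features // 2
        sf = _append_noise(sf, half, rng, "SF")
        tf = _append_noise(tf, config.n_noise_features - half, rng, "TF")
        sf.to_csv(out / f"sf_{stage}.csv", out / f"sf_{stage}.meta.json")
        tf.to_csv(out / f"tf_{stage}.csv", out / f"tf_{stage}.meta.json")
        log.info("%s: SF %d cols, TF %d cols", stage, sf.n_features,
                 tf.n_features)
        sd = select_stage(sf, tf, y, config.boruta, config.rfe,
                          stage_seed=seed + 1000 * (si + 1))
        sd.stage = stage
        with open(out / f"selection_{stage}.json", "w") as fh:
            json.dump(sd.selection_report, fh, indent=1)
        stages.append(sd)
        manifest_stages[stage] = {
            "n_plots": len(y), "sf_cols": sf.n_features,
            "tf_cols": tf.n_features,
            "sftf_cols": sf.n_features + tf.n_features,
        }

    predictions: list = []
    run_log: list = []
    runs = run_factorial(stages, experiments=config.experiments,
                         grid=config.grid, split_spec=config.split,
                         seed=seed, log=run_log, predictions=predictions)
    runs.to_csv(out / "model_runs.csv", index=False)
    pd.DataFrame(predictions).to_csv(out / "predictions.csv", index=False)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "stages": manifest_stages,
        "n_model_runs": int(len(runs)),
        "skipped": run_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def report(run_dir) -> Path:
    """Summaries of a finished run: best models, selection counts, scatter."""
    run_dir = Path(run_dir)
    runs_path = run_dir / "model_runs.csv"
    if not runs_path.exists():
        raise FileNotFoundError(f"{runs_path}: run the pipeline first")
    runs = pd.read_csv(runs_path)
    rep = run_dir / "report"
    rep.mkdir(exist_ok=True)
    if runs.empty:
        (rep / "summary.txt").write_text("no runs\n")
        return rep

    best = (runs.sort_values("R2_val", ascending=False)
                .groupby(["experiment", "stage"], as_index=False).first())
    best.to_csv(rep / "best_models.csv", index=False)

    # selection composition: counts per band / VI class per stage
    counts = []
    for sel_path in sorted(run_dir.glob("selection_*.json")):
        stage = sel_path.stem.replace("selection_", "")
        with open(sel_path) as fh:
            sel = json.load(fh)
        for table, info in sel.items():
            for sub, names in (("C-", [s["name"] for s in info["statuses"]
                                       if s["status"] == "Confirmed"]),
                               ("R-", info["rfe_selected"])):
                counts.append({"stage": stage, "table": table,
                               "subset": sub, "n_selected": len(names)})
    pd.DataFrame(counts).to_csv(rep / "selection_counts.csv", index=False)

    pred_path = run_dir / "predictions.csv"
    if pred_path.exists():
        preds = pd.read_csv(pred_path)
        if not preds.empty:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            stages_ = best["stage"].unique()
            fig, axes = plt.subplots(1, len(stages_),
                                     figsize=(4 * len(stages_), 4))
            axes = np.atleast_1d(axes)
            for ax, stage in zip(axes, stages_):
                brow = best[best["stage"] == stage].iloc[0]
                p = preds[(preds["stage"] == stage)
                          & (preds["dataset_label"] == brow["dataset_label"])
                          & (preds["experiment"] == brow["experiment"])]
                ax.scatter(p["y_true"], p["y_pred"], s=18)
                lim = [min(p["y_true"].min(), p["y_pred"].min()),
                       max(p["y_true"].max(), p["y_pred"].max())]
                ax.plot(lim, lim, "k--", lw=1)
                ax.set_title(f"{stage}: {brow['dataset_label']}")
                ax.set_xlabel("observed SPAD")
                ax.set_ylabel("predicted SPAD")
            fig.tight_layout()
            fig.savefig(rep / "scatter_best.png", dpi=120)
            plt.close(fig)
    return rep
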