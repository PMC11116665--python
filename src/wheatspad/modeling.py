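"""SVR modelling of SPAD from feature tables, with the study factorial.

The estimation model is an RBF-kernel support vector regression fitted on
standardized features.  Hyperparameters (C, γ, ε) are chosen by an inner
K-fold grid search on the calibration set only; the scaler is fitted on
the calibration set only (no leakage into validation).  Accuracy is
reported as

* R²   = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²   (conventional residual form),
* RMSE = sqrt(mean((ŷᵢ − yᵢ)²))          (SPAD units),
* RPD  = SD_reference / RMSE, with SD_reference defaulting to the
  calibration-set sample SD (n−1) — the convention consistent with the
  published descriptive tables this pipeline mirrors.

The public surface follows the model/results idiom: :class:`SpadSVR` is
built from data, ``fit()`` returns a :class:`SpadSVRResults` carrying the
chosen hyperparameters, calibration metrics and a ``summary()`` table;
``evaluate()`` scores held-out plots.

The factorial runner reproduces the study's three experiments per stage:
24 single-type runs (SF/TF × full/C-/CT-/R-), 12 selected-fusion runs
(SFTF × full/C-/CT-/R-), and 30 pairwise-fusion runs (3×3 subset combos
plus the unselected SFTF control).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import FeatureTable, concat_tables

EXPERIMENT_LABELS = {
    1: ["SF", "R-SF", "C-SF", "CT-SF", "TF", "R-TF", "C-TF", "CT-TF"],
    2: ["SFTF", "R-SFTF", "C-SFTF", "CT-SFTF"],
    3: ["SFTF"] + [f"{a}SF--{b}TF"
                   for a in ("C-", "CT-", "R-") for b in ("C-", "CT-", "R-")],
}


class DegenerateTargetError(ValueError):
    pass


# ---------------------------------------------------------------------------
# split


@dataclass
class SplitSpec:
    calibration_fraction: float = 2.0 / 3.0
    seed: int = 0
    stratify: bool = False


def split(index, spec: SplitSpec) -> tuple[list, list]:
    """Random disjoint calibration/validation partition of plot ids.

    ``n_cal = floor(f · n)``, so 36 plots give the 24/12 split and 3 give
    2/1.  Deterministic under the spec seed.
    """
    index = list(index)
    n = len(index)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_cal = int(np.floor(spec.calibration_fraction * n))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    cal = [index[i] for i in sorted(perm[:n_cal])]
    val = [index[i] for i in sorted(perm[n_cal:])]
    return cal, val


# ---------------------------------------------------------------------------
# metrics


@dataclass
class Metrics:
    r2: float
    rmse: float
    rpd: float
    n: int
    sd_reference: float
    sd_provenance: str = "calibration"


def r_squared(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateTargetError("zero target variance; R^2 undefined")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def rpd(sd_reference: float, rmse_value: float) -> float:
    """Ratio of performance to deviation; inf (flagged) at zero RMSE."""
    if rmse_value == 0:
        return float("inf")
    return float(sd_reference) / float(rmse_value)


def compute_metrics(y_true, y_pred, sd_reference: float,
                    sd_provenance: str = "calibration") -> Metrics:
    e = rmse(y_true, y_pred)
    return Metrics(
        r2=r_squared(y_true, y_pred),
        rmse=e,
        rpd=rpd(sd_reference, e),
        n=len(np.asarray(y_true)),
        sd_reference=float(sd_reference),
        sd_provenance=sd_provenance,
    )


# ---------------------------------------------------------------------------
# SVR model / results


@dataclass
class SvrGrid:
    """Hyperparameter grid for the inner search (the study names none)."""

    C: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_factors: tuple[float, ...] = (0.1, 1.0, 10.0)  # × "scale" heuristic
    epsilon: tuple[float, ...] = (0.01, 0.1, 1.0)
    cv_folds: int = 5


class SpadSVR:
    """RBF-SVR SPAD model built from a calibration feature matrix.

    Parameters
    ----------
    X : DataFrame (plots × features), no missing values
    y : 1-d array-like of SPAD, aligned with X
    grid : SvrGrid
    seed : int — controls the inner CV folds.
    """

    def __init__(self, X: pd.DataFrame, y, grid: SvrGrid | None = None,
                 seed: int = 0):
        if isinstance(X, FeatureTable):
            X = X.data
        self.X = X.astype(float)
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")
        if len(self.y) < 2:
            raise ValueError("need at least 2 calibration samples")
        if np.ptp(self.y) == 0:
            raise DegenerateTargetError("constant calibration target")
        if self.X.isna().any().any():
            raise ValueError("missing values in features; impute first")
        self.grid = grid or SvrGrid()
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "spad",
                       features: list[str] | None = None, **kw) -> "SpadSVR":
        feats = features or [c for c in df.columns if c != target]
        return cls(df[feats], df[target].to_numpy(), **kw)

    def fit(self) -> "SpadSVRResults":
        Xc = self.X.to_numpy(dtype=float)
        scaler = StandardScaler().fit(Xc)
        Xs = scaler.transform(Xc)
        n, p = Xs.shape
        var = Xs.var()
        gamma_scale = 1.0 / (p * var) if var > 0 else 1.0

        folds = min(self.grid.cv_folds, n)
        kf = KFold(n_splits=folds, shuffle=True, random_state=self.seed)
        splits = list(kf.split(Xs))

        best = None  # (cv_rmse, C, -eps) lexicographic; then params
        for C in sorted(self.grid.C):
            for gf in self.grid.gamma_factors:
                gamma = gf * gamma_scale
                for eps in sorted(self.grid.epsilon, reverse=True):
                    errs = []
                    for tr, te in splits:
                        m = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
                        m.fit(Xs[tr], self.y[tr])
                        errs.append(np.mean(
                            (m.predict(Xs[te]) - self.y[te]) ** 2))
                    cv_rmse = float(np.sqrt(np.mean(errs)))
                    key = (round(cv_rmse, 12), C, -eps)
                    if best is None or key < best[0]:
                        best = (key, {"C": C, "gamma": gamma, "epsilon": eps},
                                cv_rmse)
        params, cv_rmse = best[1], best[2]
        svr = SVR(kernel="rbf", **params).fit(Xs, self.y)
        sd_cal = float(np.std(self.y, ddof=1))
        cal_metrics = compute_metrics(self.y, svr.predict(Xs), sd_cal,
                                      "calibration")
        return SpadSVRResults(model=self, scaler=scaler, svr=svr,
                              params=params, cv_rmse=cv_rmse,
                              sd_calibration=sd_cal,
                              calibration=cal_metrics)


@dataclass
class SpadSVRResults:
    """Fitted SVR with its scaler, chosen hyperparameters and metrics."""

    model: SpadSVR
    scaler: StandardScaler
    svr: SVR
    params: dict
    cv_rmse: float
    sd_calibration: float
    calibration: Metrics
    validation: Metrics | None = None

    def predict(self, X) -> np.ndarray:
        if isinstance(X, FeatureTable):
            X = X.data
        X = np.asarray(X, dtype=float)
        return self.svr.predict(self.scaler.transform(X))

    def evaluate(self, X_val, y_val, sd_reference: float | None = None,
                 sd_provenance: str | None = None) -> Metrics:
        """Score held-out plots; RPD uses the calibration SD by default."""
        y_val = np.asarray(y_val, dtype=float)
        if len(y_val) == 0:
            raise ValueError("validation set is empty")
        if sd_reference is None:
            sd_reference = self.sd_calibration
            sd_provenance = sd_provenance or "calibration"
        m = compute_metrics(y_val, self.predict(X_val), sd_reference,
                            sd_provenance or "explicit")
        self.validation = m
        return m

    def summary(self) -> str:
        lines = [
            "SPAD SVR (RBF) results",
            "-" * 46,
            f"n calibration     {self.calibration.n:>10d}",
            f"n features        {self.model.X.shape[1]:>10d}",
            f"C                 {self.params['C']:>10.4g}",
            f"gamma             {self.params['gamma']:>10.4g}",
            f"epsilon           {self.params['epsilon']:>10.4g}",
            f"inner CV RMSE     {self.cv_rmse:>10.3f}",
            f"calibration R2    {self.calibration.r2:>10.3f}",
            f"calibration RMSE  {self.calibration.rmse:>10.3f}",
            f"calibration RPD   {self.calibration.rpd:>10.3f}",
        ]
        if self.validation is not None:
            lines += [
                f"validation R2     {self.validation.r2:>10.3f}",
                f"validation RMSE   {self.validation.rmse:>10.3f}",
                f"validation RPD    {self.validation.rpd:>10.3f}",
            ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fusion + factorial


def build_fusion_sets(sf_subsets: dict[str, FeatureTable],
                      tf_subsets: dict[str, FeatureTable],
                      log: list | None = None) -> dict[str, FeatureTable]:
    """The 3×3 pairwise fusions of {C-,CT-,R-}SF × {C-,CT-,R-}TF."""
    fused: dict[str, FeatureTable] = {}
    for a, b in itertools.product(("C-", "CT-", "R-"), repeat=2):
        la, lb = f"{a}SF", f"{b}TF"
        label = f"{la}--{lb}"
        ta, tb = sf_subsets.get(la), tf_subsets.get(lb)
        if ta is None or tb is None or ta.n_features == 0 or tb.n_features == 0:
            if log is not None:
                log.append(f"fusion {label} skipped: empty subset")
            continue
        fused[label] = concat_tables(ta, tb, label=label)
    return fused


@dataclass
class StageData:
    """Everything the factorial needs for one growth stage."""

    stage: str
    sf: FeatureTable
    tf: FeatureTable
    y: pd.Series                       # SPAD per plot_id
    sf_subsets: dict[str, FeatureTable] = field(default_factory=dict)
    tf_subsets: dict[str, FeatureTable] = field(default_factory=dict)
    sftf_subsets: dict[str, FeatureTable] = field(default_factory=dict)

    def sftf(self) -> FeatureTable:
        return concat_tables(self.sf, self.tf, label="SFTF")

    def table_for(self, label: str) -> FeatureTable | None:
        if label == "SF":
            return self.sf
        if label == "TF":
            return self.tf
        if label == "SFTF":
            return self.sftf()
        if label in self.sf_subsets:
            return self.sf_subsets[label]
        if label in self.tf_subsets:
            return self.tf_subsets[label]
        if label in self.sftf_subsets:
            return self.sftf_subsets[label]
        if "--" in label:
            fused = build_fusion_sets(self.sf_subsets, self.tf_subsets)
            return fused.get(label)
        raise KeyError(f"unknown dataset label {label!r}")


def run_factorial(stages: list[StageData], experiments=(1, 2, 3),
                  grid: SvrGrid | None = None,
                  split_spec: SplitSpec | None = None,
                  seed: int = 0,
                  log: list | None = None,
                  predictions: list | None = None) -> pd.DataFrame:
    """Fit every (stage × dataset × experiment) SVR and tabulate metrics.

    One split per stage, shared across all feature sets, so within-stage
    comparisons are paired.  Returns the machine-readable twin of the
    study's results tables with columns (experiment, stage, dataset_label,
    n_features, R2_cal, RMSE_cal, RPD_cal, R2_val, RMSE_val, RPD_val, n_cal,
    n_val, seed).
    """
    grid = grid or SvrGrid()
    split_spec = split_spec or SplitSpec(seed=seed)
    rows = []
    for sd in stages:
        cal_ids, val_ids = split(sd.y.index, split_spec)
        labels_done = set()
        for exp in experiments:
            for label in EXPERIMENT_LABELS[exp]:
                key = (exp, label)
                if key in labels_done:
                    continue
                labels_done.add(key)
                table = sd.table_for(label)
                if table is None or table.n_features == 0:
                    if log is not None:
                        log.append(
                            f"{sd.stage}/{label} (exp {exp}) skipped: "
                            "empty feature set")
                    continue
                res = SpadSVR(table.data.loc[cal_ids],
                              sd.y.loc[cal_ids].to_numpy(),
                              grid=grid, seed=seed).fit()
                val = res.evaluate(table.data.loc[val_ids],
                                   sd.y.loc[val_ids].to_numpy())
                if predictions is not None:
                    y_hat = res.predict(table.data.loc[val_ids])
                    for pid, yt, yp in zip(val_ids,
                                           sd.y.loc[val_ids], y_hat):
                        predictions.append({
                            "experiment": exp, "stage": sd.stage,
                            "dataset_label": label, "plot_id": pid,
                            "y_true": float(yt), "y_pred": float(yp),
                        })
                rows.append({
                    "experiment": exp,
                    "stage": sd.stage,
                    "dataset_label": label,
                    "n_features": table.n_features,
                    "R2_cal": res.calibration.r2,
                    "RMSE_cal": res.calibration.rmse,
                    "RPD_cal": res.calibration.rpd,
                    "R2_val": val.r2,
                    "RMSE_val": val.rmse,
                    "RPD_val": val.rpd,
                    "n_cal": len(cal_ids),
                    "n_val": len(val_ids),
                    "seed": seed,
                })
    return pd.DataFrame(rows)
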