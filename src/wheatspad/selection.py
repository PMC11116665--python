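"""Feature selection: Boruta (shadow features) and recursive elimination.

Boruta appends a permuted "shadow" copy of every candidate column (at
least five shadows are kept even when few candidates remain undecided,
so the max-shadow benchmark stays competitive), fits a random-forest
regressor, turns per-tree impurity importances into Z-scores (mean / SD
across trees), and records a *hit* for every real feature whose Z-score
beats the best shadow that iteration (the classic max-shadow rule).  A
two-sided binomial test on the accumulated hit counts — Bonferroni
adjusted across the candidate features, as in the reference algorithm —
promotes features to Confirmed or demotes them to Rejected; whatever is
undecided when iterations run out stays Tentative.  The
Confirmed (C-) and Confirmed+Tentative (CT-) subsets are both kept — no
rough-fix pass — because the two sets are analysed as distinct model
inputs downstream.

RFE ranks features with a random forest, drops the lowest-ranked
``step`` features per round, scores every visited subset size by K-fold
cross-validated RMSE, and returns the subset (prefix of the elimination
path) with the minimum mean CV-RMSE, ties broken toward the smaller
subset (R- prefix downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .features import FeatureTable

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"


@dataclass
class BorutaConfig:
    max_iterations: int = 100
    level: float = 0.01            # two-sided binomial test level
    n_estimators: int = 100
    max_features: str | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 10:
            raise ValueError("max_iterations must be >= 10")
        if not 0 < self.level < 0.5:
            raise ValueError("level must be in (0, 0.5)")


@dataclass
class RfeConfig:
    step: int = 1
    cv_folds: int = 5
    n_estimators: int = 100
    max_features: str | float = "sqrt"
    seed: int = 0


@dataclass
class FeatureStatus:
    name: str
    status: str
    hits: int
    iterations: int
    z_history: list[float] = field(default_factory=list)


@dataclass
class SelectionResult:
    method: str                       # "Boruta" | "RFE"
    subset_label: str                 # "C-", "CT-" or "R-"
    selected: list[str]
    detail: dict


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    if X.isna().any().any():
        raise ValueError("feature table contains missing values; impute first")
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant target; nothing to select for")
    return y


def _tree_z_scores(rf: RandomForestRegressor) -> np.ndarray:
    """Z-score per feature: mean per-tree importance over its SD."""
    imp = np.stack([t.feature_importances_ for t in rf.estimators_])
    mean = imp.mean(axis=0)
    sd = imp.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = mean / sd
    # a feature used identically in every tree (sd 0): infinite evidence if
    # its importance is positive, none otherwise
    z = np.where(sd > 0, z, np.where(mean > 0, np.inf, 0.0))
    return z


def boruta(X: FeatureTable | pd.DataFrame, y, config: BorutaConfig | None = None
           ) -> list[FeatureStatus]:
    """Classify every feature as Confirmed / Tentative / Rejected."""
    config = config or BorutaConfig()
    df = X.data if isinstance(X, FeatureTable) else X
    y = _check_xy(df, y)
    rng = np.random.default_rng(config.seed)
    names = list(df.columns)
    n_feat = len(names)
    values = df.to_numpy(dtype=float)

    hits = np.zeros(n_feat, dtype=int)
    seen = np.zeros(n_feat, dtype=int)
    decided = np.full(n_feat, "", dtype=object)
    z_hist: list[list[float]] = [[] for _ in range(n_feat)]

    for it in range(1, config.max_iterations + 1):
        active = np.where(decided == "")[0]
        if active.size == 0:
            break
        cols = values[:, active]
        # keep at least 5 shadows so the max-shadow benchmark stays
        # competitive when few candidates remain (reference behaviour)
        shadows = cols.copy()
        while shadows.shape[1] < 5:
            shadows = np.concatenate([shadows, cols], axis=1)
        shadows = shadows.copy()
        for k in range(shadows.shape[1]):
            shadows[:, k] = rng.permutation(shadows[:, k])
        X_aug = np.concatenate([cols, shadows], axis=1)
        rf = RandomForestRegressor(
            n_estimators=config.n_estimators,
            max_features=config.max_features,
            random_state=int(rng.integers(2 ** 31)),
        )
        rf.fit(X_aug, y)
        z = _tree_z_scores(rf)
        z_real, z_shadow = z[:cols.shape[1]], z[cols.shape[1]:]
        best_shadow = z_shadow.max() if z_shadow.size else -np.inf
        hit = z_real > best_shadow
        hits[active] += hit
        seen[active] += 1
        for a, zz in zip(active, z_real):
            z_hist[a].append(float(zz))

        # two-sided binomial test on hit counts under p = 1/2,
        # Bonferroni-adjusted across the candidate features
        threshold = config.level / 2.0 / n_feat
        for a in active:
            n, h = seen[a], hits[a]
            p_hi = stats.binom.sf(h - 1, n, 0.5)   # P[X >= h]
            p_lo = stats.binom.cdf(h, n, 0.5)      # P[X <= h]
            if p_hi < threshold:
                decided[a] = CONFIRMED
            elif p_lo < threshold:
                decided[a] = REJECTED

    return [
        FeatureStatus(
            name=names[i],
            status=decided[i] if decided[i] else TENTATIVE,
            hits=int(hits[i]),
            iterations=int(seen[i]),
            z_history=z_hist[i],
        )
        for i in range(n_feat)
    ]


def rfe(X: FeatureTable | pd.DataFrame, y, config: RfeConfig | None = None
        ) -> SelectionResult:
    """Backward elimination; returns the CV-RMSE-optimal subset (R-)."""
    config = config or RfeConfig()
    df = X.data if isinstance(X, FeatureTable) else X
    y = _check_xy(df, y)
    if len(y) < config.cv_folds:
        raise ValueError(
            f"n={len(y)} smaller than cv_folds={config.cv_folds}")
    rng = np.random.default_rng(config.seed)
    current = list(df.columns)
    path: list[tuple[list[str], float]] = []
    rank_order: list[str] = []       # elimination order, worst first

    kf = KFold(n_splits=config.cv_folds, shuffle=True,
               random_state=int(rng.integers(2 ** 31)))
    splits = list(kf.split(df))      # same folds for every subset size

    while current:
        Xc = df[current].to_numpy(dtype=float)
        rmses = []
        for tr, te in splits:
            rf = RandomForestRegressor(
                n_estimators=config.n_estimators,
                max_features=config.max_features,
                random_state=int(rng.integers(2 ** 31)),
            )
            rf.fit(Xc[tr], y[tr])
            pred = rf.predict(Xc[te])
            rmses.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
        path.append((list(current), float(np.mean(rmses))))
        if len(current) == 1:
            rank_order.append(current[0])
            break
        ranker = RandomForestRegressor(
            n_estimators=config.n_estimators,
            max_features=config.max_features,
            random_state=int(rng.integers(2 ** 31)),
        )
        ranker.fit(Xc, y)
        imp = ranker.feature_importances_
        n_drop = min(config.step, len(current) - 1)
        worst = np.argsort(imp, kind="stable")[:n_drop]
        for w in sorted(worst, key=lambda k: imp[k]):
            rank_order.append(current[w])
        current = [c for k, c in enumerate(current) if k not in set(worst)]

    sizes = [len(fs) for fs, _ in path]
    scores = [s for _, s in path]
    best = min(range(len(path)), key=lambda k: (scores[k], sizes[k]))
    selected, best_rmse = path[best]
    ranks = {name: len(rank_order) - i for i, name in enumerate(rank_order)}
    return SelectionResult(
        method="RFE",
        subset_label="R-",
        selected=selected,
        detail={
            "cv_rmse_path": list(zip(sizes, scores)),
            "best_cv_rmse": best_rmse,
            "ranks": ranks,
            "config": config,
        },
    )


def boruta_subsets(statuses: list[FeatureStatus]) -> dict[str, list[str]]:
    """C- (Confirmed) and CT- (Confirmed + Tentative) name lists."""
    c = [s.name for s in statuses if s.status == CONFIRMED]
    ct = [s.name for s in statuses if s.status in (CONFIRMED, TENTATIVE)]
    return {"C-": c, "CT-": ct}


def make_subsets(table: FeatureTable,
                 boruta_statuses: list[FeatureStatus] | None = None,
                 rfe_result: SelectionResult | None = None,
                 ) -> dict[str, FeatureTable]:
    """Labeled column subsets, e.g. "C-SF", "CT-SF", "R-SF" for an SF table.

    An empty Confirmed set yields an empty (0-column) table, not an error.
    """
    out: dict[str, FeatureTable] = {}
    suffix = table.label or "X"
    if boruta_statuses is not None:
        subs = boruta_subsets(boruta_statuses)
        for prefix, names in subs.items():
            out[f"{prefix}{suffix}"] = table.subset(names,
                                                    label=f"{prefix}{suffix}")
    if rfe_result is not None:
        out[f"R-{suffix}"] = table.subset(rfe_result.selected,
                                          label=f"R-{suffix}")
    return out
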