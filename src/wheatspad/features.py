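"""Plots × features matrix with per-feature metadata.

A thin wrapper over two aligned pandas DataFrames: ``data`` (rows = plots,
columns = features) and ``meta`` (one row per feature: feature type SF/TF,
band, vegetation-index class, GLCM metric, plot statistic, formula).
Fusion is column concatenation with type-prefix disambiguation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import pandas as pd


@dataclass
class FeatureTable:
    data: pd.DataFrame
    meta: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.meta.index):
            raise ValueError("meta rows must align with data columns")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, names, label: str = "") -> "FeatureTable":
        names = list(names)
        missing = set(names) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        return FeatureTable(self.data[names].copy(), self.meta.loc[names].copy(),
                            label=label or self.label)

    def impute_median(self, groups=None) -> "FeatureTable":
        """Median-impute missing values, optionally within groups (stages)."""
        df = self.data.copy()
        if groups is None:
            df = df.fillna(df.median())
        else:
            df = df.groupby(pd.Series(groups, index=df.index)).transform(
                lambda s: s.fillna(s.median()))
        return FeatureTable(df, self.meta.copy(), label=self.label)

    def to_csv(self, path, sidecar_path=None) -> None:
        self.data.to_csv(path, index_label="plot_id")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"label": self.label,
                     "features": self.meta.reset_index()
                                     .rename(columns={"index": "name"})
                                     .to_dict(orient="records")},
                    fh, indent=1)


def concat_tables(left: FeatureTable, right: FeatureTable,
                  label: str) -> FeatureTable:
    """Fuse two tables column-wise; clashing names get a type prefix."""
    lt, rt = left.data.copy(), right.data.copy()
    lm, rm = left.meta.copy(), right.meta.copy()
    clash = set(lt.columns) & set(rt.columns)
    if clash:
        def _prefix(df, meta, side):
            ftype = meta["feature_type"].iloc[0] if len(meta) else side
            ren = {c: f"{ftype}:{c}" for c in clash if c in df.columns}
            return df.rename(columns=ren), meta.rename(index=ren)
        lt, lm = _prefix(lt, lm, "L")
        rt, rm = _prefix(rt, rm, "R")
        still = set(lt.columns) & set(rt.columns)   # e.g. self-fusion
        if still:
            ren = {c: f"{c}#2" for c in still}
            rt, rm = rt.rename(columns=ren), rm.rename(index=ren)
    if not lt.index.equals(rt.index):
        raise ValueError("fusion requires identical plot indices")
    return FeatureTable(pd.concat([lt, rt], axis=1),
                        pd.concat([lm, rm], axis=0), label=label)
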