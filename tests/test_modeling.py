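"""Split, metrics, SVR model/results, fusion sets and the factorial."""

import numpy as np
import pandas as pd
import pytest

from wheatspad.features import FeatureTable, concat_tables
from wheatspad.modeling import (DegenerateTargetError, EXPERIMENT_LABELS,
                                SpadSVR, SplitSpec, StageData,
                                SvrGrid, build_fusion_sets, compute_metrics,
                                r_squared, rmse, rpd, run_factorial, split)


def table_of(rng, n, p, label, ftype=None):
    ftype = ftype or label
    data = pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"{label}_{k}" for k in range(p)],
                        index=[f"plot{j}" for j in range(n)])
    meta = pd.DataFrame({"feature_type": ftype}, index=data.columns)
    return FeatureTable(data, meta, label=label)


class TestSplit:
    def test_36_gives_24_12(self):
        cal, val = split([f"p{k}" for k in range(36)], SplitSpec(seed=0))
        assert len(cal) == 24 and len(val) == 12
        assert set(cal).isdisjoint(val)
        assert set(cal) | set(val) == {f"p{k}" for k in range(36)}

    def test_smallest_split(self):
        cal, val = split(["a", "b", "c"], SplitSpec(seed=1))
        assert len(cal) == 2 and len(val) == 1

    def test_determinism(self):
        idx = list(range(30))
        assert split(idx, SplitSpec(seed=5)) == split(idx, SplitSpec(seed=5))
        assert split(idx, SplitSpec(seed=5)) != split(idx, SplitSpec(seed=6))


class TestMetrics:
    def test_oracle_equivalence_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(3, 40)
            y = rng.normal(30, 10, n)
            yh = y + rng.normal(0, 3, n)
            sd = float(rng.uniform(1, 15))
            # independent literal oracles
            r2_o = 1 - np.sum((y - yh) ** 2) / np.sum((y - np.mean(y)) ** 2)
            rmse_o = np.sqrt(np.sum((yh - y) ** 2) / n)
            rpd_o = sd / rmse_o
            m = compute_metrics(y, yh, sd)
            assert m.r2 == pytest.approx(r2_o, abs=1e-12)
            assert m.rmse == pytest.approx(rmse_o, abs=1e-12)
            assert m.rpd == pytest.approx(rpd_o, abs=1e-12)

    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        m = compute_metrics(y, y, sd_reference=1.0)
        assert m.r2 == 1.0 and m.rmse == 0.0 and np.isinf(m.rpd)

    def test_constant_offset_rmse(self):
        y = np.array([10.0, 20.0, 30.0])
        assert rmse(y, y + 2.5) == pytest.approx(2.5)

    def test_published_rpd_arithmetic(self):
        # calibration SD / validation RMSE for the three consistent
        # full-table rows
        assert round(rpd(6.42, 5.463), 3) == 1.175
        assert round(rpd(12.39, 10.794), 3) == 1.148
        assert round(rpd(12.39, 10.599), 3) == 1.169

    def test_rpd_times_rmse_recovers_sd(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = rng.normal(30, 10, 12)
            yh = y + rng.normal(0, 2, 12)
            sd = float(rng.uniform(1, 15))
            m = compute_metrics(y, yh, sd)
            assert m.rpd * m.rmse == pytest.approx(sd, abs=1e-9)

    def test_zero_variance_target(self):
        with pytest.raises(DegenerateTargetError):
            r_squared(np.ones(5), np.zeros(5))


class TestSpadSVR:
    def test_recovers_noiseless_linear_function(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, (40, 1))
        y = 2.0 * x[:, 0]
        X = pd.DataFrame(x, columns=["x"])
        res = SpadSVR(X.iloc[:30], y[:30], seed=0).fit()
        m = res.evaluate(X.iloc[30:], y[30:])
        assert m.r2 > 0.99

    def test_determinism_of_hyperparameters(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(24, 5)))
        y = rng.normal(40, 8, 24)
        p1 = SpadSVR(X, y, seed=7).fit().params
        p2 = SpadSVR(X, y, seed=7).fit().params
        assert p1 == p2

    def test_anti_leakage_validation_never_touched(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(36, 4)))
        y = X.iloc[:, 0].to_numpy() * 3 + rng.normal(0, 0.5, 36)
        res = SpadSVR(X.iloc[:24], y[:24], seed=1).fit()
        pred1 = res.predict(X.iloc[24:])
        # evaluating against permuted validation targets must not change
        # the model or its predictions
        res.evaluate(X.iloc[24:], rng.permutation(y[24:]))
        pred2 = res.predict(X.iloc[24:])
        assert np.array_equal(pred1, pred2)

    def test_constant_target_rejected(self):
        X = pd.DataFrame(np.eye(4))
        with pytest.raises(DegenerateTargetError):
            SpadSVR(X, np.ones(4))

    def test_summary_contains_metrics(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        y = rng.normal(40, 5, 20)
        res = SpadSVR(X, y, seed=0).fit()
        s = res.summary()
        assert "calibration R2" in s and "C " in s


class TestFusion:
    def subsets(self, rng, suffix, sizes=(3, 5, 4)):
        return {f"{p}{suffix}": table_of(rng, 12, s, f"{p}{suffix}", suffix)
                for p, s in zip(("C-", "CT-", "R-"), sizes)}

    def test_nine_fusion_labels(self):
        rng = np.random.default_rng(6)
        fused = build_fusion_sets(self.subsets(rng, "SF"),
                                  self.subsets(rng, "TF"))
        assert len(fused) == 9
        assert "R-SF--R-TF" in fused and "C-SF--CT-TF" in fused

    def test_empty_subset_skipped_with_log(self):
        rng = np.random.default_rng(7)
        sf = self.subsets(rng, "SF")
        sf["C-SF"] = sf["C-SF"].subset([], label="C-SF")
        log = []
        fused = build_fusion_sets(sf, self.subsets(rng, "TF"), log=log)
        assert len(fused) == 6
        assert any("C-SF" in entry for entry in log)

    def test_fusion_column_count_adds(self):
        rng = np.random.default_rng(8)
        sf = table_of(rng, 12, 30, "SF")
        tf = table_of(rng, 12, 160, "TF")
        sftf = concat_tables(sf, tf, "SFTF")
        assert sftf.n_features == 190

    def test_self_fusion_never_duplicates_names(self):
        rng = np.random.default_rng(9)
        t = table_of(rng, 8, 4, "SF")
        fused = concat_tables(t, t, "twice")
        assert len(set(fused.feature_names)) == 8


class TestFactorial:
    def stage(self, rng, name):
        sf = table_of(rng, 36, 30, "SF")
        tf = table_of(rng, 36, 160, "TF")
        y = pd.Series(rng.normal(40, 8, 36), index=sf.data.index)
        # inject signal so SVR fits are meaningful
        sf.data["SF_0"] = y + rng.normal(0, 2, 36)
        def subs(t, suffix):
            names = t.feature_names
            return {f"C-{suffix}": t.subset(names[:3], f"C-{suffix}"),
                    f"CT-{suffix}": t.subset(names[:6], f"CT-{suffix}"),
                    f"R-{suffix}": t.subset(names[:4], f"R-{suffix}")}
        sftf = concat_tables(sf, tf, "SFTF")
        return StageData(stage=name, sf=sf, tf=tf, y=y,
                         sf_subsets=subs(sf, "SF"),
                         tf_subsets=subs(tf, "TF"),
                         sftf_subsets=subs(sftf, "SFTF"))

    @pytest.fixture(scope="class")
    def runs(self):
        rng = np.random.default_rng(10)
        stages = [self.stage(rng, s)
                  for s in ("heading", "flowering", "late_filling")]
        grid = SvrGrid(C=(1.0,), gamma_factors=(1.0,), epsilon=(0.1,),
                       cv_folds=3)
        return run_factorial(stages, grid=grid, seed=3)

    def test_experiment_enumeration(self, runs):
        counts = runs.groupby("experiment").size().to_dict()
        assert counts == {1: 24, 2: 12, 3: 30}

    def test_shared_split_per_stage(self, runs):
        assert (runs.n_cal == 24).all() and (runs.n_val == 12).all()

    def test_label_vocabulary(self, runs):
        allowed = set(EXPERIMENT_LABELS[1] + EXPERIMENT_LABELS[2]
                      + EXPERIMENT_LABELS[3])
        assert set(runs.dataset_label) <= allowed

    def test_rpd_consistency_in_runs(self, runs):
        # RPD_val * RMSE_val reproduces the calibration SD per stage
        for (stage,), sub in runs.groupby(["stage"]):
            sds = sub.RPD_val * sub.RMSE_val
            assert np.allclose(sds, sds.iloc[0], atol=1e-9)
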