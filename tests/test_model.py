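import dataclasses

import numpy as np
import pandas as pd
import pytest

from msre_select import assay, model
from msre_select.io import AssayTable
from msre_select.simulate import SimulationConfig, simulate_assay_counts


@pytest.fixture(scope="module")
def assay_data():
    cfg = SimulationConfig(seed=21)
    table, truth = simulate_assay_counts(cfg)
    return table, truth


def split_and_normalize(table, seed=21):
    train, test = model.train_test_split(table, seed=seed)
    filt, _ = assay.filter_low_count(train)
    norm_train, _ = assay.normalize(filt)
    test_f = dataclasses.replace(test, counts=test.counts.loc[filt.counts.index])
    norm_test, _ = assay.normalize(test_f)
    feats = [a for a in norm_train.index if a not in ("Control1", "Control3")]
    return filt, norm_train.loc[feats], test_f, norm_test.loc[feats]


class TestTrainTestSplit:
    def test_partition_properties(self, assay_data):
        table, _ = assay_data
        train, test = model.train_test_split(table, seed=3)
        all_ids = set(table.counts.columns)
        assert set(train.counts.columns) | set(test.counts.columns) == all_ids
        assert set(train.counts.columns) & set(test.counts.columns) == set()

    def test_stratification_within_one(self, assay_data):
        table, _ = assay_data
        train, test = model.train_test_split(table, seed=3)
        for grp in ("normal", "cancer"):
            n_tr = (train.metadata["group"] == grp).sum()
            n_te = (test.metadata["group"] == grp).sum()
            assert abs(n_tr - n_te) <= 1

    def test_same_seed_same_split(self, assay_data):
        table, _ = assay_data
        a1, _ = model.train_test_split(table, seed=9)
        a2, _ = model.train_test_split(table, seed=9)
        assert list(a1.counts.columns) == list(a2.counts.columns)

    def test_fractions_must_sum_to_one(self, assay_data):
        table, _ = assay_data
        with pytest.raises(ValueError):
            model.train_test_split(table, fractions=(0.6, 0.6))


class TestFitLassoLogistic:
    def test_recovers_single_separating_feature(self, rng):
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        x = rng.normal(0, 1, size=(n, 21))
        x[:, 7] = y * 3 + rng.normal(0, 0.3, n)  # near-perfect marker
        counts = pd.DataFrame(
            (2.0 ** x.T * 100).astype(int) + 1,
            index=[f"A{i}" for i in range(21)],
            columns=[f"S{i}" for i in range(n)],
        )
        meta = pd.DataFrame(
            {"group": np.where(y == 1, "cancer", "normal"), "tissue": "lung"},
            index=counts.columns,
        )
        counts.loc["Control3"] = 100
        counts.loc["Control1"] = 0
        table = AssayTable(counts=counts, metadata=meta)
        norm, _ = assay.normalize(table)
        feats = [a for a in norm.index if not a.startswith("Control")]
        m = model.fit_lasso_logistic(table, norm.loc[feats], model.ModelSpec(seed=5))
        assert "A7" in m.support
        assert np.nanmax(m.cv_auc) >= 0.95

    def test_informative_panel_train_and_test_auc(self, assay_data):
        table, truth = assay_data
        filt, norm_train, test_f, norm_test = split_and_normalize(table)
        m = model.fit_lasso_logistic(filt, norm_train, model.ModelSpec(seed=21))
        assert m.train_auc >= 0.95
        auc, ci = model.evaluate(m, test_f, norm_test)
        assert auc >= 0.90
        assert ci[0] <= auc <= ci[1]
        assert set(m.support) & set(truth.informative_amplicons)

    def test_duplicated_feature_leaves_predictions_stable(self, assay_data):
        table, _ = assay_data
        filt, norm_train, test_f, norm_test = split_and_normalize(table)
        m1 = model.fit_lasso_logistic(filt, norm_train, model.ModelSpec(seed=21))
        dup = norm_train.copy()
        first_selected = m1.support[0]
        dup.loc["DupX"] = dup.loc[first_selected]
        m2 = model.fit_lasso_logistic(filt, dup, model.ModelSpec(seed=21))
        f1 = model.features_from_normalized(norm_train)
        f2 = model.features_from_normalized(dup)
        s1 = m1.decision_function(f1)
        s2 = m2.decision_function(f2)
        # rank agreement of scores: the duplicated column must not change the
        # model's ordering materially
        y = (filt.metadata.loc[f1.index, "group"] == "cancer").to_numpy()
        a1 = assay.rank_auc(s1[y], s1[~y])
        a2 = assay.rank_auc(s2[y], s2[~y])
        assert abs(a1 - a2) <= 0.05
        assert len(m2.support) <= len(m1.support) + 1

    def test_too_few_samples_per_class(self, assay_data):
        table, _ = assay_data
        normals = table.samples_in_group("normal")[:2]
        cancers = table.samples_in_group("cancer")[:2]
        tiny = table.subset_samples(normals + cancers)
        filt, _ = assay.filter_low_count(tiny)
        norm, _ = assay.normalize(filt)
        feats = [a for a in norm.index if not a.startswith("Control")]
        with pytest.raises(ValueError, match="too few"):
            model.fit_lasso_logistic(filt, norm.loc[feats], model.ModelSpec(n_folds=3))

    def test_one_se_rule_prefers_larger_penalty(self, assay_data):
        table, _ = assay_data
        filt, norm_train, _, _ = split_and_normalize(table)
        m = model.fit_lasso_logistic(filt, norm_train, model.ModelSpec(seed=21))
        best = int(np.nanargmax(m.cv_auc))
        chosen_idx = int(np.argmin(np.abs(m.lambda_path - m.chosen_lambda)))
        assert m.chosen_lambda >= m.lambda_path[best] or chosen_idx == best


class TestEvaluate:
    def _model_for(self, feature_names):
        k = len(feature_names)
        return model.PanelModel(
            feature_names=list(feature_names),
            coefficients=np.ones(k),
            intercept=0.0,
            feature_means=np.zeros(k),
            feature_scales=np.ones(k),
            chosen_lambda=0.1,
            lambda_path=np.array([0.1]),
            cv_auc=np.array([1.0]),
            cv_auc_se=np.array([0.0]),
        )

    def _table(self, scores, labels):
        n = len(scores)
        counts = pd.DataFrame(
            {f"S{i}": [max(1, int(2 ** s * 100)), 100, 0] for i, s in enumerate(scores)},
            index=["A1", "Control3", "Control1"],
        )
        meta = pd.DataFrame(
            {"group": ["cancer" if y else "normal" for y in labels], "tissue": "x"},
            index=counts.columns,
        )
        return AssayTable(counts=counts, metadata=meta)

    def test_perfect_separation_ci_truncated_at_one(self):
        scores = [0, 0.5, 1, 5, 6, 7]
        labels = [0, 0, 0, 1, 1, 1]
        t = self._table(scores, labels)
        norm, _ = assay.normalize(t)
        auc, ci = model.evaluate(self._model_for(["A1"]), t, norm.loc[["A1"]])
        assert auc == 1.0 and ci[1] == 1.0

    def test_null_scores_near_half(self, rng):
        pos = rng.normal(0, 1, 500)
        neg = rng.normal(0, 1, 500)
        auc = assay.rank_auc(pos, neg)
        assert 0.45 <= auc <= 0.55

    def test_single_class_rejected(self):
        # a one-class table is refused at construction already
        with pytest.raises(ValueError):
            t = self._table([1, 2, 3], [1, 1, 1])
            norm, _ = assay.normalize(t)
            model.evaluate(self._model_for(["A1"]), t, norm.loc[["A1"]])

    def test_delong_variance_close_to_bootstrap(self, rng):
        for _ in range(5):
            pos = rng.normal(1.0, 1.0, 40)
            neg = rng.normal(0.0, 1.0, 45)
            v_delong = model.delong_variance(pos, neg)
            boot = []
            for _ in range(2000):
                bp = rng.choice(pos, size=len(pos), replace=True)
                bn = rng.choice(neg, size=len(neg), replace=True)
                boot.append(assay.rank_auc(bp, bn))
            v_boot = np.var(boot, ddof=1)
            assert v_delong == pytest.approx(v_boot, rel=0.35)
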