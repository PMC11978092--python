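"""Splits, cross-validation, metrics, training sanity, and z-score calls."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score, mean_squared_error, r2_score

from pathdrug.experiments import (
    build_dataset,
    reduced_model_config,
    vocab_size_of,
)
from pathdrug.model import DrugResponseModel
from pathdrug.train_eval import (
    MetricReport,
    SplitSpec,
    TrainConfig,
    aggregate_reports,
    average_precision,
    compute_metrics,
    evaluate,
    kfold,
    make_split,
    train,
    zscore_table,
)


def toy_table(n_cells=20, n_drugs=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = [
        {"cell_line": f"c{i}", "drug": f"d{j}", "response": float(rng.normal())}
        for i in range(n_cells)
        for j in range(n_drugs)
    ]
    return pd.DataFrame(rows)


class TestSplits:
    def test_mixed_partition_sizes_and_disjointness(self):
        table = toy_table()
        train_rows, test_rows = make_split(table, SplitSpec("mixed", 0.1, seed=1))
        assert len(test_rows) == 10
        assert len(train_rows) + len(test_rows) == len(table)
        joint = pd.merge(train_rows, test_rows, on=["cell_line", "drug"])
        assert joint.empty

    @pytest.mark.parametrize("strategy,col", [("cell_blind", "cell_line"),
                                              ("drug_blind", "drug")])
    def test_blind_splits_have_zero_entity_overlap(self, strategy, col):
        table = toy_table()
        for seed in range(100):
            tr, te = make_split(table, SplitSpec(strategy, 0.2, seed=seed))
            assert not set(tr[col]) & set(te[col])
            assert len(te) > 0 and len(tr) > 0

    def test_same_seed_gives_identical_split(self):
        table = toy_table()
        a = make_split(table, SplitSpec("mixed", 0.1, seed=9))
        b = make_split(table, SplitSpec("mixed", 0.1, seed=9))
        assert a[1].equals(b[1]) and a[0].equals(b[0])

    def test_single_entity_blind_split_errors(self):
        table = toy_table(n_cells=5, n_drugs=1)
        with pytest.raises(ValueError, match="distinct"):
            make_split(table, SplitSpec("drug_blind", 0.2, seed=0))

    def test_kfold_mixed_partitions_rows(self):
        table = toy_table()
        folds = kfold(table, k=10, strategy="mixed", seed=2)
        tests = [set(map(tuple, f[1][["cell_line", "drug"]].to_numpy())) for f in folds]
        assert all(len(t) == 10 for t in tests)
        assert set().union(*tests) == set(
            map(tuple, table[["cell_line", "drug"]].to_numpy())
        )
        for i in range(len(tests)):
            for j in range(i + 1, len(tests)):
                assert not tests[i] & tests[j]

    def test_kfold_blind_each_entity_in_one_test_fold(self):
        table = toy_table()
        folds = kfold(table, k=5, strategy="cell_blind", seed=3)
        seen = []
        for tr, te in folds:
            ents = set(te["cell_line"])
            assert not ents & set(tr["cell_line"])
            seen.append(ents)
        all_ents = set(table["cell_line"])
        assert set().union(*seen) == all_ents
        assert sum(len(s) for s in seen) == len(all_ents)

    def test_kfold_k_exceeding_entities_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold(toy_table(n_cells=3), k=5, strategy="cell_blind")


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        r = compute_metrics(y, y)
        assert (r.mse, r.pcc, r.r2) == (0.0, pytest.approx(1.0), pytest.approx(1.0))

    def test_constant_shift_keeps_pcc_lowers_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r = compute_metrics(y, y + 2.0)
        assert r.pcc == pytest.approx(1.0)
        assert r.r2 < 1.0
        assert r.rmse == pytest.approx(np.sqrt(r.mse))

    def test_single_point_pcc_reported_missing(self):
        r = compute_metrics(np.array([1.0]), np.array([2.0]))
        assert r.pcc is None
        assert r.mse == pytest.approx(1.0)

    def test_matches_reference_implementations(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            y = rng.normal(size=40)
            p = y * 0.5 + rng.normal(size=40)
            r = compute_metrics(y, p)
            assert r.mse == pytest.approx(mean_squared_error(y, p), rel=1e-9)
            assert r.r2 == pytest.approx(r2_score(y, p), rel=1e-9)
            assert r.pcc == pytest.approx(np.corrcoef(y, p)[0, 1], rel=1e-9)
            labels = (rng.random(40) < 0.4).astype(int)
            scores = rng.normal(size=40)
            assert average_precision(labels, scores) == pytest.approx(
                average_precision_score(labels, scores), rel=1e-9
            )

    def test_aggregate_reports_mean_sd(self):
        reports = [MetricReport(mse=1.0, rmse=1.0, pcc=0.8, r2=0.5, n=5),
                   MetricReport(mse=3.0, rmse=np.sqrt(3), pcc=0.6, r2=0.3, n=5)]
        agg = aggregate_reports(reports)
        assert agg["mse"]["mean"] == pytest.approx(2.0)
        assert agg["pcc"]["sd"] == pytest.approx(np.std([0.8, 0.6], ddof=1))


class TestTraining:
    def test_training_reduces_validation_loss_and_is_deterministic(self, small_bundle, small_dataset):
        tr, te = make_split(small_dataset.responses, SplitSpec("mixed", 0.2, seed=0))
        tr, val = make_split(tr, SplitSpec("mixed", 0.2, seed=1))
        losses = []
        for _ in range(2):
            cfg = reduced_model_config(vocab_size_of(small_dataset),
                                       small_dataset.omics_dims(), seed=0)
            model = DrugResponseModel(cfg)
            hist = train(model, small_dataset, tr, val,
                         TrainConfig(epochs=4, batch_size=64, lr=2e-3, seed=0))
            assert hist["val_loss"].iloc[-1] < hist["val_loss"].iloc[0]
            losses.append(hist["val_loss"].iloc[-1])
        assert losses[0] == losses[1]

    def test_classifier_separates_margin_labelled_data(self, small_dataset):
        # binarize responses with a margin so the classes are separable in
        # the features; the sigmoid head must then rank held-out rows well
        from pathdrug.train_eval import ResponseDataset
        resp = small_dataset.responses.copy()
        med = resp["response"].median()
        resp = resp[(resp["response"] - med).abs() > 0.5].copy()
        resp["response"] = (resp["response"] < med).astype(float)
        ds = ResponseDataset(small_dataset.features, small_dataset.tokens, resp)
        tr, te = make_split(ds.responses, SplitSpec("mixed", 0.2, seed=0))
        tr, val = make_split(tr, SplitSpec("mixed", 0.2, seed=1))
        cfg = reduced_model_config(vocab_size_of(ds), ds.omics_dims(), seed=0)
        cfg.head = "classifier"
        model = DrugResponseModel(cfg)
        train(model, ds, tr, val,
              TrainConfig(epochs=40, batch_size=64, lr=3e-3, patience=10, seed=0))
        rep = evaluate(model, ds, te)
        prevalence = te["response"].mean()  # AUC-PR of a random ranker
        assert rep.aucpr > 0.8 > prevalence + 0.1


class TestZScore:
    def test_outlier_called_sensitive(self):
        rows = pd.DataFrame({
            "cell_line": ["c1"] * 10,
            "drug": [f"d{i}" for i in range(10)],
            "prediction": [0.0] * 9 + [-10.0],
        })
        out = zscore_table(rows, axis="per_cell_line")
        assert out.loc[out["prediction"] == -10.0, "class"].iloc[0] == "sensitive"
        assert (out.loc[out["prediction"] == 0.0, "class"] == "neutral").all()

    def test_standardization_identity(self):
        rng = np.random.default_rng(6)
        rows = pd.DataFrame({
            "cell_line": np.repeat(["c1", "c2"], 20),
            "drug": [f"d{i}" for i in range(20)] * 2,
            "prediction": rng.normal(size=40),
        })
        out = zscore_table(rows, axis="per_cell_line")
        for _, grp in out.groupby("cell_line"):
            assert grp["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["z"].std(ddof=0) == pytest.approx(1.0)

    def test_zero_spread_all_neutral_with_warning(self, caplog):
        rows = pd.DataFrame({
            "cell_line": ["c1"] * 3,
            "drug": ["d1", "d2", "d3"],
            "prediction": [1.0, 1.0, 1.0],
        })
        with caplog.at_level("WARNING"):
            out = zscore_table(rows, axis="per_cell_line")
        assert (out["class"] == "neutral").all()
        assert any("zero spread" in r.message for r in caplog.records)

    def test_per_drug_axis_groups_by_drug(self):
        rows = pd.DataFrame({
            "cell_line": ["c1", "c2", "c3"] * 2,
            "drug": np.repeat(["d1", "d2"], 3),
            "prediction": [1.0, 2.0, 3.0, 5.0, 5.0, 8.0],
        })
        out = zscore_table(rows, axis="per_drug")
        for _, grp in out.groupby("drug"):
            assert grp["z"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            zscore_table(pd.DataFrame(), axis="per_gene")
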