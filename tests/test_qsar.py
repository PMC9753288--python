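import numpy as np
import pytest

from herbscreen.curation import LabeledDataset, LabeledEntry
from herbscreen.descriptors import DescriptorMatrix, FAMILIES
from herbscreen.qsar import (
    classify,
    consensus_probability,
    evaluate,
    stratified_folds,
    train_consensus,
    train_member,
)


class TestStratifiedFolds:
    def test_balanced_divisible_case(self):
        y = [0] * 50 + [1] * 50
        folds = stratified_folds(y, k=5, seed=0)
        for fold in folds:
            assert len(fold) == 20
            assert sum(np.asarray(y)[fold]) == 10

    def test_pigeonhole_on_remainders(self):
        y = [1] * 7 + [0] * 13
        folds = stratified_folds(y, k=5, seed=1)
        for fold in folds:
            labels = np.asarray(y)[fold]
            assert labels.sum() in (1, 2)
            assert (labels == 0).sum() in (2, 3)

    def test_exact_partition(self):
        y = [0, 1] * 20
        folds = stratified_folds(y, k=5, seed=2)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(40))

    def test_deterministic_per_seed(self):
        y = [0, 1] * 25
        a = stratified_folds(y, 5, seed=9)
        b = stratified_folds(y, 5, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_undersized_class_named_in_error(self):
        with pytest.raises(ValueError, match="1"):
            stratified_folds([0] * 20 + [1] * 3, k=5, seed=0)


class TestConsensusRule:
    def test_mean_of_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.random(3)
            assert consensus_probability(*p) == pytest.approx(p.mean(), abs=1e-15)

    @pytest.mark.parametrize("triple,expected", [
        ((0.4, 0.5, 0.9), 0.6), ((0, 0, 0), 0.0), ((1, 1, 1), 1.0),
    ])
    def test_worked_examples(self, triple, expected):
        assert consensus_probability(*triple) == pytest.approx(expected)

    def test_bounded_by_member_range(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(3)
            c = consensus_probability(*p)
            assert p.min() <= c <= p.max()

    def test_classify_strict_at_threshold(self):
        assert classify(0.51) == "candidate"
        assert classify(0.5) == "non-candidate"
        assert classify(0.0) == "non-candidate"

    def test_classify_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify(1.2)


def _toy_separable(n=40):
    """Feature blocks where the label is a linear function of one column."""
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * (n // 2))
    entries = [LabeledEntry(f"c{i}", "C", 10.0 if y[i] else 5000.0,
                            "active" if y[i] else "inactive") for i in range(n)]
    ds = LabeledDataset(entries, cutoff_nm=1000)
    feats = {}
    for fam in FAMILIES:
        X = rng.normal(size=(n, 8))
        X[:, 0] = y * 4.0 + rng.normal(scale=0.1, size=n)
        feats[fam] = DescriptorMatrix(fam, [f"c{i}" for i in range(n)], X,
                                      [f"f{j}" for j in range(8)])
    return feats, ds


class TestTrainMember:
    def test_noiseless_planted_motif_training_auc_is_one(self):
        """In the full-signal, zero-noise generator limit the label is a
        deterministic function of the motif, so the forest orders its own
        training set perfectly."""
        from dataclasses import replace

        from sklearn.metrics import roc_auc_score

        from herbscreen.curation import build_dataset
        from herbscreen.descriptors import featurize
        from herbscreen.synthetic import generate_bioactivity, generate_library, \
            modeling_config

        conf = replace(modeling_config(n=200, seed=17), signal_strength=1.0,
                       label_noise=0.0)
        lib, _ = generate_library(conf)
        ds = build_dataset(generate_bioactivity(lib, conf)[0], lib)
        block = featurize("keys", [e.smiles for e in ds.entries], ds.ids())
        member = train_member(block, ds, {"n_estimators": 200}, seed=0)
        p = member.predict_proba(block.matrix)
        assert roc_auc_score(ds.labels(), p) == pytest.approx(1.0, abs=1e-9)

    def test_refit_same_seed_identical(self):
        feats, ds = _toy_separable()
        a = train_member(feats["cats"], ds, {"n_estimators": 50}, seed=3)
        b = train_member(feats["cats"], ds, {"n_estimators": 50}, seed=3)
        np.testing.assert_array_equal(
            a.predict_proba(feats["cats"].matrix), b.predict_proba(feats["cats"].matrix))

    def test_single_class_rejected(self):
        feats, ds = _toy_separable()
        for e in ds.entries:
            e.label = "active"
        with pytest.raises(ValueError, match="single class"):
            train_member(feats["cats"], ds)


class TestEvaluate:
    def test_cv_report_shapes_and_partition(self):
        feats, ds = _toy_separable()
        report = evaluate(feats, ds, k=5, seed=0, hyperparams={"n_estimators": 50})
        assert set(report.acc) == {*FAMILIES, "consensus"}
        assert all(len(v) == 5 for v in report.acc.values())
        combined = np.sort(np.concatenate(report.fold_assignments))
        np.testing.assert_array_equal(combined, np.arange(len(ds.entries)))
        # separable toy problem: essentially perfect consensus
        assert report.mean_auc("consensus") > 0.95

    def test_no_leakage_from_held_out_labels(self):
        """Flipping held-out labels must not change the member fitted on the
        training fold, hence its held-out predictions."""
        feats, ds = _toy_separable()
        folds = stratified_folds(ds.labels(), 5, seed=0)
        test_idx = folds[0]
        train_idx = np.setdiff1d(np.arange(len(ds.entries)), test_idx)
        train_ds = LabeledDataset([ds.entries[i] for i in train_idx], ds.cutoff_nm)
        block = feats["keys"]
        train_block = DescriptorMatrix("keys", [block.compound_ids[i] for i in train_idx],
                                       block.matrix[train_idx], block.feature_names)
        m1 = train_member(train_block, train_ds, {"n_estimators": 50}, seed=1)
        for i in test_idx:  # flip held-out labels only
            e = ds.entries[i]
            e.label = "inactive" if e.label == "active" else "active"
        m2 = train_member(train_block, train_ds, {"n_estimators": 50}, seed=1)
        np.testing.assert_array_equal(m1.predict_proba(block.matrix[test_idx]),
                                      m2.predict_proba(block.matrix[test_idx]))

    def test_signal_recovery_is_monotone(self):
        """Mean CV consensus AUC does not decrease as the planted signal
        strengthens (checked at three signal levels, fixed seeds)."""
        from dataclasses import replace

        from herbscreen.curation import build_dataset
        from herbscreen.descriptors import featurize_library
        from herbscreen.synthetic import generate_bioactivity, generate_library, \
            modeling_config

        aucs = []
        for strength in (0.0, 0.5, 1.0):
            conf = replace(modeling_config(n=150, seed=13),
                           signal_strength=strength, label_noise=0.0)
            lib, _ = generate_library(conf)
            ds = build_dataset(generate_bioactivity(lib, conf)[0], lib)
            feats = featurize_library(lib)
            report = evaluate(feats, ds, k=5, seed=13,
                              hyperparams={"n_estimators": 100})
            aucs.append(report.mean_auc("consensus"))
        assert aucs[0] <= aucs[1] + 0.1  # null is noisy; allow slack
        assert aucs[1] <= aucs[2] + 0.05
        assert aucs[2] > aucs[0]


def test_consensus_model_save_load_roundtrip(tmp_path, modeling_assets):
    ds = modeling_assets["dataset"]
    feats = modeling_assets["features"]
    model = train_consensus(feats, ds, {"n_estimators": 50}, seed=2)
    smiles = [e.smiles for e in ds.entries[:10]]
    before = model.predict_smiles(smiles)
    path = tmp_path / "model.joblib"
    model.save(str(path))
    from herbscreen.qsar import ConsensusModel

    loaded = ConsensusModel.load(str(path))
    np.testing.assert_allclose(loaded.predict_smiles(smiles), before)


def test_export_predictions_csv(tmp_path, modeling_assets):
    import csv

    from herbscreen.qsar import export_predictions

    ds = modeling_assets["dataset"]
    model = train_consensus(modeling_assets["features"], ds,
                            {"n_estimators": 50}, seed=2)
    smiles_map = {e.compound_id: e.smiles for e in ds.entries[:5]}
    out = tmp_path / "preds.csv"
    export_predictions(model, smiles_map, str(out))
    rows = list(csv.DictReader(open(out)))
    assert len(rows) == 5
    for row in rows:
        members = [float(row[c]) for c in ("p_cats", "p_keys", "p_panel2d")]
        assert float(row["p_consensus"]) == pytest.approx(np.mean(members), abs=1e-6)
        assert row["call"] in ("candidate", "non-candidate")
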