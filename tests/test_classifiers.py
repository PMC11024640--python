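"""Training, scoring, ensembling and cross-validation."""

import numpy as np
import pytest

from plantlnc import classifiers as clf
from plantlnc.evaluation import confusion, roc_curve
from plantlnc.features import FeatureVector, extract_features
from plantlnc.labels import LNCRNA, MRNA


def separable_dataset(n=50, d=1, gap=1.0, seed=0):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(gap, 0.1, size=(n, d))
    Xn = rng.normal(-gap, 0.1, size=(n, d))
    X = np.vstack([Xp, Xn])
    y = np.array([1] * n + [0] * n)
    ids = tuple(f"s{i}" for i in range(2 * n))
    names = tuple(f"f{j}" for j in range(d))
    # tagged "plek" so no hexamer table is implied; the matrix is synthetic
    return clf.LabeledDataset(ids, X, y, names, "plek")


def test_separable_data_perfect_heldin_accuracy():
    data = separable_dataset()
    model = clf.train_model(data, clf.ModelSpec("logistic", "plek"), seed=0)
    scores = model.score_matrix(data.X)
    pred = [LNCRNA if s >= 0.5 else MRNA for s in scores]
    truth = [LNCRNA if v else MRNA for v in data.y]
    assert confusion(truth, pred).total == 100
    assert all(p == t for p, t in zip(pred, truth))


def test_label_swap_negates_logistic_weights():
    data = separable_dataset(d=3, gap=0.5, seed=1)
    swapped = clf.LabeledDataset(
        data.ids, data.X, 1 - data.y, data.feature_names, data.schema_id
    )
    spec = clf.ModelSpec("logistic", "plek")
    w1 = clf.train_model(data, spec, seed=0).params["weights"]
    w2 = clf.train_model(swapped, spec, seed=0).params["weights"]
    np.testing.assert_allclose(w1, -w2, atol=1e-6)


def test_logistic_fit_matches_gradient_descent_oracle():
    """Plain full-batch gradient descent on the same penalized likelihood
    must reach the same loss as the packaged fit (20-sample instance)."""
    data = separable_dataset(n=10, d=2, gap=0.3, seed=2)
    lam = 1.0
    model = clf.train_model(data, clf.ModelSpec("logistic", "plek", l2=lam), seed=0)
    Z = (data.X - data.X.mean(0)) / data.X.std(0)
    y = data.y

    def loss(w, b):
        z = Z @ w + b
        return float(np.sum(np.logaddexp(0, z) - y * z) + 0.5 * lam * w @ w)

    w, b = np.zeros(2), 0.0
    for _ in range(20000):
        p = 1 / (1 + np.exp(-(Z @ w + b)))
        gw = Z.T @ (p - y) + lam * w
        gb = np.sum(p - y)
        w -= 0.01 * gw
        b -= 0.01 * gb
    assert loss(model.params["weights"], model.params["intercept"]) == pytest.approx(
        loss(w, b), abs=1e-6
    )


def test_training_rejects_degenerate_input():
    data = separable_dataset()
    single = clf.LabeledDataset(
        data.ids, data.X, np.ones_like(data.y), data.feature_names, data.schema_id
    )
    with pytest.raises(ValueError):
        clf.train_model(single, clf.ModelSpec("logistic", "plek"))
    bad = clf.LabeledDataset(
        data.ids, data.X * np.nan, data.y, data.feature_names, data.schema_id
    )
    with pytest.raises(ValueError):
        clf.train_model(bad, clf.ModelSpec("logistic", "plek"))


def test_constant_features_dropped_and_recorded():
    data = separable_dataset(d=2, seed=3)
    X = data.X.copy()
    X[:, 1] = 7.0
    d2 = clf.LabeledDataset(data.ids, X, data.y, ("f0", "f1"), data.schema_id)
    model = clf.train_model(d2, clf.ModelSpec("logistic", "plek"))
    assert model.dropped_features == ("f1",)
    assert model.kept.tolist() == [True, False]


def test_predict_score_formula_oracle(cpat_model, lnc_seqs, mrna_seqs):
    """Logistic scores must equal a direct sigmoid(w . z + b) computation."""
    w = cpat_model.params["weights"]
    b = cpat_model.params["intercept"]
    for s in lnc_seqs[:10] + mrna_seqs[:10]:
        fv = extract_features(s, "cpat", cpat_model.hexamer_table)
        z = (fv.values[cpat_model.kept] - cpat_model.mean) / cpat_model.sd
        expected = 1 / (1 + np.exp(-(z @ w + b)))
        assert clf.predict_score(cpat_model, fv) == pytest.approx(expected, abs=1e-12)


def test_score_at_feature_means_is_sigmoid_intercept(cpat_model, lnc_seqs, mrna_seqs):
    fv = FeatureVector(
        "cpat", cpat_model.all_feature_names, cpat_model.mean.copy()
    )
    expected = 1 / (1 + np.exp(-cpat_model.params["intercept"]))
    assert clf.predict_score(cpat_model, fv) == pytest.approx(expected)


def test_logistic_score_monotone_in_positive_weight_feature(cpat_model):
    w = cpat_model.params["weights"]
    j = int(np.argmax(np.abs(w)))
    base = cpat_model.mean.copy()
    fv_lo = FeatureVector("cpat", cpat_model.all_feature_names, base.copy())
    hi = base.copy()
    hi[j] += np.sign(w[j]) * cpat_model.sd[j]
    fv_hi = FeatureVector("cpat", cpat_model.all_feature_names, hi)
    assert clf.predict_score(cpat_model, fv_hi) > clf.predict_score(cpat_model, fv_lo)


def test_schema_mismatch_rejected(cpat_model):
    fv = extract_features(
        __import__("plantlnc.seqio", fromlist=["NucleotideSequence"]).NucleotideSequence(
            "x", "ACGTACGTACGTACGT"
        ),
        "plek",
    )
    with pytest.raises(ValueError):
        clf.predict_score(cpat_model, fv)


def test_classify_boundary_convention(cpat_model):
    # score exactly at threshold is called lncRNA
    fv = FeatureVector("cpat", cpat_model.all_feature_names, cpat_model.mean.copy())
    score = clf.predict_score(cpat_model, fv)
    cpat_model_threshold = cpat_model.threshold
    try:
        cpat_model.threshold = score
        assert clf.classify(cpat_model, fv) == LNCRNA
        cpat_model.threshold = np.nextafter(score, 1.0)
        assert clf.classify(cpat_model, fv) == MRNA
    finally:
        cpat_model.threshold = cpat_model_threshold


def test_platt_calibration_is_monotone(lncfinder_model, lnc_seqs, mrna_seqs):
    data, _ = clf.build_dataset(lnc_seqs[:40], mrna_seqs[:40], "lncfinder-lite")
    d = lncfinder_model.decision_values(data.X)
    s = lncfinder_model.score_matrix(data.X)
    order = np.argsort(d)
    assert np.all(np.diff(s[order]) >= 0)
    assert np.all((s >= 0) & (s <= 1))


def test_training_is_deterministic(lnc_seqs, mrna_seqs):
    spec = clf.ModelSpec("svm_rbf", "cpat")
    m1 = clf.train_from_sequences(lnc_seqs[:50], mrna_seqs[:50], spec, seed=9)
    m2 = clf.train_from_sequences(lnc_seqs[:50], mrna_seqs[:50], spec, seed=9)
    np.testing.assert_array_equal(m1.params["dual_coef"], m2.params["dual_coef"])
    assert m1.params["platt_a"] == m2.params["platt_a"]


def test_model_serialization_round_trip(tmp_path, cpat_model, lnc_seqs):
    path = tmp_path / "model.json"
    clf.save_model(cpat_model, path)
    loaded = clf.load_model(path)
    fv = extract_features(lnc_seqs[0], "cpat", loaded.hexamer_table)
    assert clf.predict_score(loaded, fv) == pytest.approx(
        clf.predict_score(cpat_model, fv), abs=1e-15
    )
    assert loaded.spec == cpat_model.spec


def test_ensemble_rule_table(cpat_model, lncfinder_model, lnc_seqs, mrna_seqs):
    both_lnc = lnc_seqs[0]
    both_mrna = mrna_seqs[0]
    fa = extract_features(both_lnc, "cpat", cpat_model.hexamer_table)
    fb = extract_features(both_lnc, "lncfinder-lite", lncfinder_model.hexamer_table)
    assert clf.ensemble_classify(cpat_model, lncfinder_model, fa, fb) == LNCRNA
    fa = extract_features(both_mrna, "cpat", cpat_model.hexamer_table)
    fb = extract_features(both_mrna, "lncfinder-lite", lncfinder_model.hexamer_table)
    assert clf.ensemble_classify(cpat_model, lncfinder_model, fa, fb) == MRNA


def test_ensemble_positive_set_is_intersection(cpat_model, lncfinder_model, lnc_seqs, mrna_seqs):
    """Set identity plus the FP/TP count bounds on a labeled evaluation set."""
    seqs = lnc_seqs[100:160] + mrna_seqs[100:160]
    truth = {s.id: (LNCRNA if i < 60 else MRNA) for i, s in enumerate(seqs)}
    pos_a, pos_b, pos_ens = set(), set(), set()
    for s in seqs:
        fa = extract_features(s, "cpat", cpat_model.hexamer_table)
        fb = extract_features(s, "lncfinder-lite", lncfinder_model.hexamer_table)
        if clf.classify(cpat_model, fa) == LNCRNA:
            pos_a.add(s.id)
        if clf.classify(lncfinder_model, fb) == LNCRNA:
            pos_b.add(s.id)
        if clf.ensemble_classify(cpat_model, lncfinder_model, fa, fb) == LNCRNA:
            pos_ens.add(s.id)
    assert pos_ens == pos_a & pos_b
    fp = lambda pos: sum(truth[i] == MRNA for i in pos)
    tp = lambda pos: sum(truth[i] == LNCRNA for i in pos)
    assert fp(pos_ens) <= min(fp(pos_a), fp(pos_b))
    assert tp(pos_ens) <= min(tp(pos_a), tp(pos_b))


def test_cross_validation_determinism_and_leak_free_accuracy(lnc_seqs, mrna_seqs):
    spec = clf.ModelSpec("logistic", "cpat")
    r1 = clf.cross_validate(lnc_seqs, mrna_seqs, spec, k=5, seed=3)
    r2 = clf.cross_validate(lnc_seqs, mrna_seqs, spec, k=5, seed=3)
    np.testing.assert_array_equal(r1.oof_scores, r2.oof_scores)
    assert r1.pooled_confusion == r2.pooled_confusion
    assert r1.pooled_metrics.accuracy >= 0.90
    assert len(r1.fold_metrics) == 5
    assert r1.pooled_confusion.total == len(lnc_seqs) + len(mrna_seqs)


def test_cross_validation_rejects_k_larger_than_class(lnc_seqs, mrna_seqs):
    with pytest.raises(ValueError):
        clf.cross_validate(lnc_seqs[:3], mrna_seqs[:50], clf.ModelSpec("logistic", "cpat"), k=5)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        clf.ModelSpec("forest", "cpat")
    with pytest.raises(ValueError):
        clf.ModelSpec("logistic", "cpat", l2=-1)
    with pytest.raises(ValueError):
        clf.ModelSpec("svm_rbf", "cpat", C=0)
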