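import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralhsi import classify
from coralhsi.classify import (
    ClassifierBundle,
    cv_errors,
    evaluate,
    evaluate_reference_group,
    f1_from_pr,
    fit_pls,
    fit_standardizer,
    fit_svm,
    majority_vote,
    round_half_up,
    select_n_latent,
    train_pipeline,
    weighted_harmonic_mean,
)
from coralhsi.spectral_db import SpectraTable


def _blobs(rng, n_per_class=60, dim=10, sep=6.0):
    centers = sep * np.eye(dim)[:3]
    X = np.vstack(
        [c + rng.standard_normal((n_per_class, dim)) for c in centers]
    )
    y = np.repeat(["low", "medium", "high"], n_per_class)
    return X, y


def _annotated_table(rng, n_samples=12, px_per_sample=25, bands=40):
    """Small separable two-morph table with Y_h/Y_c filled."""
    wl = 400 + 5.0 * np.arange(bands)
    cats = ("low", "medium", "high")
    rows_X, meta, yh, yc = [], [], [], []
    for s in range(n_samples):
        morph = "white" if s % 2 else "orange"
        cat = cats[s % 3]
        base = 0.4 + 0.02 * (s % 3) * np.sin(wl / 30) + (0.1 if morph == "white" else 0)
        conc = [0.5, 1.8, 3.0][s % 3]
        mort = [0.0, 0.1, 0.5][s % 3]
        for _ in range(px_per_sample):
            rows_X.append(base + 0.003 * rng.standard_normal(bands))
            meta.append({"sample_id": f"s{s}", "morph": morph, "pixel_row": 0, "pixel_col": 0})
            yh.append({"concentration": conc, "mortality": mort})
            yc.append(cat)
    return SpectraTable(
        X=np.asarray(rows_X),
        wavelengths=wl,
        meta=pd.DataFrame(meta),
        y_h=pd.DataFrame(yh),
        y_c=pd.Series(yc),
    )


# ---------------------------------------------------------------------------
# rounding / metric arithmetic
# ---------------------------------------------------------------------------


def test_round_half_up():
    assert round_half_up(0.845, 2) == 0.85
    assert round_half_up(0.844, 2) == 0.84
    assert round_half_up(1.325, 1) == 1.3  # one-decimal concentration rule
    assert round_half_up(2.65, 1) == 2.7


def test_f1_is_harmonic_mean():
    assert f1_from_pr(0.5, 0.5) == 0.5
    assert round_half_up(f1_from_pr(0.87, 0.95)) == 0.91
    assert f1_from_pr(0.0, 0.0) == 0.0


@settings(max_examples=100, deadline=None)
@given(
    p=st.floats(min_value=0.01, max_value=1.0),
    r=st.floats(min_value=0.01, max_value=1.0),
)
def test_f1_properties(p, r):
    f1 = f1_from_pr(p, r)
    assert min(p, r) * 0.999 <= f1 <= (p + r) / 2 + 1e-12  # harmonic <= arithmetic
    assert f1 == pytest.approx(2 * p * r / (p + r))
    if p == r:
        assert f1 == pytest.approx(p)


def test_weighted_harmonic_mean_reproduces_printed_total():
    # (P, pixels) = (0.85, 512), (0.94, 235), (0.97, 216) -> 0.90 rounded.
    p = weighted_harmonic_mean([0.85, 0.94, 0.97], [512, 235, 216])
    assert round_half_up(p) == 0.90


# ---------------------------------------------------------------------------
# standardizer
# ---------------------------------------------------------------------------


def test_standardizer_population_sd_convention():
    s = fit_standardizer(np.array([[1.0], [2.0], [3.0]]))
    z = s.apply(np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(z[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)


def test_standardizer_drops_constant_columns():
    X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        s = fit_standardizer(X)
    assert s.n_dropped == 1
    assert s.apply(X).shape == (5, 1)


def test_standardizer_train_statistics(rng):
    X = rng.random((50, 8))
    s = fit_standardizer(X)
    Z = s.apply(X)
    assert np.abs(Z.mean(axis=0)).max() < 1e-10
    np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)


def test_standardizer_empty_rejected():
    with pytest.raises(ValueError, match="empty"):
        fit_standardizer(np.empty((0, 3)))


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------


def test_pls_exact_linear_relation_recovered(rng):
    X = rng.standard_normal((80, 6))
    W = rng.standard_normal((6, 2))
    Y = X @ W  # noiseless linear map, rank 6
    xs, ys = fit_standardizer(X), fit_standardizer(Y)
    model = fit_pls(xs.apply(X), ys.apply(Y), n_latent=6)
    resid = ys.apply(Y) - model.predict(xs.apply(X))
    assert np.abs(resid).max() < 1e-8


def test_pls_n_latent_beyond_rank_rejected(rng):
    X = rng.standard_normal((10, 4))
    Y = rng.standard_normal((10, 2))
    with pytest.raises(ValueError, match="n_latent"):
        fit_pls(X, Y, n_latent=5)
    with pytest.raises(ValueError, match="n_latent"):
        fit_pls(X, Y, n_latent=0)


def test_pls_sign_indeterminacy_cancels(rng):
    # Negating a (rotation, y-loading) component pair leaves predictions
    # unchanged: the documented sign convention is arbitrary.
    X = rng.standard_normal((60, 8))
    Y = X[:, :2] + 0.1 * rng.standard_normal((60, 2))
    model = fit_pls(X, Y, n_latent=3)
    rot = model.pls.x_rotations_.copy()
    yl = model.pls.y_loadings_.copy()
    pred = X @ rot @ yl.T
    rot[:, 1] *= -1
    yl[:, 1] *= -1
    np.testing.assert_allclose(X @ rot @ yl.T, pred, atol=1e-12)


def test_pls_component_covariance_ordering(rng):
    X = rng.standard_normal((200, 15))
    Y = X[:, :3] @ rng.standard_normal((3, 2)) + 0.05 * rng.standard_normal((200, 2))
    model = fit_pls(X, Y, n_latent=5)
    scores = model.x_scores
    cov = [np.abs(scores[:, i]).var() for i in range(5)]
    assert cov[0] >= cov[-1]


# ---------------------------------------------------------------------------
# latent-variable selection
# ---------------------------------------------------------------------------


def test_select_n_latent_finds_informative_directions(rng):
    # Three informative spectral directions -> at least 3 components needed.
    n, bands = 600, 30
    basis = rng.standard_normal((3, bands))
    codes = rng.standard_normal((n, 3))
    X = codes @ basis + 0.05 * rng.standard_normal((n, bands))
    # Label = octant sign count mod 3: any projection to < 3 dimensions loses
    # one sign and cannot resolve the classes, so >= 3 latents are required.
    idx = (codes > 0).sum(axis=1) % 3
    labels = np.array(["low", "medium", "high"])[idx]
    y_h = np.column_stack(
        [codes @ np.array([1.0, 0.5, 0.25]), codes @ np.array([0.25, 0.5, 1.0])]
    ) + 0.01 * rng.standard_normal((n, 2))
    chosen = select_n_latent(X, y_h, labels, candidates=(1, 2, 3, 5, 8), seed=0)
    assert chosen >= 3


def test_select_n_latent_single_candidate():
    rng = np.random.default_rng(0)
    X, y = _blobs(rng)
    y_h = np.column_stack([np.ones(len(y)), np.zeros(len(y))])
    y_h += rng.standard_normal(y_h.shape)  # avoid zero-variance Y columns
    assert select_n_latent(X, y_h, y, candidates=(10,), seed=0) == 10


def test_cv_requires_enough_rows():
    with pytest.raises(ValueError, match="rows"):
        cv_errors(
            np.ones((3, 4)), np.ones((3, 2)), ["a", "b", "a"], candidates=(1,), k=5
        )


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


def test_svm_separable_blobs_accuracy(rng):
    X, y = _blobs(rng, n_per_class=80)
    train = np.arange(0, len(y), 2)
    test = np.arange(1, len(y), 2)
    svm = fit_svm(X[train], y[train])
    acc = np.mean(svm.predict(X[test]) == y[test])
    assert acc >= 0.95


def test_svm_single_class_rejected(rng):
    X = rng.standard_normal((20, 5))
    with pytest.raises(ValueError, match="2 classes"):
        fit_svm(X, ["low"] * 20)


def test_svm_deterministic_support_count(rng):
    X, y = _blobs(rng)
    s1 = fit_svm(X, y)
    s2 = fit_svm(X, y)
    np.testing.assert_array_equal(s1.n_support_, s2.n_support_)
    np.testing.assert_array_equal(s1.predict(X), s2.predict(X))


def test_svm_infeasible_nu_names_bound(rng):
    X = np.vstack([rng.standard_normal((40, 3)), rng.standard_normal((2, 3)) + 5])
    y = ["low"] * 40 + ["high"] * 2
    with pytest.raises(ValueError, match="infeasible"):
        fit_svm(X, y, nu=0.9)


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------


def test_evaluate_simple_counts():
    y_true = ["low"] * 8 + ["medium"] * 4
    y_pred = ["low"] * 6 + ["medium"] * 2 + ["medium"] * 3 + ["low"]
    rep = evaluate(y_true, y_pred)
    low = rep.per_class.set_index("class").loc["low"]
    assert low["pixels"] == 8
    assert low["precision"] == pytest.approx(6 / 7)
    assert low["recall"] == pytest.approx(6 / 8)
    f1 = low["f1"]
    assert f1 == pytest.approx(f1_from_pr(6 / 7, 6 / 8))


def test_evaluate_p_equals_r_gives_f1():
    y_true = ["low", "low", "medium", "medium"]
    y_pred = ["low", "medium", "low", "medium"]
    rep = evaluate(y_true, y_pred)
    for _, row in rep.per_class.iterrows():
        assert row["precision"] == row["recall"] == row["f1"]


def test_evaluate_absent_class_reported():
    rep = evaluate(["low", "low"], ["low", "low"])
    assert rep.absent_classes == ["medium", "high"]
    assert list(rep.per_class["class"]) == ["low"]


def test_evaluate_rejects_unknown_labels():
    with pytest.raises(ValueError, match="outside class set"):
        evaluate(["low"], ["bananas"])


def test_evaluate_report_rounding(tmp_path):
    y_true = ["low"] * 87 + ["medium"] * 13
    y_pred = ["low"] * 80 + ["medium"] * 7 + ["medium"] * 13
    frame = evaluate(y_true, y_pred).to_frame()
    assert set(frame.columns) == {"class", "pixels", "precision", "recall", "f1"}
    assert frame["f1"].between(0, 1).all()


# ---------------------------------------------------------------------------
# majority vote
# ---------------------------------------------------------------------------


def test_majority_vote_plurality():
    pred = ["low"] * 60 + ["medium"] * 3 + ["high"] * 2
    votes = majority_vote(pred, ["s1"] * 65)
    assert votes.loc[0, "label"] == "low"
    assert votes.loc[0, "votes_low"] == 60
    assert not votes.loc[0, "tie"]


def test_majority_vote_tie_breaks_toward_severity():
    pred = ["low"] * 5 + ["medium"] * 5
    with pytest.warns(UserWarning, match="tie"):
        votes = majority_vote(pred, ["s1"] * 10)
    assert votes.loc[0, "label"] == "medium"
    assert votes.loc[0, "tie"]


def test_majority_vote_empty_rejected():
    with pytest.raises(ValueError, match="no predicted pixels"):
        majority_vote([], [])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def test_train_pipeline_per_morph_isolation(rng):
    table = _annotated_table(rng)
    result = train_pipeline(table, n_latent=3, seed=0)
    assert set(result.bundle.models) == {"white", "orange"}
    w, o = result.bundle.models["white"], result.bundle.models["orange"]
    assert w is not o
    assert not np.array_equal(w.x_standardizer.mean_, o.x_standardizer.mean_)


def test_train_pipeline_split_is_stratified_and_seeded(rng):
    table = _annotated_table(rng, n_samples=12, px_per_sample=30)
    r1 = train_pipeline(table, n_latent=3, seed=5)
    r2 = train_pipeline(table, n_latent=3, seed=5)
    for morph in ("white", "orange"):
        t1, t2 = r1.test_tables[morph], r2.test_tables[morph]
        assert (t1.meta["sample_id"] == t2.meta["sample_id"]).all()
        # class proportions preserved within +-1 sample per class
        full = table.split_by_morph()[morph]
        for cls in ("low", "medium", "high"):
            expected = 0.2 * (full.y_c == cls).sum()
            got = (t1.y_c == cls).sum()
            assert abs(got - expected) <= 1


def test_train_pipeline_deterministic(rng):
    table = _annotated_table(rng)
    r1 = train_pipeline(table, n_latent=3, seed=2)
    r2 = train_pipeline(table, n_latent=3, seed=2)
    for morph in ("white", "orange"):
        p1 = r1.bundle.predict(morph, table.split_by_morph()[morph].X)
        p2 = r2.bundle.predict(morph, table.split_by_morph()[morph].X)
        np.testing.assert_array_equal(p1, p2)
    assert r1.reports["white"].totals == r2.reports["white"].totals


def test_train_pipeline_separable_data_classifies_well(rng):
    table = _annotated_table(rng, n_samples=18, px_per_sample=40)
    result = train_pipeline(table, n_latent=4, seed=1)
    for morph, report in result.reports.items():
        assert report.totals["accuracy"] >= 0.9
        assert result.vote_accuracy[morph] == 1.0


def test_train_pipeline_requires_annotations(rng):
    table = _annotated_table(rng)
    bare = SpectraTable(
        X=table.X, wavelengths=table.wavelengths, meta=table.meta
    )
    with pytest.raises(ValueError, match="annotated"):
        train_pipeline(bare)


# ---------------------------------------------------------------------------
# reference group
# ---------------------------------------------------------------------------


def test_reference_group_all_low(rng):
    table = _annotated_table(rng)
    result = train_pipeline(table, n_latent=3, seed=0)
    low_rows = (table.y_c == "low").to_numpy()
    ref = table.subset(low_rows)
    out = evaluate_reference_group(result.bundle, ref)
    for morph, entry in out.items():
        low = entry["report"].per_class.set_index("class")
        assert low.loc["low", "recall"] >= 0.9
        assert entry["fraction_samples_low"] == 1.0


def test_reference_group_missing_morph_rejected(rng):
    table = _annotated_table(rng)
    result = train_pipeline(table, n_latent=3, seed=0)
    ref = table.subset((table.y_c == "low").to_numpy())
    bundle = ClassifierBundle(
        models={"white": result.bundle.models["white"]},
        test_fraction=0.2,
        split_seed=0,
    )
    with pytest.raises(KeyError, match="orange"):
        evaluate_reference_group(bundle, ref)


def test_reference_group_empty_rejected(rng):
    table = _annotated_table(rng)
    result = train_pipeline(table, n_latent=3, seed=0)
    empty = table.subset(np.zeros(table.n_pixels, dtype=bool))
    with pytest.raises(ValueError, match="no pixels"):
        evaluate_reference_group(result.bundle, empty)
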