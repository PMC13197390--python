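"""Tests for MANOVA, Holm correction, balanced task effects and LDA/QDA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazecoda import CompositionMatrix, fit_discriminant, ilr_inverse
from gazecoda.inference import (
    clr_coordinate_table,
    clr_task_effects,
    cross_validate,
    manova,
    pairwise_manova_holm,
    pillai_f,
)


def _grouped_matrix(n_per=30, d=5, k=3, shift=1.0, seed=0):
    """Logistic-normal groups with ilr-space mean shifts of size ``shift``."""
    rng = np.random.default_rng(seed)
    rows, tasks = [], []
    for g in range(k):
        mu = np.zeros(d - 1)
        if shift:
            mu[g % (d - 1)] = shift
        Z = rng.normal(size=(n_per, d - 1)) + mu
        rows.append(ilr_inverse(Z))
        tasks += [g + 1] * n_per
    meta = pd.DataFrame({"participant": [f"P{i}" for i in range(n_per * k)],
                         "task": tasks})
    return CompositionMatrix(np.vstack(rows), [f"A{j}" for j in range(d)], meta)


# ---------------------------------------------------------------------------
# Pillai F approximation

@pytest.mark.parametrize("p, expected_df", [(6, (36.0, 6006.0)), (7, (42.0, 6000.0))])
def test_pillai_df_arithmetic(p, expected_df):
    _, df1, df2 = pillai_f(0.5, p=p, q=6, N=1008, K=7)
    assert (df1, df2) == expected_df


def test_partial_eta2_arithmetic():
    X = _grouped_matrix()
    res = manova(X, mode="ilr")
    s = min(res.p, len(res.groups) - 1)
    assert res.partial_eta2 == pytest.approx(res.pillai / s)
    # printed-pair consistency of the eta2 = V/s formula at s = 6
    assert 1.0 / 6 == pytest.approx(0.167, abs=5e-4)
    assert 1.24 / 6 == pytest.approx(0.206, abs=1e-3)


# ---------------------------------------------------------------------------
# MANOVA

def test_manova_pivot_order_invariance():
    X = _grouped_matrix(seed=1)
    ref = manova(X, mode="ilr")
    for order in (X.parts[::-1], ["A2", "A0", "A4", "A1", "A3"]):
        alt = manova(X, mode="ilr", order=order)
        assert alt.pillai == pytest.approx(ref.pillai, abs=1e-9)
        assert alt.f_stat == pytest.approx(ref.f_stat, abs=1e-9)
        assert alt.p_value == pytest.approx(ref.p_value, abs=1e-9)


def test_manova_closure_invariance():
    X = _grouped_matrix(seed=2)
    scales = np.exp(np.random.default_rng(3).normal(size=(X.n, 1)))
    Xs = CompositionMatrix(X.values * scales, X.parts, X.row_meta)
    a, b = manova(X, mode="ilr"), manova(Xs, mode="ilr")
    assert b.pillai == pytest.approx(a.pillai, abs=1e-9)
    assert b.p_value == pytest.approx(a.p_value, abs=1e-9)


def test_manova_k2_matches_hotelling():
    X = _grouped_matrix(n_per=25, d=4, k=2, seed=4)
    res = manova(X, mode="ilr")
    Z = X.ilr()
    g = X.row_meta["task"].to_numpy()
    z1, z2 = Z[g == 1], Z[g == 2]
    n1, n2 = len(z1), len(z2)
    p = Z.shape[1]
    d = z1.mean(axis=0) - z2.mean(axis=0)
    S = ((len(z1) - 1) * np.cov(z1, rowvar=False) +
         (len(z2) - 1) * np.cov(z2, rowvar=False)) / (n1 + n2 - 2)
    t2 = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d)
    F = (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p) * t2
    p_hot = stats.f.sf(F, p, n1 + n2 - p - 1)
    assert res.p_value == pytest.approx(p_hot, abs=1e-9)


def test_manova_matches_statsmodels():
    """Independent oracle: Pillai V, F, dfs and p from statsmodels.MANOVA."""
    from statsmodels.multivariate.manova import MANOVA

    X = _grouped_matrix(n_per=20, d=4, k=3, seed=5)
    res = manova(X, mode="ilr")
    df = pd.DataFrame(X.ilr(), columns=["z1", "z2", "z3"])
    df["task"] = X.row_meta["task"].astype(str).to_numpy()
    fit = MANOVA.from_formula("z1 + z2 + z3 ~ C(task)", data=df)
    tbl = fit.mv_test().results["C(task)"]["stat"]
    row = tbl.loc["Pillai's trace"]
    assert res.pillai == pytest.approx(float(row["Value"]), abs=1e-9)
    assert res.f_stat == pytest.approx(float(row["F Value"]), rel=1e-6)
    assert (res.df1, res.df2) == (float(row["Num DF"]), float(row["Den DF"]))
    assert res.p_value == pytest.approx(float(row["Pr > F"]), abs=1e-9)


def test_manova_back_transformed_means():
    X = _grouped_matrix(seed=6)
    res = manova(X, mode="ilr")
    for g, comp in res.group_mean_compositions.items():
        assert comp.sum() == pytest.approx(100.0)
        assert np.all(comp > 0)


def test_manova_guards():
    X = _grouped_matrix(n_per=10, k=1)
    with pytest.raises(ValueError, match="2 groups"):
        manova(X, groups=np.ones(X.n, dtype=int))
    small = _grouped_matrix(n_per=4, d=6, k=2)
    with pytest.raises(ValueError, match="<= p"):
        manova(small, mode="ilr")


# ---------------------------------------------------------------------------
# Holm correction

def test_holm_hand_cases():
    from statsmodels.stats.multitest import multipletests

    np.testing.assert_allclose(
        multipletests([0.01, 0.01, 0.01], method="holm")[1], [0.03, 0.03, 0.03])
    np.testing.assert_allclose(
        multipletests([0.01, 0.04, 0.03], method="holm")[1], [0.03, 0.06, 0.06])


def test_pairwise_holm_table():
    X = _grouped_matrix(n_per=25, d=4, k=3, shift=1.5, seed=7)
    tbl = pairwise_manova_holm(X, mode="ilr")
    assert len(tbl) == 3
    assert (tbl["p_holm"] >= tbl["p_value"] - 1e-15).all()
    # K=2: the single pair is unadjusted and equals a direct MANOVA
    X2 = _grouped_matrix(n_per=25, d=4, k=2, seed=8)
    tbl2 = pairwise_manova_holm(X2)
    assert len(tbl2) == 1
    direct = manova(X2)
    assert tbl2["p_value"].iloc[0] == pytest.approx(direct.p_value)
    assert tbl2["p_holm"].iloc[0] == pytest.approx(direct.p_value)


# ---------------------------------------------------------------------------
# balanced task effects

def _balanced_long(n_participants, deltas, sigma, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        base = rng.normal()
        for t, d in enumerate(deltas, start=1):
            rows.append((f"P{i}", t, base + d + sigma * rng.normal()))
    return pd.DataFrame(rows, columns=["participant", "task", "value"])


def test_effects_zero_without_task_variation():
    long = _balanced_long(10, [0.0, 0.0, 0.0], sigma=0.0, seed=0)
    eff = clr_task_effects(long, mode="raw")
    np.testing.assert_allclose(eff.effects.to_numpy(), 0.0, atol=1e-12)


def test_effects_recover_injected_shifts():
    deltas = np.array([0.8, -0.3, -0.5, 0.0])
    long = _balanced_long(200, deltas, sigma=0.3, seed=1)
    eff = clr_task_effects(long, mode="clr")
    np.testing.assert_allclose(eff.effects.to_numpy(), deltas, atol=0.08)
    np.testing.assert_allclose(eff.exp_effects.to_numpy(), np.exp(deltas), rtol=0.1)
    assert eff.effects.sum() == pytest.approx(0.0, abs=1e-12)


def test_effects_reject_unbalanced():
    long = _balanced_long(5, [0.1, -0.1], sigma=0.1, seed=2).iloc[:-1]
    with pytest.raises(ValueError, match="unbalanced"):
        clr_task_effects(long)


def test_clr_coordinate_table(small_matrix):
    long = clr_coordinate_table(small_matrix, "B")
    assert set(long.columns) == {"participant", "task", "value"}
    assert len(long) == small_matrix.n


# ---------------------------------------------------------------------------
# discriminant analysis

def test_lda_separable_1d():
    rng = np.random.default_rng(0)
    Z = np.concatenate([rng.normal(-10, 1, 100), rng.normal(10, 1, 100)])[:, None]
    y = np.repeat([0, 1], 100)
    clf = fit_discriminant(Z, y, kind="lda")
    # decision boundary at 0: posteriors flip sides there
    assert clf.predict(np.array([[-0.5]]))[0] == 0
    assert clf.predict(np.array([[0.5]]))[0] == 1
    assert (clf.predict(Z) == y).mean() == 1.0


def test_posteriors_sum_to_one():
    X = _grouped_matrix(seed=9)
    Z = X.ilr()
    clf = fit_discriminant(Z, X.row_meta["task"], kind="lda")
    np.testing.assert_allclose(clf.posteriors(Z).sum(axis=1), 1.0, atol=1e-12)
    qda = fit_discriminant(Z, X.row_meta["task"], kind="qda")
    np.testing.assert_allclose(qda.posteriors(Z).sum(axis=1), 1.0, atol=1e-12)


def test_lda_matches_sklearn():
    sk = pytest.importorskip("sklearn.discriminant_analysis")
    X = _grouped_matrix(n_per=40, d=5, k=3, shift=0.8, seed=10)
    Z, y = X.ilr(), X.row_meta["task"].to_numpy()
    ours = fit_discriminant(Z, y, kind="lda")
    theirs = sk.LinearDiscriminantAnalysis(solver="svd").fit(Z, y)
    assert (ours.predict(Z) == theirs.predict(Z)).mean() == 1.0
    np.testing.assert_allclose(ours.posteriors(Z), theirs.predict_proba(Z), atol=1e-8)


def test_discriminant_guards():
    Z = np.random.default_rng(1).normal(size=(8, 4))
    y = np.repeat([0, 1], 4)
    with pytest.raises(ValueError, match="QDA"):
        fit_discriminant(Z, y, kind="qda")
    with pytest.raises(ValueError, match="kind"):
        fit_discriminant(Z, y, kind="forest")
    with pytest.raises(ValueError, match="priors"):
        fit_discriminant(np.vstack([Z, Z]), np.tile(y, 2), priors=[0.3, 0.3])


# ---------------------------------------------------------------------------
# cross-validation

def test_cv_deterministic_and_confusion_consistent():
    X = _grouped_matrix(n_per=30, k=3, shift=0.8, seed=11)
    a = cross_validate(X, folds=5, seed=99)
    b = cross_validate(X, folds=5, seed=99)
    np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
    pd.testing.assert_frame_equal(a.confusion, b.confusion)
    assert a.confusion.values.sum(axis=1).tolist() == [30, 30, 30]
    assert a.accuracy == pytest.approx(
        np.trace(a.confusion.values) / a.confusion.values.sum())
    c = cross_validate(X, folds=5, seed=100)
    assert not np.array_equal(a.fold_assignments, c.fold_assignments)


def test_cv_perfectly_separable():
    X = _grouped_matrix(n_per=30, d=4, k=3, shift=25.0, seed=12)
    rep = cross_validate(X, folds=5, seed=0)
    assert rep.accuracy == 1.0
    assert np.all(np.diag(rep.confusion.values) == 30)


def test_cv_infeasible_stratification():
    X = _grouped_matrix(n_per=3, d=3, k=2)
    with pytest.raises(ValueError, match="stratification"):
        cross_validate(X, folds=5, seed=0)


def test_ilr_basis_invariance_of_classification():
    """Classification is unchanged under any orthonormal ilr recoordinatization."""
    X = _grouped_matrix(n_per=25, d=5, k=3, shift=0.6, seed=13)
    y = X.row_meta["task"].to_numpy()
    Z = X.ilr()
    rng = np.random.default_rng(14)
    Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    ZQ = Z @ Q
    ours = fit_discriminant(Z, y).predict(Z)
    rotated = fit_discriminant(ZQ, y).predict(ZQ)
    assert (ours == rotated).all()
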