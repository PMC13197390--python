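"""Compositional and classical inference: MANOVA with Pillai's trace,
Holm-corrected pairwise tests, balanced-design task effects on clr
coordinates, and Gaussian discriminant classification with stratified
cross-validation.

Compositional MANOVA is classical MANOVA applied to ilr coordinates: the
group model x = mu_k (+) e becomes ilr(x) = ilr(mu_k) + ilr(e) with Gaussian
errors, so the usual between/within cross-product machinery applies and the
result is invariant to the particular orthonormal ilr basis. The classical
track runs the identical machinery on raw millisecond responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coda import CompositionMatrix, clr_transform, close, ilr_inverse

__all__ = ["CvReport", "EffectTable", "GaussianClassifier", "ManovaResult",
           "clr_task_effects", "cross_validate", "fit_discriminant", "manova",
           "pairwise_manova_holm", "pillai_f"]


# ---------------------------------------------------------------------------
# MANOVA


@dataclass
class ManovaResult:
    mode: str                      # 'ilr' or 'raw'
    groups: list
    group_means: dict              # group -> mean response vector (coordinate space)
    group_mean_compositions: dict | None  # ilr mode: back-transformed, kappa=100
    pooled_cov: np.ndarray
    pillai: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    partial_eta2: float
    n: int
    p: int


def pillai_f(V: float, p: int, q: int, N: int, K: int) -> tuple[float, float, float]:
    """F approximation for Pillai's trace with s/m/n* parameters.

    s = min(p, q), m = (|p - q| - 1)/2, n* = (N - K - p - 1)/2;
    F = (V/s) / (1 - V/s) * (2n* + s + 1)/(2m + s + 1) on
    df1 = s(2m + s + 1), df2 = s(2n* + s + 1).
    """
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nstar = (N - K - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nstar + s + 1)
    ratio = (V / s) / (1 - V / s) if V < s else np.inf
    F = ratio * (2 * nstar + s + 1) / (2 * m + s + 1)
    return F, df1, df2


def _responses(X: CompositionMatrix, mode: str, order=None) -> np.ndarray:
    if mode == "ilr":
        return X.ilr(order=order)
    if mode == "raw":
        return X.values
    raise ValueError(f"unknown mode {mode!r}; use 'ilr' or 'raw'")


def _group_labels(X: CompositionMatrix, groups) -> np.ndarray:
    if groups is not None:
        g = np.asarray(groups)
        if g.shape[0] != X.n:
            raise ValueError("group labels length does not match number of rows")
        return g
    if X.row_meta is None or "task" not in X.row_meta.columns:
        raise ValueError("no group labels given and row_meta has no 'task' column")
    return X.row_meta["task"].to_numpy()


def manova(X: CompositionMatrix, groups=None, mode: str = "ilr", order=None) -> ManovaResult:
    """Test equality of group mean compositions (mode='ilr') or of group mean
    raw vectors (mode='raw') with Pillai's trace.

    Requires K >= 2 groups and every group larger than the response dimension
    p (p = D-1 for ilr, D for raw). Pillai V is the sum of eigenvalues of
    B(B+W)^{-1}; partial eta^2 = V / min(p, K-1).
    """
    Z = _responses(X, mode, order)
    g = _group_labels(X, groups)
    labels, inv = np.unique(g, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("MANOVA needs at least 2 groups")
    N, p = Z.shape
    counts = np.bincount(inv)
    if counts.min() <= p:
        small = labels[np.argmin(counts)]
        raise ValueError(
            f"group {small!r} has n={counts.min()} <= p={p} responses; "
            "merge AOIs or reduce dimensionality")
    grand = Z.mean(axis=0)
    means = np.vstack([Z[inv == k].mean(axis=0) for k in range(K)])
    B = sum(counts[k] * np.outer(means[k] - grand, means[k] - grand) for k in range(K))
    W = np.zeros((p, p))
    for k in range(K):
        R = Z[inv == k] - means[k]
        W += R.T @ R
    T = B + W
    try:
        sol = np.linalg.solve(T, B)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "total cross-product matrix is singular; merge AOIs or reduce D"
        ) from exc
    V = float(np.trace(sol))
    q = K - 1
    s = min(p, q)
    F, df1, df2 = pillai_f(V, p, q, N, K)
    p_value = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    mean_comps = None
    if mode == "ilr":
        mean_comps = {
            labels[k]: ilr_inverse(means[k], kappa=100.0, order=order, parts=X.parts)
            for k in range(K)
        }
    return ManovaResult(
        mode=mode,
        groups=labels.tolist(),
        group_means={labels[k]: means[k] for k in range(K)},
        group_mean_compositions=mean_comps,
        pooled_cov=W / (N - K),
        pillai=V,
        f_stat=float(F),
        df1=float(df1),
        df2=float(df2),
        p_value=p_value,
        partial_eta2=V / s,
        n=N,
        p=p,
    )


def pairwise_manova_holm(X: CompositionMatrix, groups=None, mode: str = "ilr") -> pd.DataFrame:
    """All K(K-1)/2 pairwise Pillai tests with Holm step-down adjustment.

    Pairs whose MANOVA preconditions fail are skipped with a warning and do
    not enter the correction.
    """
    import logging

    g = _group_labels(X, groups)
    labels = np.unique(g)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            mask = np.isin(g, [labels[i], labels[j]])
            try:
                res = manova(X.subset(mask), groups=g[mask], mode=mode)
            except ValueError as exc:
                logging.getLogger(__name__).warning(
                    "skipping pair (%r, %r): %s", labels[i], labels[j], exc)
                continue
            rows.append({"group1": labels[i], "group2": labels[j],
                         "pillai": res.pillai, "f_stat": res.f_stat,
                         "df1": res.df1, "df2": res.df2, "p_value": res.p_value})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p_value"], method="holm")[1]
    return df


# ---------------------------------------------------------------------------
# Balanced-design task effects


@dataclass
class EffectTable:
    """Per-task fixed effects of a balanced two-way (participant x task) design.

    effect(t) = mean over participants of (value_it - participant mean over
    tasks). On balanced complete data this equals the fixed-effect estimates
    of a random-intercept mixed model. Effects sum to zero across tasks; in
    clr mode ``exp_effect`` gives the multiplicative change in relative
    dominance versus the participant-wise mean.
    """

    mode: str
    effects: pd.Series             # index: task
    exp_effects: pd.Series | None  # clr mode only

    def to_frame(self) -> pd.DataFrame:
        df = self.effects.rename("effect").to_frame()
        if self.exp_effects is not None:
            df["exp_effect"] = self.exp_effects
        return df.reset_index()


def clr_task_effects(long: pd.DataFrame, mode: str = "clr") -> EffectTable:
    """Estimate per-task effects from a long (participant, task, value) table.

    ``value`` is the clr coordinate of the AOI of interest (mode='clr') or
    the raw millisecond dwell time (mode='raw'). The design must be balanced
    and complete — every participant under every task exactly once;
    unbalanced data need general mixed-model tooling, which is out of scope
    here.
    """
    if mode not in ("clr", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    required = {"participant", "task", "value"}
    if not required <= set(long.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    wide = long.pivot(index="participant", columns="task", values="value")
    if wide.isna().any().any():
        raise ValueError(
            "design is unbalanced (missing participant-task cells); "
            "use a general mixed-effects model instead")
    centered = wide.sub(wide.mean(axis=1), axis=0)
    effects = centered.mean(axis=0)
    effects.index.name = "task"
    exp_effects = np.exp(effects) if mode == "clr" else None
    return EffectTable(mode, effects, exp_effects)


def clr_coordinate_table(X: CompositionMatrix, aoi: str) -> pd.DataFrame:
    """Long (participant, task, value) table of one AOI's clr coordinate."""
    if X.row_meta is None:
        raise ValueError("needs row_meta with participant and task")
    j = X.parts.index(aoi)
    vals = clr_transform(X.values)[:, j]
    return pd.DataFrame({
        "participant": X.row_meta["participant"],
        "task": X.row_meta["task"],
        "value": vals,
    })


# ---------------------------------------------------------------------------
# Discriminant analysis


@dataclass
class GaussianClassifier:
    """Gaussian LDA/QDA on real coordinates (ilr balances or raw ms).

    Bayes rule on class-conditional normals: LDA pools one covariance across
    classes (divisor N - K), QDA estimates one per class (divisor n_k - 1).
    Priors default to empirical class shares.
    """

    kind: str                     # 'lda' or 'qda'
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray             # (K, p)
    covariances: np.ndarray       # (p, p) pooled for LDA, (K, p, p) for QDA
    mode: str = "ilr"

    def _log_likelihoods(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(Z)
        K = len(self.classes)
        out = np.empty((Z.shape[0], K))
        for k in range(K):
            cov = self.covariances if self.kind == "lda" else self.covariances[k]
            out[:, k] = stats.multivariate_normal.logpdf(Z, self.means[k], cov)
        return out

    def posteriors(self, Z: np.ndarray) -> np.ndarray:
        logp = self._log_likelihoods(Z) + np.log(self.priors)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.posteriors(Z), axis=1)]


def fit_discriminant(Z: np.ndarray, labels, kind: str = "lda", priors=None) -> GaussianClassifier:
    """Fit Gaussian LDA or QDA to coordinates ``Z`` with class ``labels``."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(labels)
    classes, inv = np.unique(y, return_inverse=True)
    K = len(classes)
    N, p = Z.shape
    counts = np.bincount(inv)
    kind = kind.lower()
    if kind not in ("lda", "qda"):
        raise ValueError(f"unknown classifier kind {kind!r}")
    if kind == "qda" and counts.min() <= p:
        bad = classes[np.argmin(counts)]
        raise ValueError(f"class {bad!r} has n={counts.min()} <= p={p}; QDA covariance singular")
    if kind == "lda" and N - K < p:
        raise ValueError(f"N - K = {N - K} < p = {p}; pooled covariance singular")
    means = np.vstack([Z[inv == k].mean(axis=0) for k in range(K)])
    if kind == "lda":
        W = np.zeros((p, p))
        for k in range(K):
            R = Z[inv == k] - means[k]
            W += R.T @ R
        covs = W / (N - K)
        if np.linalg.matrix_rank(covs) < p:
            raise ValueError("pooled covariance is singular; merge AOIs or reduce D")
    else:
        covs = np.stack([np.cov(Z[inv == k], rowvar=False, ddof=1) for k in range(K)])
        for k in range(K):
            if np.linalg.matrix_rank(covs[k]) < p:
                raise ValueError(f"covariance of class {classes[k]!r} is singular")
    if priors is None:
        pr = counts / N
    elif isinstance(priors, str) and priors == "uniform":
        pr = np.full(K, 1.0 / K)
    else:
        pr = np.asarray(priors, dtype=float)
        if not np.isclose(pr.sum(), 1.0):
            raise ValueError("priors must sum to 1")
    return GaussianClassifier(kind, classes, pr, means, covs)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CvReport:
    accuracy: float
    confusion: pd.DataFrame       # rows = true class, columns = predicted
    fold_assignments: np.ndarray
    seed: int
    folds: int
    kind: str
    mode: str

    def per_class_accuracy(self) -> pd.Series:
        c = self.confusion
        return pd.Series(np.diag(c.values) / c.values.sum(axis=1), index=c.index)


def _stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    assign = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} rows < {folds} folds; stratification infeasible")
        perm = rng.permutation(idx)
        assign[perm] = np.arange(len(perm)) % folds
    return assign


def cross_validate(
    X: CompositionMatrix,
    groups=None,
    kind: str = "lda",
    mode: str = "ilr",
    folds: int = 10,
    seed: int = 0,
) -> CvReport:
    """Stratified k-fold cross-validated task classification.

    Folds stratify by class over observations, deterministically from
    ``seed``. Reports pooled held-out accuracy and the K x K confusion
    matrix (rows = true class); each confusion row sums to that class's n.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    Z = _responses(X, mode)
    y = _group_labels(X, groups)
    assign = _stratified_folds(y, folds, seed)
    classes = np.unique(y)
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for f in range(folds):
        test = assign == f
        clf = fit_discriminant(Z[~test], y[~test], kind=kind)
        pred = clf.predict(Z[test])
        for true, hat in zip(y[test], pred):
            conf.loc[true, hat] += 1
    acc = float(np.trace(conf.values) / conf.values.sum())
    return CvReport(acc, conf, assign, seed, folds, kind, mode)
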