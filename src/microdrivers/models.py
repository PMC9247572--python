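"""State classification and covariate regression on core taxa.

``rf_classify`` trains a bagged ensemble of randomized decision trees on
per-feature standardized abundances (80/20 stratified split), reporting
the two classic forest importances: mean decrease in accuracy (MDA,
out-of-bag accuracy drop when a feature's values are permuted) and mean
decrease in Gini impurity (MDG), plus held-out ROC/AUC.

``negbin_glm`` fits a log-link negative-binomial (NB2) regression by
iteratively reweighted least squares with a method-of-moments dispersion
update, and assigns per-term significance from a case-resampling
bootstrap.  ``all_subsets`` screens covariate subsets on a Gaussian
working model of log1p counts by adjusted R^2, mirroring the common
two-step practice of subset screening followed by count-model inference.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.tree import DecisionTreeClassifier

from .asv_tables import NormalizedTable
from .diversity import mann_whitney_auc_rank


@dataclass
class ClassifierReport:
    importances: pd.DataFrame  # mda, mdg, rank_mda, rank_mdg per feature
    top_k: list[str]
    roc: pd.DataFrame  # fpr, tpr, threshold
    auc: float
    train_samples: list[str]
    test_samples: list[str]
    positive_state: str
    n_trees: int
    train_fraction: float
    seed: int


@dataclass
class GlmReport:
    terms: list[str]
    coefficients: pd.Series
    dispersion: float
    bootstrap_p: pd.Series
    conf_int: pd.DataFrame  # lower, upper (percentile bootstrap)
    n_bootstrap: int
    loglik: float
    converged: bool
    subset_table: pd.DataFrame | None = None


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Ties count one half; invariant under strictly monotone transforms of
    the scores.  ``labels`` must contain both classes.
    """
    return mann_whitney_auc_rank(scores, labels)


# ---------------------------------------------------------------------------
# Random forest with OOB permutation importance
# ---------------------------------------------------------------------------

def _roc_points(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    tpr = np.concatenate([[0.0], tps / max(y.sum(), 1)])
    fpr = np.concatenate([[0.0], fps / max((1 - y).sum(), 1)])
    thr = np.concatenate([[np.inf], scores[order]])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def rf_classify(
    table: NormalizedTable,
    states=None,
    n_trees: int = 500,
    train_fraction: float = 0.8,
    seed: int = 0,
    top_k: int = 20,
) -> ClassifierReport:
    """Random-forest classification of treatment state from abundances.

    Features are TMM-normalized abundances z-scored per feature.  Trees
    are grown on bootstrap resamples of the training split with sqrt
    feature subsampling; MDA is each tree's out-of-bag accuracy drop
    under per-feature permutation, averaged over trees, and MDG the mean
    per-tree Gini impurity decrease.  ROC/AUC use the held-out split
    only.  The whole procedure is reproducible from ``seed``.
    """
    if states is None:
        states = table.states()
    sample_ids = table.sample_ids
    labels = pd.Series(states, index=sample_ids).loc[sample_ids]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError("rf_classify needs exactly two states")
    positive = uniq[1]  # lexicographically later state scored as positive
    y = (labels == positive).to_numpy().astype(int)
    x = table.matrix.T.astype(float)  # samples x features
    mu, sd = x.mean(axis=0), x.std(axis=0)
    x = (x - mu) / np.where(sd > 0, sd, 1.0)
    features = table.asv_ids

    rng = np.random.default_rng(seed)
    # stratified train/test split
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    if len(set(y[train_idx])) < 2 or len(set(y[test_idx])) < 2:
        raise ValueError("single-class split; choose another seed or more samples")
    xtr, ytr = x[train_idx], y[train_idx]
    n_tr, n_feat = xtr.shape

    mda_sum = np.zeros(n_feat)
    mda_n = np.zeros(n_feat)
    mdg = np.zeros(n_feat)
    test_votes = np.zeros(len(test_idx))
    for t in range(n_trees):
        boot = rng.integers(0, n_tr, size=n_tr)
        oob = np.setdiff1d(np.arange(n_tr), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2 ** 31))
        )
        tree.fit(xtr[boot], ytr[boot])
        mdg += tree.feature_importances_
        test_votes += tree.predict_proba(x[test_idx])[:, list(tree.classes_).index(1)] \
            if 1 in tree.classes_ else 0.0
        if oob.size == 0 or len(set(ytr[oob])) == 0:
            continue
        base_acc = float(np.mean(tree.predict(xtr[oob]) == ytr[oob]))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            xp = xtr[oob].copy()
            xp[:, f] = xp[rng.permutation(oob.size), f]
            perm_acc = float(np.mean(tree.predict(xp) == ytr[oob]))
            mda_sum[f] += base_acc - perm_acc
            mda_n[f] += 1
        mda_n[np.setdiff1d(np.arange(n_feat), used)] += 0  # unused features: no change
    mda = np.where(mda_n > 0, mda_sum / np.maximum(mda_n, 1), 0.0)
    mdg /= n_trees
    scores = test_votes / n_trees

    imp = pd.DataFrame({"mda": mda, "mdg": mdg}, index=features)
    imp["rank_mda"] = imp["mda"].rank(ascending=False, method="first").astype(int)
    imp["rank_mdg"] = imp["mdg"].rank(ascending=False, method="first").astype(int)
    top = list(imp.sort_values("mda", ascending=False).head(top_k).index)
    y_test = y[test_idx]
    return ClassifierReport(
        importances=imp,
        top_k=top,
        roc=_roc_points(scores, y_test),
        auc=auc(scores, y_test),
        train_samples=[sample_ids[i] for i in train_idx],
        test_samples=[sample_ids[i] for i in test_idx],
        positive_state=positive,
        n_trees=n_trees,
        train_fraction=train_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# All-subsets screening
# ---------------------------------------------------------------------------

def all_subsets(y, X: pd.DataFrame, max_size: int | None = None) -> pd.DataFrame:
    """Adjusted R^2 of a log1p-Gaussian working model for every covariate subset.

    Enumerates all subsets up to ``max_size`` (covariate count must be
    <= 15), flags the best subset per size, and marks collinear subsets
    instead of failing on them.  The empty subset scores 0.
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    if len(names) > 15:
        raise ValueError("all_subsets limited to 15 covariates (2^p enumeration)")
    if max_size is None:
        max_size = len(names)
    yv = np.log1p(np.asarray(y, dtype=float))
    n = yv.size
    sst = float(np.sum((yv - yv.mean()) ** 2))
    rows = [{"subset": (), "size": 0, "adj_r2": 0.0, "collinear": False}]
    xmat = X.to_numpy(dtype=float)
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(range(len(names)), size):
            design = np.column_stack([np.ones(n), xmat[:, subset]])
            coef, _, rank, _ = np.linalg.lstsq(design, yv, rcond=None)
            collinear = rank < design.shape[1]
            resid = yv - design @ coef
            sse = float(resid @ resid)
            r2 = 1.0 - sse / sst if sst > 0 else 0.0
            dof = n - size - 1
            adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else float("nan")
            rows.append({
                "subset": tuple(names[i] for i in subset),
                "size": size, "adj_r2": adj, "collinear": collinear,
            })
    out = pd.DataFrame(rows)
    out["best_of_size"] = False
    for size, grp in out.groupby("size"):
        if size == 0 or grp["adj_r2"].isna().all():
            continue
        out.loc[grp["adj_r2"].idxmax(), "best_of_size"] = True
    return out


# ---------------------------------------------------------------------------
# Negative-binomial GLM (NB2, log link)
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, alpha):
    if alpha <= 0:
        return float(np.sum(y * np.log(np.maximum(mu, 1e-300)) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(np.sum(
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
        + inv * np.log(inv / (inv + mu)) + y * np.log(mu / (inv + mu))
    ))


def _nb_irls(y, design, alpha, beta0=None, max_iter=50, tol=1e-9):
    """Weighted least-squares Fisher scoring for a log-link NB2 mean model."""
    n, p = design.shape
    if beta0 is None:
        beta = np.linalg.lstsq(design, np.log1p(y), rcond=None)[0]
    else:
        beta = beta0.copy()
    for _ in range(max_iter):
        eta = np.clip(design @ beta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        wx = design * w[:, None]
        try:
            new = np.linalg.solve(design.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            return beta, False
        if np.max(np.abs(new - beta)) < tol:
            return new, True
        beta = new
    return beta, False


def fit_negbin(y, design, alpha=None, max_outer=25):
    """Fit NB2 regression; estimate dispersion by method of moments.

    ``alpha`` is the NB2 dispersion (variance = mu + alpha*mu^2); pass
    0 for a Poisson fit, or None to estimate it by iterating IRLS for
    the mean with a Pearson moment update for alpha.
    Returns (beta, alpha, loglik, converged).
    """
    y = np.asarray(y, dtype=float)
    if not (y >= 0).all():
        raise ValueError("counts must be non-negative")
    if y.sum() == 0:
        raise ValueError("response is all zero")
    n, p = design.shape
    if n < p + 2:
        raise ValueError("need n >= p + 2 observations")
    estimate_alpha = alpha is None
    a = 0.1 if estimate_alpha else float(alpha)
    beta, ok = _nb_irls(y, design, a)
    if estimate_alpha:
        for _ in range(max_outer):
            mu = np.exp(np.clip(design @ beta, -30, 30))
            # moment estimator of alpha from squared Pearson departures
            num = np.sum((y - mu) ** 2 - mu)
            den = np.sum(mu ** 2)
            a_new = max(num / den, 0.0) if den > 0 else 0.0
            beta_new, ok = _nb_irls(y, design, a_new, beta0=beta)
            if abs(a_new - a) < 1e-8 and np.max(np.abs(beta_new - beta)) < 1e-8:
                beta, a = beta_new, a_new
                break
            beta, a = beta_new, a_new
    mu = np.exp(np.clip(design @ beta, -30, 30))
    return beta, a, _nb_loglik(y, mu, a), ok


def negbin_glm(
    y,
    X: pd.DataFrame,
    n_bootstrap: int = 9999,
    seed: int = 0,
    alpha: float | None = None,
    subset_screen: bool = False,
) -> GlmReport:
    """Negative-binomial regression of a taxon's counts on covariates.

    Per-term significance comes from a case-resampling bootstrap of the
    coefficient estimates: p = 2 * min(#{b* <= 0}, #{b* >= 0}) with the
    (1 + more extreme)/(1 + B) convention, so p is always in (0, 1].
    Percentile 2.5/97.5 bootstrap confidence intervals are reported.
    With ``subset_screen`` the all-subsets adjusted-R^2 table is attached.
    """
    X = pd.DataFrame(X)
    terms = ["intercept"] + list(X.columns)
    y = np.asarray(y, dtype=float)
    n = y.size
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    beta, a_hat, ll, ok = fit_negbin(y, design, alpha=alpha)
    if not ok:
        warnings.warn("negative-binomial IRLS did not fully converge", stacklevel=2)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, len(terms)))
    boots.fill(np.nan)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.sum() == 0:
            continue
        try:
            bb, _, _, _ = fit_negbin(yb, design[idx], alpha=alpha)
        except (ValueError, np.linalg.LinAlgError):
            continue
        boots[b] = bb
    valid = boots[~np.isnan(boots).any(axis=1)]
    n_valid = valid.shape[0]
    lo = np.percentile(valid, 2.5, axis=0)
    hi = np.percentile(valid, 97.5, axis=0)
    n_le = (valid <= 0).sum(axis=0)
    n_ge = (valid >= 0).sum(axis=0)
    pvals = np.minimum(1.0, 2.0 * (np.minimum(n_le, n_ge) + 1) / (n_valid + 1))
    report = GlmReport(
        terms=terms,
        coefficients=pd.Series(beta, index=terms),
        dispersion=float(a_hat),
        bootstrap_p=pd.Series(pvals, index=terms),
        conf_int=pd.DataFrame({"lower": lo, "upper": hi}, index=terms),
        n_bootstrap=n_bootstrap,
        loglik=ll,
        converged=ok,
    )
    if subset_screen:
        report.subset_table = all_subsets(y, X)
    return report
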