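"""Alpha/beta diversity, ordination, PERMANOVA and rank-sum differential tests.

Shannon diversity uses the natural logarithm.  Bray-Curtis is a
semimetric, so no triangle inequality is assumed anywhere downstream.
PERMANOVA permutes sample labels freely by default (matching an
unrestricted ``adonis`` call); pass ``strata`` to restrict permutations
within subjects for the paired design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu, rankdata
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .asv_tables import CountTable, RelAbundanceTable


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal sample-by-sample dissimilarities."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class OrdinationResult:
    method: str
    coordinates: pd.DataFrame  # sample x axis
    eigenvalues: np.ndarray | None = None
    stress: float | None = None
    converged: bool = True
    species_scores: pd.DataFrame | None = None


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample observed richness and Shannon index (natural log)."""
    counts = table.matrix.astype(float)
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        warnings.warn("all-zero samples: richness 0, Shannon 0", stacklevel=2)
    shannon = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if totals[j] == 0:
            continue
        p = counts[:, j][counts[:, j] > 0] / totals[j]
        shannon[j] = -np.sum(p * np.log(p))
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon}, index=table.sample_ids
    )


def rarefaction_curve(table: CountTable, depths) -> pd.DataFrame:
    """Analytic expected richness per subsampling depth per sample.

    E[S_d] = sum_i [1 - C(N - n_i, d) / C(N, d)] (hypergeometric form,
    evaluated with log-gamma for numerical stability).  Depths above a
    sample's total are clipped to that total with a warning.
    """
    depths = np.asarray(sorted(depths), dtype=np.int64)
    counts = table.matrix
    out = np.zeros((len(depths), counts.shape[1]))
    for j in range(counts.shape[1]):
        n = counts[:, j]
        total = int(n.sum())
        nz = n[n > 0].astype(np.int64)
        for k, d in enumerate(depths):
            dd = int(d)
            if dd > total:
                warnings.warn(
                    f"depth {dd} exceeds total {total} in {table.sample_ids[j]}; clipped",
                    stacklevel=2,
                )
                dd = total
            if dd == 0 or total == 0:
                out[k, j] = 0.0
                continue
            # log C(total - n_i, dd) - log C(total, dd); term 0 when n_i > total - dd
            rem = total - nz
            ok = rem >= dd
            log_ratio = np.full(nz.shape, -np.inf)
            log_ratio[ok] = (
                gammaln(rem[ok] + 1) - gammaln(dd + 1) - gammaln(rem[ok] - dd + 1)
                - (gammaln(total + 1) - gammaln(dd + 1) - gammaln(total - dd + 1))
            )
            # clip log-gamma round-off; expectation cannot exceed the
            # depth or the observed richness
            out[k, j] = min(np.sum(1.0 - np.exp(log_ratio)), float(nz.size), float(dd))
    return pd.DataFrame(out, index=depths, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable | RelAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(a, b) = 1 - 2 * sum_i min(x_ia, x_ib) / (sum_i x_ia + sum_i x_ib).
    A pair of all-zero samples gets distance 0 with a warning.
    """
    x = table.matrix.astype(float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("bray_curtis needs at least 2 samples")
    d = np.zeros((n, n))
    totals = x.sum(axis=0)
    for a in range(n):
        for b in range(a + 1, n):
            denom = totals[a] + totals[b]
            if denom == 0:
                warnings.warn("two all-zero samples: distance set to 0", stacklevel=2)
                continue
            d[a, b] = d[b, a] = 1.0 - 2.0 * np.minimum(x[:, a], x[:, b]).sum() / denom
    return DistanceMatrix(labels=table.sample_ids, d=d)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling of a Gower matrix).

    Axes are built from positive eigenvalues only, ordered by descending
    eigenvalue; negative eigenvalues are reported unaltered (no Cailliez
    correction).
    """
    d = dm.d
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals).max())
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    return OrdinationResult(
        method="PCoA",
        coordinates=pd.DataFrame(
            coords, index=dm.labels,
            columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eigvals,
    )


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    restarts: int = 4,
    seed: int = 0,
    table: CountTable | RelAbundanceTable | None = None,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 (best of ``restarts``).

    When ``table`` is given, species scores are computed as
    abundance-weighted averages of the sample coordinates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=restarts,
        random_state=int(seed) % (2 ** 31),
        normalized_stress=True,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(dm.d)
    stress = float(model.stress_)
    result = OrdinationResult(
        method="NMDS",
        coordinates=pd.DataFrame(
            coords, index=dm.labels, columns=[f"NMDS{i + 1}" for i in range(k)]
        ),
        stress=stress,
        converged=model.n_iter_ < max_iter,
    )
    if table is not None:
        x = table.matrix.astype(float)  # ASV x sample
        w = x / np.maximum(x.sum(axis=1, keepdims=True), 1e-300)
        result.species_scores = pd.DataFrame(
            w @ coords, index=table.asv_ids, columns=result.coordinates.columns
        )
    return result


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    strata=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (one-way pseudo-F) on a distance matrix.

    p = (1 + #{perm F >= obs F}) / (1 + n_permutations).  With ``strata``
    (e.g. subject ids) labels are permuted within each stratum only.
    """
    labels = np.asarray(pd.Series(groups, index=dm.labels).loc[dm.labels])
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("permanova needs at least 2 groups")
    counts = np.bincount(inv)
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 samples")
    d2 = dm.d ** 2
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    a = len(uniq)

    def pseudo_f(assignment):
        ssw = 0.0
        for g in range(a):
            idx = np.flatnonzero(assignment == g)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        ssa = sst - ssw
        return (ssa / (a - 1)) / (ssw / (n - a)), ssa

    f_obs, ssa_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    strata_arr = None
    if strata is not None:
        strata_arr = np.asarray(pd.Series(strata, index=dm.labels).loc[dm.labels])
    count_ge = 0
    for _ in range(n_permutations):
        if strata_arr is None:
            perm = rng.permutation(inv)
        else:
            perm = inv.copy()
            for s in np.unique(strata_arr):
                idx = np.flatnonzero(strata_arr == s)
                perm[idx] = perm[rng.permutation(idx)]
        f_perm, _ = pseudo_f(perm)
        if f_perm >= f_obs:
            count_ge += 1
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(ssa_obs / sst) if sst > 0 else 0.0,
        p=(1 + count_ge) / (1 + n_permutations),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

def rank_sum_differential(table: RelAbundanceTable, groups=None) -> pd.DataFrame:
    """Per-ASV two-sided Mann-Whitney test between two groups, BH-adjusted.

    Constant ASVs get p = 1.  Returns a frame with the U statistic, raw p
    and BH-adjusted p, indexed by ASV id.
    """
    if groups is None:
        groups = table.states()
    labels = np.asarray(pd.Series(groups, index=table.sample_ids).loc[table.sample_ids])
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("rank_sum_differential needs exactly two groups")
    x = table.matrix
    ga, gb = labels == uniq[0], labels == uniq[1]
    stats = np.zeros(x.shape[0])
    pvals = np.ones(x.shape[0])
    for i in range(x.shape[0]):
        a, b = x[i, ga], x[i, gb]
        if np.ptp(np.concatenate([a, b])) == 0:
            stats[i] = a.size * b.size / 2.0
            continue
        res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        stats[i], pvals[i] = res.statistic, res.pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"U": stats, "p": pvals, "p_adj": adj,
         "group_a": uniq[0], "group_b": uniq[1]},
        index=table.asv_ids,
    )


def mann_whitney_auc_rank(scores, labels) -> float:
    """Rank-based concordance used by both diversity and model reporting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(scores)
    return float((r[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
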