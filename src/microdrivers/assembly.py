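"""Community assembly inference: Sloan neutral model, niche breadth, C-score nulls.

Three complementary views of stochastic vs deterministic assembly:

* ``fit_ncm`` fits the Sloan neutral community model, which predicts a
  taxon's occurrence frequency from its mean relative abundance through
  a beta distribution parameterized by N*m (metacommunity size times
  migration rate), and scores the fit with an R-squared computed on
  frequencies (1 - SSE/SST).
* ``levins_niche`` / ``classify_niche`` compute the Levins niche breadth
  B = 1/sum(p^2) and classify taxa as generalist / specialist / neutral
  against a fixed-marginal randomization null (95% band).
* ``c_score`` / ``c_score_ses`` measure pairwise segregation
  (checkerboard units) and standardize the observed value against a
  sequential-swap null that preserves both matrix marginals exactly.
  Positive SES means segregated co-occurrence, negative aggregated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist

from .asv_tables import CountTable, to_relative


class FitError(RuntimeError):
    """Neutral-model fit failed or is degenerate."""


@dataclass
class NcmFit:
    Nm: float
    detection_limit: float
    R2: float
    per_asv: pd.DataFrame  # mean_relabund, frequency, predicted, lower, upper, band
    n_samples: int

    def band_counts(self) -> pd.Series:
        return self.per_asv["band"].value_counts()


@dataclass
class NicheResult:
    per_asv: pd.DataFrame  # B, null_lower, null_upper, class
    n_null: int

    def class_counts(self) -> pd.Series:
        return self.per_asv["class"].value_counts()


@dataclass
class CscoreResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p: float
    n_null: int


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

def _ncm_predict(p_mean: np.ndarray, Nm: float, d: float) -> np.ndarray:
    """Predicted occurrence frequency: survival of Beta(Nm*p, Nm*(1-p)) at d."""
    a = np.maximum(Nm * p_mean, 1e-12)
    b = np.maximum(Nm * (1.0 - p_mean), 1e-12)
    return beta_dist.sf(d, a, b)


def _wilson_interval(phat: np.ndarray, n: int, z: float = 1.959963984540054):
    denom = 1.0 + z ** 2 / n
    center = (phat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def fit_ncm(table: CountTable, detection_limit: float | None = None) -> NcmFit:
    """Fit the Sloan neutral model to occupancy vs mean relative abundance.

    The detection limit defaults to 1/mean(library size).  N*m is fitted
    by Levenberg-Marquardt least squares after a coarse grid search over
    10^0..10^5 to provide a stable starting value.  The 95% prediction
    band is the Wilson binomial interval of the predicted frequency at
    n = number of samples; each taxon is labelled above/within/below it.
    """
    counts = table.matrix
    n_samples = counts.shape[1]
    if n_samples < 10:
        warnings.warn(f"fit_ncm on only {n_samples} samples", stacklevel=2)
    libs = counts.sum(axis=0)
    if detection_limit is None:
        detection_limit = 1.0 / libs.mean()
    rel = to_relative(table).matrix
    p_mean = rel.mean(axis=1)
    freq = (counts > 0).mean(axis=1)
    keep = p_mean > 0
    p_fit, f_fit = p_mean[keep], freq[keep]
    if np.all((f_fit == 0) | (f_fit == 1)):
        raise FitError("degenerate fit: all occurrence frequencies are 0 or 1")

    def residuals(log_nm):
        return f_fit - _ncm_predict(p_fit, np.exp(log_nm[0]), detection_limit)

    grid = np.linspace(0, np.log(10) * 5, 26)
    sse_grid = [float(np.sum(residuals([g]) ** 2)) for g in grid]
    x0 = grid[int(np.argmin(sse_grid))]
    sol = optimize.least_squares(residuals, [x0], method="lm", max_nfev=200)
    if not sol.success:
        raise FitError(f"NCM fit divergence (last Nm = {np.exp(sol.x[0]):.4g})")
    Nm = float(np.exp(sol.x[0]))
    pred_all = _ncm_predict(np.where(keep, p_mean, 1e-12), Nm, detection_limit)
    sse = float(np.sum((f_fit - _ncm_predict(p_fit, Nm, detection_limit)) ** 2))
    sst = float(np.sum((f_fit - f_fit.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    lower, upper = _wilson_interval(pred_all, n_samples)
    band = np.where(freq > upper, "above", np.where(freq < lower, "below", "within"))
    per_asv = pd.DataFrame(
        {
            "mean_relabund": p_mean,
            "frequency": freq,
            "predicted": pred_all,
            "lower": lower,
            "upper": upper,
            "band": band,
        },
        index=table.asv_ids,
    )
    per_asv.loc[~keep, "band"] = "below"
    return NcmFit(
        Nm=Nm, detection_limit=float(detection_limit), R2=r2,
        per_asv=per_asv, n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# Levins niche breadth
# ---------------------------------------------------------------------------

def levins_niche(table: CountTable) -> pd.Series:
    """Levins niche breadth B_i = 1 / sum_j (n_ij / N_i)^2 per ASV.

    B is the effective number of samples a taxon occupies: 1 for a taxon
    confined to one sample, the sample count for a perfectly even one.
    Zero-total ASVs are omitted with a warning.
    """
    counts = table.matrix.astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"omitting {int(zero.sum())} zero-total ASVs from niche breadth", stacklevel=2
        )
    p = counts[~zero] / totals[~zero, None]
    b = 1.0 / np.sum(p ** 2, axis=1)
    return pd.Series(b, index=np.asarray(table.asv_ids)[~zero], name="levins_B")


def _random_fixed_margin_table(
    row_totals: np.ndarray, col_totals: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random count table with the given margins (independence null).

    Rows are filled sequentially by multivariate hypergeometric draws
    against the remaining column capacities — the classic ``r2dtable``
    scheme, yielding independent samples from the fixed-margin null.
    """
    remaining = np.asarray(col_totals, dtype=np.int64).copy()
    out = np.empty((len(row_totals), len(col_totals)), dtype=np.int64)
    for i, n in enumerate(row_totals):
        draw = rng.multivariate_hypergeometric(remaining, int(n))
        out[i] = draw
        remaining -= draw
    return out


def classify_niche(
    table: CountTable,
    n_null: int = 1000,
    seed: int = 0,
) -> NicheResult:
    """Classify taxa by niche breadth against a fixed-marginal count null.

    Null tables are independent random fills preserving both ASV and
    sample totals (sequential multivariate hypergeometric draws); a
    taxon is a generalist when its B exceeds the null 97.5th percentile,
    a specialist below the 2.5th, otherwise neutral.  Degenerate nulls
    (zero spread) default to neutral.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    counts = table.matrix.astype(np.int64)
    obs_b = levins_niche(table)
    row_totals = counts.sum(axis=1)
    col_totals = counts.sum(axis=0)
    null_b = np.empty((n_null, counts.shape[0]))
    totals = row_totals.astype(float)
    for m in range(n_null):
        work = _random_fixed_margin_table(row_totals, col_totals, rng)
        p = work / np.maximum(totals[:, None], 1.0)
        null_b[m] = 1.0 / np.maximum(np.sum(p ** 2, axis=1), 1e-300)
    lower = np.percentile(null_b, 2.5, axis=0)
    upper = np.percentile(null_b, 97.5, axis=0)
    spread = null_b.max(axis=0) - null_b.min(axis=0)
    per = pd.DataFrame(index=table.asv_ids)
    per["B"] = obs_b.reindex(per.index)
    per["null_lower"] = lower
    per["null_upper"] = upper
    cls = np.where(
        per["B"] > upper, "generalist", np.where(per["B"] < lower, "specialist", "neutral")
    )
    cls = np.where(spread <= 1e-12, "neutral", cls)
    per["class"] = np.where(per["B"].isna(), "neutral", cls)
    return NicheResult(per_asv=per, n_null=n_null)


# ---------------------------------------------------------------------------
# C-score and sequential-swap null
# ---------------------------------------------------------------------------

def c_score(presence: np.ndarray) -> float:
    """Mean checkerboard units (r_i - S_ij)(r_j - S_ij) over species pairs."""
    a = (np.asarray(presence) > 0).astype(np.int64)
    if a.shape[0] < 2:
        raise ValueError("c_score needs at least 2 species rows")
    r = a.sum(axis=1)
    s = a @ a.T
    cu = (r[:, None] - s) * (r[None, :] - s)
    iu = np.triu_indices(a.shape[0], 1)
    return float(cu[iu].mean())


def _sequential_swap(a: np.ndarray, rng: np.random.Generator, n_attempts: int) -> None:
    """In-place checkerboard swaps preserving row and column totals."""
    n_rows, n_cols = a.shape
    rows = rng.integers(0, n_rows, size=(n_attempts, 2))
    cols = rng.integers(0, n_cols, size=(n_attempts, 2))
    for s in range(n_attempts):
        i, j = rows[s]
        k, l = cols[s]
        if i == j or k == l:
            continue
        aik, ail, ajk, ajl = a[i, k], a[i, l], a[j, k], a[j, l]
        if aik == 1 and ajl == 1 and ail == 0 and ajk == 0:
            a[i, k] = a[j, l] = 0
            a[i, l] = a[j, k] = 1
        elif aik == 0 and ajl == 0 and ail == 1 and ajk == 1:
            a[i, k] = a[j, l] = 1
            a[i, l] = a[j, k] = 0


def _has_checkerboard(a: np.ndarray) -> bool:
    s = a @ a.T
    r = a.sum(axis=1)
    cu = (r[:, None] - s) * (r[None, :] - s)
    np.fill_diagonal(cu, 0)
    return bool((cu > 0).any())


def c_score_ses(
    presence: np.ndarray,
    n_null: int = 1000,
    burn_in: int = 5000,
    thin: int = 100,
    seed: int = 0,
) -> CscoreResult:
    """Standardized effect size of the C-score under a sequential-swap null.

    Null matrices are produced by an MCMC of random 2x2 checkerboard
    swaps (burn-in, then one saved matrix every ``thin`` attempts); both
    marginals are preserved exactly.  SES = (obs - mean_null)/sd_null;
    the two-sided empirical p uses the (1 + more extreme)/(1 + n_null)
    convention.
    """
    a = (np.asarray(presence) > 0).astype(np.int8)
    if not _has_checkerboard(a):
        raise ValueError("degenerate matrix: no swappable checkerboard submatrix")
    rng = np.random.default_rng(seed)
    obs = c_score(a)
    work = a.copy()
    _sequential_swap(work, rng, burn_in)
    null = np.empty(n_null)
    for m in range(n_null):
        _sequential_swap(work, rng, thin)
        null[m] = c_score(work)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null distribution (zero spread)")
    ses = (obs - mean) / sd
    p = (1 + np.sum(np.abs(null - mean) >= abs(obs - mean))) / (1 + n_null)
    return CscoreResult(
        observed=obs, null_mean=mean, null_sd=sd, ses=float(ses), p=float(p), n_null=n_null
    )
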