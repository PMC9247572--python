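"""ASV count tables: containers, TSV IO, prevalence/abundance filtering, TMM normalization.

The central object is :class:`CountTable`, an ASV-by-sample matrix of
non-negative integer counts together with per-sample metadata (treatment
state, subject id, covariates) and optional taxonomy strings.  Every
downstream stage of the pipeline consumes one of the three table types
defined here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: column in the metadata table holding the treatment state label
STATE_COL = "state"
#: recognised treatment states (before / after treatment)
STATES = ("BT", "AT")
#: name of the optional taxonomy column in a count-table TSV
TAXONOMY_COL = "taxonomy"


class TableError(ValueError):
    """Invalid count table, metadata, or id mismatch."""


@dataclass
class CountTable:
    """ASV x sample integer counts plus sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integers; rows are ASV ids, columns are sample ids.
    metadata : pandas.DataFrame
        Indexed by sample id; must cover every sample column.  The
        ``state`` column, when present, holds ``"BT"``/``"AT"`` labels.
    taxonomy : dict, optional
        ASV id -> rank-delimited lineage string.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise TableError(f"duplicate ASV ids: {sorted(c.index[c.index.duplicated()])}")
        if c.columns.has_duplicates:
            raise TableError(f"duplicate sample ids: {sorted(c.columns[c.columns.duplicated()])}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise TableError("counts must be numeric")
        if not np.all(np.isfinite(vals)):
            raise TableError("counts must be finite")
        if (vals < 0).any():
            raise TableError("counts must be non-negative")
        if np.any(vals != np.round(vals)):
            raise TableError("counts must be integers")
        missing = [s for s in c.columns if s not in self.metadata.index]
        if missing:
            raise TableError(f"samples missing from metadata: {missing}")

    # -- convenience accessors -------------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Counts as an int64 ndarray (ASV x sample)."""
        return self.counts.to_numpy(dtype=np.int64)

    def states(self) -> pd.Series:
        """Per-sample state labels aligned to the sample columns."""
        return self.metadata.loc[self.sample_ids, STATE_COL]

    def subset_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        return replace(
            self,
            counts=self.counts[sample_ids],
            metadata=self.metadata.loc[sample_ids],
        )

    def subset_state(self, state: str) -> "CountTable":
        keep = [s for s in self.sample_ids if self.metadata.at[s, STATE_COL] == state]
        return self.subset_samples(keep)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class RelAbundanceTable:
    """Column-wise proportions with the same id axes as the source counts."""

    proportions: pd.DataFrame
    metadata: pd.DataFrame
    zero_samples: list[str] = field(default_factory=list)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.proportions.to_numpy(dtype=float)

    def states(self) -> pd.Series:
        return self.metadata.loc[self.sample_ids, STATE_COL]


@dataclass
class NormalizedTable:
    """Counts rescaled by per-sample effective library sizes (TMM).

    ``values[i, j] = counts[i, j] / (library_size[j] * norm_factor[j])``
    scaled by the mean effective size, so values stay on a count-like scale.
    """

    values: pd.DataFrame
    norm_factors: pd.Series
    metadata: pd.DataFrame

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.values.index)

    def states(self) -> pd.Series:
        return self.metadata.loc[self.sample_ids, STATE_COL]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_count_table(path, metadata_path) -> CountTable:
    """Read an ASV-by-sample TSV plus a sample metadata TSV.

    The count TSV has ASV ids in the first column and sample ids in the
    header; an optional trailing ``taxonomy`` column holds lineage strings.
    The metadata TSV is indexed by its first column (sample id).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    if TAXONOMY_COL in df.columns:
        taxonomy = df[TAXONOMY_COL].astype(str).to_dict()
        df = df.drop(columns=[TAXONOMY_COL])
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise TableError(f"non-numeric counts in {path}: {exc}") from exc
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    meta.index.name = None
    return CountTable(counts=df, metadata=meta, taxonomy=taxonomy)


def write_count_table(table: CountTable, path, metadata_path=None) -> None:
    """Write a count table (and optionally its metadata) as TSV.

    Column order is the table's sample order, so writes are deterministic.
    """
    df = table.counts.copy()
    if table.taxonomy is not None:
        df[TAXONOMY_COL] = [table.taxonomy.get(a, "") for a in df.index]
    df.to_csv(path, sep="\t", index_label="asv_id")
    if metadata_path is not None:
        table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Filtering and relative abundance
# ---------------------------------------------------------------------------

def filter_asvs(
    table: CountTable,
    min_prevalence: float = 0.20,
    min_mean_relabund: float = 0.025,
) -> CountTable:
    """Drop rare, low-abundance ASVs before network/model stages.

    An ASV is retained when it is detected (count > 0) in at least
    ``min_prevalence`` of samples, or when its mean relative abundance
    across samples exceeds ``min_mean_relabund``.  Detection is a plain
    nonzero count: ASV tables are already denoised, so no pseudo-detection
    threshold is applied.
    """
    if not (0 <= min_prevalence <= 1 and 0 <= min_mean_relabund <= 1):
        raise ValueError("filter thresholds must lie in [0, 1]")
    counts = table.matrix
    n_samples = counts.shape[1]
    prevalence = (counts > 0).mean(axis=1)
    totals = counts.sum(axis=0, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, counts / totals, 0.0)
    mean_relabund = props.mean(axis=1)
    keep = (prevalence >= min_prevalence) | (mean_relabund > min_mean_relabund)
    if min_prevalence == 0 and min_mean_relabund == 0:
        keep = np.ones(counts.shape[0], dtype=bool)
    removed = int((~keep).sum())
    log.info(
        "filter_asvs: kept %d of %d ASVs (prevalence >= %.2f or mean rel. abundance > %.3f) "
        "across %d samples; removed %d",
        int(keep.sum()), counts.shape[0], min_prevalence, min_mean_relabund, n_samples, removed,
    )
    if not keep.any():
        warnings.warn("filter_asvs removed every ASV", stacklevel=2)
    return replace(table, counts=table.counts.loc[keep])


def to_relative(table: CountTable) -> RelAbundanceTable:
    """Column-wise proportions; all-zero samples stay all-zero and are flagged."""
    counts = table.matrix.astype(float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"all-zero samples: {[s for s, z in zip(table.sample_ids, zero) if z]}",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    props = counts / safe
    return RelAbundanceTable(
        proportions=pd.DataFrame(props, index=table.counts.index, columns=table.counts.columns),
        metadata=table.metadata,
        zero_samples=[s for s, z in zip(table.sample_ids, zero) if z],
    )


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_factor_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a):
    """Two-sample trimmed weighted mean of M-values (log2 scale factor)."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 0.0
    o = obs[both].astype(float)
    r = ref[both].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M per gene
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    n = m.size
    if n == 0:
        return 0.0
    # doubly trimmed: drop trim_m of each M tail and trim_a of each A tail
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    inv_w = 1.0 / w[keep]
    return float(np.sum(inv_w * m[keep]) / np.sum(inv_w))


def tmm_normalize(table: CountTable, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizedTable:
    """Trimmed-mean-of-M-values normalization of a count table.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean across samples (ties broken by the
    lexicographically first sample id).  Per-sample factors are
    inverse-variance weighted means of M-values after trimming ``trim_m``
    of each M tail and ``trim_a`` of each A tail, then rescaled so their
    geometric mean is 1.
    """
    counts = table.matrix.astype(float)
    lib = counts.sum(axis=0)
    nonzero = lib > 0
    if nonzero.sum() < 2:
        raise TableError("TMM needs at least 2 samples with nonzero totals")
    # reference selection on upper-quartile count fraction
    with np.errstate(invalid="ignore", divide="ignore"):
        uq = np.array([
            np.quantile(counts[:, j] / lib[j], 0.75) if lib[j] > 0 else np.nan
            for j in range(counts.shape[1])
        ])
    mean_uq = np.nanmean(uq)
    dist = np.abs(uq - mean_uq)
    order = sorted(
        (j for j in range(counts.shape[1]) if np.isfinite(dist[j])),
        key=lambda j: (dist[j], table.sample_ids[j]),
    )
    ref_idx = order[0]
    ref = counts[:, ref_idx]
    log2f = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx or lib[j] == 0:
            continue
        shares = (counts[:, j] > 0) & (ref > 0)
        if not shares.any():
            warnings.warn(
                f"sample {table.sample_ids[j]} shares no nonzero ASV with reference; factor 1",
                stacklevel=2,
            )
            continue
        log2f[j] = _tmm_factor_pair(counts[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
    factors = 2.0 ** log2f
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    eff = lib * factors
    mean_eff = eff[nonzero].mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(eff > 0, counts / eff, 0.0) * mean_eff
    return NormalizedTable(
        values=pd.DataFrame(values, index=table.counts.index, columns=table.counts.columns),
        norm_factors=pd.Series(factors, index=table.counts.columns, name="tmm_factor"),
        metadata=table.metadata,
    )
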