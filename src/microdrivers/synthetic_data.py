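"""Synthetic paired-cohort microbiome data with known planted structure.

Two generators are provided.  ``simulate_neutral_community`` draws every
sample from a Sloan-style neutral assembly process (Dirichlet local
communities around a fixed source community, with migration parameter
N*m), so the neutral-model fit can be tested as parameter recovery.
``simulate_paired_cohort`` emulates the study design this pipeline is
built for: ~25 subjects sampled before (BT) and after (AT) treatment at
~29,000 reads per sample, with log-normal baseline abundances and, on
top, planted differential taxa, planted correlation modules that exist
only in one state (Gaussian-copula latent factors), planted indicator
taxa, and covariate effects on a focal taxon.  The returned truth object
is sufficient to score every downstream recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .asv_tables import STATE_COL, CountTable


class ConfigurationError(ValueError):
    """Invalid or conflicting simulation configuration."""


@dataclass(frozen=True)
class PlantedModule:
    """A set of ASVs sharing a latent factor in one state (or both)."""

    asv_indices: tuple[int, ...]
    latent_correlation: float
    state: str = "AT"  # "BT", "AT" or "both"

    def __post_init__(self):
        if not -1.0 <= self.latent_correlation <= 1.0:
            raise ConfigurationError("latent_correlation must lie in [-1, 1]")
        if self.state not in ("BT", "AT", "both"):
            raise ConfigurationError(f"bad module state {self.state!r}")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the emulated study: 25 paired subjects, ~29,319
    reads per sample, and a community of thousands of ASVs.  The
    negative-binomial ``library_size_dispersion`` is the NB shape
    parameter (variance = mu + mu^2/shape); real per-subject depth
    variance is unreported, so it is a free parameter.
    """

    n_subjects: int = 25
    n_asvs: int = 2000
    library_size_mean: int = 29319
    library_size_dispersion: float = 10.0
    source_community: np.ndarray | None = None
    migration_Nm: float = 500.0
    planted_modules: Sequence[PlantedModule] = field(default_factory=tuple)
    planted_differential: Sequence[tuple[int, float]] = field(default_factory=tuple)
    planted_indicators: Sequence[tuple[int, str]] = field(default_factory=tuple)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    focal_asv: int = 0
    log_abundance_sigma: float = 2.0
    sample_noise_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self):
        # accept plain mappings/lists (e.g. from a YAML config)
        self.planted_modules = tuple(
            m if isinstance(m, PlantedModule)
            else PlantedModule(tuple(m["asv_indices"]), m["latent_correlation"],
                               m.get("state", "AT"))
            for m in self.planted_modules
        )
        self.planted_differential = tuple(
            (int(i), float(f)) for i, f in self.planted_differential
        )
        self.planted_indicators = tuple(
            (int(i), str(s)) for i, s in self.planted_indicators
        )

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_asvs < 1:
            raise ConfigurationError("n_subjects and n_asvs must be positive")
        if self.library_size_mean < 1 or self.library_size_dispersion <= 0:
            raise ConfigurationError("library size parameters must be positive")
        if not np.isfinite(self.migration_Nm) or self.migration_Nm <= 0:
            raise ConfigurationError("migration_Nm must be a finite positive real")
        if self.source_community is not None:
            p = np.asarray(self.source_community, dtype=float)
            if p.shape != (self.n_asvs,):
                raise ConfigurationError("source_community length must equal n_asvs")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError("source_community must be a probability vector")
        planted: set[int] = set()
        for mod in self.planted_modules:
            for i in mod.asv_indices:
                self._check_index(i)
        for i, _ in self.planted_differential:
            self._check_index(i)
            self._check_conflict(planted, i)
        for i, state in self.planted_indicators:
            self._check_index(i)
            self._check_conflict(planted, i)
            if state not in ("BT", "AT"):
                raise ConfigurationError(f"bad indicator state {state!r}")

    def _check_index(self, i: int) -> None:
        if not 0 <= i < self.n_asvs:
            raise ConfigurationError(f"planted ASV index {i} out of range")

    def _check_conflict(self, planted: set[int], i: int) -> None:
        if i in planted:
            raise ConfigurationError(f"conflicting plants on ASV index {i}")
        planted.add(i)


# Covariate scheme: age per the cohort inclusion window, anthropometrics
# roughly adult-male, education ordinal 0-4, six habit variables
# (smoking/drinking/exercise Bernoulli; dietary flavors, fruit & vegetable
# intake, sleep quality ordinal 0-2).
COVARIATE_NAMES = (
    "age", "height", "weight", "education",
    "smoking", "drinking", "flavors", "fruit_veg", "exercise", "sleep",
)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.integers(18, 71, size=n),
            "height": np.round(rng.normal(170, 8, size=n), 1),
            "weight": np.round(rng.normal(65, 12, size=n), 1),
            "education": rng.integers(0, 5, size=n),
            "smoking": rng.integers(0, 2, size=n),
            "drinking": rng.integers(0, 2, size=n),
            "flavors": rng.integers(0, 3, size=n),
            "fruit_veg": rng.integers(0, 3, size=n),
            "exercise": rng.integers(0, 2, size=n),
            "sleep": rng.integers(0, 3, size=n),
        },
        index=[f"S{i + 1}" for i in range(n)],
    )


@dataclass
class SyntheticDataset:
    """Generated counts for both states plus metadata and planted truth."""

    counts_bt: pd.DataFrame  # ASV x subject-sample
    counts_at: pd.DataFrame
    metadata: pd.DataFrame  # indexed by sample id
    truth: dict

    def to_count_table(self) -> CountTable:
        counts = pd.concat([self.counts_bt, self.counts_at], axis=1)
        return CountTable(counts=counts, metadata=self.metadata)

    def state_table(self, state: str) -> CountTable:
        counts = self.counts_bt if state == "BT" else self.counts_at
        return CountTable(counts=counts, metadata=self.metadata.loc[counts.columns])


def _library_sizes(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    shape = cfg.library_size_dispersion
    p = shape / (shape + cfg.library_size_mean)
    sizes = rng.negative_binomial(shape, p, size=n)
    return np.maximum(sizes, 1)


def _assemble(asv_ids, sample_ids, counts, metadata, truth) -> SyntheticDataset:
    states = metadata[STATE_COL]
    bt_cols = [s for s in sample_ids if states[s] == "BT"]
    at_cols = [s for s in sample_ids if states[s] == "AT"]
    df = pd.DataFrame(counts, index=asv_ids, columns=sample_ids)
    return SyntheticDataset(
        counts_bt=df[bt_cols], counts_at=df[at_cols], metadata=metadata, truth=truth,
    )


def _paired_metadata(rng: np.random.Generator, cfg: SimulationConfig) -> pd.DataFrame:
    cov = _draw_covariates(rng, cfg.n_subjects)
    rows = []
    for k, subj in enumerate(cov.index):
        for state in ("BT", "AT"):
            rows.append({"sample_id": f"{subj}_{state}", "subject": subj, STATE_COL: state,
                         **cov.iloc[k].to_dict()})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_neutral_community(config: SimulationConfig) -> SyntheticDataset:
    """Draw a cohort assembled purely by neutral processes.

    Each sample's relative abundances come from a Dirichlet distribution
    with concentration ``Nm * source_community`` (the stationary local
    community of the Sloan model), and counts from a multinomial at the
    sample's drawn library size.  Column sums equal the drawn library
    sizes exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = 2 * config.n_subjects
    if config.source_community is None:
        raw = rng.lognormal(0.0, config.log_abundance_sigma, size=config.n_asvs)
        source = raw / raw.sum()
    else:
        source = np.asarray(config.source_community, dtype=float)
    metadata = _paired_metadata(rng, config)
    sample_ids = list(metadata.index)
    libs = _library_sizes(rng, config, n_samples)
    alpha = config.migration_Nm * source
    # gamma representation tolerates very small concentration entries
    gam = rng.standard_gamma(np.broadcast_to(alpha, (n_samples, config.n_asvs)))
    rel = gam / np.maximum(gam.sum(axis=1, keepdims=True), 1e-300)
    counts = np.empty((config.n_asvs, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(libs[j], rel[j])
    asv_ids = [f"ASV{i + 1}" for i in range(config.n_asvs)]
    truth = {
        "model": "neutral",
        "Nm": config.migration_Nm,
        "source_community": source,
        "library_sizes": pd.Series(libs, index=sample_ids),
    }
    return _assemble(asv_ids, sample_ids, counts, metadata, truth)


def simulate_paired_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Generate a paired BT/AT cohort with planted structure.

    The latent log-abundance of ASV i in sample (subject s, state t) is

    ``log a_i + u_{s,i} + beta-effects`` where ``u`` is standard normal
    noise scaled by ``sample_noise_sigma``.  Planted modules replace the
    independent noise of their member ASVs by a shared subject-level
    factor (correlation ``r`` on the latent Gaussian scale, i.e. a
    Gaussian copula, so count marginals are preserved); they act only in
    their designated state.  Planted differential ASVs get ``log2fc *
    log 2`` added in AT; planted indicators are zeroed outside their
    state; covariate effects enter the focal ASV's log-mean linearly in
    the z-scored covariate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub, n_asv = config.n_subjects, config.n_asvs
    metadata = _paired_metadata(rng, config)
    sample_ids = list(metadata.index)
    n_samples = len(sample_ids)
    libs = _library_sizes(rng, config, n_samples)

    base_log = rng.normal(0.0, config.log_abundance_sigma, size=n_asv)
    # plants emulate effects on major (filter-surviving) taxa: lift planted
    # ASVs to at least the community's median baseline abundance
    planted_idx = sorted(
        {i for mod in config.planted_modules for i in mod.asv_indices}
        | {i for i, _ in config.planted_differential}
        | {i for i, _ in config.planted_indicators}
        | ({config.focal_asv} if config.covariate_effects else set())
    )
    if planted_idx:
        base_log[planted_idx] = np.maximum(base_log[planted_idx], np.median(base_log))
    # latent noise: (state, subject, asv)
    eps = rng.normal(0.0, 1.0, size=(2, n_sub, n_asv))
    for mod in config.planted_modules:
        idx = np.asarray(mod.asv_indices)
        r = mod.latent_correlation
        states = (0, 1) if mod.state == "both" else ((0,) if mod.state == "BT" else (1,))
        for t in states:
            factor = rng.normal(0.0, 1.0, size=n_sub)
            sign = np.where(np.arange(idx.size) == 0, 1.0, np.sign(r) if r < 0 else 1.0)
            load = np.sqrt(abs(r))
            eps[t][:, idx] = (
                load * np.outer(factor, sign)
                + np.sqrt(1.0 - abs(r)) * rng.normal(0.0, 1.0, size=(n_sub, idx.size))
            )

    log_mean = np.broadcast_to(base_log, (2, n_sub, n_asv)).copy()
    for i, lfc in config.planted_differential:
        log_mean[1, :, i] += lfc * np.log(2.0)
    if config.covariate_effects:
        cov = metadata.loc[[f"S{k + 1}_BT" for k in range(n_sub)], list(config.covariate_effects)]
        z = (cov - cov.mean()) / cov.std(ddof=0).replace(0, 1.0)
        effect = sum(
            beta * z[name].to_numpy() for name, beta in config.covariate_effects.items()
        )
        log_mean[0, :, config.focal_asv] += effect
        log_mean[1, :, config.focal_asv] += effect

    weights = np.exp(log_mean + config.sample_noise_sigma * eps)
    for i, state in config.planted_indicators:
        absent = 0 if state == "AT" else 1
        present = 1 - absent
        weights[absent, :, i] = 0.0
        # ensure the indicator is comfortably detectable in its own state
        weights[present, :, i] = np.maximum(
            weights[present, :, i], np.median(weights[present], axis=1)
        )

    counts = np.empty((n_asv, n_samples), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        t = 0 if metadata.at[sid, STATE_COL] == "BT" else 1
        s = int(sid.split("_")[0][1:]) - 1
        w = weights[t, s]
        rel = w / w.sum()
        counts[:, j] = rng.multinomial(libs[j], rel)
    asv_ids = [f"ASV{i + 1}" for i in range(n_asv)]
    truth = {
        "model": "paired_cohort",
        "planted_modules": tuple(config.planted_modules),
        "planted_differential": tuple(config.planted_differential),
        "planted_indicators": tuple(config.planted_indicators),
        "covariate_effects": dict(config.covariate_effects),
        "focal_asv": config.focal_asv,
        "library_sizes": pd.Series(libs, index=sample_ids),
        "asv_ids": asv_ids,
    }
    return _assemble(asv_ids, sample_ids, counts, metadata, truth)
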