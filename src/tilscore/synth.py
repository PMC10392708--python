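"""Synthetic two-panel cohort generator with known planted structure.

Emulates the data shape of a targeted immune gene-expression study of a
prostate-cancer cohort: two overlapping probe panels (each with
endogenous and housekeeping probes), immune cell types driven by latent
per-sample log2 abundances that their marker genes report on, per-sample
library size factors, overdispersed count noise, clinicopathologic
covariates, and two censored time-to-event endpoints (biochemical
recurrence and metastasis) whose hazards depend on chosen latent cell
scores.

Every draw is reproducible from the master seed; each operation uses its
own independent substream, so adding an operation never perturbs the
others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .matrix import ENDOGENOUS, HOUSEKEEPING, ExpressionMatrix

#: the five constituents whose raw scores average into the TIL composite
TIL_COMPONENTS = ("B_cells", "T_cells", "CD45", "macrophages", "cytotoxic_cells")

DEFAULT_CELL_TYPES = TIL_COMPONENTS + (
    "DC", "mast_cells", "NK", "CD8", "exhausted_CD8", "Treg", "Th1", "neutrophils",
)

ENDPOINTS = ("bcr", "metastasis")

# substream indices; fixed so streams never shift between operations
_STREAM_MARKER_MAP = 0
_STREAM_COUNTS = 1
_STREAM_CLINICAL = 2


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class SynthConfig:
    """Study-shaped generator configuration.

    Defaults mirror the emulated study: 51 samples, a 770+10-probe panel
    and a 730+40-probe panel, thirteen immune cell types, and one
    planted survival effect (log-hazard -1 of the mast-vs-TIL score on
    the metastasis endpoint).
    """

    n_samples: int = 51
    n_endog_a: int = 770
    n_endog_b: int = 730
    n_hk_a: int = 10
    n_hk_b: int = 40
    n_common: int = 300
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    markers_per_type: int = 5
    dispersion: float = 0.05
    size_factor_sd: float = 0.25
    effect_map: tuple[tuple[str, float, str], ...] = (
        ("mast_cells:TIL", -1.0, "metastasis"),
    )
    censor_rate: float = 0.3
    baseline_hazard: float = 0.01
    seed: int = 0
    # secondary knobs of the generative model
    abundance_sd: float = 1.0
    baseline_count: float = 200.0
    hk_mean: float = 1000.0
    panel_b_efficiency: float = 1.5
    race_prob_aa: float = 26 / 51
    n_qc_fail: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")
        if min(self.n_endog_a, self.n_endog_b, self.n_hk_a, self.n_hk_b) < 1:
            raise ConfigurationError("gene counts must be positive")
        if not 0 <= self.n_common <= min(self.n_endog_a, self.n_endog_b):
            raise ConfigurationError("n_common must be <= min(n_endog_a, n_endog_b)")
        if self.markers_per_type < 2:
            raise ConfigurationError("markers_per_type must be >= 2")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ConfigurationError("cell-type names must be unique")
        missing = set(TIL_COMPONENTS) - set(self.cell_types)
        if missing:
            raise ConfigurationError(f"cell_types must include TIL constituents: {sorted(missing)}")
        for val, name in [(self.dispersion, "dispersion"),
                          (self.size_factor_sd, "size_factor_sd"),
                          (self.abundance_sd, "abundance_sd")]:
            if val < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        for _, _, endpoint in self.effect_map:
            if endpoint not in ENDPOINTS:
                raise ConfigurationError(f"unknown endpoint {endpoint!r}")
        if not 0 <= self.n_qc_fail < self.n_samples:
            raise ConfigurationError("n_qc_fail must be < n_samples")

    # -- derived name sets -------------------------------------------
    @property
    def common_genes(self) -> list[str]:
        return [f"COM{i:04d}" for i in range(self.n_common)]

    @property
    def unique_genes_a(self) -> list[str]:
        return [f"GA{i:04d}" for i in range(self.n_endog_a - self.n_common)]

    @property
    def unique_genes_b(self) -> list[str]:
        return [f"GB{i:04d}" for i in range(self.n_endog_b - self.n_common)]

    @property
    def endogenous_union(self) -> list[str]:
        return self.common_genes + self.unique_genes_a + self.unique_genes_b

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))))


@dataclass
class MarkerMap:
    """Cell type -> ordered marker gene lists; validates TIL coverage."""

    entries: dict[str, list[str]]
    til_components: tuple[str, ...] = TIL_COMPONENTS

    def __post_init__(self) -> None:
        for cell_type, genes in self.entries.items():
            if not genes:
                raise ValueError(f"cell type {cell_type!r} has an empty marker list")
        missing = set(self.til_components) - set(self.entries)
        if missing:
            raise ValueError(f"marker map missing TIL constituents: {sorted(missing)}")

    def __getitem__(self, cell_type: str) -> list[str]:
        return self.entries[cell_type]

    @property
    def cell_types(self) -> list[str]:
        return list(self.entries)


@dataclass
class LatentTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    abundance: pd.DataFrame            # cell type x sample, log2 scale
    size_factors: pd.Series            # per-sample positive scalars
    true_cutpoints: dict[tuple[str, str], float]
    true_coefficients: tuple[tuple[str, float, str], ...]
    gene_means: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    def score(self, name: str) -> pd.Series:
        """Resolve a planted score name against the latent abundances.

        ``"mast_cells:TIL"`` is the mast latent log2 abundance minus the
        mean of the five TIL-constituent abundances; ``"CD8:exhausted_CD8"``
        a between-type difference; a bare cell-type name its raw abundance.
        """
        def one(part: str) -> pd.Series:
            if part == "TIL":
                return self.abundance.loc[list(TIL_COMPONENTS)].mean(axis=0)
            if part not in self.abundance.index:
                raise KeyError(f"unknown cell type in score name: {part!r}")
            return self.abundance.loc[part]

        if ":" in name:
            num, den = name.split(":", 1)
            return one(num) - one(den)
        return one(name)


def generate_marker_map(config: SynthConfig) -> MarkerMap:
    """Assign disjoint marker-gene blocks to each configured cell type.

    Markers are drawn without replacement from the union of endogenous
    genes of both panels; every remaining endogenous gene is unassigned
    background.
    """
    pool = config.endogenous_union
    need = config.markers_per_type * len(config.cell_types)
    if need > len(pool):
        raise ConfigurationError(
            f"need {need} marker genes but only {len(pool)} endogenous genes exist")
    rng = config._rng(_STREAM_MARKER_MAP)
    shuffled = [pool[i] for i in rng.permutation(len(pool))]
    entries = {}
    for i, cell_type in enumerate(config.cell_types):
        lo = i * config.markers_per_type
        entries[cell_type] = sorted(shuffled[lo:lo + config.markers_per_type])
    return MarkerMap(entries=entries)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Overdispersed counts with var = mu + dispersion * mu^2.

    dispersion > 0 samples a gamma-Poisson mixture (negative binomial);
    the Poisson is recovered continuously as dispersion -> 0, and
    dispersion == 0 exactly is the deterministic rounded-mean limit.
    """
    if dispersion == 0:
        return np.rint(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    return rng.poisson(lam).astype(float)


def generate_counts(config: SynthConfig, marker_map: MarkerMap
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix, LatentTruth]:
    """Simulate raw counts for both panels from one latent truth.

    Marker-gene means scale with ``2**abundance`` of their cell type;
    housekeeping means are independent of abundance; every count is
    drawn around ``mean = baseline * 2**abundance * size_factor`` with
    the configured overdispersion. Common probes appear in both panels
    with independent noise; panel B means carry a global efficiency
    factor, which the merge step later corrects.
    """
    rng = config._rng(_STREAM_COUNTS)
    samples = config.sample_names
    n = config.n_samples

    abundance = pd.DataFrame(
        rng.normal(0.0, config.abundance_sd, size=(len(config.cell_types), n)),
        index=list(config.cell_types), columns=samples)
    size_factors = pd.Series(
        np.exp2(rng.normal(0.0, config.size_factor_sd, size=n)),
        index=samples, name="size_factor")

    gene_of_type: dict[str, str] = {}
    for cell_type, genes in marker_map.entries.items():
        for g in genes:
            gene_of_type[g] = cell_type

    # per-gene baselines: markers sit at baseline_count; background genes
    # get a lognormal spread of baselines; housekeepers are high expressors
    def panel_means(endog: list[str], hk: list[str], efficiency: float) -> pd.DataFrame:
        rows = []
        for g in endog:
            if g in gene_of_type:
                mu_g = config.baseline_count * np.exp2(
                    abundance.loc[gene_of_type[g]].to_numpy())
            else:
                base = config.baseline_count * np.exp2(rng.normal(0.0, 1.0))
                mu_g = np.full(n, base)
            rows.append(mu_g)
        for g in hk:
            base = config.hk_mean * np.exp2(rng.normal(0.0, 0.5))
            rows.append(np.full(n, base))
        mu = np.asarray(rows) * size_factors.to_numpy()[None, :] * efficiency
        return pd.DataFrame(mu, index=endog + hk, columns=samples)

    genes_a = config.common_genes + config.unique_genes_a
    genes_b = config.common_genes + config.unique_genes_b
    hk_a = [f"HKA{i:02d}" for i in range(config.n_hk_a)]
    hk_b = [f"HKB{i:02d}" for i in range(config.n_hk_b)]

    mu_a = panel_means(genes_a, hk_a, 1.0)
    mu_b = panel_means(genes_b, hk_b, config.panel_b_efficiency)

    counts_a = _draw_counts(rng, mu_a.to_numpy(), config.dispersion)
    counts_b = _draw_counts(rng, mu_b.to_numpy(), config.dispersion)

    if config.n_qc_fail:
        # planted QC failures: near-empty libraries
        fail_idx = rng.choice(n, size=config.n_qc_fail, replace=False)
        counts_a[:, fail_idx] = np.rint(counts_a[:, fail_idx] * 0.001)
        counts_b[:, fail_idx] = np.rint(counts_b[:, fail_idx] * 0.001)

    def build(counts, genes, hk, panel_id):
        probe_class = pd.Series(
            [ENDOGENOUS] * len(genes) + [HOUSEKEEPING] * len(hk),
            index=genes + hk)
        return ExpressionMatrix(
            values=pd.DataFrame(counts, index=genes + hk, columns=samples),
            probe_class=probe_class, panel_id=panel_id, scale="raw_counts")

    truth = LatentTruth(
        abundance=abundance, size_factors=size_factors,
        true_cutpoints={}, true_coefficients=tuple(config.effect_map),
        gene_means={"A": mu_a, "B": mu_b})
    for score_name, _, endpoint in config.effect_map:
        truth.true_cutpoints[(score_name, endpoint)] = float(
            truth.score(score_name).median())
    return build(counts_a, genes_a, hk_a, "A"), build(counts_b, genes_b, hk_b, "B"), truth


# pooled frequencies of the emulated cohort's clinicopathologic categories
_COVARIATE_LEVELS = {
    "age_group": (("40s", "50s", "60s", "70s"), (6, 17, 23, 5)),
    "psa_group": (("1", "2", "3"), (8, 26, 17)),
    "gleason": (("6", "7", "8", "9-10"), (14, 19, 5, 13)),
    "grade_group": (("low", "high"), (33, 18)),
}


def _calibrated_censor_rate(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate c with mean_i c/(c + lambda_i) = censor_rate."""
    def frac(c):
        return float(np.mean(c / (c + hazards))) - censor_rate
    lo, hi = 1e-12 * hazards.min(), 1e12 * hazards.max()
    return brentq(frac, lo, hi)


def generate_clinical(truth: LatentTruth, config: SynthConfig) -> pd.DataFrame:
    """Sample covariates and censored event times for both endpoints.

    Event times are exponential with per-sample log-hazard
    ``log(baseline_hazard) + sum(coefficient * score)`` over the effects
    planted for that endpoint; censoring is independent exponential,
    calibrated so the expected censored fraction equals ``censor_rate``.
    """
    rng = config._rng(_STREAM_CLINICAL)
    samples = list(truth.abundance.columns)
    n = len(samples)
    clinical = pd.DataFrame({"sample": samples})
    clinical["race"] = np.where(
        rng.random(n) < config.race_prob_aa, "AA", "CA")
    for col, (levels, weights) in _COVARIATE_LEVELS.items():
        p = np.asarray(weights, dtype=float)
        clinical[col] = rng.choice(levels, size=n, p=p / p.sum())

    for endpoint in ENDPOINTS:
        lp = np.zeros(n)
        for score_name, coef, ep in config.effect_map:
            if ep == endpoint:
                lp += coef * truth.score(score_name).to_numpy()
        hazards = config.baseline_hazard * np.exp(lp)
        times = rng.exponential(1.0 / hazards)
        if config.censor_rate > 0:
            c = _calibrated_censor_rate(hazards, config.censor_rate)
            censor = rng.exponential(1.0 / c, size=n)
        else:
            censor = np.full(n, np.inf)
        observed = np.minimum(times, censor)
        clinical[f"time_{endpoint}"] = np.maximum(observed, 1e-9)
        clinical[f"event_{endpoint}"] = (times <= censor).astype(int)
    return clinical


@dataclass
class SynthCohort:
    """Bundle of one simulated cohort's artifacts."""

    config: SynthConfig
    marker_map: MarkerMap
    panel_a: ExpressionMatrix
    panel_b: ExpressionMatrix
    truth: LatentTruth
    clinical: pd.DataFrame


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Run marker map -> counts -> clinical generation from one config."""
    marker_map = generate_marker_map(config)
    panel_a, panel_b, truth = generate_counts(config, marker_map)
    clinical = generate_clinical(truth, config)
    return SynthCohort(config=config, marker_map=marker_map, panel_a=panel_a,
                       panel_b=panel_b, truth=truth, clinical=clinical)
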