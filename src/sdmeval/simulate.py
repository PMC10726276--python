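"""Synthetic hierarchical presence-absence communities.

Generates data with the structure of a multi-species fungal occupancy survey:
16 forest sites, 5 plots per site, and a variable number of deadwood sampling
units per plot (defaults give roughly 5100 units in total). Each site is
managed or natural; each unit carries a deadwood volume (log-normal, entering
models as log-volume) and a decay stage (integer 1-5, entering as a
standardized score plus its square).

Species occurrence follows a probit model,

    P(y_ij = 1) = Phi(L_ij),   L_ij = x_i' beta_j  +  sum_k eta_ik lambda_kj,

with species-specific fixed-effect responses beta_j drawn from a community
distribution and latent-variable random effects at three levels: latent
factors eta are drawn per site, per plot and per unit, and each species loads
on them through its own loadings lambda. The unit-level factors create
residual species associations; in a single-species fit they are confounded
with the residual and are therefore present only here, in the generator.

The intercept distribution is wide so that the species pool spans prevalences
from well under 1% to above 20%; after filtering to species with at least 10
occurrences (the default), a community of several dozen species remains, with
both rare and common members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .hierarchy import HierarchicalDesign

__all__ = [
    "SyntheticConfig",
    "TrueParameters",
    "CommunityData",
    "generate_design",
    "generate_parameters",
    "compute_true_probabilities",
    "generate_occurrences",
    "filter_rare_species",
    "simulate_community",
]

FIXED_TERMS = ("intercept", "management", "log_volume", "decay", "decay2")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the community generator.

    Defaults emulate the survey design this package targets: 16 sites x 5
    plots x ~64 units/plot (~5100 units), a 150-species pool with intercepts
    spread widely on the probit scale, moderate fixed-effect heterogeneity,
    and latent factors whose per-level loading scales put a substantial share
    of linear-predictor variance into the random effects.
    """

    n_sites: int = 16
    plots_per_site: int = 5
    units_per_plot_mean: float = 64.0
    units_per_plot_shape: float = 8.0  # negative-binomial size; larger = more even
    n_species_pool: int = 150
    intercept_mean: float = -3.2
    intercept_sd: float = 1.3
    # community means/sds of (management, log_volume, decay, decay^2) responses
    beta_means: tuple[float, ...] = (0.0, 0.5, 0.3, -0.3)
    beta_sds: tuple[float, ...] = (0.5, 0.4, 0.4, 0.3)
    n_factors: tuple[int, int, int] = (2, 2, 2)  # site, plot, unit
    loading_scale: tuple[float, float, float] = (0.6, 0.5, 0.4)
    management_fraction: float = 0.5
    log_volume_mean: float = 6.0
    log_volume_sd: float = 1.5
    decay_probs: tuple[float, ...] = (0.15, 0.20, 0.25, 0.25, 0.15)
    min_occurrences: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.plots_per_site, self.n_species_pool) <= 0:
            raise ValueError("site, plot and species counts must be positive")
        if self.units_per_plot_mean < 1:
            raise ValueError("units_per_plot_mean must be at least 1")
        if abs(sum(self.decay_probs) - 1.0) > 1e-9 or min(self.decay_probs) < 0:
            raise ValueError("decay_probs must be a probability vector")
        if not 0.0 <= self.management_fraction <= 1.0:
            raise ValueError("management_fraction must lie in [0, 1]")


@dataclass
class TrueParameters:
    """Generating parameters of a synthetic community (for oracle checks)."""

    beta: np.ndarray               # (5, S): intercept, management, log_volume, decay, decay2
    site_factors: np.ndarray       # (n_sites, K_site)
    plot_factors: np.ndarray       # (n_plots, K_plot)
    unit_factors: np.ndarray       # (n_units, K_unit)
    site_loadings: np.ndarray      # (K_site, S)
    plot_loadings: np.ndarray      # (K_plot, S)
    unit_loadings: np.ndarray      # (K_unit, S)

    def level_variances(self) -> dict[str, np.ndarray]:
        """Per-species random-effect variance contributed by each level (sum of squared loadings)."""
        return {
            "site": (self.site_loadings**2).sum(axis=0),
            "plot": (self.plot_loadings**2).sum(axis=0),
            "unit": (self.unit_loadings**2).sum(axis=0),
        }


@dataclass
class CommunityData:
    """Occurrence matrix, covariates and design — real or synthetic.

    ``occurrences`` is a units x species 0/1 DataFrame (columns are species
    names) aligned row-wise with ``covariates`` and ``design.unit_ids``.
    ``true_probabilities`` and ``true_parameters`` are present only for
    synthetic data.
    """

    design: HierarchicalDesign
    covariates: pd.DataFrame
    occurrences: pd.DataFrame
    true_probabilities: pd.DataFrame | None = None
    true_parameters: TrueParameters | None = None
    config: SyntheticConfig | None = None

    @property
    def species(self) -> list[str]:
        return list(self.occurrences.columns)

    @property
    def n_units(self) -> int:
        return self.design.n_units

    def occurrence_matrix(self) -> np.ndarray:
        return self.occurrences.to_numpy(dtype=np.int64)

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        """Write occurrence + covariate CSVs (and a parameter sidecar if synthetic)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        occ_path = out / "occurrences.csv"
        cov_path = out / "covariates.csv"
        occ = self.occurrences.copy()
        occ.insert(0, "unit_id", self.design.unit_ids)
        occ.to_csv(occ_path, index=False)
        self.covariates.to_csv(cov_path, index=False)
        paths = {"occurrences": occ_path, "covariates": cov_path}
        if self.config is not None:
            sidecar = out / "generator_params.json"
            sidecar.write_text(json.dumps(asdict(self.config), indent=2))
            paths["params"] = sidecar
        return paths


def generate_design(config: SyntheticConfig, rng: np.random.Generator) -> tuple[HierarchicalDesign, pd.DataFrame]:
    """Draw the nested design and per-unit covariate table.

    Units per plot are 1 + NegBin(shape, mean-1): strictly positive counts
    whose mean matches ``units_per_plot_mean``.
    """
    site_ids = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    managed = np.zeros(config.n_sites, dtype=np.int64)
    n_managed = int(round(config.management_fraction * config.n_sites))
    managed[rng.choice(config.n_sites, size=n_managed, replace=False)] = 1

    rows: list[tuple[str, str, str, int]] = []
    mean_extra = max(config.units_per_plot_mean - 1.0, 1e-9)
    shape = config.units_per_plot_shape
    for s, site in enumerate(site_ids):
        for pl in range(config.plots_per_site):
            plot = f"{site}P{pl + 1:02d}"
            n_units = 1 + rng.negative_binomial(shape, shape / (shape + mean_extra))
            for u in range(n_units):
                rows.append((f"{plot}U{u + 1:03d}", plot, site, managed[s]))
    frame = pd.DataFrame(rows, columns=["unit_id", "plot_id", "site_id", "management"])
    n = len(frame)
    frame["volume"] = np.exp(rng.normal(config.log_volume_mean, config.log_volume_sd, size=n))
    frame["decay"] = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.decay_probs))
    design = HierarchicalDesign.from_frame(frame)
    return design, frame


def generate_parameters(config: SyntheticConfig, design: HierarchicalDesign,
                        rng: np.random.Generator) -> TrueParameters:
    """Draw species responses, latent factors and loadings."""
    s = config.n_species_pool
    beta = np.empty((5, s))
    beta[0] = rng.normal(config.intercept_mean, config.intercept_sd, size=s)
    for k in range(4):
        beta[k + 1] = rng.normal(config.beta_means[k], config.beta_sds[k], size=s)
    k_site, k_plot, k_unit = config.n_factors
    sc_site, sc_plot, sc_unit = config.loading_scale
    return TrueParameters(
        beta=beta,
        site_factors=rng.standard_normal((design.n_sites, k_site)),
        plot_factors=rng.standard_normal((design.n_plots, k_plot)),
        unit_factors=rng.standard_normal((design.n_units, k_unit)),
        site_loadings=rng.normal(0.0, sc_site, size=(k_site, s)),
        plot_loadings=rng.normal(0.0, sc_plot, size=(k_plot, s)),
        unit_loadings=rng.normal(0.0, sc_unit, size=(k_unit, s)),
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def fixed_effect_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Generator-side design matrix: [1, management, z(log volume), z(decay), z(decay²)]."""
    x = np.column_stack([
        np.ones(len(covariates)),
        covariates["management"].to_numpy(dtype=float),
        _standardize(np.log(covariates["volume"].to_numpy(dtype=float))),
        _standardize(covariates["decay"].to_numpy(dtype=float)),
        _standardize(covariates["decay"].to_numpy(dtype=float) ** 2),
    ])
    return x


def compute_true_probabilities(params: TrueParameters, covariates: pd.DataFrame,
                               design: HierarchicalDesign) -> np.ndarray:
    """P_ij = Phi(L^F + L^R): probit of fixed plus latent-factor linear predictors."""
    x = fixed_effect_matrix(covariates)
    lf = x @ params.beta
    plot_codes, _ = design.group_codes("plot")
    site_codes, _ = design.group_codes("site")
    lr = (
        params.site_factors[site_codes] @ params.site_loadings
        + params.plot_factors[plot_codes] @ params.plot_loadings
        + params.unit_factors @ params.unit_loadings
    )
    linpred = lf + lr
    if not np.isfinite(linpred).all():
        bad = np.argwhere(~np.isfinite(linpred))[0]
        raise FloatingPointError(f"non-finite linear predictor at unit {bad[0]}, species {bad[1]}")
    return ndtr(linpred)


def generate_occurrences(probabilities: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli draws from a units x species probability matrix."""
    p = np.asarray(probabilities, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (rng.random(p.shape) < p).astype(np.int64)


def filter_rare_species(occurrences: np.ndarray, min_occurrences: int) -> np.ndarray:
    """Indices of species with at least ``min_occurrences`` occupied units (order kept)."""
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be at least 1")
    counts = np.asarray(occurrences).sum(axis=0)
    return np.flatnonzero(counts >= min_occurrences)


def simulate_community(config: SyntheticConfig | None = None, seed: int | None = None) -> CommunityData:
    """Generate a filtered synthetic community end-to-end.

    ``seed`` overrides ``config.seed``. The species pool is generated in
    full, occurrences are realized, and species below the occurrence floor
    are dropped — mirroring how a field survey is reduced before modelling.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "seed": int(seed)})
    rng = np.random.default_rng(config.seed)
    design, covariates = generate_design(config, rng)
    params = generate_parameters(config, design, rng)
    probs = compute_true_probabilities(params, covariates, design)
    occ = generate_occurrences(probs, rng)
    keep = filter_rare_species(occ, config.min_occurrences)
    names = [f"sp{j + 1:03d}" for j in keep]
    kept_params = TrueParameters(
        beta=params.beta[:, keep],
        site_factors=params.site_factors,
        plot_factors=params.plot_factors,
        unit_factors=params.unit_factors,
        site_loadings=params.site_loadings[:, keep],
        plot_loadings=params.plot_loadings[:, keep],
        unit_loadings=params.unit_loadings[:, keep],
    )
    return CommunityData(
        design=design,
        covariates=covariates,
        occurrences=pd.DataFrame(occ[:, keep], columns=names),
        true_probabilities=pd.DataFrame(probs[:, keep], columns=names),
        true_parameters=kept_params,
        config=config,
    )
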