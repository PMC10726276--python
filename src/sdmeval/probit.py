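"""Hierarchical Bayesian probit occupancy models.

A per-species probit regression with optional scalar random intercepts at the
site and plot levels of a nested design:

    z_i = x_i' beta + u_site(i) + u_plot(i) + eps_i,   eps_i ~ N(0, 1)
    y_i = 1[z_i > 0],
    u_site ~ N(0, sigma_site^2),   u_plot ~ N(0, sigma_plot^2).

Fitting is by Gibbs sampling with latent-utility data augmentation
(Albert & Chib): truncated-normal draws for z, conjugate normal updates for
beta and the level intercepts, and conjugate inverse-gamma updates for the
level variances. All updates are vectorized across species, so a whole
community sharing one design matrix is fitted in a single pass.

Three model variants are supported:

* ``FR`` — fixed effects (management, log-volume, decay, decay²) plus site
  and plot random intercepts;
* ``F``  — fixed effects only;
* ``R``  — species-specific intercept plus the random intercepts.

Prediction respects which hierarchical levels were seen during training: a
unit in a training site/plot receives that level's posterior intercept; for
an unseen level the intercept is integrated out analytically, using the
probit marginalization Phi(L / sqrt(1 + sigma^2)) within each posterior draw.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

__all__ = [
    "SamplerSettings",
    "DesignMatrixBuilder",
    "build_design_matrix",
    "HierarchicalProbitModel",
    "HierarchicalProbitResults",
    "VARIANTS",
]

VARIANTS = ("FR", "F", "R")

_Q_LO = 1e-15          # truncated-normal quantile clipping, keeps |z - m| <= ~8
_Q_HI = 1.0 - 1e-16


@dataclass(frozen=True)
class SamplerSettings:
    """Gibbs sampler configuration (two moderate chains by default)."""

    chains: int = 2
    draws: int = 1000
    burn: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.draws <= 0 or self.burn < 0 or self.thin <= 0 or self.chains <= 0:
            raise ValueError("sampler settings require draws, thin, chains > 0 and burn >= 0")

    def with_seed(self, seed: int) -> "SamplerSettings":
        return replace(self, seed=int(seed))


class DesignMatrixBuilder:
    """Fixed-effects design matrix with training-set standardization.

    Columns: intercept, management (0/1), standardized log(volume),
    standardized decay, standardized decay². The standardization constants
    are learned from the training table and reused for held-out units, so a
    test row maps through exactly the training transformation.
    """

    TERMS = ("intercept", "management", "log_volume", "decay", "decay2")

    def __init__(self, intercept_only: bool = False) -> None:
        self.intercept_only = intercept_only
        self._centers: np.ndarray | None = None
        self._scales: np.ndarray | None = None

    @property
    def names(self) -> tuple[str, ...]:
        return ("intercept",) if self.intercept_only else self.TERMS

    def _raw(self, covariates: pd.DataFrame) -> np.ndarray:
        vol = covariates["volume"].to_numpy(dtype=float)
        decay = covariates["decay"].to_numpy(dtype=float)
        if np.any(vol <= 0):
            raise ValueError("volume must be positive (log transform)")
        if np.any((decay < 1) | (decay > 5)):
            raise ValueError("decay stage must lie in 1..5")
        return np.column_stack([np.log(vol), decay, decay**2])

    def fit(self, covariates: pd.DataFrame) -> "DesignMatrixBuilder":
        if not self.intercept_only:
            raw = self._raw(covariates)
            self._centers = raw.mean(axis=0)
            scales = raw.std(axis=0, ddof=0)
            self._scales = np.where(scales > 0, scales, 1.0)
        return self

    def transform(self, covariates: pd.DataFrame) -> np.ndarray:
        n = len(covariates)
        if self.intercept_only:
            return np.ones((n, 1))
        if self._centers is None:
            raise RuntimeError("builder must be fitted before transform")
        for col in ("management", "volume", "decay"):
            if col not in covariates.columns:
                raise KeyError(f"covariate column {col!r} missing")
        raw = (self._raw(covariates) - self._centers) / self._scales
        return np.column_stack([
            np.ones(n),
            covariates["management"].to_numpy(dtype=float),
            raw,
        ])

    def fit_transform(self, covariates: pd.DataFrame) -> np.ndarray:
        return self.fit(covariates).transform(covariates)


def build_design_matrix(covariates: pd.DataFrame, builder: DesignMatrixBuilder | None = None
                        ) -> tuple[np.ndarray, DesignMatrixBuilder]:
    """Convenience wrapper: build (fitting the standardization if needed)."""
    if builder is None:
        builder = DesignMatrixBuilder().fit(covariates)
    return builder.transform(covariates), builder


def _codes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = np.unique(labels)
    return np.searchsorted(ids, labels), ids


class HierarchicalProbitModel:
    """Probit occupancy model for one or many species on a shared design.

    Parameters
    ----------
    endog : array-like
        Binary outcomes; shape ``(n,)`` for a single species or ``(n, S)``
        for a community sharing the design matrix. Every column must contain
        both classes.
    exog : array-like, shape (n, p)
        Fixed-effects design matrix (build with :class:`DesignMatrixBuilder`).
    site, plot : array-like or None
        Level membership labels; ``None`` omits that random intercept.
    prior_beta_sd : float
        Standard deviation of the mean-zero normal prior on each coefficient
        (wide relative to standardized covariates).
    prior_sigma_a, prior_sigma_b : float
        Inverse-gamma prior on each level variance sigma²; the defaults are
        weakly informative with prior mean b/(a-1) = 0.5.
    """

    def __init__(self, endog, exog, site=None, plot=None, exog_names=None,
                 species_names=None, prior_beta_sd: float = 5.0,
                 prior_sigma_a: float = 2.0, prior_sigma_b: float = 0.5) -> None:
        y = np.asarray(endog)
        self._single = y.ndim == 1
        y = y.reshape(len(y), -1).astype(np.int64)
        x = np.asarray(exog, dtype=float)
        if x.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ValueError("exog must be (n, p) aligned with endog")
        if not np.isin(np.unique(y), (0, 1)).all():
            raise ValueError("endog must be binary")
        counts = y.sum(axis=0)
        if np.any(counts == 0) or np.any(counts == y.shape[0]):
            j = int(np.flatnonzero((counts == 0) | (counts == y.shape[0]))[0])
            raise ValueError(
                f"species column {j} is single-class in the training data; "
                "a probit fit is not identified — skip and log this species"
            )
        self.endog = y
        self.exog = x
        self.exog_names = tuple(exog_names) if exog_names is not None else tuple(
            f"x{i}" for i in range(x.shape[1]))
        self.species_names = tuple(species_names) if species_names is not None else tuple(
            f"y{j}" for j in range(y.shape[1]))
        self.prior_beta_sd = float(prior_beta_sd)
        self.prior_sigma_a = float(prior_sigma_a)
        self.prior_sigma_b = float(prior_sigma_b)
        self._levels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if site is not None:
            self._levels["site"] = _codes(np.asarray(site))
        if plot is not None:
            self._levels["plot"] = _codes(np.asarray(plot))

    # ------------------------------------------------------------------
    @classmethod
    def from_community(cls, data, variant: str = "FR", species=None,
                       builder: DesignMatrixBuilder | None = None, **priors
                       ) -> "HierarchicalProbitModel":
        """Build a community model from :class:`~sdmeval.simulate.CommunityData`.

        ``variant`` selects fixed terms and random levels; ``species`` may
        subset columns (names or indices). Single-class species must be
        removed by the caller beforehand.
        """
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        occ = data.occurrences
        if species is not None:
            occ = occ.iloc[:, species] if not isinstance(species[0], str) else occ[list(species)]
        if builder is None:
            builder = DesignMatrixBuilder(intercept_only=(variant == "R")).fit(data.covariates)
        x = builder.transform(data.covariates)
        random = variant in ("FR", "R")
        return cls(
            occ.to_numpy(), x,
            site=data.design.unit_to_site if random else None,
            plot=data.design.unit_to_plot if random else None,
            exog_names=builder.names,
            species_names=occ.columns,
            **priors,
        )

    @property
    def has_random(self) -> bool:
        return bool(self._levels)

    # ------------------------------------------------------------------
    def fit(self, settings: SamplerSettings | None = None, **kwargs) -> "HierarchicalProbitResults":
        """Run the Gibbs sampler and return posterior results.

        Keyword arguments (``chains``, ``draws``, ``burn``, ``thin``,
        ``seed``) override the provided settings.
        """
        settings = replace(settings or SamplerSettings(), **kwargs)
        n, p = self.exog.shape
        s = self.endog.shape[1]
        xtx = self.exog.T @ self.exog + np.eye(p) / self.prior_beta_sd**2
        chol = cho_factor(xtx, lower=True)
        l_upper = np.linalg.cholesky(xtx).T  # for sampling: beta = mean + L^-T eps

        level_names = list(self._levels)
        level_codes = {k: v[0] for k, v in self._levels.items()}
        level_sizes = {k: len(v[1]) for k, v in self._levels.items()}
        level_counts = {k: np.bincount(c, minlength=level_sizes[k]).astype(float)
                        for k, c in level_codes.items()}

        keep = settings.draws
        chain_beta = np.empty((settings.chains, keep, p, s))
        chain_u = {k: np.empty((settings.chains, keep, level_sizes[k], s)) for k in level_names}
        chain_sig2 = {k: np.empty((settings.chains, keep, s)) for k in level_names}

        y1 = self.endog == 1
        for c in range(settings.chains):
            rng = np.random.default_rng([settings.seed, c])
            beta = np.zeros((p, s))
            u = {k: np.zeros((level_sizes[k], s)) for k in level_names}
            sig2 = {k: np.ones(s) for k in level_names}
            stored = 0
            total = settings.burn + keep * settings.thin
            for it in range(total):
                m = self.exog @ beta
                for k in level_names:
                    m += u[k][level_codes[k]]
                # latent utilities: truncated normal above/below 0
                lo = ndtr(-m)  # P(z < 0 | mean m)
                q = rng.random((n, s))
                q = np.where(y1, lo + q * (1.0 - lo), q * lo)
                z = m + ndtri(np.clip(q, _Q_LO, _Q_HI))
                # fixed effects
                resid = z
                for k in level_names:
                    resid = resid - u[k][level_codes[k]]
                mean_beta = cho_solve(chol, self.exog.T @ resid)
                beta = mean_beta + solve_triangular(l_upper, rng.standard_normal((p, s)), lower=False)
                # random intercepts + variances
                base = z - self.exog @ beta
                for k in level_names:
                    other = base.copy()
                    for k2 in level_names:
                        if k2 != k:
                            other -= u[k2][level_codes[k2]]
                    sums = np.zeros((level_sizes[k], s))
                    np.add.at(sums, level_codes[k], other)
                    var = 1.0 / (level_counts[k][:, None] + 1.0 / sig2[k][None, :])
                    u[k] = var * sums + np.sqrt(var) * rng.standard_normal((level_sizes[k], s))
                    shape = self.prior_sigma_a + level_sizes[k] / 2.0
                    rate = self.prior_sigma_b + 0.5 * (u[k] ** 2).sum(axis=0)
                    sig2[k] = rate / rng.gamma(shape, 1.0, size=s)
                if it >= settings.burn and (it - settings.burn) % settings.thin == 0:
                    chain_beta[c, stored] = beta
                    for k in level_names:
                        chain_u[k][c, stored] = u[k]
                        chain_sig2[k][c, stored] = sig2[k]
                    stored += 1

        return HierarchicalProbitResults(self, settings, chain_beta, chain_u, chain_sig2)


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction; ``chains`` is (C, D, ...)."""
    c, d = chains.shape[:2]
    half = d // 2
    if half < 2:
        return np.full(chains.shape[2:], np.nan)
    split = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, ell = split.shape[:2]
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean(axis=0)
    b = ell * means.var(axis=0, ddof=1)
    var_hat = (ell - 1) / ell * w + b / ell
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / w)


class HierarchicalProbitResults:
    """Posterior draws, summaries and predictions for a fitted probit model."""

    def __init__(self, model: HierarchicalProbitModel, settings: SamplerSettings,
                 chain_beta: np.ndarray, chain_u: dict, chain_sig2: dict) -> None:
        self.model = model
        self.settings = settings
        self._chain_beta = chain_beta
        c, d, p, s = chain_beta.shape
        self.beta_draws = chain_beta.reshape(c * d, p, s)
        self.u_draws = {k: v.reshape(c * d, *v.shape[2:]) for k, v in chain_u.items()}
        self.sigma2_draws = {k: v.reshape(c * d, -1) for k, v in chain_sig2.items()}
        self.level_ids = {k: model._levels[k][1] for k in model._levels}
        self.rhat = _split_rhat(chain_beta)
        finite = self.rhat[np.isfinite(self.rhat)]
        bad = finite.max() if finite.size else np.nan
        if np.isfinite(bad) and bad > 1.1:
            warnings.warn(
                f"split-chain Rhat reached {bad:.3f} (> 1.1) for at least one "
                "coefficient; consider longer chains", stacklevel=2)

    # -- statsmodels-flavoured accessors -------------------------------
    @property
    def params(self) -> np.ndarray:
        """Posterior-mean coefficients, shape (p,) or (p, S)."""
        mean = self.beta_draws.mean(axis=0)
        return mean[:, 0] if self.model._single else mean

    @property
    def bse(self) -> np.ndarray:
        """Posterior standard deviations of the coefficients."""
        sd = self.beta_draws.std(axis=0, ddof=1)
        return sd[:, 0] if self.model._single else sd

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Central posterior intervals, shape (p, 2) or (p, S, 2)."""
        qs = np.quantile(self.beta_draws, [alpha / 2, 1 - alpha / 2], axis=0)
        ci = np.moveaxis(qs, 0, -1)
        return ci[:, 0, :] if self.model._single else ci

    def sigma(self, level: str) -> np.ndarray:
        """Posterior-mean random-intercept standard deviation at ``level``."""
        sd = np.sqrt(self.sigma2_draws[level]).mean(axis=0)
        return sd[0] if self.model._single else sd

    def training_levels(self, level: str) -> np.ndarray:
        """Identifiers of the groups at ``level`` seen during training."""
        return self.level_ids[level]

    # ------------------------------------------------------------------
    def predict(self, exog, site=None, plot=None, chunk: int = 64,
                marginalize: str = "simulate") -> np.ndarray:
        """Posterior-mean occurrence probabilities for new units.

        For units whose site/plot appeared in training, the corresponding
        posterior intercept draws enter the linear predictor. For a group
        never seen in training the intercept is unknown and is integrated
        out over its ``N(0, sigma²)`` distribution:

        * ``marginalize='simulate'`` (default) draws one intercept per
          posterior draw for each unseen group — the new group's units share
          the draw, exactly as held-out prediction works in latent-variable
          fitting software. Draws are seeded deterministically from the fit
          seed and the group identifier, so repeated calls agree.
        * ``marginalize='analytic'`` uses the closed form
          ``Phi(L / sqrt(1 + sigma²))`` within each draw (the infinite-draw
          limit of the above).

        Returns shape ``(n,)`` or ``(n, S)``.
        """
        if marginalize not in ("simulate", "analytic"):
            raise ValueError("marginalize must be 'simulate' or 'analytic'")
        x = np.asarray(exog, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"exog has {x.shape[1] if x.ndim == 2 else 'wrong'} columns; "
                f"training used {self.model.exog.shape[1]} ({self.model.exog_names})")
        n = x.shape[0]
        labels = {"site": site, "plot": plot}
        idx, seen, new_eps = {}, {}, {}
        d, _, s = self.beta_draws.shape
        for k in self.model._levels:
            if labels[k] is None:
                raise ValueError(f"model was trained with a {k} random effect; "
                                 f"pass {k} labels to predict")
            lab = np.asarray(labels[k])
            ids = self.level_ids[k]
            lookup = {v: i for i, v in enumerate(ids)}
            pos = np.fromiter((lookup.get(v, -1) for v in lab), dtype=np.int64, count=n)
            ok = pos >= 0
            idx[k] = np.where(ok, pos, 0)
            seen[k] = ok
            if marginalize == "simulate" and not ok.all():
                # one standard-normal sequence per unseen group, shared by its units
                groups = []
                for g in np.unique(lab[~ok]):
                    ghash = zlib.crc32(f"{k}:{g}".encode())
                    grng = np.random.default_rng([self.settings.seed, ghash])
                    members = np.flatnonzero(lab == g)
                    groups.append((members, grng.standard_normal((d, s))))
                new_eps[k] = groups
        acc = np.zeros((n, s))
        for start in range(0, d, chunk):
            sl = slice(start, min(start + chunk, d))
            nb = sl.stop - sl.start
            lin = np.einsum("np,dps->nds", x, self.beta_draws[sl])
            extra_var = np.zeros((n, nb, s))
            for k in self.model._levels:
                u = self.u_draws[k][sl]                     # (nb, G, S)
                contrib = u[:, idx[k], :].transpose(1, 0, 2)  # (n, nb, S)
                contrib[~seen[k]] = 0.0
                lin += contrib
                sig2 = self.sigma2_draws[k][sl]             # (nb, S)
                if marginalize == "analytic":
                    extra_var[~seen[k]] += sig2
                elif k in new_eps:
                    for members, eps in new_eps[k]:
                        lin[members] += eps[sl] * np.sqrt(sig2)
            acc += ndtr(lin / np.sqrt(1.0 + extra_var)).sum(axis=1)
        probs = acc / d
        return probs[:, 0] if self.model._single else probs

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Serialize the fit to a single ``.npz`` archive (draws + JSON manifest)."""
        manifest = {
            "exog_names": list(self.model.exog_names),
            "species_names": list(self.model.species_names),
            "single": self.model._single,
            "n_exog": self.model.exog.shape[1],
            "levels": list(self.model._levels),
            "settings": {"chains": self.settings.chains, "draws": self.settings.draws,
                         "burn": self.settings.burn, "thin": self.settings.thin,
                         "seed": self.settings.seed},
        }
        arrays = {"beta_draws": self.beta_draws, "chain_beta": self._chain_beta,
                  "manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)}
        for k in self.model._levels:
            arrays[f"u_{k}"] = self.u_draws[k]
            arrays[f"sigma2_{k}"] = self.sigma2_draws[k]
            arrays[f"ids_{k}"] = self.level_ids[k]
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "HierarchicalProbitResults":
        """Rebuild a results object (sufficient for prediction and summaries)."""
        with np.load(path, allow_pickle=False) as archive:
            manifest = json.loads(bytes(archive["manifest"]).decode())
            settings = SamplerSettings(**manifest["settings"])
            obj = cls.__new__(cls)
            obj.settings = settings
            obj._chain_beta = archive["chain_beta"]
            obj.beta_draws = archive["beta_draws"]
            obj.u_draws = {k: archive[f"u_{k}"] for k in manifest["levels"]}
            obj.sigma2_draws = {k: archive[f"sigma2_{k}"] for k in manifest["levels"]}
            obj.level_ids = {k: archive[f"ids_{k}"] for k in manifest["levels"]}
        obj.rhat = _split_rhat(obj._chain_beta)
        obj.model = _ModelStub(manifest)
        return obj

    # ------------------------------------------------------------------
    def summary(self, species: int | str = 0) -> str:
        """Text summary of one species' posterior (coefficients and sigmas)."""
        names = self.model.species_names
        j = names.index(species) if isinstance(species, str) else int(species)
        beta = self.beta_draws[:, :, j]
        lines = [
            "Hierarchical probit occupancy model (Gibbs)",
            f"species: {names[j]}    n = {self.model.exog.shape[0]}"
            f"    draws = {beta.shape[0]} ({self.settings.chains} chains)",
            "-" * 70,
            f"{'term':<12}{'mean':>10}{'sd':>10}{'2.5%':>10}{'97.5%':>10}{'Rhat':>8}",
        ]
        lo, hi = np.quantile(beta, [0.025, 0.975], axis=0)
        for i, name in enumerate(self.model.exog_names):
            rh = self.rhat[i, j] if self.rhat.size else np.nan
            lines.append(f"{name:<12}{beta[:, i].mean():>10.3f}{beta[:, i].std(ddof=1):>10.3f}"
                         f"{lo[i]:>10.3f}{hi[i]:>10.3f}{rh:>8.3f}")
        for k in self.model._levels:
            sd = np.sqrt(self.sigma2_draws[k][:, j])
            qlo, qhi = np.quantile(sd, [0.025, 0.975])
            lines.append(f"{'sigma_' + k:<12}{sd.mean():>10.3f}{sd.std(ddof=1):>10.3f}"
                         f"{qlo:>10.3f}{qhi:>10.3f}{'':>8}")
        lines.append("-" * 70)
        return "\n".join(lines)


class _ModelStub:
    """Just enough model surface for a deserialized results object to predict."""

    def __init__(self, manifest: dict) -> None:
        self.exog_names = tuple(manifest["exog_names"])
        self.species_names = tuple(manifest["species_names"])
        self._single = bool(manifest["single"])
        self.exog = np.empty((0, int(manifest["n_exog"])))
        self._levels = {k: (None, None) for k in manifest["levels"]}
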