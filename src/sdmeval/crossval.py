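"""Evaluation strategies: explanatory power and blocked k-fold cross-validation.

Four strategies of increasing difficulty are supported:

* ``explanatory`` — fit to all data, predict the same data (resubstitution);
* ``cv_unit``     — 5-fold CV with units assigned to folds at random;
* ``cv_plot``     — 5-fold CV blocking whole plots into folds;
* ``cv_site``     — 5-fold CV blocking whole sites into folds.

Blocked folds keep every unit of a plot (or site) together, so the held-out
predictions genuinely face new plots or new sites, and the model's random
intercepts for those groups cannot be used. Fold balance is in blocks, not
units. Cross-validation is repeated with fresh fold assignments and results
averaged downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import HierarchicalDesign
from .probit import DesignMatrixBuilder, HierarchicalProbitModel, SamplerSettings
from .simulate import CommunityData

__all__ = [
    "STRATEGIES",
    "FoldAssignment",
    "FitLog",
    "make_folds",
    "explanatory_predictions",
    "cross_validate",
    "repeat_cv",
]

STRATEGIES = ("explanatory", "cv_unit", "cv_plot", "cv_site")


@dataclass(frozen=True)
class FoldAssignment:
    """Assignment of every sampling unit to one of ``k`` folds."""

    blocking_level: str
    k: int
    unit_to_fold: np.ndarray  # int fold index per unit, aligned with design.unit_ids
    repeat_index: int
    seed: int

    def to_frame(self, design: HierarchicalDesign) -> pd.DataFrame:
        return pd.DataFrame({
            "unit_id": design.unit_ids,
            "repeat": self.repeat_index,
            "fold": self.unit_to_fold,
        })


@dataclass
class FitLog:
    """Species skipped or degraded during fitting, for audit trails."""

    skipped: list[dict] = field(default_factory=list)

    def skip(self, species: str, fold: int | None, reason: str) -> None:
        self.skipped.append({"species": species, "fold": fold, "reason": reason})

    def extend(self, other: "FitLog") -> None:
        self.skipped.extend(other.skipped)


def make_folds(design: HierarchicalDesign, blocking_level: str, k: int = 5,
               seed: int = 0, repeat_index: int = 0) -> FoldAssignment:
    """Shuffle the blocks at ``blocking_level`` and deal them round-robin to folds.

    Fold sizes in blocks differ by at most one; all units of a block share
    its fold.
    """
    if blocking_level not in ("unit", "plot", "site"):
        raise ValueError("blocking_level must be 'unit', 'plot' or 'site'")
    codes, ids = design.group_codes(blocking_level)
    if len(ids) < k:
        raise ValueError(
            f"cannot make {k} folds from {len(ids)} {blocking_level}s")
    rng = np.random.default_rng([seed, repeat_index])
    order = rng.permutation(len(ids))
    block_fold = np.empty(len(ids), dtype=np.int64)
    block_fold[order] = np.arange(len(ids)) % k
    unit_to_fold = block_fold[codes]
    fa = FoldAssignment(blocking_level, k, unit_to_fold, repeat_index, seed)
    _assert_fold_invariants(fa, design)
    return fa


def _assert_fold_invariants(folds: FoldAssignment, design: HierarchicalDesign) -> None:
    """Exhaustive block-integrity and coverage checks (run on every assignment)."""
    assert folds.unit_to_fold.shape == (design.n_units,)
    assert set(np.unique(folds.unit_to_fold)) <= set(range(folds.k))
    if folds.blocking_level != "unit":
        labels = design.group_labels(folds.blocking_level)
        per_block = pd.Series(folds.unit_to_fold).groupby(pd.Series(labels)).nunique()
        assert (per_block == 1).all(), "a block is split across folds"


def _mixed_class_mask(y: np.ndarray) -> np.ndarray:
    counts = y.sum(axis=0)
    return (counts > 0) & (counts < y.shape[0])


def _fit_predict(data: CommunityData, variant: str, train: np.ndarray,
                 test: np.ndarray, sampler: SamplerSettings, log: FitLog,
                 fold: int | None) -> np.ndarray:
    """Fit on ``train`` units, predict ``test`` units; NaN for skipped species."""
    y = data.occurrence_matrix()[train]
    species = np.asarray(data.species)
    ok = _mixed_class_mask(y)
    for name in species[~ok]:
        log.skip(str(name), fold, "single-class training data")
    out = np.full((test.sum(), len(species)), np.nan)
    if not ok.any():
        return out
    cov_train = data.covariates.iloc[train]
    builder = DesignMatrixBuilder(intercept_only=(variant == "R")).fit(cov_train)
    random = variant in ("FR", "R")
    design = data.design
    model = HierarchicalProbitModel(
        y[:, ok], builder.transform(cov_train),
        site=design.unit_to_site[train] if random else None,
        plot=design.unit_to_plot[train] if random else None,
        exog_names=builder.names,
        species_names=species[ok],
    )
    res = model.fit(sampler)
    preds = res.predict(
        builder.transform(data.covariates.iloc[test]),
        site=design.unit_to_site[test] if random else None,
        plot=design.unit_to_plot[test] if random else None,
    )
    out[:, ok] = preds
    return out


def explanatory_predictions(data: CommunityData, variant: str,
                            sampler: SamplerSettings | None = None,
                            log: FitLog | None = None) -> pd.DataFrame:
    """Resubstitution: fit each species to all units and predict those same units."""
    sampler = sampler or SamplerSettings()
    log = log if log is not None else FitLog()
    full = np.ones(data.n_units, dtype=bool)
    preds = _fit_predict(data, variant, full, full, sampler, log, fold=None)
    return pd.DataFrame(preds, columns=data.species)


def cross_validate(data: CommunityData, variant: str, folds: FoldAssignment,
                   sampler: SamplerSettings | None = None,
                   log: FitLog | None = None) -> pd.DataFrame:
    """Held-out predictions for every unit under one fold assignment.

    Each unit's prediction comes from the model trained without its fold;
    under plot/site blocking the unit's plot/site is absent from training, so
    prediction integrates over the unseen random intercepts. Species that are
    single-class within a training split get NaN for that fold (logged).
    """
    sampler = sampler or SamplerSettings()
    log = log if log is not None else FitLog()
    _assert_fold_invariants(folds, data.design)
    preds = np.full((data.n_units, len(data.species)), np.nan)
    for fold in range(folds.k):
        test = folds.unit_to_fold == fold
        train = ~test
        assert not np.any(train & test), "leakage: a unit appears in its own training set"
        if not test.any():
            continue
        fold_sampler = sampler.with_seed(
            np.random.SeedSequence([sampler.seed, folds.repeat_index, fold]).generate_state(1)[0] % (2**31)
        )
        preds[test] = _fit_predict(data, variant, train, test, fold_sampler, log, fold)
    return pd.DataFrame(preds, columns=data.species)


def repeat_cv(data: CommunityData, variant: str, blocking_level: str, k: int = 5,
              n_repeats: int = 10, base_seed: int = 0,
              sampler: SamplerSettings | None = None,
              log: FitLog | None = None) -> list[pd.DataFrame]:
    """Repeated blocked CV: fresh fold assignment per repeat, one prediction matrix each."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    sampler = sampler or SamplerSettings()
    log = log if log is not None else FitLog()
    out = []
    for r in range(n_repeats):
        folds = make_folds(data.design, blocking_level, k=k, seed=base_seed, repeat_index=r)
        out.append(cross_validate(data, variant, folds, sampler=sampler, log=log))
    return out
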