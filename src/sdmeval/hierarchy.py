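"""Nested sampling designs and hierarchical aggregation of occurrences and probabilities.

A three-level design — sampling units nested in plots nested in sites — is the
backbone of everything downstream: probability aggregation, level-wise
prevalence, and blocked cross-validation. A plot (or site) is scored occupied
if any of its units is occupied; the matching probability statement is the
noisy-OR ``p_G = 1 - prod_{i in G} (1 - p_i)``, which treats units as
independent when combining their occurrence probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "HierarchicalDesign",
    "aggregate_occurrence",
    "aggregate_probability",
    "aggregate_matrix",
    "prevalence",
]

#: Hierarchy levels, finest first.
LEVELS = ("unit", "plot", "site")


class DesignError(ValueError):
    """Raised when a nested design violates its structural invariants."""


@dataclass(frozen=True)
class HierarchicalDesign:
    """Strictly nested unit -> plot -> site membership map.

    Parameters
    ----------
    unit_ids : array-like
        Identifiers of the sampling units, in data order; must be unique.
    unit_to_plot : array-like
        Plot identifier of each unit, aligned with ``unit_ids``.
    unit_to_site : array-like
        Site identifier of each unit, aligned with ``unit_ids``. Each plot
        must map to exactly one site (strict nesting).

    Notes
    -----
    Group identifiers at each level are reported in lexicographic order so
    that aggregated vectors join deterministically.
    """

    unit_ids: np.ndarray
    unit_to_plot: np.ndarray
    unit_to_site: np.ndarray
    plot_ids: np.ndarray = field(init=False)
    site_ids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        units = np.asarray(self.unit_ids)
        plots = np.asarray(self.unit_to_plot)
        sites = np.asarray(self.unit_to_site)
        if not (len(units) == len(plots) == len(sites)):
            raise DesignError("unit, plot and site columns must have equal length")
        if len(units) == 0:
            raise DesignError("design is empty")
        if len(np.unique(units)) != len(units):
            dup = pd.Index(units)[pd.Index(units).duplicated()][0]
            raise DesignError(f"duplicate unit identifier: {dup!r}")
        # strict nesting: a plot may not appear under two different sites
        pairs = pd.DataFrame({"plot": plots, "site": sites}).drop_duplicates()
        bad = pairs["plot"].value_counts()
        bad = bad[bad > 1]
        if len(bad):
            raise DesignError(f"plot {bad.index[0]!r} maps to more than one site")
        object.__setattr__(self, "unit_ids", units)
        object.__setattr__(self, "unit_to_plot", plots)
        object.__setattr__(self, "unit_to_site", sites)
        object.__setattr__(self, "plot_ids", np.unique(plots))
        object.__setattr__(self, "site_ids", np.unique(sites))

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        unit_col: str = "unit_id",
        plot_col: str = "plot_id",
        site_col: str = "site_id",
    ) -> "HierarchicalDesign":
        """Build a design from a covariate table with membership columns."""
        for col in (unit_col, plot_col, site_col):
            if col not in frame.columns:
                raise DesignError(f"missing design column {col!r}")
        return cls(
            frame[unit_col].to_numpy(),
            frame[plot_col].to_numpy(),
            frame[site_col].to_numpy(),
        )

    # -- sizes -------------------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def n_groups(self, level: str) -> int:
        return {"unit": self.n_units, "plot": self.n_plots, "site": self.n_sites}[level]

    def group_labels(self, level: str) -> np.ndarray:
        """Per-unit group label at ``level`` (identity at unit level)."""
        _check_level(level)
        if level == "unit":
            return self.unit_ids
        return self.unit_to_plot if level == "plot" else self.unit_to_site

    def group_codes(self, level: str) -> tuple[np.ndarray, np.ndarray]:
        """Integer codes into the sorted group-id array at ``level``.

        Returns ``(codes, ids)`` with ``ids[codes[i]]`` the group of unit i.
        """
        labels = self.group_labels(level)
        ids = np.unique(labels)
        codes = np.searchsorted(ids, labels)
        return codes, ids


def _check_level(level: str) -> None:
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")


def _check_aligned(values: np.ndarray, design: HierarchicalDesign) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape[0] != design.n_units:
        raise IndexError(
            f"vector has {arr.shape[0]} entries but the design has "
            f"{design.n_units} units (first unit {design.unit_ids[0]!r})"
        )
    return arr


def aggregate_occurrence(y, design: HierarchicalDesign, target_level: str) -> pd.Series:
    """Aggregate binary unit occurrences to plot or site level.

    Implements the any-presence rule ``y_G = 1 - prod_{i in G}(1 - y_i)``,
    identically the group-wise maximum for binary input.
    """
    _check_level(target_level)
    arr = _check_aligned(y, design)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("occurrence vector entries must be exactly 0 or 1")
    if target_level == "unit":
        return pd.Series(arr.astype(np.int64), index=design.unit_ids, name="y")
    codes, ids = design.group_codes(target_level)
    out = np.zeros(len(ids), dtype=np.int64)
    np.maximum.at(out, codes, arr.astype(np.int64))
    return pd.Series(out, index=ids, name="y")


def aggregate_probability(p, design: HierarchicalDesign, target_level: str) -> pd.Series:
    """Aggregate unit occurrence probabilities to plot or site level.

    ``p_G = 1 - prod_{i in G}(1 - p_i)``: the probability that at least one
    unit of the group is occupied, treating units as independent.
    """
    _check_level(target_level)
    arr = _check_aligned(p, design).astype(float)
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        bad = int(np.flatnonzero((arr < 0) | (arr > 1) | ~np.isfinite(arr))[0])
        raise ValueError(
            f"probability outside [0, 1] at unit {design.unit_ids[bad]!r}: {arr[bad]}"
        )
    if target_level == "unit":
        return pd.Series(arr, index=design.unit_ids, name="p")
    codes, ids = design.group_codes(target_level)
    surv = np.ones(len(ids), dtype=float)
    np.multiply.at(surv, codes, 1.0 - arr)
    return pd.Series(1.0 - surv, index=ids, name="p")


def aggregate_matrix(values: np.ndarray, design: HierarchicalDesign, target_level: str,
                     kind: str = "probability") -> np.ndarray:
    """Column-wise aggregation of a units x species matrix (NaN columns pass through).

    ``kind='probability'`` applies the noisy-OR; ``kind='occurrence'`` the
    group maximum. Rows of the result follow the sorted group ids of
    ``target_level``.
    """
    _check_level(target_level)
    mat = _check_aligned(values, design).astype(float)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D units x species matrix")
    if target_level == "unit":
        return mat.copy()
    codes, ids = design.group_codes(target_level)
    if kind == "occurrence":
        out = np.zeros((len(ids), mat.shape[1]))
        np.maximum.at(out, codes, mat)
    else:
        surv = np.ones((len(ids), mat.shape[1]))
        np.multiply.at(surv, codes, 1.0 - mat)
        out = 1.0 - surv
    # a NaN anywhere in a group poisons that group's cell, as it should
    nan_cols = np.isnan(mat).any(axis=0)
    if nan_cols.any():
        nan_groups = np.zeros((len(ids), mat.shape[1]), dtype=bool)
        np.logical_or.at(nan_groups, codes, np.isnan(mat))
        out[nan_groups] = np.nan
    return out


def prevalence(y, design: HierarchicalDesign, level: str = "unit") -> float:
    """Fraction of entities occupied at ``level`` (aggregating first if needed)."""
    agg = aggregate_occurrence(y, design, level)
    return float(agg.mean())
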