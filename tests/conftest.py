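import numpy as np
import pandas as pd
import pytest

from sdmeval import HierarchicalDesign, PredictionSet, SamplerSettings, SyntheticConfig, simulate_community


@pytest.fixture
def micro_ps() -> PredictionSet:
    """Hand-enumerable worked example: 2 presences, 2 absences.

    Presence-absence pairs for AUC: (0.9, 0.8) win, (0.9, 0.1) win,
    (0.2, 0.8) loss, (0.2, 0.1) win -> AUC = 3/4. Tjur: 0.55 - 0.45 = 0.10.
    TSS sweep peaks at 0.5 for thresholds in (0.1, 0.2].
    """
    return PredictionSet(np.array([1, 1, 0, 0]), np.array([0.9, 0.2, 0.8, 0.1]))


@pytest.fixture
def small_design() -> HierarchicalDesign:
    """Four units in two plots of one site plus a second site with one plot."""
    return HierarchicalDesign(
        unit_ids=np.array(["u1", "u2", "u3", "u4", "u5", "u6"]),
        unit_to_plot=np.array(["p1", "p1", "p2", "p2", "p3", "p3"]),
        unit_to_site=np.array(["s1", "s1", "s1", "s1", "s2", "s2"]),
    )


@pytest.fixture(scope="session")
def tiny_community():
    """A small but complete community for model/CV plumbing tests (~350 units)."""
    cfg = SyntheticConfig(
        n_sites=8, plots_per_site=3, units_per_plot_mean=15.0,
        n_species_pool=40, min_occurrences=10, seed=42,
    )
    return simulate_community(cfg)


@pytest.fixture(scope="session")
def fast_sampler() -> SamplerSettings:
    """Short chains for plumbing tests where posterior quality is irrelevant."""
    return SamplerSettings(chains=2, draws=120, burn=120, seed=7)
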