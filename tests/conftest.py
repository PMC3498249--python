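import numpy as np
import pytest

from forestrec import (
    Census,
    CensusCollection,
    PlotMeta,
    SimConfig,
    SpeciesAbundance,
    Treatment,
    simulate,
)


def make_census(plot_id, label, triples):
    """triples: (species, stems, basal_area)"""
    return Census(
        plot_id, label, {sp: SpeciesAbundance(s, b) for sp, s, b in triples}
    )


@pytest.fixture
def toy_collection() -> CensusCollection:
    """The deterministic worked example: 2 gap/control pairs, 4 species."""
    return simulate(SimConfig(fixed_example=True))


@pytest.fixture
def sim_collection() -> CensusCollection:
    return simulate(SimConfig(seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def single_plot_collection(triples_by_plot, treatment=Treatment.REFERENCE,
                           label="survey", forest_type="f", area=100.0):
    """Single-census plots, e.g. {'A': [('oak', 3, 0.1)], ...}."""
    censuses = [make_census(p, label, t) for p, t in triples_by_plot.items()]
    meta = [PlotMeta(p, None, treatment, area, forest_type) for p in triples_by_plot]
    return CensusCollection(censuses, meta)
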