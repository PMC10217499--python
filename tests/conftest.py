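import numpy as np
import pandas as pd
import pytest

import fishspec as fs
from fishspec.spectra import SpectraSet


def make_set(n_spectra=4, grid=None, rng=None, days=None):
    """Small random SpectraSet for structural tests."""
    rng = rng or np.random.default_rng(0)
    grid = np.arange(600.0, 700.0, 2.0) if grid is None else np.asarray(grid, float)
    X = rng.normal(1.0, 0.1, size=(n_spectra, grid.size))
    days = days or [0] * n_spectra
    meta = pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(n_spectra)],
        "fish_id": [f"fish{i % 2 + 1}" for i in range(n_spectra)],
        "day": days,
        "fibre_id": [f"fib{i}" for i in range(n_spectra)],
    })
    return SpectraSet(grid, X, meta)


@pytest.fixture(scope="session")
def paper_set():
    """One full paper_effects campaign (819 spectra), generated once."""
    return fs.generate_spectra(fs.default_scenario("paper_effects"))


@pytest.fixture(scope="session")
def paper_pre(paper_set):
    """The same campaign through the default preprocessing chain."""
    return fs.preprocess(paper_set)


@pytest.fixture(scope="session")
def paper_pre_raw(paper_set):
    """Baseline-corrected but un-normalised (for intensity-scale statistics)."""
    return fs.preprocess(paper_set, fs.PreprocessConfig(normalise=False))


def d0d7_set(seed):
    """D0-vs-D7 campaign with the study's fibre counts (111 vs 114)."""
    cfg = fs.default_scenario("paper_effects")
    cfg.days = (0, 7)
    cfg.n_fibres_per_fish_day = 38
    cfg.seed = seed
    sset = fs.generate_spectra(cfg)
    idx0 = np.flatnonzero(sset.labels == 0)
    keep = np.setdiff1d(np.arange(len(sset)), idx0[-3:])
    return sset.select(keep), cfg
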