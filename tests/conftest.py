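import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chromassoc.genome import GenomeLayout, IntervalSet
from chromassoc.simulate import SimulationConfig, make_fixture


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout(("chrA", "chrB"), (10_000, 6_000))


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    return GenomeLayout(("chrA",), (1_000,))


def iset(layout, rows, merged=False) -> IntervalSet:
    """Rows of (chrom, start, end[, name[, strand]])."""
    recs = []
    for r in rows:
        r = tuple(r) + (".",) * (5 - len(r))
        recs.append(r)
    frame = pd.DataFrame(recs, columns=["chrom", "start", "end", "name", "strand"])
    return IntervalSet(layout, frame, merged=merged)


@pytest.fixture
def make_set():
    return iset


def small_sim_config(**overrides) -> SimulationConfig:
    """Desk-scale simulation: 3 x 1 Mb, 50-150 kb domains, short genes."""
    defaults = dict(
        n_chroms=3,
        chrom_length=1_000_000,
        n_genes=150,
        gene_length_range=(1_000, 5_000),
        domain_length_range=(50_000, 150_000),
        n_narrow_peaks=30,
        n_up=20,
        n_down=40,
        step_bp=200,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """One shared small synthetic dataset on disk."""
    outdir = tmp_path_factory.mktemp("fixture")
    cfg = small_sim_config()
    make_fixture(cfg, outdir, seed=7)
    return outdir


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
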