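import numpy as np
import pandas as pd
import pytest

from shatterscan.genome import GenomeModel


@pytest.fixture
def toy_genome() -> GenomeModel:
    """Three 100 Mb chromosomes with centromeres at 45-55 Mb."""
    names = ("1", "2", "3")
    return GenomeModel(
        names,
        {c: 100_000_000 for c in names},
        {c: (45_000_000, 55_000_000) for c in names},
    )


def make_profile(boundaries, states, sample="s1", chrom="1"):
    """Segment table from breakpoints [b0, b1, ..., bn] and n states."""
    assert len(boundaries) == len(states) + 1
    rows = [
        {
            "sample": sample,
            "chrom": chrom,
            "start": boundaries[i],
            "end": boundaries[i + 1],
            "copy_number": float(states[i]),
            "state": int(states[i]),
        }
        for i in range(len(states))
    ]
    return pd.DataFrame(rows)


def switch_profile(positions, length=200_000_000, sample="s1", chrom="1"):
    """Profile whose state switches exactly at the given positions."""
    bounds = [0, *sorted(positions), length]
    states = [2 + (i % 2) for i in range(len(bounds) - 1)]
    return make_profile(bounds, states, sample=sample, chrom=chrom)


@pytest.fixture
def make_segments():
    return make_profile


@pytest.fixture
def make_switch_profile():
    return switch_profile


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured simulated cohort shared across tests."""
    from shatterscan.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(seed=7, n_samples=30, n_pairs=6)
    return cfg, simulate_cohort(cfg)
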