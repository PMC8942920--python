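import math

import numpy as np
import pandas as pd
import pytest

import nucleomorph as nm
from nucleomorph.pipeline import classify_table, measure_pairs


@pytest.fixture(scope="session")
def gc_population():
    """50 guard-cell-preset nuclei at default noise, seed 1."""
    return nm.generate_population("GC", 50, seed=1)


@pytest.fixture(scope="session")
def pc_population():
    """50 parenchyma/pavement-preset nuclei at default noise, seed 1."""
    return nm.generate_population("PC", 50, seed=1)


@pytest.fixture(scope="session")
def gc_measured(gc_population):
    return measure_pairs(gc_population)


@pytest.fixture(scope="session")
def pc_measured(pc_population):
    return measure_pairs(pc_population)


@pytest.fixture(scope="session")
def mixed_measured():
    """Measured + classified table for a 4-cell-type mixed population (n=50 each)."""
    frames = [
        measure_pairs(nm.generate_population(name, 50, seed=2))
        for name in ("GC", "PC", "VC", "EC")
    ]
    return classify_table(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def welch_type1_rate():
    """Empirical type-I error of the pairwise Welch test at alpha = 0.05.

    10,000 two-group datasets drawn from a single normal distribution; the
    rejection rate of the package's own Welch routine should match the
    nominal level.
    """
    from nucleomorph.profiling import welch_anova_tests

    rng = np.random.default_rng(20240501)
    n, reps = 15, 10_000
    rejections = 0
    for _ in range(reps):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        table = welch_anova_tests({"a": a, "b": b})
        p = float(table.loc[table["test"] == "welch_t", "p_value"].iloc[0])
        rejections += p < 0.05
    return rejections / reps


def simple_nucleus_spec(**overrides):
    """A small, fast, round test nucleus; fields overridable per test."""
    defaults = dict(
        semi_axes=(2.4, 2.2),
        eu_intensity=2000.0,
        cc_count=4,
        cc_radius_range=(0.22, 0.26),
        cc_intensity_factor=3.0,
        nucleolus_radius=0.0,
        noise_sd=0.05,
        pixel_size=0.1,
        bit_depth=16,
    )
    defaults.update(overrides)
    return nm.NucleusSpec(**defaults)
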