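import numpy as np
import pandas as pd
import pytest

from rtgpoly import afshift
from rtgpoly.simulate import (
    ForcedCrossover,
    GenomeSpec,
    NoiseModel,
    exact_observations,
    simulate_parent,
    simulate_rtg,
)


@pytest.fixture(scope="session")
def small_spec():
    """Two short triploid chromosomes — fast enough for most unit tests."""
    return GenomeSpec(
        chrom_lengths=(300_000, 200_000), ploidy=(3, 3), marker_density=3.4, seed=11
    )


@pytest.fixture(scope="session")
def small_parent(small_spec):
    return simulate_parent(small_spec)


@pytest.fixture(scope="session")
def forced_co_pair(small_parent):
    """A mother-daughter pair with exactly one CO, recombinants split."""
    fc = ForcedCrossover(chrom=0, pos=100_000, homologs=(0, 1), sisters=(0, 0))
    mother, daughter, truth = simulate_rtg(
        small_parent, n_dsb_per_Mb=0.0, seed=5, forced_cos=(fc,)
    )
    return mother, daughter, truth, fc


def calls_and_regions(cell, min_run=9):
    """Noise-free shift calls and regions for a simulated cell."""
    table = exact_observations(cell)
    calls = afshift.classify_sample(table)
    return calls, afshift.call_regions(calls, min_run=min_run)


def make_calls(statuses, directions=None, chrom="chrI"):
    """Hand-built shift-call table for region-assembly tests."""
    n = len(statuses)
    directions = directions or ["none"] * n
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * 100,
            "k": 1,
            "p": 3,
            "shift_status": statuses,
            "direction": directions,
            "delta_af": [0.3 if s == "shift" else 0.0 for s in statuses],
        }
    )


def brute_force_regions(statuses, min_run):
    """Independent run-length oracle: scan every maximal run of 'shift'."""
    out = []
    i = 0
    n = len(statuses)
    while i < n:
        if statuses[i] != "shift":
            i += 1
            continue
        j = i
        while j < n and statuses[j] == "shift":
            j += 1
        if j - i >= min_run:
            out.append((i, j))
        i = j
    return out
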