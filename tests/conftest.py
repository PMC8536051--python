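"""Shared fixtures: packaged reference table, small synthetic input sets."""

from __future__ import annotations

import math
from fractions import Fraction

import pytest

from vdfreq.datasets import (
    POPULATION_ORDER,
    extreme_snps_catalog,
    extreme_snps_frequency_table,
    extreme_snps_printed_matrix,
    load_extreme_korean_snps,
)
from vdfreq.simulate import PopulationSpec, SimulationConfig, emit_fixtures

# ---------------------------------------------------------------------------
# independent Fisher oracle: exact integer combinatorics, no floating point
# until the final division.  Sums hypergeometric point weights not exceeding
# the observed table's weight; weights are integers so the comparison is
# exact.

_MAX_N = 82
_COMB = [[math.comb(n, k) for k in range(n + 1)] for n in range(_MAX_N + 1)]


def fisher_exact_two_sided(k1: int, n1: int, k2: int, n2: int) -> Fraction:
    """Two-sided Fisher p for [[k1, n1-k1], [k2, n2-k2]] as an exact rational."""
    N, K = n1 + n2, k1 + k2
    if K == 0 or K == N:
        return Fraction(1)
    lo, hi = max(0, K - n2), min(K, n1)
    w_obs = _COMB[K][k1] * _COMB[N - K][n1 - k1]
    total = sum(
        w
        for k in range(lo, hi + 1)
        if (w := _COMB[K][k] * _COMB[N - K][n1 - k]) <= w_obs
    )
    return Fraction(total, _COMB[N][n1])


@pytest.fixture(scope="session")
def reference_table():
    return load_extreme_korean_snps()


@pytest.fixture(scope="session")
def reference_catalog():
    return extreme_snps_catalog()


@pytest.fixture(scope="session")
def reference_frequencies():
    return extreme_snps_frequency_table()


@pytest.fixture(scope="session")
def printed_matrix():
    return extreme_snps_printed_matrix()


@pytest.fixture(scope="session")
def population_order():
    return list(POPULATION_ORDER)


def small_simulation_config(seed: int = 7, n_snps: int = 40) -> SimulationConfig:
    """Six small cohorts in two clades; fast enough for per-test use."""
    pops = (
        PopulationSpec("EUR", 40, 0.02, 50.0, "WEST"),
        PopulationSpec("AMR", 30, 0.02, 10.0, "WEST"),
        PopulationSpec("SAS", 30, 0.02, 25.0, "WEST"),
        PopulationSpec("AFR", 40, 0.02, 0.0, "EAST"),
        PopulationSpec("EAS", 30, 0.02, 35.0, "EAST"),
        PopulationSpec("KOR", 100, 0.02, 37.0, "EAST"),
    )
    return SimulationConfig(populations=pops, n_snps=n_snps, seed=seed)


@pytest.fixture(scope="session")
def sim_config():
    return small_simulation_config()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    """A complete emitted synthetic input set, shared across tests."""
    out = tmp_path_factory.mktemp("fixtures")
    paths = emit_fixtures(out, sim_config)
    return paths
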