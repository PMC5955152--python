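"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately coded differently from the library paths
they check (explicit loops and dict scans instead of numpy/set algebra).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def trapezoid_oracle(x, y) -> float:
    """Composite trapezoid by explicit pairwise summation."""
    total = 0.0
    for i in range(len(x) - 1):
        total += (x[i + 1] - x[i]) * (y[i] + y[i + 1]) / 2.0
    return total


def bh_oracle(pvals) -> list[float]:
    """Benjamini–Hochberg adjusted p-values by the sorted-rank definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        candidate = pvals[i] * m / rank_from_end
        running_min = min(running_min, candidate)
        adj[i] = min(running_min, 1.0)
    return adj


def venn_oracle(named_sets: dict[str, set]) -> dict[frozenset, int]:
    """Region counts by per-element scan over the union."""
    union = set()
    for s in named_sets.values():
        union |= s
    counts: dict[frozenset, int] = {}
    for el in union:
        region = frozenset(name for name, s in named_sets.items() if el in s)
        counts[region] = counts.get(region, 0) + 1
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_curve():
    from synercurve.dose_response import SurvivalCurve

    return SurvivalCurve(
        cell_line="L1",
        condition="CTRL",
        doses=(0.0, 1.0, 10.0, 100.0, 1000.0),
        survival=(1.0, 1.0, 0.8, 0.5, 0.2),
        sem=(0.0,) * 5,
    )
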