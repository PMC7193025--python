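"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chemscreen.scoring import GeneScoreTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def es_bruteforce(scores: GeneScoreTable, members: set[str], p: float) -> float:
    """Explicit double-loop enrichment score, independent of the O(N) path.

    For every prefix length j it re-sums the hit mass and miss count from
    scratch, then takes the maximum over j = 1..N.
    """
    genes = scores.gene_ids
    r = scores.scores
    N = len(genes)
    hit = [g in members for g in genes]
    n_h = sum(hit)
    n_r = sum(abs(r[i]) ** p for i in range(N) if hit[i])
    best = -np.inf
    for j in range(1, N + 1):
        hit_sum = 0.0
        misses = 0
        for i in range(j):
            if hit[i]:
                hit_sum += abs(r[i]) ** p
            else:
                misses += 1
        best = max(best, hit_sum / n_r - misses / (N - n_h))
    return best


def random_score_table(rng: np.random.Generator, n: int,
                       stream: str = "random") -> GeneScoreTable:
    scores = np.abs(rng.standard_normal(n))
    return GeneScoreTable.from_scores([f"g{i:04d}" for i in range(n)],
                                      scores, stream)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240385)


@pytest.fixture
def five_gene_table() -> GeneScoreTable:
    """The hand-checkable 5-gene universe with scores 5,4,3,2,1."""
    return GeneScoreTable.from_scores(
        ["g1", "g2", "g3", "g4", "g5"], [5.0, 4.0, 3.0, 2.0, 1.0], "toy"
    )
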