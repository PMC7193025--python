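"""Weighted running-sum gene-set enrichment with a permutation null.

For a ranked universe of N genes with scores r_1 >= ... >= r_N and a set S
of N_H member genes, the enrichment score is the maximum of the running sum

    ES(S) = max_{1<=j<=N} [ sum_{hits <= j} |r|^p / N_R
                            - sum_{misses <= j} 1 / (N - N_H) ],

with N_R = sum_{G in S} |r|^p.  The running sum ends at exactly 0 (hit mass
1 minus miss mass 1), so 0 <= ES <= 1: enrichment is one-sided toward the
top of the list, and bottom-concentrated sets score 0.  A classic
two-sided variant (maximum absolute deviation, signed) is available behind
a non-default flag.

The null is built by drawing uniformly random same-size gene subsets and
recording their ES; sets of equal size share one null.  NES standardizes
the observed ES by the null mean and SD, and the empirical p-value uses
the add-one estimator (1 + #{ES_null >= ES_obs}) / (n_perm + 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .dataio import GeneSet
from .errors import ValidationError
from .scoring import GeneScoreTable

logger = logging.getLogger(__name__)

_NULL_CHUNK = 2048  # permutation rows sampled per block, bounds memory


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the enrichment screen.

    weight_exponent : p in |r|^p; p=0 is the unweighted Kolmogorov-Smirnov
        form, p=1 (default) weighs hits by their score.
    n_permutations  : null draws per set size (default 5,000).
    min/max_set_size: sets outside [min, max] after intersection with the
        ranked universe are skipped.
    alpha           : empirical-p significance threshold.
    """

    weight_exponent: float = 1.0
    n_permutations: int = 5_000
    min_set_size: int = 5
    max_set_size: int = 500
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValidationError("weight_exponent must be >= 0")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not (1 <= self.min_set_size <= self.max_set_size):
            raise ValidationError("need 1 <= min_set_size <= max_set_size")


@dataclass(frozen=True)
class EnrichmentResult:
    chemical_name: str
    stream: str
    n_overlap: int
    es: float
    nes: float
    p_empirical: float
    significant: bool
    q_bh: float = float("nan")


def _hit_weights(scores: GeneScoreTable, p: float) -> np.ndarray:
    r = scores.scores
    if p == 0.0:
        return np.ones_like(r)
    if p == 1.0:
        return r.copy()
    return np.abs(r) ** p


def enrichment_score(
    scores: GeneScoreTable,
    gene_set: GeneSet | Iterable[str],
    p: float = 1.0,
    two_sided: bool = False,
) -> tuple[float, np.ndarray]:
    """Single-pass O(N) enrichment score with the full running sum.

    Returns ``(es, hit_curve)`` where ``hit_curve[j-1]`` is the running sum
    after position j (diagnostic).  With ``two_sided=True`` the classic
    signed maximum-absolute-deviation statistic is returned instead.

    Raises on degenerate sets: no overlap with the universe, overlap equal
    to the whole universe, or zero score mass N_R.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
    pos = scores.positions()
    N = len(scores)
    hit = np.zeros(N, dtype=bool)
    for g in members:
        i = pos.get(g)
        if i is not None:
            hit[i] = True
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValidationError("gene set has no overlap with the ranked universe")
    if n_hit == N:
        raise ValidationError("gene set covers the entire universe (N_H = N)")
    u = _hit_weights(scores, p)
    n_r = float(u[hit].sum())
    if n_r <= 0.0:
        raise ValidationError("zero total score mass N_R in gene set")
    step = np.where(hit, u / n_r, -1.0 / (N - n_hit))
    curve = np.cumsum(step)
    if two_sided:
        i = int(np.argmax(np.abs(curve)))
        return float(curve[i]), curve
    return max(float(curve.max()), 0.0), curve


def _es_from_positions(positions: np.ndarray, u: np.ndarray, N: int) -> np.ndarray:
    """Vectorized ES for many same-size sets given their rank positions.

    ``positions`` is (n_sets, k), 0-based ranks, each row sorted ascending.
    Exploits that the running sum attains its maximum immediately after a
    hit, so only k evaluations per set are needed.
    """
    k = positions.shape[1]
    U = u[positions]
    hit_mass = np.cumsum(U, axis=1)
    n_r = hit_mass[:, -1:]
    miss = (positions + 1 - np.arange(1, k + 1)) / (N - k)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = hit_mass / n_r - miss
    es = vals.max(axis=1)
    es[~np.isfinite(es)] = 0.0  # sets with zero score mass
    return np.clip(es, 0.0, None)


def permutation_null(
    scores: GeneScoreTable,
    set_size: int,
    p: float = 1.0,
    n_perm: int = 5_000,
    seed: int | np.random.SeedSequence | None = 0,
) -> np.ndarray:
    """ES null: uniformly random subsets of ``set_size`` genes, one ES each.

    Deterministic given ``seed``.  Nulls for equal set sizes can be shared
    across chemicals of that size (done by :func:`run_gsea`).
    """
    N = len(scores)
    if not (1 <= set_size < N):
        raise ValidationError(f"need 1 <= set_size < N, got {set_size} (N={N})")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    u = _hit_weights(scores, p)
    out = np.empty(n_perm, dtype=float)
    for start in range(0, n_perm, _NULL_CHUNK):
        n = min(_NULL_CHUNK, n_perm - start)
        keys = rng.random((n, N))
        positions = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        positions.sort(axis=1)
        out[start:start + n] = _es_from_positions(positions, u, N)
    return out


def normalize_and_test(es_obs: float, es_null: Sequence[float] | np.ndarray
                       ) -> tuple[float, float]:
    """NES = (ES - mean(null)) / SD(null); empirical p with add-one rule.

    SD uses denominator n-1; if the null is (numerically) constant the NES
    is reported as 0 while the p-value still comes from the counts.
    """
    es_null = np.asarray(es_null, dtype=float)
    if es_null.size < 1:
        raise ValidationError("empty permutation null")
    sd = float(es_null.std(ddof=1)) if es_null.size > 1 else 0.0
    nes = 0.0 if sd < 1e-12 else (es_obs - float(es_null.mean())) / sd
    p_emp = (1.0 + int((es_null >= es_obs).sum())) / (es_null.size + 1.0)
    return float(nes), float(p_emp)


def run_gsea(
    scores: GeneScoreTable,
    sets: Sequence[GeneSet],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentResult]:
    """Screen every chemical gene set against one ranked gene list.

    Sets are filtered on overlap size (min_set_size <= N_H <= max_set_size,
    N_H < N); survivors of equal N_H share one permutation null, seeded per
    size from ``config.seed``.  Results are sorted by empirical p-value,
    then chemical name, and carry Benjamini-Hochberg q-values alongside the
    raw-p significance flag.
    """
    N = len(scores)
    if N < 2:
        raise ValidationError("ranked universe must contain >= 2 genes")
    universe = set(scores.gene_ids)
    p = config.weight_exponent
    surviving: list[tuple[GeneSet, int]] = []
    skipped = {"no_overlap": 0, "too_small": 0, "too_large": 0, "full_universe": 0}
    for s in sets:
        n_h = len(s.members & universe)
        if n_h == 0:
            skipped["no_overlap"] += 1
        elif n_h == N:
            skipped["full_universe"] += 1
        elif n_h < config.min_set_size:
            skipped["too_small"] += 1
        elif n_h > config.max_set_size:
            skipped["too_large"] += 1
        else:
            surviving.append((s, n_h))
    if any(skipped.values()):
        logger.info("run_gsea[%s]: skipped sets by reason: %s", scores.stream, skipped)
    if not surviving:
        logger.warning("run_gsea[%s]: no gene set survives filtering", scores.stream)
        return []

    nulls: dict[int, np.ndarray] = {}
    for size in sorted({n_h for _, n_h in surviving}):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(size,))
        nulls[size] = permutation_null(scores, size, p=p,
                                       n_perm=config.n_permutations, seed=ss)

    rows: list[EnrichmentResult] = []
    for s, n_h in surviving:
        es, _ = enrichment_score(scores, s, p=p)
        nes, p_emp = normalize_and_test(es, nulls[n_h])
        rows.append(EnrichmentResult(s.chemical_name, scores.stream, n_h, es,
                                     nes, p_emp, p_emp < config.alpha))
    q = multipletests([r.p_empirical for r in rows], method="fdr_bh")[1]
    rows = [EnrichmentResult(r.chemical_name, r.stream, r.n_overlap, r.es,
                             r.nes, r.p_empirical, r.significant, float(qi))
            for r, qi in zip(rows, q)]
    rows.sort(key=lambda r: (r.p_empirical, r.chemical_name))
    return rows
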