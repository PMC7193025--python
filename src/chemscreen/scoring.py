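"""Gene-level scoring: build the ranked list that feeds enrichment analysis.

Each evidence stream reduces to the same object — a :class:`GeneScoreTable`
holding non-negative scores r_j sorted from highest to lowest:

* ``gwas_best_snp``   r_j = max |z| over SNPs within a window of gene j
* ``twas:<tissue>``   r_j = |z_twas| from the summary-based TWAS
* ``expression``      r_j = |t| from a Welch two-sample comparison

Scores are magnitudes because the downstream running-sum statistic weighs
genes by |r|^p and is one-sided toward the top of the list.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .dataio import ExpressionMatrix, GeneRecord, GwasSummary
from .errors import ValidationError
from .twas import TwasResult

logger = logging.getLogger(__name__)

#: Default SNP-to-gene assignment window in base pairs (either side).
DEFAULT_WINDOW_BP = 50_000


@dataclass(frozen=True)
class GeneScoreTable:
    """Ranked gene list: (gene_id, r >= 0) sorted by r descending.

    Ties are broken by gene_id ascending; gene_ids are unique.  ``stream``
    labels the evidence source (``gwas_best_snp``, ``twas:<tissue>``,
    ``expression``).
    """

    entries: tuple[tuple[str, float], ...]
    stream: str

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate gene_id in {self.stream} score table")
        for (g1, r1), (g2, r2) in zip(self.entries, self.entries[1:]):
            if r1 < r2 or (r1 == r2 and g1 > g2):
                raise ValidationError("score table not sorted by (r desc, gene asc)")
        if any(r < 0 for _, r in self.entries):
            raise ValidationError("scores must be non-negative")

    @classmethod
    def from_scores(cls, gene_ids: Sequence[str], scores: Sequence[float],
                    stream: str) -> "GeneScoreTable":
        order = sorted(range(len(gene_ids)),
                       key=lambda i: (-float(scores[i]), gene_ids[i]))
        return cls(tuple((gene_ids[i], float(scores[i])) for i in order), stream)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([r for _, r in self.entries], dtype=float)

    def positions(self) -> dict[str, int]:
        """gene_id -> 0-based rank position."""
        return {g: i for i, (g, _) in enumerate(self.entries)}


def score_genes_best_snp(gwas: GwasSummary, genes: Iterable[GeneRecord],
                         window_bp: int = DEFAULT_WINDOW_BP) -> GeneScoreTable:
    """Assign each gene its most significant SNP: r = max in-window |z|.

    A SNP is in-window if it lies on the gene's chromosome with position in
    ``[start - window_bp, end + window_bp]``.  Genes with no in-window SNP
    are excluded (count logged), not scored zero.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    df = gwas.table.dropna(subset=["z"])
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        order = np.argsort(grp["pos"].to_numpy())
        by_chrom[str(chrom)] = (grp["pos"].to_numpy()[order],
                                np.abs(grp["z"].to_numpy(float))[order])
    ids, scores = [], []
    n_excluded = 0
    for gene in genes:
        pos_z = by_chrom.get(gene.chrom)
        if pos_z is None:
            n_excluded += 1
            continue
        pos, absz = pos_z
        lo = np.searchsorted(pos, gene.start - window_bp, side="left")
        hi = np.searchsorted(pos, gene.end + window_bp, side="right")
        if hi <= lo:
            n_excluded += 1
            continue
        ids.append(gene.gene_id)
        scores.append(float(absz[lo:hi].max()))
    if n_excluded:
        logger.info("score_genes_best_snp: %d gene(s) with no in-window SNP excluded",
                    n_excluded)
    return GeneScoreTable.from_scores(ids, scores, "gwas_best_snp")


def score_genes_from_twas(twas: Sequence[TwasResult]) -> GeneScoreTable:
    """r = |z_twas| per gene, one tissue per call."""
    tissues = {r.tissue for r in twas}
    if len(tissues) > 1:
        raise ValidationError(f"mixed tissues in TWAS input: {sorted(tissues)}")
    tissue = tissues.pop() if tissues else "none"
    return GeneScoreTable.from_scores(
        [r.gene_id for r in twas], [abs(r.z_twas) for r in twas], f"twas:{tissue}"
    )


def score_genes_expression(expr: ExpressionMatrix) -> GeneScoreTable:
    """r = |Welch t| comparing case vs control expression per gene.

    Genes with zero variance in both groups get r = 0 with a logged
    warning rather than an error.
    """
    case = expr.group_values("case")
    control = expr.group_values("control")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes trip scipy's precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, _ = stats.ttest_ind(case, control, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.warning("score_genes_expression: %d gene(s) with zero variance "
                       "in both groups scored 0", int(degenerate.sum()))
        t[degenerate] = 0.0
    return GeneScoreTable.from_scores(expr.gene_ids, np.abs(t), "expression")
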