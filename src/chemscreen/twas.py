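"""Summary-based TWAS association statistics.

A transcriptome-wide association study (TWAS) tests each gene by combining
three summary-level ingredients: the GWAS z-scores ``Z`` of the SNPs in the
gene's expression model, the eQTL weight vector ``w`` of that model, and the
SNP-correlation (LD) matrix ``L`` from a reference panel.  The gene-level
statistic is

    z_twas = w'Z / sqrt(w'Lw)

which is standard normal when the GWAS z-scores are null draws from
``MVN(0, L)``.  A two-sided normal p-value is attached per gene and tissue.

Weight training (elastic net / BLUP on individual-level genotypes) and
allele harmonization are out of scope: weights and z-scores are assumed
pre-aligned to the same effect allele.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateModelError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .dataio import GwasSummary

logger = logging.getLogger(__name__)

#: Ridge mixing coefficient used by :func:`run_twas` to guard near-singular
#: LD blocks: L <- (1 - tau) L + tau I.
DEFAULT_LD_RIDGE = 0.01

#: Below this value of w'Lw a model is considered degenerate and skipped.
QUADRATIC_FORM_TOL = 1e-10


@dataclass(frozen=True)
class GeneModel:
    """Per-gene, per-tissue expression weight vector aligned to SNP ids."""

    gene_id: str
    tissue: str
    snp_ids: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if w.ndim != 1 or len(self.snp_ids) != w.shape[0] or w.shape[0] < 1:
            raise ValidationError(
                f"gene {self.gene_id}: weight vector and snp_ids must be "
                f"1-D and of equal nonzero length"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError(f"gene {self.gene_id}: duplicate snp_ids in model")


@dataclass(frozen=True)
class LdBlock:
    """SNP-correlation matrix for one gene's cis region.

    Symmetric with unit diagonal; eigenvalues may only dip below zero by
    numerical noise (>= -1e-8 before any regularization).
    """

    snp_ids: tuple[str, ...]
    L: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        m = len(self.snp_ids)
        if L.shape != (m, m):
            raise ValidationError(f"LD matrix shape {L.shape} != ({m}, {m})")
        if not np.allclose(L, L.T, atol=1e-8):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(L), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal is not 1 within 1e-8")
        if m <= 200:  # eigendecomposition is cheap at cis-block sizes
            if np.linalg.eigvalsh(L).min() < -1e-8:
                raise ValidationError("LD matrix has eigenvalue < -1e-8")


@dataclass(frozen=True)
class TwasResult:
    gene_id: str
    tissue: str
    z_twas: float
    p: float


def _regularized(L: np.ndarray, ridge: float) -> np.ndarray:
    if ridge == 0.0:
        return L
    return (1.0 - ridge) * L + ridge * np.eye(L.shape[0])


def twas_z(
    model: GeneModel,
    ld: LdBlock,
    z: Sequence[float] | np.ndarray,
    ridge: float = 0.0,
) -> float:
    """Gene-level association statistic ``w'Z / sqrt(w'Lw)``.

    ``model``, ``ld`` and ``z`` must be aligned on an identical SNP order.
    ``ridge`` mixes the LD matrix toward the identity before the quadratic
    form; pipelines pass :data:`DEFAULT_LD_RIDGE`, direct calls default to
    the exact formula.

    Raises
    ------
    DegenerateModelError
        If w'Lw falls below :data:`QUADRATIC_FORM_TOL` after regularization.
    """
    if model.snp_ids != ld.snp_ids:
        raise ValidationError(
            f"gene {model.gene_id}: model and LD block disagree on SNP order"
        )
    z = np.asarray(z, dtype=float)
    if z.shape != model.w.shape:
        raise ValidationError(
            f"gene {model.gene_id}: z-vector length {z.shape} does not match "
            f"model ({model.w.shape})"
        )
    L = _regularized(ld.L, ridge)
    denom = float(model.w @ L @ model.w)
    if denom <= QUADRATIC_FORM_TOL:
        raise DegenerateModelError(
            f"gene {model.gene_id}: w'Lw = {denom:.3g} below tolerance"
        )
    return float(model.w @ z) / math.sqrt(denom)


def twas_pvalue(z_twas: float) -> float:
    """Two-sided standard-normal p-value, clipped to [1e-300, 1]."""
    if not math.isfinite(z_twas):
        raise ValidationError(f"non-finite TWAS statistic: {z_twas!r}")
    p = 2.0 * stats.norm.sf(abs(z_twas))
    return float(min(1.0, max(p, 1e-300)))


def run_twas(
    gwas: "GwasSummary",
    models: Iterable[GeneModel],
    ld: Mapping[str, LdBlock],
    ridge: float = DEFAULT_LD_RIDGE,
) -> list[TwasResult]:
    """Compute TWAS statistics for every computable gene model.

    Model SNPs missing from the GWAS summary are dropped jointly from
    ``w``, ``L`` and ``Z``; a gene with no SNP left, or with a degenerate
    quadratic form, is skipped and counted in the log.
    """
    zmap = gwas.z_map()
    results: list[TwasResult] = []
    n_skipped_empty = n_skipped_degenerate = n_partial = 0
    for model in models:
        block = ld[model.gene_id]
        keep = [i for i, s in enumerate(model.snp_ids) if s in zmap and not math.isnan(zmap[s])]
        if len(keep) < len(model.snp_ids):
            n_partial += 1
        if not keep:
            n_skipped_empty += 1
            continue
        if len(keep) < len(model.snp_ids):
            idx = np.asarray(keep)
            snps = tuple(model.snp_ids[i] for i in keep)
            model = GeneModel(model.gene_id, model.tissue, snps, model.w[idx])
            block = LdBlock(snps, block.L[np.ix_(idx, idx)])
        zvec = np.array([zmap[s] for s in model.snp_ids])
        try:
            zt = twas_z(model, block, zvec, ridge=ridge)
        except DegenerateModelError:
            n_skipped_degenerate += 1
            continue
        results.append(TwasResult(model.gene_id, model.tissue, zt, twas_pvalue(zt)))
    if n_partial or n_skipped_empty or n_skipped_degenerate:
        logger.warning(
            "run_twas: %d genes with partially missing SNPs, %d skipped "
            "(no SNPs), %d skipped (degenerate w'Lw)",
            n_partial, n_skipped_empty, n_skipped_degenerate,
        )
    if not results:
        logger.warning("run_twas: no computable genes; returning empty result")
    return results
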