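"""Synthetic inputs with the statistical structure the pipeline assumes.

Real applications of this pipeline consume GWAS summary statistics, per-gene
eQTL weight models with an LD reference, CTD-style chemical gene sets, and a
two-group expression matrix.  This module generates all four with planted
effects so that every downstream stage can be tested for calibration and
power without any external download.

Generative model
----------------
* LD: one AR(1) correlation block per gene, ``L[i, j] = rho^|i-j|`` —
  positive definite with realistic decay.
* Weights: per gene, i.i.d. standard-normal entries rescaled so
  ``w'Lw = 1``; the TWAS denominator is then unit by construction.
* GWAS z-scores: per gene ``Z = lambda * L w / sqrt(w'Lw) + eps`` with
  ``eps ~ MVN(0, L)`` for causal genes and ``eps`` alone otherwise, so the
  downstream TWAS statistic has expectation ``lambda`` for causal genes and
  is standard normal for null genes.
* Chemical sets: uniformly sized member samples from the gene universe
  (overlap allowed); the first ``n_causal_chemicals`` sets are causal and
  contribute a ``causal_fraction`` share of their members to the causal
  gene pool.
* Expression: unit-normal log intensities; case samples of causal genes are
  shifted by ``+expr_effect``.

Effects enter through the means of exactly the statistics the pipeline
computes (no individual-level genotypes are simulated).  A single global
seed fans out to fixed-offset child seeds per component, so each generator
is independently reproducible.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .dataio import (ExpressionMatrix, GeneRecord, GeneSet, GwasSummary,
                     write_expression, write_gene_records, write_gmt,
                     write_gwas_summary, write_ld_matrix, write_weights)
from .errors import ValidationError
from .twas import GeneModel, LdBlock

_GENE_SPAN_BP = 50_000
_GENE_SLOT_BP = 1_000_000
_N_CHROMS = 22

# fixed spawn keys: one child seed stream per generator component
_KEY_SETS = 0
_KEY_WEIGHTS = 1
_KEY_GWAS = 2
_KEY_EXPR = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a desk-scale study: 2,000 genes with 10 SNPs each under
    AR(1) LD (rho = 0.5), 500 chemical sets of 10-200 genes of which 5 are
    causal, TWAS effect lambda = 4, expression shift delta = 1, and the
    77-case / 117-control sample split of a tumor-vs-mucosa comparison.
    """

    n_genes: int = 2_000
    n_snps_per_gene: int = 10
    ld_rho: float = 0.5
    n_chemicals: int = 500
    set_size_range: tuple[int, int] = (10, 200)
    n_causal_chemicals: int = 5
    causal_fraction: float = 0.5
    twas_effect: float = 4.0
    expr_effect: float = 1.0
    n_case: int = 77
    n_control: int = 117
    seed: int = 0
    tissues: tuple[str, ...] = ("colon", "whole_blood")

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_size_range", tuple(self.set_size_range))
        object.__setattr__(self, "tissues", tuple(self.tissues))
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValidationError("set_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ValidationError("set_size_range max cannot exceed n_genes")
        if self.n_causal_chemicals > self.n_chemicals:
            raise ValidationError("n_causal_chemicals cannot exceed n_chemicals")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValidationError("causal_fraction must lie in (0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValidationError("ld_rho must lie in [0, 1)")
        if self.twas_effect < 0 or self.expr_effect < 0:
            raise ValidationError("effect sizes must be >= 0")
        for name in ("n_genes", "n_snps_per_gene", "n_chemicals",
                     "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("each expression group needs >= 2 samples")


@dataclass(frozen=True)
class GroundTruth:
    """Planted causal chemicals and the genes that carry their effects."""

    causal_chemicals: frozenset[str]
    causal_genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "causal_chemicals", frozenset(self.causal_chemicals))
        object.__setattr__(self, "causal_genes", frozenset(self.causal_genes))


def child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    """Fixed-offset child seed: component streams are independent."""
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))


def make_gene_records(n_genes: int) -> list[GeneRecord]:
    """Deterministic gene grid: 50 kb genes in 1 Mb slots over 22 chromosomes."""
    genes = []
    for i in range(n_genes):
        chrom = str(i % _N_CHROMS + 1)
        start = (i // _N_CHROMS) * _GENE_SLOT_BP + 1
        genes.append(GeneRecord(f"G{i:05d}", chrom, start, start + _GENE_SPAN_BP - 1))
    return genes


def _snp_ids(gene: GeneRecord, n_snps: int) -> tuple[str, ...]:
    return tuple(f"{gene.gene_id}_s{j}" for j in range(n_snps))


def _snp_positions(gene: GeneRecord, n_snps: int) -> list[int]:
    if n_snps == 1:
        return [gene.start]
    step = (gene.end - gene.start) // (n_snps - 1)
    return [gene.start + j * step for j in range(n_snps)]


def simulate_ld_block(m: int, rho: float,
                      seed: int | None = None) -> np.ndarray:
    """AR(1) correlation matrix with entries rho^|i-j| (deterministic; the
    ``seed`` argument exists for interface symmetry with the other
    generators and is unused)."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValidationError("rho must lie in [0, 1)")
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_weights(
    genes: Sequence[GeneRecord],
    n_snps: int,
    ld: np.ndarray,
    seed: int | np.random.SeedSequence,
    tissue: str = "sim",
) -> list[GeneModel]:
    """Per gene, standard-normal weights rescaled so that w'Lw = 1."""
    if n_snps < 1:
        raise ValidationError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    models = []
    for gene in genes:
        w = rng.standard_normal(n_snps)
        w /= np.sqrt(w @ ld @ w)
        models.append(GeneModel(gene.gene_id, tissue, _snp_ids(gene, n_snps), w))
    return models


def simulate_gwas_z(
    models: Sequence[GeneModel],
    ld: np.ndarray,
    genes: Sequence[GeneRecord],
    truth: GroundTruth,
    lam: float,
    seed: int | np.random.SeedSequence,
) -> GwasSummary:
    """Per-gene SNP z-vectors: Z = lambda * Lw / sqrt(w'Lw) + MVN(0, L) noise
    for causal genes, noise alone otherwise; E[z_twas] = lambda for causal
    genes, standard normal for the rest."""
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if len(models) != len(genes):
        raise ValidationError("models and genes must align one-to-one")
    m = ld.shape[0]
    chol = np.linalg.cholesky(ld)
    rng = np.random.default_rng(seed)
    rows: dict[str, list] = {c: [] for c in
                             ("snp_id", "chrom", "pos", "effect_allele",
                              "other_allele", "z")}
    eps = rng.standard_normal((len(models), m)) @ chol.T
    for g, (model, gene) in enumerate(zip(models, genes)):
        if model.w.shape[0] != m:
            raise ValidationError(
                f"gene {model.gene_id}: model has {model.w.shape[0]} SNPs, "
                f"LD block is {m}x{m}"
            )
        z = eps[g]
        if gene.gene_id in truth.causal_genes:
            z = z + lam * (ld @ model.w) / np.sqrt(model.w @ ld @ model.w)
        rows["snp_id"].extend(model.snp_ids)
        rows["chrom"].extend([gene.chrom] * m)
        rows["pos"].extend(_snp_positions(gene, m))
        rows["effect_allele"].extend(["A"] * m)
        rows["other_allele"].extend(["G"] * m)
        rows["z"].extend(z.tolist())
    df = pd.DataFrame(rows)
    df["p"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
    return GwasSummary(df)


def simulate_gene_sets(config: SimulationConfig) -> tuple[list[GeneSet], GroundTruth]:
    """Chemical gene sets with a designated causal subset.

    Sizes are uniform over ``set_size_range``; members are sampled without
    replacement per set from the gene universe (overlap across sets is
    allowed).  The first ``n_causal_chemicals`` sets are causal; each
    contributes a ``causal_fraction`` share of its members (at least one)
    to the causal gene pool.
    """
    rng = np.random.default_rng(child_seed(config.seed, _KEY_SETS))
    gene_ids = [g.gene_id for g in make_gene_records(config.n_genes)]
    lo, hi = config.set_size_range
    sets: list[GeneSet] = []
    causal_genes: set[str] = set()
    for i in range(config.n_chemicals):
        size = int(rng.integers(lo, hi + 1))
        members = [gene_ids[j] for j in
                   rng.choice(config.n_genes, size=size, replace=False)]
        sets.append(GeneSet(f"chem{i:04d}", f"SIM:{i:04d}", frozenset(members)))
        if i < config.n_causal_chemicals:
            k = max(1, int(round(config.causal_fraction * size)))
            picked = rng.choice(size, size=k, replace=False)
            causal_genes.update(members[j] for j in picked)
    truth = GroundTruth(
        frozenset(s.chemical_name for s in sets[: config.n_causal_chemicals]),
        frozenset(causal_genes),
    )
    return sets, truth


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    seed: int | np.random.SeedSequence | None = None,
) -> ExpressionMatrix:
    """Unit-normal expression; causal genes shifted by +expr_effect in cases."""
    if seed is None:
        seed = child_seed(config.seed, _KEY_EXPR)
    rng = np.random.default_rng(seed)
    genes = [g.gene_id for g in make_gene_records(config.n_genes)]
    n_samples = config.n_case + config.n_control
    values = rng.standard_normal((config.n_genes, n_samples))
    causal_rows = [i for i, g in enumerate(genes) if g in truth.causal_genes]
    values[np.ix_(causal_rows, range(config.n_case))] += config.expr_effect
    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[f"S{i:04d}" for i in range(n_samples)],
        values=values,
        group_labels=["case"] * config.n_case + ["control"] * config.n_control,
    )


# ---------------------------------------------------------------------------
# one-disease bundles and on-disk layout
# ---------------------------------------------------------------------------

@dataclass
class SimulatedInputs:
    """Everything one disease's pipeline run needs, plus the ground truth."""

    config: SimulationConfig
    genes: list[GeneRecord]
    ld: np.ndarray
    models: dict[str, list[GeneModel]]        # tissue -> models
    gwas: dict[str, GwasSummary]              # tissue -> summary stats
    gene_sets: list[GeneSet]
    truth: GroundTruth
    expression: ExpressionMatrix


def simulate_inputs(config: SimulationConfig,
                    disease_index: int = 0) -> SimulatedInputs:
    """Generate all inputs for one disease.

    ``disease_index`` shifts the GWAS-noise and expression child seeds so
    several diseases can share one config (and hence one chemical-set
    collection and causal-gene pool) while drawing independent data.
    """
    genes = make_gene_records(config.n_genes)
    ld = simulate_ld_block(config.n_snps_per_gene, config.ld_rho)
    gene_sets, truth = simulate_gene_sets(config)
    models: dict[str, list[GeneModel]] = {}
    gwas: dict[str, GwasSummary] = {}
    for t, tissue in enumerate(config.tissues):
        models[tissue] = simulate_weights(
            genes, config.n_snps_per_gene, ld,
            child_seed(config.seed, _KEY_WEIGHTS, t), tissue=tissue,
        )
        gwas[tissue] = simulate_gwas_z(
            models[tissue], ld, genes, truth, config.twas_effect,
            child_seed(config.seed, _KEY_GWAS, disease_index, t),
        )
    expression = simulate_expression(
        config, truth, child_seed(config.seed, _KEY_EXPR, disease_index)
    )
    return SimulatedInputs(config, genes, ld, models, gwas, gene_sets, truth,
                           expression)


def write_inputs(inputs: SimulatedInputs, out_dir: str | Path) -> None:
    """Write one disease's inputs in the pipeline's on-disk layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_records(inputs.genes, out / "genes.tsv")
    write_gmt(inputs.gene_sets, out / "chemsets.gmt")
    for tissue in inputs.config.tissues:
        write_weights(inputs.models[tissue], out / f"weights_{tissue}.tsv")
        write_gwas_summary(inputs.gwas[tissue], out / f"gwas_{tissue}.tsv")
    ld_dir = out / "ld"
    ld_dir.mkdir(exist_ok=True)
    tissue0 = inputs.config.tissues[0]
    for model in inputs.models[tissue0]:
        write_ld_matrix(LdBlock(model.snp_ids, inputs.ld),
                        ld_dir / f"{model.gene_id}.tsv")
    write_expression(inputs.expression, out / "expression.tsv", out / "groups.tsv")
    truth = {"causal_chemicals": sorted(inputs.truth.causal_chemicals),
             "causal_genes": sorted(inputs.truth.causal_genes)}
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def load_config(path: str | Path) -> SimulationConfig:
    """Load a flat-YAML mirror of :class:`SimulationConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["set_size_range"] = list(config.set_size_range)
    d["tissues"] = list(config.tissues)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
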