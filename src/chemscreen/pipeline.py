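"""End-to-end orchestration: simulate -> TWAS -> score -> GSEA -> integrate.

A "study" is one or more diseases screened against a shared chemical
gene-set collection.  Each disease contributes one GWAS/TWAS stream per
tissue plus one expression stream; the integration step intersects the
significant chemicals across streams and diseases.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .dataio import write_results_table
from .gsea import EnrichmentConfig, EnrichmentResult, run_gsea
from .integration import IntegrationReport, StreamIntersection, build_report
from .scoring import (GeneScoreTable, score_genes_best_snp,
                      score_genes_expression, score_genes_from_twas)
from .synthetic import SimulatedInputs, SimulationConfig, simulate_inputs, write_inputs
from .twas import LdBlock, TwasResult, run_twas

logger = logging.getLogger(__name__)

DEFAULT_DISEASES = ("colon_cancer", "rectal_cancer")


@dataclass
class DiseaseRun:
    disease: str
    inputs: SimulatedInputs
    twas: dict[str, list[TwasResult]]               # tissue -> results
    scores: dict[str, GeneScoreTable]               # stream -> ranked list
    enrichment: dict[str, list[EnrichmentResult]]   # stream -> GSEA results


@dataclass
class StudyRun:
    config: SimulationConfig
    enrichment_config: EnrichmentConfig
    diseases: dict[str, DiseaseRun]
    report: IntegrationReport


def run_disease(
    config: SimulationConfig,
    enrichment_config: EnrichmentConfig,
    disease: str = "disease",
    disease_index: int = 0,
    gwas_scoring: str = "twas",
) -> DiseaseRun:
    """Simulate one disease's inputs and run every stream through GSEA.

    ``gwas_scoring`` selects the GWAS-side gene score: ``"twas"`` (default,
    tissue-stratified |z_twas|) or ``"best_snp"`` (max |z| of SNPs within a
    window of each gene, one untissued stream).
    """
    inputs = simulate_inputs(config, disease_index=disease_index)
    twas_by_tissue: dict[str, list[TwasResult]] = {}
    scores: dict[str, GeneScoreTable] = {}

    if gwas_scoring == "twas":
        for tissue in config.tissues:
            models = inputs.models[tissue]
            ld = {m.gene_id: LdBlock(m.snp_ids, inputs.ld) for m in models}
            res = run_twas(inputs.gwas[tissue], models, ld)
            twas_by_tissue[tissue] = res
            scores[f"twas:{tissue}"] = score_genes_from_twas(res)
    elif gwas_scoring == "best_snp":
        # one GWAS-side stream per tissue's summary file, best-SNP scored
        for tissue in config.tissues:
            table = score_genes_best_snp(inputs.gwas[tissue], inputs.genes)
            scores[f"gwas_best_snp:{tissue}"] = dataclasses.replace(
                table, stream=f"gwas_best_snp:{tissue}"
            )
    else:
        raise ValueError(f"unknown gwas_scoring {gwas_scoring!r}")

    scores["expression"] = score_genes_expression(inputs.expression)

    enrichment: dict[str, list[EnrichmentResult]] = {}
    for i, (stream, table) in enumerate(sorted(scores.items())):
        cfg = dataclasses.replace(
            enrichment_config,
            seed=enrichment_config.seed + 1009 * disease_index + i,
        )
        enrichment[stream] = run_gsea(table, inputs.gene_sets, cfg)
    return DiseaseRun(disease, inputs, twas_by_tissue, scores, enrichment)


def run_study(
    config: SimulationConfig,
    enrichment_config: EnrichmentConfig = EnrichmentConfig(),
    diseases: Sequence[str] = DEFAULT_DISEASES,
    gwas_scoring: str = "twas",
) -> StudyRun:
    """Run the full multi-disease study and integrate the results.

    All diseases share the chemical gene-set collection and causal-gene
    pool drawn from ``config``; GWAS and expression noise are independent
    per disease.
    """
    runs: dict[str, DiseaseRun] = {}
    for d, disease in enumerate(diseases):
        runs[disease] = run_disease(config, enrichment_config, disease,
                                    disease_index=d, gwas_scoring=gwas_scoring)
    report = build_report(
        {name: run.enrichment for name, run in runs.items()},
        alpha=enrichment_config.alpha,
    )
    return StudyRun(config, enrichment_config, runs, report)


# ---------------------------------------------------------------------------
# on-disk study layout
# ---------------------------------------------------------------------------

def _write_twas(results: Sequence[TwasResult], path: Path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.tissue, r.z_twas, r.p) for r in results],
        columns=["gene_id", "tissue", "z_twas", "p"],
    ).to_csv(path, sep="\t", index=False)


def _write_scores(table: GeneScoreTable, path: Path) -> None:
    pd.DataFrame(
        [(g, r, i + 1) for i, (g, r) in enumerate(table.entries)],
        columns=["gene_id", "score", "rank"],
    ).to_csv(path, sep="\t", index=False)


def run_all(
    config: SimulationConfig,
    enrichment_config: EnrichmentConfig,
    out_dir: str | Path,
    diseases: Sequence[str] = DEFAULT_DISEASES,
    gwas_scoring: str = "twas",
) -> StudyRun:
    """Run the full study and write every stage's inputs and outputs.

    Layout: ``<out>/<disease>/inputs/``, ``twas_<tissue>.tsv``,
    ``scores_<stream>.tsv``, ``gsea_<stream>.tsv``; integration report at
    the top level.  Deterministic given the config seeds: two runs with
    identical configs produce byte-identical trees.
    """
    out = Path(out_dir)
    study = run_study(config, enrichment_config, diseases, gwas_scoring)
    for name, run in study.diseases.items():
        ddir = out / name
        ddir.mkdir(parents=True, exist_ok=True)
        write_inputs(run.inputs, ddir / "inputs")
        for tissue, res in run.twas.items():
            _write_twas(res, ddir / f"twas_{tissue}.tsv")
        for stream, table in run.scores.items():
            _write_scores(table, ddir / f"scores_{stream.replace(':', '_')}.tsv")
        for stream, res in run.enrichment.items():
            write_results_table(res, ddir / f"gsea_{stream.replace(':', '_')}.tsv")
    study.report.write(out)
    return study
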