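"""Cross-evidence intersection of significant chemicals.

A chemical counts as "common" for a disease when it is significant in the
expression-side enrichment screen AND in at least one GWAS/TWAS-side tissue
screen.  With several tissues the per-tissue counts are kept alongside the
multi-tissue overlap, so that |union| = sum of tissue counts minus the
overlap.  Chemicals absent (untested) from a stream are never declared
common — absence is not non-significance.  Across diseases, the pan-disease
common set is the exact name intersection of the per-disease common sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .gsea import EnrichmentResult


def _significant_names(results: Sequence[EnrichmentResult], alpha: float) -> set[str]:
    return {r.chemical_name for r in results if r.p_empirical < alpha}


@dataclass(frozen=True)
class StreamIntersection:
    """Expression-vs-GWAS-side common chemicals for one disease."""

    common: frozenset[str]
    per_tissue: dict[str, frozenset[str]]     # stream label -> common with expr
    multi_tissue: frozenset[str]              # common in >= 2 tissue streams

    @property
    def counts(self) -> dict[str, int]:
        out = {label: len(v) for label, v in self.per_tissue.items()}
        out["multi_tissue"] = len(self.multi_tissue)
        out["total"] = len(self.common)
        return out


def intersect_streams_detail(
    gwas_side: Mapping[str, Sequence[EnrichmentResult]],
    expr_side: Sequence[EnrichmentResult],
    alpha: float = 0.05,
) -> StreamIntersection:
    """Chemicals significant in expression and in >= 1 GWAS-side tissue.

    ``gwas_side`` maps a stream label (one per tissue) to its enrichment
    results.  The per-tissue breakdown satisfies
    ``total = sum(per-tissue) - multi-tissue overlap`` for two tissues and,
    in general, inclusion-exclusion over the tissue sets.
    """
    expr_sig = _significant_names(expr_side, alpha)
    per_tissue: dict[str, frozenset[str]] = {}
    for label, results in gwas_side.items():
        per_tissue[label] = frozenset(_significant_names(results, alpha) & expr_sig)
    common: set[str] = set().union(*per_tissue.values()) if per_tissue else set()
    multi = {c for c in common
             if sum(c in v for v in per_tissue.values()) >= 2}
    return StreamIntersection(frozenset(common), per_tissue, frozenset(multi))


def intersect_streams(
    gwas_side: Mapping[str, Sequence[EnrichmentResult]],
    expr_side: Sequence[EnrichmentResult],
    alpha: float = 0.05,
) -> set[str]:
    """Common-chemical names only; see :func:`intersect_streams_detail`."""
    return set(intersect_streams_detail(gwas_side, expr_side, alpha).common)


def common_chemicals(*per_disease_common: set[str] | frozenset[str]) -> set[str]:
    """Exact name intersection of per-disease common-chemical sets."""
    if not per_disease_common:
        return set()
    out = set(per_disease_common[0])
    for s in per_disease_common[1:]:
        out &= set(s)
    return out


@dataclass
class IntegrationReport:
    """Per-chemical significance bookkeeping across diseases and streams.

    ``table`` has one row per chemical seen in any stream, with per-stream
    p-values and significance flags (NA when the chemical was not tested in
    a stream), membership flags per intersection, and ``counts`` the
    cardinalities of every intersection region.
    """

    table: pd.DataFrame
    per_disease: dict[str, StreamIntersection]
    pan_common: frozenset[str]
    counts: dict[str, int]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "report.tsv", sep="\t", index=False, na_rep=".")
        rows = sorted(self.counts.items())
        pd.DataFrame(rows, columns=["region", "count"]).to_csv(
            out / "venn_counts.tsv", sep="\t", index=False
        )
        (out / "common_chemicals.txt").write_text(
            "".join(f"{c}\n" for c in sorted(self.pan_common))
        )


def build_report(
    results: Mapping[str, Mapping[str, Sequence[EnrichmentResult]]],
    alpha: float = 0.05,
    expression_stream: str = "expression",
) -> IntegrationReport:
    """Assemble the cross-evidence report.

    ``results[disease][stream]`` are one screen's enrichment results; each
    disease must contain the ``expression_stream`` plus one or more
    GWAS/TWAS-side streams.  The pan-disease common set is the intersection
    of every disease's common set.
    """
    if not results:
        raise ValidationError("no results to integrate")
    per_disease: dict[str, StreamIntersection] = {}
    pvals: dict[tuple[str, str], dict[str, float]] = {}
    for disease, streams in results.items():
        if expression_stream not in streams:
            raise ValidationError(
                f"disease {disease!r} lacks the {expression_stream!r} stream"
            )
        gwas_side = {s: r for s, r in streams.items() if s != expression_stream}
        if not gwas_side:
            raise ValidationError(f"disease {disease!r} has no GWAS-side stream")
        per_disease[disease] = intersect_streams_detail(
            gwas_side, streams[expression_stream], alpha
        )
        for stream, rs in streams.items():
            pvals[(disease, stream)] = {r.chemical_name: r.p_empirical for r in rs}

    pan = frozenset(common_chemicals(*(s.common for s in per_disease.values())))

    chemicals = sorted({c for m in pvals.values() for c in m})
    rows = []
    for chem in chemicals:
        row: dict[str, object] = {"chemical": chem}
        for (disease, stream), pmap in sorted(pvals.items()):
            p = pmap.get(chem)
            row[f"p[{disease}|{stream}]"] = p
            row[f"sig[{disease}|{stream}]"] = (None if p is None else p < alpha)
        for disease, inter in per_disease.items():
            row[f"common[{disease}]"] = chem in inter.common
        row["pan_common"] = chem in pan
        rows.append(row)
    table = pd.DataFrame(rows)

    counts: dict[str, int] = {"pan_common": len(pan)}
    for disease, inter in per_disease.items():
        for label, n in inter.counts.items():
            counts[f"{disease}:{label}"] = n
    return IntegrationReport(table, per_disease, pan, counts)
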