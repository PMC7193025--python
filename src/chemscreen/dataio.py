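"""Readers and writers for every on-disk format the pipeline touches.

All tables are UTF-8, tab-separated, with a mandatory header row; ``.``
denotes a missing value.  Genomic coordinates are 1-based inclusive, the
GWAS-summary convention.  Chemical names are opaque keys: matching across
evidence streams is exact string equality after whitespace trimming.

Formats
-------
GWAS summary     snp_id, chrom, pos, effect_allele, other_allele, z, p
                 (z reconstructed from p + direction when absent)
GMT              one gene set per line: name TAB description TAB members...
weights          long TSV: gene_id, snp_id, weight (one tissue per file)
LD matrix        square TSV per gene, header row of SNP ids, unit diagonal
expression       genes x samples TSV plus a two-column sample->group file
results          chemical, stream, n_overlap, es, nes, p_empirical, ...
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

MISSING = "."

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "z", "p"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association statistics for a trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    z: float
    p: float


class GwasSummary:
    """Validated collection of per-SNP association statistics.

    Wraps a DataFrame with columns ``snp_id, chrom, pos, effect_allele,
    other_allele, z, p``.  Invariants: snp_id non-empty and unique,
    pos >= 1, p in (0, 1], and p consistent with z under a two-sided
    normal test within 1e-6 whenever both are present.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ("snp_id", "chrom", "pos") if c not in table.columns]
        if missing:
            raise SchemaError(f"GWAS summary missing required column(s): {missing}")
        if "z" not in table.columns and "p" not in table.columns:
            raise SchemaError("GWAS summary needs at least one of columns 'z', 'p'")
        df = table.copy()
        for col in GWAS_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("z", "p") else MISSING
        df = df[GWAS_COLUMNS].reset_index(drop=True)
        df["snp_id"] = df["snp_id"].astype(str)
        df["pos"] = df["pos"].astype(int)
        df["z"] = pd.to_numeric(df["z"], errors="coerce")
        df["p"] = pd.to_numeric(df["p"], errors="coerce")
        if (df["snp_id"].str.len() == 0).any():
            raise ValidationError("empty snp_id")
        dup = df["snp_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate snp_id(s): {sorted(df.loc[dup, 'snp_id'].unique())[:5]}"
            )
        if (df["pos"] < 1).any():
            raise ValidationError("pos must be >= 1 (1-based coordinates)")
        has_z = df["z"].notna()
        has_p = df["p"].notna()
        if ((df.loc[has_p, "p"] <= 0) | (df.loc[has_p, "p"] > 1)).any():
            raise ValidationError("p-values must lie in (0, 1]")
        # fill whichever of z/p is derivable from the other
        df.loc[has_z & ~has_p, "p"] = 2.0 * stats.norm.sf(np.abs(df.loc[has_z & ~has_p, "z"]))
        both = has_z & has_p
        if both.any():
            expect = 2.0 * stats.norm.sf(np.abs(df.loc[both, "z"]))
            bad = np.abs(expect - df.loc[both, "p"]) > 1e-6
            if bad.any():
                snp = df.loc[both].loc[bad.values, "snp_id"].iloc[0]
                raise ValidationError(
                    f"p inconsistent with z under two-sided normal test (e.g. {snp})"
                )
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def z_map(self) -> dict[str, float]:
        """snp_id -> z lookup (NaN for SNPs lacking a z-score)."""
        return dict(zip(self.table["snp_id"], self.table["z"]))

    def records(self) -> Iterator[SnpAssociation]:
        for row in self.table.itertuples(index=False):
            yield SnpAssociation(row.snp_id, str(row.chrom), int(row.pos),
                                 row.effect_allele, row.other_allele,
                                 float(row.z), float(row.p))


@dataclass(frozen=True)
class GeneRecord:
    """Gene span in 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: 1-based start must be >= 1")


@dataclass(frozen=True)
class GeneSet:
    """One chemical's interacting-gene set (CTD-style)."""

    chemical_name: str
    source_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"gene set {self.chemical_name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExpressionMatrix:
    """Two-group (case/control) log-scale expression matrix, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValidationError("one group label required per sample")
        bad = set(self.group_labels) - {"case", "control"}
        if bad:
            raise ValidationError(f"group labels must be 'case'/'control', got {bad}")
        for grp in ("case", "control"):
            if self.group_labels.count(grp) < 2:
                raise ValidationError(f"group {grp!r} needs >= 2 samples")

    def group_values(self, group: str) -> np.ndarray:
        cols = [i for i, g in enumerate(self.group_labels) if g == group]
        return self.values[:, cols]


# ---------------------------------------------------------------------------
# GWAS summary
# ---------------------------------------------------------------------------

def read_gwas_summary(path: str | Path) -> GwasSummary:
    """Read a tab-separated GWAS summary file.

    Requires header columns ``snp_id, chrom, pos`` and at least one of
    ``z`` / ``p``.  If only p is given together with a ``direction`` column
    (``+``/``-``), z is reconstructed as the signed two-sided normal
    quantile ``sign * Phi^-1(1 - p/2)``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str},
                     na_values=[MISSING], keep_default_na=False)
    required = [c for c in ("snp_id", "chrom", "pos") if c not in df.columns]
    if required:
        raise SchemaError(f"{path}: missing required column(s): {required}")
    if "z" not in df.columns and "p" not in df.columns:
        raise SchemaError(f"{path}: needs at least one of columns 'z', 'p'")
    if "z" not in df.columns and "direction" in df.columns:
        sign = df["direction"].map({"+": 1.0, "-": -1.0})
        if sign.isna().any():
            row = int(sign.isna().idxmax()) + 2  # +2: header + 1-based
            raise ParseError(f"{path}:{row}: direction must be '+' or '-'")
        df["z"] = sign * stats.norm.isf(pd.to_numeric(df["p"]) / 2.0)
    return GwasSummary(df)


def write_gwas_summary(gwas: GwasSummary, path: str | Path) -> None:
    df = gwas.table.copy()
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# gene records
# ---------------------------------------------------------------------------

def read_gene_records(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in ("gene_id", "chrom", "start", "end") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id")
    return [GeneRecord(r.gene_id, str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def write_gene_records(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         "chrom": [g.chrom for g in genes],
         "start": [g.start for g in genes],
         "end": [g.end for g in genes]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: ``name TAB description TAB member TAB member...``

    Set order is preserved; duplicate members within a line are collapsed.
    A line with fewer than 3 fields raises :class:`ParseError` naming the
    line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, source_id = fields[0].strip(), fields[1].strip()
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            sets.append(GeneSet(name, source_id, members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.chemical_name, s.source_id, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# expression weights + LD
# ---------------------------------------------------------------------------

def read_weights(path: str | Path, tissue: str) -> "dict[str, object]":
    """Read a per-tissue weights TSV (gene_id, snp_id, weight).

    Returns an ordered mapping gene_id -> GeneModel; SNP order within a
    gene follows file order.
    """
    from .twas import GeneModel

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "snp_id": str})
    missing = [c for c in ("gene_id", "snp_id", "weight") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    models: dict[str, GeneModel] = {}
    for gene_id, grp in df.groupby("gene_id", sort=False):
        models[gene_id] = GeneModel(
            gene_id, tissue, tuple(grp["snp_id"]), grp["weight"].to_numpy(float)
        )
    return models


def write_weights(models: Iterable, path: str | Path) -> None:
    rows = [(m.gene_id, s, w) for m in models for s, w in zip(m.snp_ids, m.w)]
    pd.DataFrame(rows, columns=["gene_id", "snp_id", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_ld_matrix(path: str | Path):
    """Read one gene's square LD matrix; the header row carries SNP ids."""
    from .twas import LdBlock

    df = pd.read_csv(path, sep="\t")
    return LdBlock(tuple(df.columns), df.to_numpy(float))


def write_ld_matrix(block, path: str | Path) -> None:
    pd.DataFrame(block.L, columns=list(block.snp_ids)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression(values_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read genes-x-samples TSV (first column gene_id) plus sample->group TSV."""
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "group") if c not in groups.columns]
    if missing:
        raise SchemaError(f"{groups_path}: missing required column(s): {missing}")
    gmap = dict(zip(groups["sample_id"], groups["group"]))
    absent = [s for s in df.columns if s not in gmap]
    if absent:
        raise ValidationError(f"{groups_path}: no group for sample(s) {absent[:5]}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(float),
        group_labels=[gmap[s] for s in df.columns],
    )


def write_expression(expr: ExpressionMatrix, values_path: str | Path,
                     groups_path: str | Path) -> None:
    pd.DataFrame(expr.values, index=pd.Index(expr.gene_ids, name="gene_id"),
                 columns=expr.sample_ids).to_csv(values_path, sep="\t")
    pd.DataFrame({"sample_id": expr.sample_ids, "group": expr.group_labels}).to_csv(
        groups_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# enrichment results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["chemical", "stream", "n_overlap", "es", "nes",
                  "p_empirical", "q_bh", "significant"]


def write_results_table(results: Iterable, path: str | Path) -> None:
    """Serialize enrichment results; numeric fields round-trip to 1e-6."""
    rows = [(r.chemical_name, r.stream, r.n_overlap, r.es, r.nes,
             r.p_empirical, r.q_bh, r.significant) for r in results]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> list:
    from .gsea import EnrichmentResult

    df = pd.read_csv(path, sep="\t", dtype={"chemical": str, "stream": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    return [
        EnrichmentResult(r.chemical, r.stream, int(r.n_overlap), float(r.es),
                         float(r.nes), float(r.p_empirical), bool(r.significant),
                         float(r.q_bh))
        for r in df.itertuples(index=False)
    ]
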