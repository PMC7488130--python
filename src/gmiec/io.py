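"""Domain types and tab-delimited readers/writers.

All files the tool touches are plain TSV: omics matrices (genes x samples),
the mandatory gene-drug association table, optional clinical variables, and
the wide per-patient results table. Matching of gene symbols and sample ids
is exact, case-sensitive string equality throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gmiec")

LAYER_KINDS = ("expression", "copy_number", "methylation", "mutation", "other")

#: canonical layer order; column order of per-patient matrices follows it
LAYER_ORDER = {kind: i for i, kind in enumerate(LAYER_KINDS)}

#: cell tokens treated as missing on input
NA_TOKENS = frozenset({"", "NA", "na", "NaN", "nan", "N/A"})


class GmiecError(Exception):
    """Base class for user-facing validation and configuration errors."""


class ParseError(GmiecError):
    pass


class ValidationError(GmiecError):
    pass


@dataclass
class OmicsDataset:
    """One omics layer: numeric matrix with gene rows and sample columns.

    Units are layer-dependent: expression is continuous abundance, copy
    number a continuous log-ratio or integer call, methylation a beta value
    in [0, 1], mutation a non-negative integer indicator or count.
    """

    layer_kind: str
    values: pd.DataFrame  # rows: gene symbols, columns: sample ids

    def __post_init__(self) -> None:
        if self.layer_kind not in LAYER_KINDS:
            raise ValidationError(f"unknown layer kind {self.layer_kind!r}")
        validate_omics_values(self.values, self.layer_kind)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def validate_omics_values(values: pd.DataFrame, layer_kind: str) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene symbols: {dups}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    arr = values.to_numpy(dtype=float)
    if layer_kind == "methylation":
        if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0):
            raise ValidationError("methylation values must lie in [0, 1]")
    elif layer_kind == "mutation":
        if arr.size and (np.nanmin(arr) < 0 or not np.allclose(arr, np.round(arr))):
            raise ValidationError("mutation values must be non-negative integers")


def read_omics_table(path, layer_kind: str) -> OmicsDataset:
    """Read a tab-delimited genes-x-samples matrix.

    First column holds gene symbols, the header row sample ids. Cells equal
    to ""/"NA" are imputed: 0 for mutation layers, the per-gene (row) median
    otherwise; the imputed count is logged. Any other non-numeric cell is a
    parse error naming its row and column.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene symbols: {dups}")

    numeric = raw.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    is_na_token = raw.apply(lambda col: col.str.strip().isin(NA_TOKENS))
    bad = numeric.isna() & ~is_na_token
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"{path}: non-numeric value {raw.loc[gene, sample]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )

    n_missing = int(is_na_token.to_numpy().sum())
    if n_missing:
        if layer_kind == "mutation":
            numeric = numeric.fillna(0)
        else:
            medians = numeric.median(axis=1)
            numeric = numeric.apply(lambda col: col.fillna(medians))
            numeric = numeric.fillna(0.0)  # genes with every cell missing
        logger.info("%s: imputed %d missing cells", path, n_missing)
    return OmicsDataset(layer_kind=layer_kind, values=numeric)


def write_omics_table(dataset: OmicsDataset, path) -> None:
    df = dataset.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


@dataclass
class OmicsBundle:
    """Aligned collection of >=2 omics layers over shared genes and samples.

    ``genes`` is the ordered gene set G and ``samples`` the ordered
    individual vector I; every member dataset covers exactly G x I.
    """

    datasets: list[OmicsDataset]
    genes: list[str]
    samples: list[str]

    @property
    def m(self) -> int:
        return len(self.datasets)

    @property
    def layer_kinds(self) -> list[str]:
        return [d.layer_kind for d in self.datasets]

    def layer(self, kind: str) -> OmicsDataset:
        for d in self.datasets:
            if d.layer_kind == kind:
                return d
        raise KeyError(kind)


def align_bundle(
    datasets: list[OmicsDataset], gene_set: list[str] | None = None
) -> OmicsBundle:
    """Intersect genes and samples across layers into an analysis-ready bundle.

    Layer order is fixed (expression, copy_number, methylation, mutation,
    other) regardless of input order; gene and sample order is lexicographic.
    Dropped genes and samples are logged. Raises if fewer than two layers are
    given or either intersection is empty.
    """
    if len(datasets) < 2:
        raise ValidationError("at least two omics datasets are required")
    datasets = sorted(datasets, key=lambda d: LAYER_ORDER[d.layer_kind])

    genes = set(datasets[0].genes)
    samples = set(datasets[0].samples)
    for d in datasets[1:]:
        genes &= set(d.genes)
        samples &= set(d.samples)
    all_genes = set().union(*(d.genes for d in datasets))
    all_samples = set().union(*(d.samples for d in datasets))
    if gene_set is not None:
        requested = set(gene_set)
        dropped_request = requested - genes
        if dropped_request:
            logger.info(
                "%d requested genes absent from some layer: %s",
                len(dropped_request),
                sorted(dropped_request)[:10],
            )
        genes &= requested
    if not genes:
        raise ValidationError("gene intersection across layers is empty")
    if not samples:
        raise ValidationError("sample intersection across layers is empty")
    dropped_g = all_genes - genes
    dropped_s = all_samples - samples
    if dropped_g:
        logger.info("dropped %d genes not shared by all layers", len(dropped_g))
    if dropped_s:
        logger.info("dropped %d samples not shared by all layers", len(dropped_s))

    genes_sorted = sorted(genes)
    samples_sorted = sorted(samples)
    aligned = [
        OmicsDataset(d.layer_kind, d.values.loc[genes_sorted, samples_sorted])
        for d in datasets
    ]
    return OmicsBundle(datasets=aligned, genes=genes_sorted, samples=samples_sorted)


@dataclass
class DrugGeneMap:
    """Set of (gene symbol, drug name) associations; matching case-sensitive."""

    associations: set[tuple[str, str]]

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.associations}

    def drugs_for(self, gene: str) -> list[str]:
        return sorted(d for g, d in self.associations if g == gene)


def read_drug_gene_map(path) -> DrugGeneMap:
    """Read the mandatory gene-drug table (header ``gene<TAB>drug``).

    Additional columns are ignored; duplicate rows collapse to one
    association. An empty table is a fatal error: the association table is
    the one input every analysis requires.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: drug-gene table needs two columns (gene, drug)")
    pairs = {
        (str(g), str(d))
        for g, d in zip(df.iloc[:, 0], df.iloc[:, 1])
        if str(g).strip() and str(d).strip()
    }
    if not pairs:
        raise ValidationError(
            f"{path}: drug-gene table is empty; it is the mandatory input"
        )
    return DrugGeneMap(associations=pairs)


@dataclass
class ClinicalTable:
    """Optional clinical variables keyed by sample id; annotation only."""

    values: pd.DataFrame  # rows: sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    return ClinicalTable(values=df)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; order kept, duplicates rejected."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValidationError(f"{path}: gene list is empty")
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{path}: gene list contains duplicates")
    return genes


# ---------------------------------------------------------------------------
# results table


@dataclass
class ModuleRecord:
    """One scored gene module of one patient, with its attached drugs."""

    index: int
    genes: list[str]
    drugs: list[str]
    score_genes: float
    score_drugs: float
    s_score: float
    sub_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class ResultTable:
    """Wide per-patient results: one row per sample, one column block per module."""

    modules: dict[str, list[ModuleRecord]]  # sample id -> module records
    clinical: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.modules)

    def max_modules(self) -> int:
        return max((len(v) for v in self.modules.values()), default=0)

    def rule_names(self) -> list[str]:
        names: list[str] = []
        for recs in self.modules.values():
            for rec in recs:
                for name in rec.sub_scores:
                    if name not in names:
                        names.append(name)
        return names


def _join(items: list[str]) -> str:
    return ",".join(items) if items else "NA"


def _split(cell: str) -> list[str]:
    return [] if cell == "NA" else cell.split(",")


def write_result_table(result: ResultTable, path) -> None:
    """Serialize to TSV; ``read_result_table`` reproduces the table exactly.

    Column block per module j: module_j_genes, module_j_drugs,
    module_j_score_genes, module_j_score_drugs, module_j_s_score and one
    module_j_sub_<rule> per rule column. Patients with fewer modules than the
    widest row pad with "NA". Clinical columns, when present, trail.
    """
    kmax = result.max_modules()
    rules = result.rule_names()
    cols = ["sample"]
    for j in range(1, kmax + 1):
        cols += [
            f"module_{j}_genes",
            f"module_{j}_drugs",
            f"module_{j}_score_genes",
            f"module_{j}_score_drugs",
            f"module_{j}_s_score",
        ]
        cols += [f"module_{j}_sub_{r}" for r in rules]
    clin_cols = []
    if result.clinical is not None:
        clin_cols = [f"clinical_{c}" for c in result.clinical.columns]
    rows = []
    for sample, recs in result.modules.items():
        row = [sample]
        for j in range(1, kmax + 1):
            rec = next((r for r in recs if r.index == j), None)
            if rec is None:
                row += ["NA"] * (5 + len(rules))
            else:
                row += [
                    _join(rec.genes),
                    _join(rec.drugs),
                    repr(float(rec.score_genes)),
                    repr(float(rec.score_drugs)),
                    repr(float(rec.s_score)),
                ]
                row += [
                    repr(float(rec.sub_scores[r])) if r in rec.sub_scores else "NA"
                    for r in rules
                ]
        if result.clinical is not None:
            clin = result.clinical
            for c in clin.columns:
                row.append(str(clin.loc[sample, c]) if sample in clin.index else "NA")
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols + clin_cols)
    df.to_csv(path, sep="\t", index=False)


def read_result_table(path) -> ResultTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    module_ids: list[int] = []
    rules: list[str] = []
    for col in df.columns:
        match = re.fullmatch(r"module_(\d+)_genes", col)
        if match:
            module_ids.append(int(match.group(1)))
        if col.startswith("module_1_sub_"):
            rules.append(col[len("module_1_sub_"):])
    clin_cols = [c for c in df.columns if c.startswith("clinical_")]
    modules: dict[str, list[ModuleRecord]] = {}
    for _, row in df.iterrows():
        recs = []
        for j in sorted(module_ids):
            genes_cell = row[f"module_{j}_genes"]
            if genes_cell == "NA":
                continue
            sub = {
                r: float(row[f"module_{j}_sub_{r}"])
                for r in rules
                if row[f"module_{j}_sub_{r}"] != "NA"
            }
            recs.append(
                ModuleRecord(
                    index=j,
                    genes=_split(genes_cell),
                    drugs=_split(row[f"module_{j}_drugs"]),
                    score_genes=float(row[f"module_{j}_score_genes"]),
                    score_drugs=float(row[f"module_{j}_score_drugs"]),
                    s_score=float(row[f"module_{j}_s_score"]),
                    sub_scores=sub,
                )
            )
        modules[row["sample"]] = recs
    clinical = None
    if clin_cols:
        clinical = df[["sample"] + clin_cols].set_index("sample")
        clinical.columns = [c[len("clinical_"):] for c in clin_cols]
        clinical.index.name = None
    return ResultTable(modules=modules, clinical=clinical)
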