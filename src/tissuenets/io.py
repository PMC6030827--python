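"""Readers and writers for the on-disk formats the pipeline touches.

All formats are UTF-8 text; lines starting with ``#`` are comments.  Parsers
validate strictly and reject malformed input with the offending line number
rather than silently repairing it.  Gene identifiers are normalized to
uppercase with surrounding whitespace stripped; no symbol/accession mapping
is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConflictError,
    DuplicateError,
    FormatError,
    InsufficientSamplesError,
)

__all__ = [
    "ExpressionDataset",
    "Network",
    "GeneSetCollection",
    "GwasResult",
    "canonical_pair",
    "normalize_gene",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_gwas_pvalues",
    "write_gwas_pvalues",
    "read_expression_matrix",
    "write_expression_matrix",
]


def normalize_gene(gene: str) -> str:
    """Canonical gene identifier: stripped, uppercased."""
    return gene.strip().upper()


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair in canonical (lexicographically sorted) order."""
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix; missing entries are NaN.

    Parameters
    ----------
    dataset_id : str
        Identifier of the originating experiment.
    context : str
        Tissue/condition label; may be empty for context-free data.
    genes, samples : list of str
        Row and column identifiers, unique and ordered.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; NaN marks missing measurements.
    """

    dataset_id: str
    context: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise DuplicateError("duplicate gene IDs in expression dataset")
        if len(self.samples) < 3:
            raise InsufficientSamplesError(
                f"dataset {self.dataset_id!r} has {len(self.samples)} samples; "
                "at least 3 are required for correlation"
            )
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class Network:
    """Undirected weighted gene network.

    Edge weights are posterior probabilities of a tissue-specific functional
    relationship, so they live in [0, 1].  Edge keys are canonical pairs
    ``(a, b)`` with ``a < b``; self-edges are forbidden.
    """

    tissue: str
    nodes: set[str]
    edges: dict[tuple[str, str], float]

    def __post_init__(self):
        for (a, b), w in self.edges.items():
            if a >= b:
                raise FormatError(f"edge ({a}, {b}) is not in canonical order")
            if a not in self.nodes or b not in self.nodes:
                raise FormatError(f"edge ({a}, {b}) has an endpoint outside nodes")
            if not (0.0 <= w <= 1.0):
                raise FormatError(f"edge ({a}, {b}) weight {w} outside [0, 1]")

    def weight(self, a: str, b: str, default: float = 0.0) -> float:
        """Weight of the undirected edge a--b, or *default* if absent."""
        if a == b:
            return 0.0
        return self.edges.get(canonical_pair(a, b), default)

    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        adj: dict[str, list[tuple[str, float]]] = {g: [] for g in self.nodes}
        for (a, b), w in self.edges.items():
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (GMT semantics).

    ``terms`` maps a term identifier to ``(description, genes)`` where genes
    is a non-empty set of normalized gene IDs.
    """

    name: str
    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self):
        for term, (_, genes) in self.terms.items():
            if not genes:
                raise FormatError(f"term {term!r} has no genes")

    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)


@dataclass
class GwasResult:
    """Gene-level GWAS association p-values, each strictly in (0, 1]."""

    study_id: str
    pvalues: dict[str, float]

    def __post_init__(self):
        for gene, p in self.pvalues.items():
            if not (0.0 < p <= 1.0):
                raise FormatError(f"gene {gene!r}: p-value {p} outside (0, 1]")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def _data_lines(path):
    """Yield (line_number, stripped_line) skipping blanks and '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path, tissue: str) -> Network:
    """Read a TSV edge list (gene_a, gene_b, weight) into a Network.

    Edges are canonicalized (a < b); symmetric duplicates with equal weight
    collapse to one edge, while contradictory duplicates raise
    :class:`ConflictError`.  Self-edges and weights outside [0, 1] raise
    :class:`FormatError`.
    """
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError("expected >= 3 tab-separated columns", path, lineno)
        a, b = normalize_gene(fields[0]), normalize_gene(fields[1])
        if not a or not b:
            raise FormatError("empty gene identifier", path, lineno)
        if a == b:
            raise FormatError(f"self-edge on gene {a!r}", path, lineno)
        try:
            w = float(fields[2])
        except ValueError:
            raise FormatError(f"weight {fields[2]!r} is not a number", path, lineno)
        if not (0.0 <= w <= 1.0) or math.isnan(w):
            raise FormatError(f"weight {w} outside [0, 1]", path, lineno)
        pair = canonical_pair(a, b)
        if pair in edges and edges[pair] != w:
            raise ConflictError(
                f"pair {pair} listed with conflicting weights "
                f"{edges[pair]} and {w}",
                path,
                lineno,
            )
        edges[pair] = w
        nodes.add(a)
        nodes.add(b)
    return Network(tissue=tissue, nodes=nodes, edges=edges)


def write_edge_list(network: Network, path) -> None:
    """Write a Network as a deterministic TSV edge list.

    Edges are sorted by (gene_a, gene_b) and weights printed with six decimal
    digits.  Isolated nodes are not representable in this format; the
    write/read round trip is the identity for networks whose every node has
    at least one edge.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_a\tgene_b\tweight\n")
        for (a, b) in sorted(network.edges):
            fh.write(f"{a}\t{b}\t{network.edges[(a, b)]:.6f}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: term TAB description TAB gene [TAB gene ...].

    Genes are uppercased and deduplicated per term; a line with fewer than
    three fields raises :class:`FormatError`.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                "GMT line needs term, description and >= 1 gene", path, lineno
            )
        term = fields[0].strip()
        if term in terms:
            raise DuplicateError(f"duplicate term {term!r}", path, lineno)
        genes = frozenset(
            normalize_gene(g) for g in fields[2:] if normalize_gene(g)
        )
        if not genes:
            raise FormatError(f"term {term!r} has no genes", path, lineno)
        terms[term] = (fields[1].strip(), genes)
    return GeneSetCollection(name=name or str(path), terms=terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(collection.terms):
            desc, genes = collection.terms[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# GWAS gene-level p-values
# ---------------------------------------------------------------------------

GWAS_DIALECTS = ("two_column", "vegas_like", "auto")


def _parse_p(text: str, path, lineno) -> float:
    try:
        p = float(text)
    except ValueError:
        raise FormatError(f"p-value {text!r} is not a number", path, lineno)
    if not (0.0 < p <= 1.0):
        raise FormatError(
            f"p-value {p} outside (0, 1] (exact zeros must be pre-clamped)",
            path,
            lineno,
        )
    return p


def read_gwas_pvalues(path, dialect: str = "auto", study_id: str | None = None) -> GwasResult:
    """Read gene-level GWAS p-values.

    Dialects
    --------
    two_column
        ``gene TAB p`` per line, no header required.
    vegas_like
        Header line present; gene in column 2, p-value in the last column
        (the layout of common SNP-to-gene pooling tools).
    auto
        Sniff: if the first data line's last field is not a number it is a
        header, and >= 3 columns selects vegas_like; otherwise two_column.
    """
    if dialect not in GWAS_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {GWAS_DIALECTS}")

    lines = list(_data_lines(path))
    if dialect == "auto":
        dialect = "two_column"
        if lines:
            first = lines[0][1].split("\t")
            try:
                float(first[-1])
            except ValueError:
                dialect = "vegas_like" if len(first) >= 3 else "two_column"
                lines = lines[1:] if dialect == "two_column" else lines

    if dialect == "vegas_like":
        if not lines:
            raise FormatError("empty GWAS file", path)
        lines = lines[1:]  # header mandated by the dialect
        gene_col, p_col = 1, -1
        min_fields = 3
    else:
        gene_col, p_col = 0, 1
        min_fields = 2

    pvalues: dict[str, float] = {}
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) < min_fields:
            raise FormatError(
                f"expected >= {min_fields} tab-separated columns", path, lineno
            )
        gene = normalize_gene(fields[gene_col])
        if not gene:
            raise FormatError("empty gene identifier", path, lineno)
        if gene in pvalues:
            raise DuplicateError(f"duplicate gene {gene!r}", path, lineno)
        pvalues[gene] = _parse_p(fields[p_col], path, lineno)
    return GwasResult(study_id=study_id or str(path), pvalues=pvalues)


def write_gwas_pvalues(gwas: GwasResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene\tp\n")
        for gene in sorted(gwas.pvalues):
            fh.write(f"{gene}\t{gwas.pvalues[gene]:.6g}\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path, dataset_id: str, context: str = "") -> ExpressionDataset:
    """Read a TSV expression matrix (rows = genes, columns = samples).

    The first row holds sample IDs and the first column gene IDs.  Cells
    equal to ``NA`` or empty are missing (kept as NaN, never imputed to 0).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        comment="#",
        na_values=["NA", ""],
        keep_default_na=False,
    )
    genes = [normalize_gene(str(g)) for g in df.index]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise DuplicateError(f"duplicate gene rows: {', '.join(dupes)}", path)
    if df.shape[1] < 3:
        raise InsufficientSamplesError(
            f"{df.shape[1]} samples; at least 3 required", path
        )
    values = df.to_numpy(dtype=float)
    return ExpressionDataset(
        dataset_id=dataset_id,
        context=context,
        genes=genes,
        samples=[str(s) for s in df.columns],
        values=values,
    )


def write_expression_matrix(dataset: ExpressionDataset, path) -> None:
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
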