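"""Gold-standard construction: global functional standards from gene-set
co-annotation, specialized per tissue by tissue-expression weighting.

A *global* standard labels gene pairs positive when they are co-annotated to
at least one informative functional term and negative when both genes are
annotated somewhere in the collection but never share a term.  A *tissue*
standard keeps a positive pair only when both genes are expressed/annotated
in that tissue, down-weighting it by the product of the two genes' tissue
weights; pairs failing the both-expressed test are dropped (not relabeled),
and negatives pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .exceptions import EmptyStandardError, EmptyTissueError, FormatError
from .io import (
    ExpressionDataset,
    GeneSetCollection,
    canonical_pair,
    normalize_gene,
    _data_lines,
)

__all__ = [
    "TissueGeneMap",
    "GoldStandard",
    "build_tissue_gene_map",
    "build_global_standard",
    "specialize_to_tissue",
    "read_gold_standard",
    "write_gold_standard",
]


@dataclass
class TissueGeneMap:
    """tissue -> {gene -> weight in (0, 1]}.

    A gene absent from a tissue's mapping is treated as not expressed (or
    not annotated) in that tissue.
    """

    tissues: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for tissue, genes in self.tissues.items():
            for gene, w in genes.items():
                if not (0.0 < w <= 1.0):
                    raise FormatError(
                        f"tissue {tissue!r} gene {gene!r}: weight {w} outside (0, 1]"
                    )

    def genes(self, tissue: str) -> dict[str, float]:
        return self.tissues[tissue]


@dataclass
class GoldStandard:
    """Labeled gene pairs for Bayesian training.

    ``pairs`` maps a canonical pair to ``(label, weight)`` with label 1
    (functionally related) or 0 (unrelated) and weight in (0, 1].
    """

    tissue: str
    pairs: dict[tuple[str, str], tuple[int, float]] = field(default_factory=dict)

    def __post_init__(self):
        for pair, (label, w) in self.pairs.items():
            if label not in (0, 1):
                raise FormatError(f"pair {pair}: label {label} not in {{0, 1}}")
            if not (0.0 < w <= 1.0):
                raise FormatError(f"pair {pair}: weight {w} outside (0, 1]")

    @property
    def positives(self) -> dict[tuple[str, str], float]:
        return {p: w for p, (lbl, w) in self.pairs.items() if lbl == 1}

    @property
    def negatives(self) -> dict[tuple[str, str], float]:
        return {p: w for p, (lbl, w) in self.pairs.items() if lbl == 0}


def build_tissue_gene_map(
    source, expression_cutoff: float = 0.0
) -> TissueGeneMap:
    """Derive tissue->gene weights from expression data or a tissue GMT.

    Parameters
    ----------
    source : list of ExpressionDataset or GeneSetCollection
        With expression datasets, each dataset's ``context`` names its
        tissue; a gene is expressed there iff its mean expression exceeds
        ``expression_cutoff`` (strict), and its weight is
        ``min(1, mean / max_mean)`` over the tissue's genes, clipped to
        (0, 1].  Datasets sharing a context are pooled by averaging per-gene
        means.  With a GeneSetCollection (tissue GMT), every listed gene
        gets weight 1.
    """
    if isinstance(source, GeneSetCollection):
        tissues = {
            term: {g: 1.0 for g in genes}
            for term, (_, genes) in source.terms.items()
        }
        for tissue, genes in tissues.items():
            if not genes:
                raise EmptyTissueError(f"tissue {tissue!r} has no genes")
        return TissueGeneMap(tissues=tissues)

    by_context: dict[str, dict[str, list[float]]] = {}
    for ds in source:
        if not isinstance(ds, ExpressionDataset):
            raise TypeError(
                "source must be a GeneSetCollection or a list of ExpressionDataset"
            )
        means = np.nanmean(ds.values, axis=1)
        ctx = by_context.setdefault(ds.context, {})
        for gene, m in zip(ds.genes, means):
            if np.isfinite(m):
                ctx.setdefault(gene, []).append(float(m))

    tissues: dict[str, dict[str, float]] = {}
    for context, gene_means in by_context.items():
        pooled = {g: float(np.mean(ms)) for g, ms in gene_means.items()}
        expressed = {g: m for g, m in pooled.items() if m > expression_cutoff}
        if not expressed:
            raise EmptyTissueError(
                f"tissue {context!r} has zero genes above cutoff {expression_cutoff}"
            )
        max_mean = max(expressed.values())
        weights = {}
        for g, m in expressed.items():
            w = min(1.0, m / max_mean) if max_mean > 0 else 1.0
            if w > 0.0:
                weights[g] = w
        if not weights:
            raise EmptyTissueError(f"tissue {context!r} has zero expressed genes")
        tissues[context] = weights
    return TissueGeneMap(tissues=tissues)


def build_global_standard(
    functional_sets: GeneSetCollection,
    min_term: int = 3,
    max_term: int = 300,
) -> GoldStandard:
    """Co-annotation gold standard over a functional gene-set collection.

    Positives are pairs co-annotated to at least one term whose size lies in
    ``[min_term, max_term]``.  Negatives are pairs of genes that are each
    annotated somewhere in the collection but never share any term (terms of
    all sizes count for annotation and for sharing).  All weights are 1.
    """
    if min_term < 2:
        raise ValueError("min_term must be >= 2")

    memberships: dict[str, set[str]] = {}
    for term, (_, genes) in functional_sets.terms.items():
        for g in genes:
            memberships.setdefault(g, set()).add(term)

    positives: set[tuple[str, str]] = set()
    for term, (_, genes) in functional_sets.terms.items():
        if not (min_term <= len(genes) <= max_term):
            continue
        for a, b in combinations(sorted(genes), 2):
            positives.add(canonical_pair(a, b))
    if not positives:
        raise EmptyStandardError(
            "collection yields zero positive pairs under the term-size filter"
        )

    pairs: dict[tuple[str, str], tuple[int, float]] = {
        p: (1, 1.0) for p in positives
    }
    annotated = sorted(memberships)
    for a, b in combinations(annotated, 2):
        pair = (a, b)
        if pair in pairs:
            continue
        if memberships[a].isdisjoint(memberships[b]):
            pairs[pair] = (0, 1.0)
    return GoldStandard(tissue="global", pairs=pairs)


def specialize_to_tissue(
    global_standard: GoldStandard, tissue_map: TissueGeneMap, tissue: str
) -> GoldStandard:
    """Specialize a global standard to one tissue.

    A positive pair survives iff both genes appear in the tissue's gene map,
    with weight equal to the product of the two gene weights; positives
    failing the test are dropped entirely.  Negatives are retained unchanged
    with weight 1.
    """
    if tissue not in tissue_map.tissues:
        raise KeyError(tissue)
    gene_w = tissue_map.tissues[tissue]
    pairs: dict[tuple[str, str], tuple[int, float]] = {}
    n_pos = 0
    for pair, (label, w) in global_standard.pairs.items():
        if label == 1:
            a, b = pair
            if a in gene_w and b in gene_w:
                pairs[pair] = (1, w * gene_w[a] * gene_w[b])
                n_pos += 1
        else:
            pairs[pair] = (0, 1.0)
    if n_pos == 0:
        raise EmptyStandardError(
            f"no positive pair survives tissue {tissue!r} specialization"
        )
    return GoldStandard(tissue=tissue, pairs=pairs)


def read_gold_standard(path, tissue: str = "global") -> GoldStandard:
    """Read a gold standard TSV: gene_a, gene_b, label(0/1), weight."""
    pairs: dict[tuple[str, str], tuple[int, float]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError("expected gene_a, gene_b, label, weight", path, lineno)
        a, b = normalize_gene(fields[0]), normalize_gene(fields[1])
        if a == b:
            raise FormatError(f"self-pair on gene {a!r}", path, lineno)
        try:
            label = int(fields[2])
            weight = float(fields[3])
        except ValueError:
            raise FormatError("label must be 0/1 and weight numeric", path, lineno)
        pair = canonical_pair(a, b)
        if pair in pairs:
            raise FormatError(f"pair {pair} listed twice", path, lineno)
        pairs[pair] = (label, weight)
    return GoldStandard(tissue=tissue, pairs=pairs)


def write_gold_standard(standard: GoldStandard, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_a\tgene_b\tlabel\tweight\n")
        for (a, b) in sorted(standard.pairs):
            label, w = standard.pairs[(a, b)]
            fh.write(f"{a}\t{b}\t{label}\t{w:.6f}\n")
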