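"""Synthetic multi-tissue expression compendia with planted co-expression
modules, plus synthetic gene-level GWAS p-values, with full ground truth.

Each module is a single-factor Gaussian block: in every dataset whose
context activates the module, member genes follow
``sqrt(s) * factor + sqrt(1 - s) * noise`` with a fresh latent factor per
dataset, so their pairwise correlation targets the module strength ``s``.
Shared modules are active in every tissue's datasets; tissue modules only
in their own tissue's.  All other genes are independent Gaussian noise.
The emitted truth object records module memberships, the per-tissue planted
edge sets and a designated disease module for GWAS simulation.

The defaults describe the standard study condition used throughout the test
suite: 200 genes, two tissues, one shared and one tissue-specific 20-gene
module each, six 50-sample datasets per tissue, module strength 0.7 and
unit background noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .exceptions import SimulationSpecError
from .gold import TissueGeneMap
from .io import ExpressionDataset, GwasResult, canonical_pair

__all__ = ["SimulationSpec", "SimTruth", "simulate_compendium", "simulate_gwas"]

BACKGROUND = "background"


@dataclass
class SimulationSpec:
    """Parameters of a synthetic compendium.

    ``module_strength`` is the target within-module correlation; module
    memberships are disjoint; every module size must be >= 2.
    """

    n_genes: int = 200
    tissues: tuple[str, ...] = ("tissue_a", "tissue_b")
    shared_modules: tuple[int, ...] = (20,)
    tissue_modules: dict[str, tuple[int, ...]] | None = None
    datasets_per_tissue: int = 6
    samples_per_dataset: int = 50
    module_strength: float = 0.7
    noise_sd: float = 1.0
    background_tissue_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.tissue_modules is None:
            self.tissue_modules = {t: (20,) for t in self.tissues}
        if not self.tissues:
            raise SimulationSpecError("at least one tissue is required")
        if set(self.tissue_modules) - set(self.tissues):
            raise SimulationSpecError("tissue_modules names an unknown tissue")
        sizes = list(self.shared_modules)
        for t in self.tissues:
            sizes.extend(self.tissue_modules.get(t, ()))
        if any(s < 2 for s in sizes):
            raise SimulationSpecError("every module size must be >= 2")
        if sum(sizes) > self.n_genes:
            raise SimulationSpecError(
                f"module genes ({sum(sizes)}) exceed n_genes ({self.n_genes})"
            )
        if not (0.0 < self.module_strength < 1.0):
            raise SimulationSpecError("module_strength must be in (0, 1)")
        if self.noise_sd <= 0:
            raise SimulationSpecError("noise_sd must be > 0")
        if self.samples_per_dataset < 3:
            raise SimulationSpecError("samples_per_dataset must be >= 3")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated compendium."""

    module_assignment: dict[str, str]
    module_tissue: dict[str, str | None] = field(default_factory=dict)
    true_edges: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    tissue_genes: dict[str, set[str]] = field(default_factory=dict)
    disease_module: str = ""

    def module_genes(self, module_id: str) -> list[str]:
        return sorted(g for g, m in self.module_assignment.items() if m == module_id)

    def tissue_specific_edges(self, tissue: str) -> set[tuple[str, str]]:
        """Planted edges of modules exclusive to *tissue* (shared excluded)."""
        out: set[tuple[str, str]] = set()
        for mid, t in self.module_tissue.items():
            if t == tissue:
                out |= _module_pairs(self.module_genes(mid))
        return out

    def background_pairs(self, gene_universe=None) -> set[tuple[str, str]]:
        """All pairs not planted within any module."""
        genes = sorted(gene_universe) if gene_universe else sorted(self.module_assignment)
        planted: set[tuple[str, str]] = set()
        for mid in self.module_tissue:
            planted |= _module_pairs(self.module_genes(mid))
        return {
            canonical_pair(a, b)
            for a, b in combinations(genes, 2)
        } - planted

    def to_json(self) -> str:
        doc = {
            "module_assignment": self.module_assignment,
            "module_tissue": self.module_tissue,
            "true_edges": {
                t: sorted([list(p) for p in pairs])
                for t, pairs in self.true_edges.items()
            },
            "tissue_genes": {t: sorted(g) for t, g in self.tissue_genes.items()},
            "disease_module": self.disease_module,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        doc = json.loads(text)
        return cls(
            module_assignment=doc["module_assignment"],
            module_tissue=doc["module_tissue"],
            true_edges={
                t: {tuple(p) for p in pairs}
                for t, pairs in doc["true_edges"].items()
            },
            tissue_genes={t: set(g) for t, g in doc["tissue_genes"].items()},
            disease_module=doc["disease_module"],
        )


def _module_pairs(genes) -> set[tuple[str, str]]:
    return {canonical_pair(a, b) for a, b in combinations(sorted(genes), 2)}


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_compendium(
    spec: SimulationSpec,
) -> tuple[list[ExpressionDataset], TissueGeneMap, SimTruth]:
    """Generate the compendium, the tissue-gene map and the ground truth.

    Fully reproducible from ``spec.seed``: the same spec yields identical
    datasets, maps and truth.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)

    # carve disjoint module blocks: shared first, then per-tissue in order
    assignment = {g: BACKGROUND for g in genes}
    module_tissue: dict[str, str | None] = {}
    module_members: dict[str, list[str]] = {}
    cursor = 0
    for i, size in enumerate(spec.shared_modules):
        mid = f"shared_{i}"
        module_members[mid] = genes[cursor: cursor + size]
        module_tissue[mid] = None
        cursor += size
    for tissue in spec.tissues:
        for i, size in enumerate(spec.tissue_modules.get(tissue, ())):
            mid = f"{tissue}_{i}"
            module_members[mid] = genes[cursor: cursor + size]
            module_tissue[mid] = tissue
            cursor += size
    for mid, members in module_members.items():
        for g in members:
            assignment[g] = mid
    background = [g for g in genes if assignment[g] == BACKGROUND]

    true_edges: dict[str, set[tuple[str, str]]] = {}
    tissue_genes: dict[str, set[str]] = {}
    for tissue in spec.tissues:
        active = [
            mid for mid, t in module_tissue.items() if t is None or t == tissue
        ]
        edges: set[tuple[str, str]] = set()
        active_genes: set[str] = set()
        for mid in active:
            edges |= _module_pairs(module_members[mid])
            active_genes |= set(module_members[mid])
        true_edges[tissue] = edges
        n_bg = int(round(spec.background_tissue_fraction * len(background)))
        bg_sample = rng.choice(len(background), size=n_bg, replace=False) if n_bg else []
        tissue_genes[tissue] = active_genes | {background[i] for i in sorted(bg_sample)}

    s = spec.module_strength
    datasets: list[ExpressionDataset] = []
    gene_index = {g: i for i, g in enumerate(genes)}
    for tissue in spec.tissues:
        active = [
            mid for mid, t in module_tissue.items() if t is None or t == tissue
        ]
        for d in range(spec.datasets_per_tissue):
            values = rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.samples_per_dataset))
            for mid in active:
                members = module_members[mid]
                rows = [gene_index[g] for g in members]
                factor = rng.normal(size=spec.samples_per_dataset)
                noise = rng.normal(size=(len(rows), spec.samples_per_dataset))
                values[rows] = np.sqrt(s) * factor[None, :] + np.sqrt(1.0 - s) * noise
            datasets.append(
                ExpressionDataset(
                    dataset_id=f"{tissue}_ds{d}",
                    context=tissue,
                    genes=list(genes),
                    samples=[f"S{j:03d}" for j in range(spec.samples_per_dataset)],
                    values=values,
                )
            )

    disease = ""
    for tissue in spec.tissues:
        mids = [m for m, t in module_tissue.items() if t == tissue]
        if mids:
            disease = mids[0]
            break
    if not disease and module_members:
        disease = next(iter(module_members))

    truth = SimTruth(
        module_assignment=assignment,
        module_tissue=module_tissue,
        true_edges=true_edges,
        tissue_genes=tissue_genes,
        disease_module=disease,
    )
    tissue_map = TissueGeneMap(
        tissues={t: {g: 1.0 for g in gs} for t, gs in tissue_genes.items()}
    )
    return datasets, tissue_map, truth


def simulate_gwas(
    truth: SimTruth, signal_alpha: float = 0.3, seed: int = 0
) -> GwasResult:
    """Synthetic gene-level GWAS p-values.

    Disease-module genes draw p ~ Beta(signal_alpha, 1) — CDF ``p**alpha``,
    so smaller alpha concentrates them near zero; alpha = 1 is the uniform
    null.  All other genes draw p ~ Uniform(0, 1).
    """
    if not (0.0 < signal_alpha <= 1.0):
        raise SimulationSpecError("signal_alpha must be in (0, 1]")
    disease_genes = set(truth.module_genes(truth.disease_module))
    if not disease_genes:
        raise SimulationSpecError(
            f"disease module {truth.disease_module!r} has no genes"
        )
    rng = np.random.default_rng(seed)
    genes = sorted(truth.module_assignment)
    u = rng.uniform(size=len(genes))
    pvals = {}
    for g, x in zip(genes, u):
        p = x ** (1.0 / signal_alpha) if g in disease_genes else x
        pvals[g] = max(p, 1e-300)  # keep strictly inside (0, 1]
    return GwasResult(study_id=f"sim_alpha{signal_alpha}", pvalues=pvals)
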