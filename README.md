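# tissuenets

Tissue-specific functional gene networks from heterogeneous genomics
evidence, with network-guided GWAS re-prioritization (NetWAS), network
querying, and gene-set enrichment.

## The problem

Most functional-genomics data — co-expression compendia especially — are
collected in many different biological contexts, while gene function is
often exercised only in particular tissues. A single global gene network
averages away exactly the tissue-specific relationships that matter for
understanding disease. `tissuenets` builds a *separate* network per
tissue by (1) constructing a tissue-specific gold standard of
functionally related gene pairs and (2) integrating all available
evidence with a naive-Bayes model trained against that standard, so that
each dataset is weighted by how informative it is *for that tissue*.

The resulting networks support two downstream analyses:

- **NetWAS**: genes falling below a nominal GWAS p-value cutoff are
  treated as noisy positive labels, an SVM is trained on network
  connectivity features under cross-validation, and all genes are
  re-ranked by their distance to the decision hyperplane. Network
  structure rescues true disease genes whose individual association
  p-values are unremarkable.
- **Query and enrichment**: extract the most connected neighbourhood
  around a gene set, compare it across tissues in coordinated views, and
  test it for gene-set over-representation with exact hypergeometric
  upper-tail p-values and Benjamini–Hochberg FDR control.

## Core model

For each dataset *d*, co-expression evidence is the Fisher transform
*z* = atanh(*r*) of the Pearson correlation of each gene pair, discretized
into quantile bins. Given a gold standard of positive (FR = 1) and
negative (FR = 0) pairs, each dataset contributes a conditional
probability table P(bin | FR) with Laplace smoothing. The posterior that
a pair is functionally related is

```
P(FR=1 | e_1..e_D)  ∝  P(FR=1) · ∏_d P(e_d | FR=1)
```

computed in log space; a pair unobserved in a dataset contributes a
likelihood ratio of 1 (the dataset is simply skipped). Tissue
specificity enters through the standard: global co-annotation positives
are kept for a tissue only when both genes are expressed/annotated
there, weighted by the product of the genes' tissue weights.

See [docs/methods.md](docs/methods.md) for the full model, parameter
defaults, and design rationale.

## Worked example

The package ships a generative simulator with planted co-expression
modules, so the whole pipeline can be exercised end-to-end with a known
ground truth:

```python
from tissuenets import (
    SimulationSpec, simulate_compendium, simulate_gwas,
    TissueNetworkIntegrator, NetWAS, correlation_evidence,
    query_subnetwork, enrich,
)
from tissuenets.pipeline import standard_for_tissue, modules_as_gene_sets

spec = SimulationSpec(
    n_genes=120, tissues=("brain", "kidney"),
    shared_modules=(15,), tissue_modules={"brain": (15,), "kidney": (15,)},
    datasets_per_tissue=4, samples_per_dataset=40, seed=7,
)
datasets, tissue_map, truth = simulate_compendium(spec)

standard = standard_for_tissue(truth, tissue_map, "brain")
evidences = [correlation_evidence(ds) for ds in datasets]
integrator = TissueNetworkIntegrator(n_bins=5).fit(evidences, standard)
network = integrator.predict(sorted(truth.module_assignment))
print(f"prior: {integrator.model_.prior:.4f}")

module = truth.module_genes("brain_0")
a, b = module[0], module[1]
bg = next(g for g, m in truth.module_assignment.items() if m == "background")
print(f"posterior({a},{b}) = {network.weight(a, b):.4f}   (same brain module)")
print(f"posterior({a},{bg}) = {network.weight(a, bg):.4f}   (background pair)")

sub = query_subnetwork(network, {a}, max_genes=8)
print("query neighbourhood:", ", ".join(sub.nodes))
print(f"{sum(g in module for g in sub.nodes)}/8 retrieved genes are in the planted module")

gwas = simulate_gwas(truth, signal_alpha=0.2, seed=8)
ranker = NetWAS(cutoff=0.05, random_state=0).fit(network, gwas)
top10 = ranker.ranking_.ranking[:10]
print(f"NetWAS top 10: {sum(g in module for g in top10)}/10 disease-module genes")
naive = sorted(gwas.pvalues, key=gwas.pvalues.get)[:10]
print(f"p-value top 10: {sum(g in module for g in naive)}/10 disease-module genes")

results = enrich(set(sub.nodes), modules_as_gene_sets(truth), set(network.nodes))
r = results[0]
print(f"top enrichment: {r.term}  k={r.k}/{r.n}  p={r.p:.3g}  q={r.q:.3g}")
```

This prints:

```
prior: 0.2373
posterior(G0016,G0017) = 0.9076   (same brain module)
posterior(G0016,G0046) = 0.0000   (background pair)
query neighbourhood: G0016, G0023, G0026, G0029, G0020, G0021, G0028, G0030
8/8 retrieved genes are in the planted module
NetWAS top 10: 10/10 disease-module genes
p-value top 10: 9/10 disease-module genes
top enrichment: brain_0  k=8/8  p=7.66e-09  q=2.3e-08
```

A pair inside the planted brain module gets posterior 0.91 while a
background pair gets ~0; the 8-gene neighbourhood around `G0016` is
drawn entirely from the planted module and is strongly enriched for it;
and NetWAS recovers all 10 of its top genes from the disease module
versus 9/10 for the raw p-value ranking.

The same pipeline is available from the command line:

```sh
tissuenets simulate --out-dir sim --seed 7 --n-genes 120
tissuenets build-standard --gene-sets sim/tissues.gmt --out std.tsv
tissuenets integrate --standard std.tsv --tissue tissue_a \
    --expression sim/tissue_a_ds0.tsv ... --out net.tsv
tissuenets netwas --gwas sim/gwas.tsv --network net.tsv --out ranked.tsv
tissuenets query --network tissue_a=net.tsv --genes G0016 --out-prefix sub
tissuenets enrich --genes G0016 --gene-sets sim/tissues.gmt --network net.tsv --out enr.tsv
```

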