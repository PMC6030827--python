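"""NetWAS: network-guided re-prioritization of GWAS gene-level p-values.

The premise is that top GWAS associations are enriched for disease-relevant
genes even below genome-wide significance.  Genes with p below a cutoff
(default 0.01) become positive labels; an equally sized seeded random sample
of above-cutoff genes becomes the negatives.  A linear soft-margin SVM is
trained on tissue-network edge weights as features, with five-fold
stratified cross-validation: each labeled gene is scored only by the model
whose training folds exclude it, and unlabeled genes by the mean decision
value of the five fold models.  The output re-ranks every GWAS gene by its
signed distance to the separating hyperplane (higher = more likely
trait-associated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import InsufficientLabelsError, UndefinedMetricError
from .io import GwasResult, Network, normalize_gene

__all__ = [
    "LabelSet",
    "FeatureMatrix",
    "NetwasRanking",
    "label_genes",
    "build_features",
    "run_netwas",
    "evaluate_ranking",
    "write_netwas_ranking",
    "NetWAS",
]

MIN_LABELS_PER_CLASS = 5  # five-fold CV needs one member of each class per fold


@dataclass
class LabelSet:
    """Positive/negative training genes derived from GWAS p-values."""

    positives: set[str]
    negatives: set[str]
    cutoff: float
    seed: int

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValueError("positive and negative label sets overlap")


@dataclass
class FeatureMatrix:
    """Rows = genes to score, columns = network genes, entries = edge weights."""

    row_genes: list[str]
    feature_genes: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_genes), len(self.feature_genes)):
            raise ValueError("feature matrix shape does not match gene lists")


@dataclass
class NetwasRanking:
    """Signed SVM decision scores and the descending re-ranking they induce."""

    scores: dict[str, float]
    ranking: list[str]
    provenance: dict = field(default_factory=dict)


def label_genes(
    gwas: GwasResult,
    cutoff: float = 0.01,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> LabelSet:
    """Threshold-label GWAS genes for SVM training.

    Positives are genes with p strictly below ``cutoff``; negatives are a
    seeded uniform sample (without replacement) of genes at or above the
    cutoff, of size ``round(negative_ratio * n_positives)`` capped at the
    available pool.  The same seed always yields the same sample.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff {cutoff} outside (0, 1)")
    positives = {g for g, p in gwas.pvalues.items() if p < cutoff}
    pool = sorted(g for g, p in gwas.pvalues.items() if p >= cutoff)
    n_neg = min(int(round(negative_ratio * len(positives))), len(pool))
    if len(positives) < MIN_LABELS_PER_CLASS or n_neg < MIN_LABELS_PER_CLASS:
        raise InsufficientLabelsError(
            f"{len(positives)} positives / {n_neg} negatives at cutoff {cutoff}; "
            f"five-fold CV needs >= {MIN_LABELS_PER_CLASS} of each"
        )
    rng = np.random.default_rng(seed)
    negatives = set(rng.choice(np.array(pool, dtype=object), size=n_neg, replace=False))
    return LabelSet(positives=positives, negatives=negatives, cutoff=cutoff, seed=seed)


def build_features(network: Network, rows, feature_genes) -> FeatureMatrix:
    """Edge-weight feature matrix.

    ``entry(g, f)`` is the network weight of the g--f edge (0 when absent,
    0 on the diagonal).  A row gene absent from the network gets an all-zero
    row with a warning — it is simply unmeasured in this tissue.
    """
    rows = [normalize_gene(g) for g in rows]
    feature_genes = [normalize_gene(g) for g in feature_genes]
    if not feature_genes:
        raise ValueError("feature_genes must be non-empty")
    missing = [g for g in rows if g not in network.nodes]
    if missing:
        warnings.warn(
            f"{len(missing)} row gene(s) absent from the {network.tissue!r} "
            "network; their feature rows are zero",
            stacklevel=2,
        )
    col_index = {g: j for j, g in enumerate(feature_genes)}
    row_index = {g: i for i, g in enumerate(rows)}
    values = np.zeros((len(rows), len(feature_genes)))
    for (a, b), w in network.edges.items():
        ia, ib = row_index.get(a), row_index.get(b)
        ja, jb = col_index.get(a), col_index.get(b)
        if ia is not None and jb is not None:
            values[ia, jb] = w
        if ib is not None and ja is not None:
            values[ib, ja] = w
    return FeatureMatrix(row_genes=rows, feature_genes=feature_genes, values=values)


class NetWAS(BaseEstimator):
    """GWAS re-prioritization by SVM over tissue-network features.

    Parameters
    ----------
    cutoff : float, default=0.01
        p-value threshold selecting positive training genes (strict <).
    negative_ratio : float, default=1.0
        Negatives sampled per positive.
    svm_c : float, default=1.0
        Soft-margin regularization of the linear SVM.
    n_folds : int, default=5
        Stratified cross-validation folds.
    random_state : int, default=0
        Seeds both the negative sample and the fold shuffle.

    Attributes
    ----------
    labels_ : LabelSet
    ranking_ : NetwasRanking
    folds_ : list of (train_genes, test_genes)
        Fold composition over the labeled genes, for leakage audits.
    feature_genes_ : list of str
    """

    def __init__(
        self,
        cutoff: float = 0.01,
        negative_ratio: float = 1.0,
        svm_c: float = 1.0,
        n_folds: int = 5,
        random_state: int = 0,
    ):
        self.cutoff = cutoff
        self.negative_ratio = negative_ratio
        self.svm_c = svm_c
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, network: Network, gwas: GwasResult):
        """Label, cross-validate the SVM, and score every GWAS gene."""
        labels = label_genes(
            gwas, self.cutoff, self.negative_ratio, self.random_state
        )
        all_genes = sorted(gwas.pvalues)
        labeled = sorted(labels.positives | labels.negatives)
        unlabeled = [g for g in all_genes if g not in labels.positives and g not in labels.negatives]
        feature_genes = sorted(network.nodes)

        fm = build_features(network, labeled + unlabeled, feature_genes)
        X_lab = fm.values[: len(labeled)]
        X_unl = fm.values[len(labeled):]
        y = np.array([1 if g in labels.positives else 0 for g in labeled])

        if np.allclose(X_lab, X_lab[0]):
            raise ValueError(
                "all labeled genes have identical feature rows; the SVM "
                "cannot separate them"
            )

        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        scores = np.zeros(len(labeled))
        unl_scores = np.zeros((self.n_folds, len(unlabeled)))
        folds: list[tuple[list[str], list[str]]] = []
        for f, (train_idx, test_idx) in enumerate(skf.split(X_lab, y)):
            clf = SVC(kernel="linear", C=self.svm_c)
            clf.fit(X_lab[train_idx], y[train_idx])
            scores[test_idx] = clf.decision_function(X_lab[test_idx])
            if len(unlabeled):
                unl_scores[f] = clf.decision_function(X_unl)
            folds.append(
                ([labeled[i] for i in train_idx], [labeled[i] for i in test_idx])
            )

        all_scores = {g: float(s) for g, s in zip(labeled, scores)}
        if len(unlabeled):
            for g, s in zip(unlabeled, unl_scores.mean(axis=0)):
                all_scores[g] = float(s)
        ranking = sorted(all_scores, key=lambda g: (-all_scores[g], g))

        self.labels_ = labels
        self.folds_ = folds
        self.feature_genes_ = feature_genes
        self.ranking_ = NetwasRanking(
            scores=all_scores,
            ranking=ranking,
            provenance={
                "tissue": network.tissue,
                "cutoff": self.cutoff,
                "negative_ratio": self.negative_ratio,
                "svm_c": self.svm_c,
                "seed": self.random_state,
                "n_pos": len(labels.positives),
                "n_neg": len(labels.negatives),
            },
        )
        return self


def run_netwas(
    network: Network,
    gwas: GwasResult,
    cutoff: float = 0.01,
    svm_c: float = 1.0,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> NetwasRanking:
    """One-call NetWAS: returns the re-ranking of every GWAS gene."""
    est = NetWAS(
        cutoff=cutoff,
        negative_ratio=negative_ratio,
        svm_c=svm_c,
        random_state=seed,
    )
    return est.fit(network, gwas).ranking_


def evaluate_ranking(ranking: NetwasRanking, truth) -> float:
    """ROC AUC of the ranking against a truth gene set.

    Equivalent to the normalized Mann-Whitney U of truth vs non-truth
    scores, with ties counted one half.
    """
    truth = {normalize_gene(g) for g in truth}
    genes = list(ranking.scores)
    y = np.array([1 if g in truth else 0 for g in genes])
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError(
            "truth must overlap the scored genes and leave non-truth genes"
        )
    s = np.array([ranking.scores[g] for g in genes])
    return float(roc_auc_score(y, s))


def write_netwas_ranking(
    ranking: NetwasRanking, gwas: GwasResult, path, labels: LabelSet | None = None
) -> None:
    """TSV output: gene, netwas_score, rank, original_p, label.

    Provenance (cutoff, tissue, seed, label counts) goes into '#' header
    lines, so identical inputs and seed produce byte-identical files.
    """
    prov = ranking.provenance
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(prov):
            fh.write(f"# {key}={prov[key]}\n")
        fh.write("#gene\tnetwas_score\trank\toriginal_p\tlabel\n")
        for rank, gene in enumerate(ranking.ranking, start=1):
            p = gwas.pvalues.get(gene, float("nan"))
            if labels is None:
                label = "unlabeled"
            elif gene in labels.positives:
                label = "pos"
            elif gene in labels.negatives:
                label = "neg"
            else:
                label = "unlabeled"
            fh.write(
                f"{gene}\t{ranking.scores[gene]:.6f}\t{rank}\t{p:.6g}\t{label}\n"
            )
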