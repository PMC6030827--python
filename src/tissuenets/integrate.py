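"""Naive-Bayes integration of functional-genomics evidence into
posterior-probability tissue networks.

The pipeline is: per-dataset evidence scores for gene pairs (Fisher-z of
Pearson co-expression, or raw values for pre-scored evidence), quantile
discretization into bins, then a naive-Bayes model fit against a labeled
gold standard.  Each dataset contributes a conditional probability table
(CPT) ``P(bin | FR)`` for the functional-relationship classes FR=1 / FR=0;
the posterior for a pair multiplies the per-dataset likelihood ratios onto
the prior odds, skipping datasets where the pair is unobserved (their
likelihood ratio is 1).  All products are carried in log space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations, compress

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .exceptions import EmptyStandardError, FormatError
from .gold import GoldStandard
from .io import ExpressionDataset, Network

__all__ = [
    "EvidenceMatrix",
    "DiscretizedEvidence",
    "BayesModel",
    "correlation_evidence",
    "discretize",
    "fit_bayes",
    "posterior",
    "predict_network",
    "TissueNetworkIntegrator",
]

#: Pearson correlations are capped at this magnitude before the Fisher
#: z-transform so that z = atanh(r) stays finite.
MAX_ABS_CORRELATION = 0.999


@dataclass
class EvidenceMatrix:
    """Per-dataset evidence scores for canonical gene pairs.

    Pairs absent from ``scores`` are unobserved in this dataset and later
    become MISSING bins.  ``kind`` is "continuous" (e.g. Fisher-z
    co-expression) or "binary" (e.g. a reported physical interaction).
    """

    dataset_id: str
    scores: dict[tuple[str, str], float]
    kind: str = "continuous"

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown evidence kind {self.kind!r}")


@dataclass
class DiscretizedEvidence:
    """Binned evidence for one dataset.

    ``bins`` maps canonical pair -> bin index in ``[0, n_bins)``; a pair
    absent from the mapping is MISSING.  ``bin_edges`` are the interior
    quantile edges (strictly increasing, length ``n_bins - 1``); intervals
    are right-closed, i.e. a score equal to an edge falls in the lower bin.
    """

    dataset_id: str
    n_bins: int
    bin_edges: list[float]
    bins: dict[tuple[str, str], int]

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.size and np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


@dataclass
class BayesModel:
    """Fitted naive-Bayes integration model for one tissue.

    ``cpts`` maps dataset_id -> dict with keys ``pos``/``neg`` (probability
    vectors over bins, each summing to 1 and strictly positive thanks to
    Laplace smoothing), ``bin_edges`` and ``n_bins``.
    """

    tissue: str
    prior: float
    cpts: dict[str, dict] = field(default_factory=dict)
    pseudocount: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.prior < 1.0):
            raise ValueError(f"prior {self.prior} outside (0, 1)")
        for ds, cpt in self.cpts.items():
            for key in ("pos", "neg"):
                row = np.asarray(cpt[key], dtype=float)
                if np.any(row <= 0.0):
                    raise ValueError(f"dataset {ds!r}: CPT {key} row has zeros")
                if abs(row.sum() - 1.0) > 1e-9:
                    raise ValueError(f"dataset {ds!r}: CPT {key} row sums to {row.sum()}")

    def to_json(self) -> str:
        doc = {
            "format_version": 1,
            "tissue": self.tissue,
            "prior": self.prior,
            "pseudocount": self.pseudocount,
            "datasets": {
                ds: {
                    "n_bins": int(cpt["n_bins"]),
                    "bin_edges": [float(e) for e in cpt["bin_edges"]],
                    "pos": [float(x) for x in cpt["pos"]],
                    "neg": [float(x) for x in cpt["neg"]],
                }
                for ds, cpt in self.cpts.items()
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BayesModel":
        doc = json.loads(text)
        if doc.get("format_version") != 1:
            raise FormatError(f"unsupported model format version {doc.get('format_version')!r}")
        cpts = {
            ds: {
                "n_bins": d["n_bins"],
                "bin_edges": list(d["bin_edges"]),
                "pos": np.asarray(d["pos"], dtype=float),
                "neg": np.asarray(d["neg"], dtype=float),
            }
            for ds, d in doc["datasets"].items()
        }
        return cls(
            tissue=doc["tissue"],
            prior=doc["prior"],
            cpts=cpts,
            pseudocount=doc["pseudocount"],
        )


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def correlation_evidence(dataset: ExpressionDataset) -> EvidenceMatrix:
    """Fisher-z co-expression evidence from one expression dataset.

    For every gene pair with >= 3 pairwise-complete samples, the score is
    ``atanh(r)`` of the Pearson correlation, with |r| capped at 0.999 to
    stay finite.  Pairs involving a zero-variance gene or with fewer than 3
    shared samples are absent from the scores (later MISSING).
    """
    df = dataset.to_frame().T  # samples x genes; pandas corr is pairwise-complete
    # sorting genes first makes the upper-triangle pairs canonical by construction
    order = sorted(range(len(dataset.genes)), key=dataset.genes.__getitem__)
    genes = [dataset.genes[i] for i in order]
    corr = df.corr(min_periods=3).to_numpy()[np.ix_(order, order)]
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    r = corr[iu, ju]
    ok = np.isfinite(r)
    z = np.arctanh(np.clip(r[ok], -MAX_ABS_CORRELATION, MAX_ABS_CORRELATION))
    pairs = list(compress(combinations(genes, 2), ok))
    scores = dict(zip(pairs, z.tolist()))
    return EvidenceMatrix(dataset_id=dataset.dataset_id, scores=scores, kind="continuous")


def discretize(evidence: EvidenceMatrix, n_bins: int = 5) -> DiscretizedEvidence:
    """Quantile-bin continuous evidence; binary evidence passes through.

    Interior edges sit at the ``i/n_bins`` empirical quantiles of the
    present scores; duplicate edges collapse (with a warning) so the
    effective bin count can shrink down to 1 when the score distribution is
    degenerate.  Absent pairs stay absent (MISSING).
    """
    if evidence.kind == "binary":
        bins = {p: int(v > 0.5) for p, v in evidence.scores.items()}
        return DiscretizedEvidence(evidence.dataset_id, 2, [0.5], bins)

    if n_bins < 2:
        raise ValueError("n_bins must be >= 2 for continuous evidence")
    pairs = list(evidence.scores)
    vals = np.fromiter(evidence.scores.values(), dtype=float, count=len(pairs))
    if vals.size == 0:
        return DiscretizedEvidence(evidence.dataset_id, 1, [], {})
    qs = np.quantile(vals, np.arange(1, n_bins) / n_bins)
    edges = np.unique(qs)
    # with right-closed intervals an edge at/above the maximum leaves the top
    # bin empty; drop such edges (all-equal scores collapse to one bin)
    edges = edges[edges < vals.max()]
    if edges.size < n_bins - 1:
        warnings.warn(
            f"dataset {evidence.dataset_id!r}: fewer distinct quantiles than "
            f"requested; collapsing to {edges.size + 1} bins",
            stacklevel=2,
        )
    idx = np.searchsorted(edges, vals, side="left")  # right-closed intervals
    bins = dict(zip(pairs, idx.tolist()))
    return DiscretizedEvidence(
        evidence.dataset_id, int(edges.size) + 1, [float(e) for e in edges], bins
    )


# ---------------------------------------------------------------------------
# model fitting and prediction
# ---------------------------------------------------------------------------

def fit_bayes(
    evidences: list[DiscretizedEvidence],
    standard: GoldStandard,
    prior="auto",
    pseudocount: float = 1.0,
) -> BayesModel:
    """Fit per-dataset CPTs against a labeled gold standard.

    CPT entry ``P(bin=b | class=c)`` is the Laplace-smoothed weighted
    fraction ``(W_cb + pseudocount) / (W_c + n_bins * pseudocount)`` where
    ``W_cb`` sums the weights of class-c pairs observed in bin b and ``W_c``
    those observed in any bin; MISSING pairs contribute to no bin.  With
    ``prior="auto"`` the prior is the weighted positive fraction of the
    standard.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    pos_w = sum(w for _, (lbl, w) in standard.pairs.items() if lbl == 1)
    neg_w = sum(w for _, (lbl, w) in standard.pairs.items() if lbl == 0)
    if pos_w == 0 or neg_w == 0:
        raise EmptyStandardError("standard needs >= 1 positive and >= 1 negative pair")
    if prior == "auto":
        prior_value = pos_w / (pos_w + neg_w)
    else:
        prior_value = float(prior)
        if not (0.0 < prior_value < 1.0):
            raise ValueError(f"prior {prior_value} outside (0, 1)")

    cpts: dict[str, dict] = {}
    for ev in evidences:
        nb = ev.n_bins
        counts = np.zeros((2, nb))
        observed = 0
        for pair, (label, w) in standard.pairs.items():
            b = ev.bins.get(pair)
            if b is None:
                continue
            counts[label, b] += w
            observed += 1
        if observed == 0:
            warnings.warn(
                f"dataset {ev.dataset_id!r}: every labeled pair is MISSING; "
                "CPT rows fall back to uniform",
                stacklevel=2,
            )
        smoothed = counts + pseudocount
        smoothed /= smoothed.sum(axis=1, keepdims=True)
        cpts[ev.dataset_id] = {
            "n_bins": nb,
            "bin_edges": list(ev.bin_edges),
            "neg": smoothed[0],
            "pos": smoothed[1],
        }
    return BayesModel(
        tissue=standard.tissue, prior=prior_value, cpts=cpts, pseudocount=pseudocount
    )


def posterior(model: BayesModel, pair_bins: dict[str, int | None]) -> float:
    """Posterior P(FR=1 | evidence) for one pair.

    ``pair_bins`` maps each of the model's dataset IDs to a bin index or
    None (MISSING, contributing likelihood ratio 1).  Computed in log space
    and renormalized, so the FR=1 / FR=0 posteriors sum to one exactly.
    """
    if set(pair_bins) != set(model.cpts):
        raise KeyError("pair_bins must cover exactly the model's datasets")
    log_odds = logit(model.prior)
    for ds, b in pair_bins.items():
        if b is None:
            continue
        cpt = model.cpts[ds]
        log_odds += np.log(cpt["pos"][b]) - np.log(cpt["neg"][b])
    return float(expit(log_odds))


def predict_network(
    model: BayesModel,
    evidences: list[DiscretizedEvidence],
    gene_universe,
    tissue: str | None = None,
) -> Network:
    """Posterior network over every unordered pair of the gene universe.

    Pairs unobserved in every dataset receive exactly the prior.
    """
    ev_by_id = {ev.dataset_id: ev for ev in evidences}
    if set(ev_by_id) != set(model.cpts):
        raise KeyError("model and evidences must share dataset IDs")
    genes = sorted(set(gene_universe))
    pairs = list(combinations(genes, 2))
    log_odds = np.full(len(pairs), logit(model.prior))
    for ds, cpt in model.cpts.items():
        llr = np.log(np.asarray(cpt["pos"], dtype=float)) - np.log(
            np.asarray(cpt["neg"], dtype=float)
        )
        bins = ev_by_id[ds].bins
        idx = np.fromiter((bins.get(p, -1) for p in pairs), dtype=np.int64, count=len(pairs))
        mask = idx >= 0
        log_odds[mask] += llr[idx[mask]]
    post = expit(log_odds)
    edges = {p: float(w) for p, w in zip(pairs, post)}
    return Network(tissue=tissue or model.tissue, nodes=set(genes), edges=edges)


class TissueNetworkIntegrator(BaseEstimator):
    """Tissue-specific evidence integrator (scikit-learn style).

    Discretizes a list of :class:`EvidenceMatrix`, fits the naive-Bayes
    model against a :class:`~tissuenets.gold.GoldStandard`, and predicts a
    posterior-probability :class:`~tissuenets.io.Network`.

    Parameters
    ----------
    n_bins : int, default=5
        Quantile bins per continuous dataset.
    pseudocount : float, default=1.0
        Laplace smoothing mass per CPT cell.
    prior : "auto" or float in (0, 1), default="auto"
        "auto" uses the standard's weighted positive fraction; co-annotation
        standards overstate the genomic prior, so a fixed value (e.g. 0.05)
        can be supplied instead.

    Attributes
    ----------
    model_ : BayesModel
        The fitted prior and per-dataset CPTs.
    discretized_ : list of DiscretizedEvidence
        The binned evidence the model was fit on (reused by ``predict``).

    Examples
    --------
    >>> integ = TissueNetworkIntegrator(n_bins=3)
    >>> net = integ.fit(evidences, standard).predict(gene_universe)  # doctest: +SKIP
    """

    def __init__(self, n_bins: int = 5, pseudocount: float = 1.0, prior="auto"):
        self.n_bins = n_bins
        self.pseudocount = pseudocount
        self.prior = prior

    def fit(self, evidences: list[EvidenceMatrix], standard: GoldStandard):
        """Discretize evidence and fit the per-dataset CPTs."""
        self.discretized_ = [discretize(ev, self.n_bins) for ev in evidences]
        self.model_ = fit_bayes(
            self.discretized_, standard, prior=self.prior, pseudocount=self.pseudocount
        )
        return self

    def predict(self, gene_universe, evidences: list[EvidenceMatrix] | None = None) -> Network:
        """Posterior network over the gene universe.

        By default the evidence seen at fit time is reused; passing fresh
        ``evidences`` re-bins them with the fitted edges' dataset layout.
        """
        if not hasattr(self, "model_"):
            raise RuntimeError("fit must be called before predict")
        if evidences is None:
            disc = self.discretized_
        else:
            disc = [discretize(ev, self.n_bins) for ev in evidences]
        return predict_network(self.model_, disc, gene_universe)
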