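"""Evidence transformation, discretization and the naive-Bayes integrator."""

import math

import numpy as np
import pytest

from tissuenets.gold import GoldStandard
from tissuenets.integrate import (
    BayesModel,
    DiscretizedEvidence,
    EvidenceMatrix,
    TissueNetworkIntegrator,
    correlation_evidence,
    discretize,
    fit_bayes,
    posterior,
    predict_network,
)
from tissuenets.io import ExpressionDataset


def make_dataset(values, genes=None, dataset_id="d1", context=""):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionDataset(dataset_id, context, genes, samples, values)


def random_model(rng, n_datasets, n_bins):
    cpts = {}
    for d in range(n_datasets):
        rows = rng.uniform(0.05, 1.0, size=(2, n_bins))
        rows /= rows.sum(axis=1, keepdims=True)
        cpts[f"d{d}"] = {
            "n_bins": n_bins,
            "bin_edges": list(range(1, n_bins)),
            "neg": rows[0],
            "pos": rows[1],
        }
    prior = float(rng.uniform(0.02, 0.98))
    return BayesModel(tissue="t", prior=prior, cpts=cpts)


def bruteforce_posterior(model, pair_bins):
    """Independent oracle: explicit sum over both classes, no log tricks."""
    num = {1: model.prior, 0: 1.0 - model.prior}
    for ds, b in pair_bins.items():
        if b is None:
            continue
        num[1] *= model.cpts[ds]["pos"][b]
        num[0] *= model.cpts[ds]["neg"][b]
    return num[1] / (num[1] + num[0])


class TestCorrelationEvidence:
    def test_identical_profiles_capped_fisher_z(self):
        ds = make_dataset([[1, 2, 3, 4], [1, 2, 3, 4]])
        ev = correlation_evidence(ds)
        assert ev.scores[("G0", "G1")] == pytest.approx(math.atanh(0.999), abs=1e-12)
        # frozen reference value of atanh(0.999)
        assert ev.scores[("G0", "G1")] == pytest.approx(3.8002011672502151, abs=1e-9)

    def test_orthogonal_profiles_zero(self):
        ds = make_dataset([[1, -1, 1, -1], [1, 1, -1, -1]])
        ev = correlation_evidence(ds)
        assert ev.scores[("G0", "G1")] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_absent(self):
        ds = make_dataset([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]])
        ev = correlation_evidence(ds)
        assert all("G0" not in pair for pair in ev.scores)
        assert ("G1", "G2") in ev.scores

    def test_pairwise_complete_minimum_three_samples(self):
        values = np.array(
            [[1.0, 2.0, np.nan, np.nan], [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 0.5, 0.0]]
        )
        ev = correlation_evidence(make_dataset(values))
        # G0 shares only 2 complete samples with the others
        assert all("G0" not in pair for pair in ev.scores)

    def test_pairs_are_canonical_for_unsorted_gene_lists(self):
        ds = make_dataset([[1, 2, 3, 4], [2, 1, 4, 3]], genes=["ZZ", "AA"])
        ev = correlation_evidence(ds)
        assert all(a < b for a, b in ev.scores)


class TestDiscretize:
    def _ev(self, scores):
        return EvidenceMatrix("d", scores)

    def test_median_split(self):
        scores = {("A", "B"): 1.0, ("A", "C"): 2.0, ("B", "C"): 3.0, ("B", "D"): 4.0}
        disc = discretize(self._ev(scores), n_bins=2)
        assert disc.bins == {("A", "B"): 0, ("A", "C"): 0, ("B", "C"): 1, ("B", "D"): 1}

    def test_all_equal_collapse_to_single_bin(self):
        scores = {("A", "B"): 1.0, ("A", "C"): 1.0}
        with pytest.warns(UserWarning, match="collapsing"):
            disc = discretize(self._ev(scores), n_bins=3)
        assert disc.n_bins == 1
        assert set(disc.bins.values()) == {0}

    def test_missing_pair_stays_missing(self):
        disc = discretize(self._ev({("A", "B"): 1.0, ("A", "C"): 2.0}), n_bins=2)
        assert ("B", "C") not in disc.bins

    def test_binary_evidence_passthrough(self):
        ev = EvidenceMatrix("d", {("A", "B"): 1.0, ("A", "C"): 0.0}, kind="binary")
        disc = discretize(ev, n_bins=5)
        assert disc.n_bins == 2
        assert disc.bins == {("A", "B"): 1, ("A", "C"): 0}

    def test_quantile_bins_roughly_balanced(self, rng):
        scores = {(f"A{i}", f"B{i}"): float(v) for i, v in enumerate(rng.normal(size=1000))}
        disc = discretize(self._ev(scores), n_bins=5)
        counts = np.bincount(list(disc.bins.values()), minlength=5)
        assert counts.min() > 150


class TestFitBayes:
    def test_laplace_smoothed_counts_exact(self):
        # positives in bins [0, 0, 0, 1] -> P(bin0 | FR=1) = (3+1)/(4+2) = 2/3
        bins = {("A", "B"): 0, ("A", "C"): 0, ("A", "D"): 0, ("A", "E"): 1,
                ("X", "Y"): 1}
        disc = DiscretizedEvidence("d", 2, [0.5], bins)
        std = GoldStandard(
            tissue="t",
            pairs={
                ("A", "B"): (1, 1.0), ("A", "C"): (1, 1.0),
                ("A", "D"): (1, 1.0), ("A", "E"): (1, 1.0),
                ("X", "Y"): (0, 1.0),
            },
        )
        model = fit_bayes([disc], std, pseudocount=1.0)
        assert model.cpts["d"]["pos"][0] == pytest.approx(2.0 / 3.0, abs=1e-15)
        assert model.cpts["d"]["pos"][1] == pytest.approx(1.0 / 3.0, abs=1e-15)

    def test_fractional_weight_contributes_linearly(self):
        disc = DiscretizedEvidence("d", 2, [0.5], {("A", "B"): 0, ("X", "Y"): 1})
        std = GoldStandard(
            tissue="t", pairs={("A", "B"): (1, 0.5), ("X", "Y"): (0, 1.0)}
        )
        model = fit_bayes([disc], std, pseudocount=1.0)
        assert model.cpts["d"]["pos"][0] == pytest.approx((0.5 + 1) / (0.5 + 2))

    def test_unobserved_dataset_uniform_rows(self):
        disc = DiscretizedEvidence("d", 2, [0.5], {})
        std = GoldStandard(
            tissue="t", pairs={("A", "B"): (1, 1.0), ("X", "Y"): (0, 1.0)}
        )
        with pytest.warns(UserWarning, match="MISSING"):
            model = fit_bayes([disc], std)
        np.testing.assert_allclose(model.cpts["d"]["pos"], [0.5, 0.5])
        np.testing.assert_allclose(model.cpts["d"]["neg"], [0.5, 0.5])

    def test_auto_prior_is_weighted_positive_fraction(self):
        disc = DiscretizedEvidence("d", 2, [0.5], {("A", "B"): 0, ("X", "Y"): 1})
        std = GoldStandard(
            tissue="t", pairs={("A", "B"): (1, 0.5), ("X", "Y"): (0, 1.0)}
        )
        model = fit_bayes([disc], std, prior="auto")
        assert model.prior == pytest.approx(0.5 / 1.5)

    def test_cpt_rows_sum_to_one(self, rng):
        pairs = [(f"A{i}", f"B{i}") for i in range(30)]
        disc = DiscretizedEvidence(
            "d", 3, [0.3, 0.6],
            {p: int(rng.integers(0, 3)) for p in pairs},
        )
        std = GoldStandard(
            tissue="t",
            pairs={p: (int(rng.integers(0, 2)) if i > 1 else i % 2, 1.0)
                   for i, p in enumerate(pairs)},
        )
        model = fit_bayes([disc], std)
        for key in ("pos", "neg"):
            assert abs(model.cpts["d"][key].sum() - 1.0) < 1e-12


class TestPosterior:
    def test_single_dataset_bayes_rule(self):
        model = BayesModel(
            tissue="t",
            prior=0.1,
            cpts={"d": {"n_bins": 2, "bin_edges": [0.5],
                        "pos": np.array([0.8, 0.2]),
                        "neg": np.array([0.2, 0.8])}},
        )
        # 0.1*0.8 / (0.1*0.8 + 0.9*0.2) = 0.08 / 0.26
        assert posterior(model, {"d": 0}) == pytest.approx(0.08 / 0.26, abs=1e-12)

    def test_uniform_cpts_return_prior(self, rng):
        model = BayesModel(
            tissue="t", prior=0.37,
            cpts={"d": {"n_bins": 2, "bin_edges": [0.5],
                        "pos": np.array([0.5, 0.5]),
                        "neg": np.array([0.5, 0.5])}},
        )
        assert posterior(model, {"d": 1}) == pytest.approx(0.37, abs=1e-12)

    def test_all_missing_returns_prior(self, rng):
        model = random_model(rng, 3, 4)
        bins = {ds: None for ds in model.cpts}
        assert posterior(model, bins) == pytest.approx(model.prior, abs=1e-12)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(50):
            n_datasets = int(rng.integers(1, 5))
            n_bins = int(rng.integers(2, 6))
            model = random_model(rng, n_datasets, n_bins)
            bins = {
                ds: (None if rng.random() < 0.25 else int(rng.integers(0, n_bins)))
                for ds in model.cpts
            }
            assert posterior(model, bins) == pytest.approx(
                bruteforce_posterior(model, bins), abs=1e-12
            )

    def test_conservation_of_probability(self, rng):
        model = random_model(rng, 3, 3)
        bins = {ds: 1 for ds in model.cpts}
        p1 = posterior(model, bins)
        flipped = BayesModel(
            tissue="t", prior=1 - model.prior,
            cpts={ds: {**cpt, "pos": cpt["neg"], "neg": cpt["pos"]}
                  for ds, cpt in model.cpts.items()},
        )
        assert p1 + posterior(flipped, bins) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_likelihood_ratio(self, rng):
        model = random_model(rng, 2, 3)
        bins = {"d0": 0, "d1": 1}
        base = posterior(model, bins)
        boosted_cpts = {ds: dict(cpt) for ds, cpt in model.cpts.items()}
        pos = boosted_cpts["d0"]["pos"].copy()
        pos[0] = min(0.95, pos[0] * 1.5)
        pos /= pos.sum()
        boosted_cpts["d0"] = {**boosted_cpts["d0"], "pos": pos}
        if pos[0] / boosted_cpts["d0"]["neg"][0] >= (
            model.cpts["d0"]["pos"][0] / model.cpts["d0"]["neg"][0]
        ):
            boosted = BayesModel(tissue="t", prior=model.prior, cpts=boosted_cpts)
            assert posterior(boosted, bins) >= base - 1e-15


class TestPredictNetwork:
    def _setup(self):
        bins = {("A", "B"): 0}
        disc = DiscretizedEvidence("d", 2, [0.5], bins)
        model = BayesModel(
            tissue="t", prior=0.1,
            cpts={"d": {"n_bins": 2, "bin_edges": [0.5],
                        "pos": np.array([0.8, 0.2]),
                        "neg": np.array([0.2, 0.8])}},
        )
        return model, disc

    def test_pair_enumeration_and_prior_fallback(self):
        model, disc = self._setup()
        net = predict_network(model, [disc], {"A", "B", "C"})
        assert len(net.edges) == 3
        assert net.edges[("A", "C")] == pytest.approx(0.1, abs=1e-12)
        assert net.edges[("A", "B")] == pytest.approx(0.08 / 0.26, abs=1e-12)

    def test_empty_universe_empty_network(self):
        model, disc = self._setup()
        net = predict_network(model, [disc], set())
        assert net.edges == {} and net.nodes == set()

    def test_weights_in_unit_interval(self, rng):
        model = random_model(rng, 3, 4)
        discs = [
            DiscretizedEvidence(
                ds, 4, [1, 2, 3],
                {("A", "B"): int(rng.integers(0, 4))},
            )
            for ds in model.cpts
        ]
        net = predict_network(model, discs, {"A", "B", "C"})
        assert all(0.0 <= w <= 1.0 for w in net.edges.values())


class TestIntegratorEstimator:
    def test_fit_predict_and_sklearn_params(self):
        from sklearn.base import clone

        ev = EvidenceMatrix("d", {("A", "B"): 3.0, ("A", "C"): 0.1, ("B", "C"): 0.2,
                                  ("C", "D"): 2.9})
        std = GoldStandard(
            tissue="t",
            pairs={("A", "B"): (1, 1.0), ("C", "D"): (1, 1.0),
                   ("A", "C"): (0, 1.0), ("B", "C"): (0, 1.0)},
        )
        integ = TissueNetworkIntegrator(n_bins=2, prior=0.2)
        assert clone(integ).get_params()["n_bins"] == 2
        net = integ.fit([ev], std).predict({"A", "B", "C", "D"})
        assert integ.model_.prior == 0.2
        # co-expressed pairs end above the anticorrelated ones
        assert net.edges[("A", "B")] > net.edges[("A", "C")]

    def test_model_json_round_trip(self, rng):
        model = random_model(rng, 2, 3)
        back = BayesModel.from_json(model.to_json())
        assert back.prior == pytest.approx(model.prior)
        for ds in model.cpts:
            np.testing.assert_allclose(back.cpts[ds]["pos"], model.cpts[ds]["pos"])
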