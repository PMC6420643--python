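"""Binomial-mixture edit calling, site selection and barcode encoding."""

import numpy as np
import pytest
from scipy import stats

from deamtrace import calling


def synth_counts(rng, n_sites=200, depth=100, eps=0.002, theta=0.5, pi=0.3):
    out = []
    for i in range(n_sites):
        edited = rng.random() < pi
        p = theta if edited else eps
        k = rng.binomial(depth, p)
        out.append(calling.SiteCounts.from_counts(f"s{i}", "S1", depth, int(k)))
    return out


class TestFitMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        counts = synth_counts(rng)
        fit = calling.fit_mixture(counts, seed=0)
        assert abs(fit.pi - 0.3) <= 0.05
        assert abs(fit.theta - 0.5) <= 0.05
        assert abs(fit.epsilon - 0.002) <= 0.05
        assert fit.epsilon < fit.theta

    def test_all_zero_alt_degenerate(self):
        counts = [
            calling.SiteCounts.from_counts(f"s{i}", "S", 50, 0) for i in range(20)
        ]
        fit = calling.fit_mixture(counts)
        assert fit.degenerate
        assert fit.pi <= 0.01

    def test_two_component_nests_single_component(self):
        # background-only data: the mixture can always match the single
        # binomial's likelihood at its MLE
        rng = np.random.default_rng(2)
        counts = [
            calling.SiteCounts.from_counts(f"s{i}", "S", 100, int(rng.binomial(100, 0.01)))
            for i in range(100)
        ]
        fit = calling.fit_mixture(counts, seed=0)
        k = np.array([c.alt_count for c in counts])
        n = np.array([c.depth for c in counts])
        p_hat = k.sum() / n.sum()
        loglik_1 = stats.binom.logpmf(k, n, p_hat).sum()
        assert fit.loglik >= loglik_1 - 1e-6

    def test_requires_ten_covered_sites(self):
        counts = [calling.SiteCounts.from_counts("s", "S", 10, 1)] * 5
        with pytest.raises(ValueError):
            calling.fit_mixture(counts)

    def test_site_order_invariance(self):
        rng = np.random.default_rng(7)
        counts = synth_counts(rng, n_sites=60)
        fit1 = calling.fit_mixture(counts, seed=0)
        fit2 = calling.fit_mixture(list(reversed(counts)), seed=0)
        assert fit1.loglik == pytest.approx(fit2.loglik)
        assert fit1.pi == pytest.approx(fit2.pi)

    def test_ploidy_levels_mode(self):
        rng = np.random.default_rng(3)
        counts = synth_counts(rng, theta=1 / 3)
        fit = calling.fit_mixture(counts, ploidy_levels=[1 / 3, 2 / 3, 1.0], seed=0)
        assert fit.theta == (1 / 3, 2 / 3, 1.0)
        assert 0 < fit.pi < 1


class TestCallEdits:
    @pytest.fixture
    def fit(self):
        return calling.MixtureFit(
            pi=0.3, theta=0.5, epsilon=0.002, loglik=0.0, n_iter=1, converged=True
        )

    def test_strong_signal_called(self, fit):
        c = calling.SiteCounts.from_counts("s1", "S", 100, 50)
        (call,) = calling.call_edits([c], fit)
        assert call.posterior > 0.999
        assert call.called

    def test_depth_threshold_is_strict(self, fit):
        c = calling.SiteCounts.from_counts("s1", "S", 8, 8)
        (call,) = calling.call_edits([c], fit)
        assert not call.called

    def test_alt_count_threshold_is_strict(self, fit):
        c = calling.SiteCounts.from_counts("s1", "S", 1000, 2)
        (call,) = calling.call_edits([c], fit)
        assert not call.called

    def test_control_vaf_filter(self, fit):
        c = calling.SiteCounts.from_counts("s1", "S", 100, 50)
        (call,) = calling.call_edits([c], fit, control_vafs={"s1": 0.6})
        assert not call.called
        (call,) = calling.call_edits([c], fit, control_vafs={"s1": 0.1})
        assert call.called

    def test_posterior_monotone_in_alt_count(self, fit):
        posts = [
            calling.posterior_edited(fit, k, 100) for k in range(0, 60, 5)
        ]
        assert all(b >= a for a, b in zip(posts, posts[1:]))


class TestAveragePairedC:
    def mk(self, site, depth, alt):
        return calling.SiteCounts.from_counts(site, "S", depth, alt)

    def test_mean_of_vafs(self):
        m = calling.average_paired_c(self.mk("a", 100, 10), self.mk("b", 100, 30))
        assert m.vaf == pytest.approx(0.20)
        assert m.depth == 100

    def test_idempotent_on_equal_vafs(self):
        m = calling.average_paired_c(self.mk("a", 50, 10), self.mk("b", 200, 40))
        assert m.vaf == pytest.approx(0.2)
        assert m.depth == 50  # conservative minimum

    def test_zero_depth_fallback(self):
        m = calling.average_paired_c(self.mk("a", 0, 0), self.mk("b", 100, 25))
        assert m.vaf == pytest.approx(0.25)
        assert m.depth == 100

    def test_different_targets_error(self):
        with pytest.raises(ValueError):
            calling.average_paired_c(
                self.mk("a", 10, 1),
                self.mk("b", 10, 1),
                target_of={"a": "t1", "b": "t2"},
            )


class TestSiteProbabilities:
    def test_normalisation(self):
        mat = np.array([[0.1, 0.1], [0.3, 0.3]])
        probs = calling.site_probabilities(mat, ["a", "b"])
        assert probs == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}

    def test_single_site(self):
        assert calling.site_probabilities(np.array([[0.4]]), ["x"]) == {"x": 1.0}

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            calling.site_probabilities(np.zeros((3, 2)), list("abc"))

    def test_permutation_equivariance(self):
        mat = np.array([[0.1, 0.2], [0.3, 0.1], [0.2, 0.2]])
        p1 = calling.site_probabilities(mat, list("abc"))
        p2 = calling.site_probabilities(mat[::-1], list("cba"))
        for k in "abc":
            assert p1[k] == pytest.approx(p2[k])


class TestFilterSites:
    def test_saturated_site_removed(self, rng):
        mat = np.vstack([np.full(10, 0.85), rng.uniform(0.0, 0.3, size=(3, 10))])
        sites = ["sat", "a", "b", "c"]
        probs = {s: 0.001 for s in sites}
        kept = calling.filter_sites(probs, mat, blacklist=())
        assert "sat" not in kept

    def test_probability_rule_removes(self, rng):
        mat = rng.uniform(0.0, 0.3, size=(3, 10))
        probs = {"a": 0.005, "b": 0.001, "c": 0.001}
        kept = calling.filter_sites(probs, mat)
        assert "a" not in kept and {"b", "c"} <= set(kept)

    def test_identical_columns_one_removed(self):
        col = np.linspace(0.05, 0.5, 8)
        mat = np.vstack([col, col])
        kept = calling.filter_sites({"a": 0.001, "b": 0.001}, mat)
        assert kept == ["a"]

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(0)
        mat = rng.uniform(0.0, 0.5, size=(2, 50))
        r2 = np.corrcoef(mat[0], mat[1])[0, 1] ** 2
        assert r2 < 0.8  # oracle: explicit correlation
        kept = calling.filter_sites({"a": 0.001, "b": 0.001}, mat)
        assert kept == ["a", "b"]

    def test_blacklist_and_idempotence(self, rng):
        mat = rng.uniform(0.0, 0.4, size=(4, 20))
        sites = list("abcd")
        probs = {s: 0.001 for s in sites}
        kept = calling.filter_sites(probs, mat, blacklist={"c"})
        assert "c" not in kept
        # applying the filter to the retained submatrix changes nothing
        idx = [sites.index(s) for s in kept]
        again = calling.filter_sites(
            {s: probs[s] for s in kept}, mat[idx]
        )
        assert again == kept


class TestBarcodeEncoding:
    sites = [f"site{i}" for i in range(12)]

    def test_cigar_example(self):
        bc = calling.encode_barcode("S", [self.sites[0], self.sites[9]], self.sites)
        assert bc.cigar_string == "1E10E"

    def test_empty(self):
        bc = calling.encode_barcode("S", [], self.sites)
        assert bc.cigar_string == ""
        assert calling.decode_barcode("", self.sites) == frozenset()

    def test_unknown_site(self):
        with pytest.raises(KeyError):
            calling.encode_barcode("S", ["nope"], self.sites)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        chosen = [s for s in self.sites if rng.random() < 0.4]
        bc = calling.encode_barcode("S", chosen, self.sites)
        assert calling.decode_barcode(bc.cigar_string, self.sites) == frozenset(chosen)

    def test_binary_vector(self):
        bc = calling.encode_barcode("S", [self.sites[2]], self.sites)
        vec = calling.binary_vector(bc, self.sites)
        assert vec.sum() == 1 and vec[2] == 1


class TestProbabilityTransfer:
    def test_restriction_to_shared_sites(self):
        bulk = {"a": 0.4, "b": 0.35, "c": 0.25}
        assert calling.transfer_site_probabilities(bulk, ["a", "c", "zz"]) == {
            "a": 0.4,
            "c": 0.25,
        }
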