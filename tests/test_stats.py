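import numpy as np
import pytest

import oracles
from essconserv import (
    bootstrap_means,
    cross_organism_ttest,
    mann_whitney_u,
    summarize_organism,
)
from essconserv.ng86 import KaKsResult
from essconserv.stats import MetricSummary, OrganismSummary


def result(ka=0.1, ks=0.5, ratio="auto", valid=True, zero=False):
    if ratio == "auto":
        ratio = (ka / ks) if (valid and ks and ks > 0) else None
    return KaKsResult(
        S=100, N=200, Sd=10, Nd=5, pS=0.1, pN=0.025,
        Ka=ka if valid else None, Ks=ks if valid else None, ratio=ratio,
        valid_ka=valid, valid_ks=valid, zero_variation=zero, n_codons=100,
    )


class TestMannWhitney:
    def test_fully_separated_three_vs_three(self):
        _, p = mann_whitney_u([0.05, 0.06, 0.07], [0.2, 0.3, 0.4])
        assert p == pytest.approx(0.1)

    def test_identical_value_sets_give_p_one(self):
        _, p = mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_constant_large_samples_give_p_one(self):
        _, p = mann_whitney_u([2.0] * 30, [2.0] * 40)
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_branch_matches_rank_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 10 - n1 + 1))
        # ties made likely on purpose
        x = list(rng.integers(0, 4, n1).astype(float))
        y = list(rng.integers(0, 4, n2).astype(float))
        u, p = mann_whitney_u(x, y)
        u_exp, p_exp = oracles.mwu_exact(x, y)
        assert u == pytest.approx(u_exp)
        assert p == pytest.approx(p_exp)

    def test_large_sample_branch_close_to_exact_enumeration(self):
        rng = np.random.default_rng(3)
        x = list(rng.normal(0, 1, 5))
        y = list(rng.normal(1, 1, 6))
        # n = 11 uses the normal approximation; compare loosely to the
        # exact enumeration of the same data
        _, p_asym = mann_whitney_u(x, y)
        _, p_exact = oracles.mwu_exact(x, y)
        assert p_asym == pytest.approx(p_exact, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSummarizeOrganism:
    def test_means_and_exact_p(self):
        triples = [
            ("e1", True, result(ka=0.05, ks=1.0)),
            ("e2", True, result(ka=0.06, ks=1.0)),
            ("e3", True, result(ka=0.07, ks=1.0)),
            ("n1", False, result(ka=0.2, ks=1.0)),
            ("n2", False, result(ka=0.3, ks=1.0)),
            ("n3", False, result(ka=0.4, ks=1.0)),
        ]
        summary = summarize_organism("orgA", triples)
        ka = summary.metrics["Ka"]
        assert ka.mean_essential == pytest.approx(0.06)
        assert ka.mean_nonessential == pytest.approx(0.30)
        assert ka.p_value == pytest.approx(0.1)
        kaks = summary.metrics["KaKs"]
        assert kaks.mean_essential == pytest.approx(0.06)

    def test_undefined_ratio_excluded_from_ratio_mean(self):
        triples = [
            ("e1", True, result(ka=0.1, ks=0.5)),
            ("n1", False, result(ka=0.2, ks=0.5)),
            ("n2", False, result(ka=0.0, ks=0.0, ratio=None, zero=True)),
        ]
        summary = summarize_organism("orgA", triples)
        kaks = summary.metrics["KaKs"]
        assert kaks.n_nonessential == 1
        assert kaks.mean_nonessential == pytest.approx(0.4)
        # the zero-variation gene still contributes Ka = Ks = 0
        assert summary.metrics["Ka"].n_nonessential == 2
        assert summary.metrics["Ka"].mean_nonessential == pytest.approx(0.1)

    def test_empty_class_reports_none_entries(self):
        triples = [("e1", True, result())]
        summary = summarize_organism("orgA", triples)
        assert summary.metrics["Ka"].p_value is None
        assert summary.metrics["Ka"].mean_nonessential is None


class TestBootstrap:
    def test_constant_input_constant_output(self):
        boot = bootstrap_means([0.2] * 10, reps=50, seed=1)
        assert np.all(boot.replicate_means == 0.2)

    def test_replicate_count(self):
        boot = bootstrap_means([1.0, 2.0, 3.0], reps=1000, seed=2)
        assert boot.replicate_means.shape == (1000,)

    def test_deterministic_for_fixed_seed(self):
        a = bootstrap_means([1.0, 5.0, 9.0, 2.0], reps=200, seed=7)
        b = bootstrap_means([1.0, 5.0, 9.0, 2.0], reps=200, seed=7)
        assert np.array_equal(a.replicate_means, b.replicate_means)

    def test_grand_mean_near_population_mean(self):
        boot = bootstrap_means([0.0, 1.0], reps=10000, seed=3)
        assert abs(boot.replicate_means.mean() - 0.5) < 0.02

    def test_replicate_means_bounded_by_input_range(self):
        values = [0.1, 0.4, 0.9, 1.5]
        boot = bootstrap_means(values, reps=500, seed=4)
        assert boot.replicate_means.min() >= min(values)
        assert boot.replicate_means.max() <= max(values)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            bootstrap_means([], reps=10, seed=0)
        with pytest.raises(ValueError):
            bootstrap_means([1.0], reps=0, seed=0)

    def test_coverage_of_population_mean(self):
        """Central 95% of replicate means brackets the sample mean in most
        repeated experiments (loose anti-bug check)."""
        rng = np.random.default_rng(11)
        covered = 0
        trials = 25
        for k in range(trials):
            values = rng.exponential(1.0, size=30)
            boot = bootstrap_means(values, reps=400, seed=k)
            lo, hi = np.percentile(boot.replicate_means, [2.5, 97.5])
            covered += lo <= values.mean() <= hi
        assert covered / trials >= 0.8


def summary_from_means(pairs):
    metrics = {
        "Ka": MetricSummary(None, None, None, 0, 0),
        "Ks": MetricSummary(None, None, None, 0, 0),
    }
    out = []
    for i, (e, n) in enumerate(pairs):
        m = dict(metrics)
        m["KaKs"] = MetricSummary(e, n, 0.5, 10, 10)
        out.append(OrganismSummary(organism_id=f"org{i}", metrics=m))
    return out


class TestCrossOrganismTTest:
    def test_equal_means_give_t_zero_p_one(self):
        summaries = summary_from_means([(0.1, 0.1), (0.2, 0.2), (0.3, 0.3)])
        t, p = cross_organism_ttest(summaries, "KaKs")
        assert t == 0.0 and p == 1.0

    def test_matches_closed_form_on_worked_differences(self):
        pairs = [(0.1, 0.2), (0.1, 0.3), (0.1, 0.4), (0.1, 0.5)]
        t, p = cross_organism_ttest(summary_from_means(pairs), "KaKs")
        t_exp, p_exp = oracles.paired_t(*zip(*pairs))
        assert t == pytest.approx(t_exp)
        assert p == pytest.approx(p_exp)

    def test_reversed_pairs_flip_sign(self):
        pairs = [(0.1, 0.2), (0.15, 0.3), (0.12, 0.4), (0.1, 0.5)]
        t1, p1 = cross_organism_ttest(summary_from_means(pairs), "KaKs")
        t2, p2 = cross_organism_ttest(
            summary_from_means([(b, a) for a, b in pairs]), "KaKs"
        )
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_few_organisms(self):
        with pytest.raises(ValueError, match=">= 3"):
            cross_organism_ttest(summary_from_means([(0.1, 0.2)]), "KaKs")
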