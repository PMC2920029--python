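"""Metropolis-Hastings kernel: correctness on analytic targets."""

import numpy as np
import pytest
from scipy import stats

from mesoproj.sampler import (
    PosteriorChain,
    PriorSpec,
    ProposalSpec,
    mh_step,
    run_chain,
    summarise,
    tune_proposals,
)


def gaussian_target(mu=0.0, sd=1.0):
    return lambda s: float(-0.5 * ((s["x"] - mu) / sd) ** 2)


class TestMhStep:
    def test_out_of_support_always_rejected(self):
        priors = PriorSpec({"x": (0.0, 1.0)})
        props = ProposalSpec({"x": 100.0})  # virtually every proposal leaves [0, 1]
        rng = np.random.default_rng(0)
        state, lp = {"x": 0.5}, 0.0
        accepts = 0
        for _ in range(200):
            state, lp, acc = mh_step(state, "x", lambda s: 0.0, lp, priors, props, rng)
            accepts += acc
        assert accepts <= 2
        assert 0.0 <= state["x"] <= 1.0

    def test_flat_target_accepts_in_support(self):
        priors = PriorSpec({"x": (0.0, 1.0)})
        props = ProposalSpec({"x": 0.05})  # small steps stay in support
        rng = np.random.default_rng(1)
        state, lp = {"x": 0.5}, 0.0
        accepts = sum(
            mh_step(state, "x", lambda s: 0.0, lp, priors, props, rng)[2] for _ in range(500)
        )
        assert accepts / 500 > 0.9

    def test_nonfinite_state_raises(self):
        priors = PriorSpec({"x": (0.0, 1.0)})
        props = ProposalSpec({"x": 0.1})
        with pytest.raises(ValueError):
            mh_step({"x": 0.5}, "x", lambda s: 0.0, -np.inf, priors, props, np.random.default_rng(0))

    def test_integer_parameter_steps_are_integral(self):
        priors = PriorSpec({"n": (0, 100)}, integer=frozenset({"n"}))
        props = ProposalSpec({"n": 2.0})
        rng = np.random.default_rng(2)
        state, lp = {"n": 50}, 0.0
        for _ in range(100):
            state, lp, _ = mh_step(state, "n", lambda s: 0.0, lp, priors, props, rng)
        assert state["n"] == int(state["n"])


class TestConjugateValidation:
    def test_poisson_gamma_posterior(self):
        """Chain quantiles match the closed-form Gamma posterior of a
        Poisson rate with a (truncated) flat prior within MC error."""
        rng = np.random.default_rng(3)
        y = rng.poisson(4.0, size=25)
        a, b = 1.0 + y.sum(), 25.0  # Gamma(a, b) posterior under flat prior

        def log_post(s):
            lam = s["lam"]
            return float(y.sum() * np.log(lam) - 25 * lam)

        priors = PriorSpec({"lam": (1e-9, 50.0)})
        props, state = tune_proposals(log_post, priors, {"lam": 4.0}, rng)
        chain = run_chain(log_post, priors, props, state, n_burn=2000, n_keep=20_000, rng=rng)
        draws = chain.column("lam")
        post = stats.gamma(a, scale=1.0 / b)
        # MC standard error of the mean, inflated for autocorrelation
        se = post.std() / np.sqrt(len(draws) / 10)
        assert abs(draws.mean() - post.mean()) < 3 * se
        for q in (0.05, 0.5, 0.95):
            assert np.quantile(draws, q) == pytest.approx(post.ppf(q), rel=0.05)

    def test_discrete_three_state_stationary(self):
        """Detailed-balance smoke test on a 3-state discrete target."""
        target = np.array([0.2, 0.5, 0.3])

        def log_post(s):
            return float(np.log(target[int(s["n"])]))

        priors = PriorSpec({"n": (0, 2)}, integer=frozenset({"n"}))
        props = ProposalSpec({"n": 1.0})
        chain = run_chain(log_post, priors, props, {"n": 1}, n_burn=500, n_keep=30_000, seed=5)
        freq = np.bincount(chain.column("n").astype(int), minlength=3) / len(chain)
        assert freq == pytest.approx(target, abs=0.02)


class TestTuning:
    def test_well_scaled_unchanged(self):
        priors = PriorSpec({"x": (-50.0, 50.0)})
        rng = np.random.default_rng(6)
        good = ProposalSpec({"x": 4.0})  # acceptance comfortably inside the band
        tuned, _ = tune_proposals(gaussian_target(), priors, {"x": 0.0}, rng, proposals=good)
        assert tuned.scales["x"] == pytest.approx(4.0)

    def test_oversized_scale_reduced(self):
        priors = PriorSpec({"x": (-50.0, 50.0)})
        rng = np.random.default_rng(7)
        huge = ProposalSpec({"x": 240.0})
        tuned, _ = tune_proposals(gaussian_target(), priors, {"x": 0.0}, rng, proposals=huge)
        assert tuned.scales["x"] < 240.0 / 4

    def test_integer_scale_keeps_minimum_step(self):
        target = np.array([0.98, 0.01, 0.01])  # sharply peaked discrete target

        def log_post(s):
            return float(np.log(target[int(s["n"])]))

        priors = PriorSpec({"n": (0, 2)}, integer=frozenset({"n"}))
        rng = np.random.default_rng(8)
        tuned, _ = tune_proposals(log_post, priors, {"n": 0}, rng)
        assert tuned.scales["n"] >= 0.5


class TestRunChain:
    def test_empty_chain_bookkeeping(self):
        priors = PriorSpec({"x": (-5.0, 5.0)})
        chain = run_chain(gaussian_target(), priors, ProposalSpec({"x": 1.0}),
                          {"x": 0.0}, n_burn=10, n_keep=0, seed=1)
        assert len(chain) == 0
        with pytest.raises(ValueError):
            summarise(chain)

    def test_same_seed_identical_chains(self):
        priors = PriorSpec({"x": (-5.0, 5.0)})
        props = ProposalSpec({"x": 1.0})
        a = run_chain(gaussian_target(), priors, props, {"x": 0.0}, n_burn=100, n_keep=500, seed=42)
        b = run_chain(gaussian_target(), priors, props, {"x": 0.0}, n_burn=100, n_keep=500, seed=42)
        assert np.array_equal(a.draws, b.draws)

    def test_draws_respect_support(self):
        priors = PriorSpec({"x": (0.0, 1.0)})
        chain = run_chain(gaussian_target(), priors, ProposalSpec({"x": 0.3}),
                          {"x": 0.5}, n_burn=100, n_keep=2000, seed=9)
        assert chain.draws.min() >= 0.0 and chain.draws.max() <= 1.0

    def test_invalid_init_rejected(self):
        priors = PriorSpec({"x": (0.0, 1.0)})
        with pytest.raises(ValueError):
            run_chain(gaussian_target(), priors, ProposalSpec({"x": 0.3}), {"x": 2.0},
                      n_burn=10, n_keep=10, seed=0)

    def test_csv_round_trip(self, tmp_path):
        priors = PriorSpec({"x": (-5.0, 5.0)})
        chain = run_chain(gaussian_target(), priors, ProposalSpec({"x": 1.0}),
                          {"x": 0.0}, n_burn=10, n_keep=50, seed=3)
        chain.to_csv(tmp_path / "chain.csv")
        back = PosteriorChain.from_csv(tmp_path / "chain.csv")
        assert back.names == chain.names
        assert back.draws == pytest.approx(chain.draws)


class TestSummarise:
    def test_constant_chain(self):
        chain = PosteriorChain(names=["a"], draws=np.full((100, 1), 3.3),
                               acceptance={"a": 0.0}, n_burn=0)
        s = summarise(chain)
        assert s.loc["a", "median"] == 3.3
        assert s.loc["a", "ci5"] == s.loc["a", "ci95"] == 3.3

    def test_percentile_definition(self):
        chain = PosteriorChain(names=["a"], draws=np.arange(1.0, 101.0)[:, None],
                               acceptance={}, n_burn=0)
        s = summarise(chain)
        assert s.loc["a", "median"] == pytest.approx(50.5)
        assert s.loc["a", "ci5"] == pytest.approx(5.95)
        assert s.loc["a", "ci95"] == pytest.approx(95.05)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=500)
        a = PosteriorChain(names=["a"], draws=x[:, None], acceptance={}, n_burn=0)
        b = PosteriorChain(names=["a"], draws=rng.permutation(x)[:, None], acceptance={}, n_burn=0)
        assert summarise(a).loc["a", "median"] == summarise(b).loc["a", "median"]

    def test_integer_mode_reported(self):
        draws = np.array([1963] * 80 + [1964] * 20, dtype=float)[:, None]
        chain = PosteriorChain(names=["peakyear"], draws=draws, acceptance={}, n_burn=0)
        s = summarise(chain, integer={"peakyear"})
        assert s.loc["peakyear", "mode"] == 1963
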