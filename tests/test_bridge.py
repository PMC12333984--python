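import numpy as np
import pandas as pd
import pytest

from mirsig import (
    CoordinatePrior,
    SimulationParams,
    attach_labels,
    fit_block_splsda,
    fit_bridge,
    simulate_d14_cohort,
    summarize_coordinates,
)

DOSES = (0.0, 20.0, 40.0, 80.0)


def tight_prior(means=(0.0, 1.0, 2.0, 3.0), sd=0.05):
    return CoordinatePrior(
        mu=dict(zip(DOSES, means)),
        sd={d: sd for d in DOSES},
        n={d: 15 for d in DOSES},
    )


def d14_from(y, doses):
    return pd.DataFrame({"dose_gy": np.asarray(doses, float), "injury_score": y},
                        index=[f"a{i}" for i in range(len(y))])


class TestSummarizeCoordinates:
    def test_matches_direct_groupby(self, default_dataset):
        model = fit_block_splsda(default_dataset, ncomp=2, keepX={"miR": 10})
        attach_labels(model, default_dataset.outcome)
        prior = summarize_coordinates(model, component=1)
        t = pd.Series(model.scores["miR"][:, 0], index=default_dataset.outcome.index)
        by = t.groupby(default_dataset.outcome.values)
        for d in DOSES:
            assert prior.mu[d] == pytest.approx(by.mean()[d])
            assert prior.sd[d] == pytest.approx(by.std(ddof=1)[d])

    def test_sample_order_irrelevant(self, default_dataset):
        model = fit_block_splsda(default_dataset, ncomp=1, keepX={"miR": 5})
        attach_labels(model, default_dataset.outcome)
        p1 = summarize_coordinates(model, 1)
        perm = np.random.default_rng(0).permutation(len(default_dataset.outcome))
        model.scores = {b: s[perm] for b, s in model.scores.items()}
        model._train_labels = model._train_labels[perm]
        p2 = summarize_coordinates(model, 1)
        assert p1.mu == pytest.approx(p2.mu)

    def test_invalid_component_rejected(self, default_dataset):
        model = fit_block_splsda(default_dataset, ncomp=1, keepX={"miR": 5})
        attach_labels(model, default_dataset.outcome)
        with pytest.raises(ValueError, match="component"):
            summarize_coordinates(model, 3)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            CoordinatePrior(mu={0.0: 0.0}, sd={0.0: 0.0}, n={0.0: 5})


class TestFitBridge:
    def test_strong_signal_recovers_high_r(self):
        """Outcome equal to the group coordinate mean plus tiny noise, with
        tight priors, pushes the posterior correlation above 0.95."""
        rng = np.random.default_rng(1)
        doses = np.repeat(DOSES, 10)
        prior = tight_prior()
        y = np.array([prior.mu[d] for d in doses]) + rng.normal(0, 0.01, len(doses))
        res = fit_bridge(prior, d14_from(y, doses), burn_in=1500, draws=3000, seed=3)
        assert res.summaries["r"]["mean"] > 0.95

    def test_draws_of_r_bounded_and_summaries_inside_range(self):
        rng = np.random.default_rng(2)
        doses = np.repeat(DOSES, 8)
        y = rng.normal(size=len(doses))
        res = fit_bridge(tight_prior(sd=0.5), d14_from(y, doses),
                         burn_in=400, draws=800, seed=4)
        r = res.draws["r"]
        assert (r > -1).all() and (r < 1).all()
        assert r.min() <= res.summaries["r"]["median"] <= r.max()
        lo, hi = res.summaries["r"]["ci95"]
        assert r.min() <= lo <= hi <= r.max()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        doses = np.repeat(DOSES, 6)
        y = rng.normal(size=len(doses))
        kw = dict(burn_in=300, draws=600, seed=11)
        a = fit_bridge(tight_prior(sd=0.4), d14_from(y, doses), **kw)
        b = fit_bridge(tight_prior(sd=0.4), d14_from(y, doses), **kw)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_affine_outcome_invariance(self):
        """r is a correlation: y -> a*y + b (a>0) leaves its posterior unchanged
        up to Monte-Carlo error."""
        rng = np.random.default_rng(4)
        doses = np.repeat(DOSES, 8)
        y = np.array([tight_prior().mu[d] for d in doses]) + rng.normal(0, 0.5, len(doses))
        kw = dict(burn_in=800, draws=1600, seed=5)
        r1 = fit_bridge(tight_prior(sd=0.3), d14_from(y, doses), **kw)
        r2 = fit_bridge(tight_prior(sd=0.3), d14_from(7.3 * y - 20.0, doses), **kw)
        assert r1.summaries["r"]["mean"] == pytest.approx(
            r2.summaries["r"]["mean"], abs=0.05)

    def test_constant_outcome_rejected(self):
        doses = np.repeat(DOSES, 4)
        with pytest.raises(ValueError, match="constant"):
            fit_bridge(tight_prior(), d14_from(np.ones(len(doses)), doses))

    def test_uncovered_dose_group_rejected(self):
        prior = CoordinatePrior(mu={0.0: 0.0, 20.0: 1.0}, sd={0.0: 1.0, 20.0: 1.0},
                                n={0.0: 5, 20.0: 5})
        doses = [0.0, 0.0, 40.0, 40.0]
        with pytest.raises(ValueError, match="40"):
            fit_bridge(prior, d14_from(np.arange(4.0), doses))

    def test_monotone_in_effect_size(self):
        """Stronger alignment between group means and outcome raises posterior r."""
        rng = np.random.default_rng(6)
        doses = np.repeat(DOSES, 8)
        prior = tight_prior(sd=0.3)
        base = np.array([prior.mu[d] for d in doses])
        means = []
        for slope in (0.0, 0.5, 2.0):
            y = slope * base + rng.normal(0, 1.0, len(doses))
            res = fit_bridge(prior, d14_from(y, doses), burn_in=600, draws=1200, seed=7)
            means.append(res.summaries["r"]["mean"])
        assert means[0] < means[1] < means[2]

    def test_hyperprior_mode_agrees_with_plugin(self):
        """Adding Normal(mu_g, s_g/sqrt(n_g)) uncertainty on the group means
        barely moves the posterior when group n is moderate."""
        rng = np.random.default_rng(8)
        doses = np.repeat(DOSES, 10)
        prior = tight_prior(sd=0.3)
        y = np.array([prior.mu[d] for d in doses]) + rng.normal(0, 0.3, len(doses))
        kw = dict(burn_in=800, draws=1600, seed=9)
        plug = fit_bridge(prior, d14_from(y, doses), **kw)
        hyper = fit_bridge(prior, d14_from(y, doses), hyperprior_means=True, **kw)
        assert hyper.summaries["r"]["mean"] == pytest.approx(
            plug.summaries["r"]["mean"], abs=0.1)
        assert (hyper.draws["r"].abs() < 1).all()

    def test_null_tail_probability_roughly_uniform(self):
        """Under no association the two-sided tail probability should not pile
        up near zero (coarse calibration check, scaled down)."""
        prior = tight_prior(sd=0.4)
        doses = np.repeat(DOSES, 8)
        ps = []
        for s in range(12):
            y = np.random.default_rng(500 + s).normal(size=len(doses))
            res = fit_bridge(prior, d14_from(y, doses), burn_in=400, draws=800, seed=s)
            ps.append(res.tail_probability)
        assert np.mean(np.array(ps) < 0.05) <= 0.25
        assert np.mean(ps) > 0.2
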