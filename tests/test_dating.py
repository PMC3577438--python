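"""Strict-clock dating: fixed-rate conversion, MCMC sampler, summaries."""

import numpy as np
import pandas as pd
import pytest

import mitochron as mc
from mitochron.dating import DatingResults, effective_sample_size


def test_rate_date_examples():
    assert mc.rate_date(0.0) == 0.0
    assert mc.rate_date(0.23) == pytest.approx(10.0)  # 0.23 / (2 x 0.0115)
    assert mc.rate_date(0.23, 0.0115 / 2) == pytest.approx(20.0)  # halving mu doubles T
    with pytest.raises(ValueError):
        mc.rate_date(0.1, rate=0.0)
    with pytest.raises(ValueError):
        mc.rate_date(-0.1)


def test_calibration_prior_validation():
    with pytest.raises(ValueError):
        mc.CalibrationPrior(sd=0.0)
    with pytest.raises(ValueError):
        mc.CalibrationPrior(mean=100.0, bounds=(243.0, 276.0))
    prior = mc.CalibrationPrior(truncated=True)
    assert prior.logpdf(200.0) == -np.inf
    assert np.isfinite(prior.logpdf(260.0))


def test_prior_recovery_likelihood_off():
    """Sampling with the likelihood disabled reproduces the calibration
    prior's mean and sd within Monte-Carlo error (two-taxon tree, where the
    root marginal is exactly the calibration density)."""
    tree = mc.simulate_time_tree(2, root_age=250.0, seed=0)
    cal = mc.CalibrationPrior(mean=260.0, sd=8.42)
    res = mc.mcmc_date({}, tree, clock=mc.ClockModel(rate=None),
                       calibration=cal, chain_length=120_000, n_runs=1,
                       seed=1, likelihood_off=True)
    samples = res.trace["root"].to_numpy()
    ess = effective_sample_size(samples)
    mc_se = 8.42 / np.sqrt(ess)
    assert res.posterior_mean("root") == pytest.approx(260.0, abs=3 * mc_se)
    assert samples.std() == pytest.approx(8.42, rel=0.1)


def test_two_taxon_fixed_rate_posterior_recovers_truth():
    true_T = 10.0
    tree = mc.simulate_time_tree(2, root_age=true_T, seed=2)
    aln = mc.simulate_alignment(tree, 10_770, 0.0115, seed=3)
    res = mc.mcmc_date(aln, tree, clock=mc.ClockModel(rate=0.0115),
                       chain_length=50_000, n_runs=1, seed=4, root_max=200.0)
    mean = res.posterior_mean("root")
    sd = res.trace["root"].std()
    # posterior concentrates near the truth; the binomial information at
    # 10,770 sites puts the posterior sd near 0.25 my here
    assert abs(mean - true_T) < 3 * sd
    lo, hi = res.credible_interval("root")
    assert lo < hi and lo < mean < hi


def test_rate_date_and_mcmc_agree_on_two_taxa():
    tree = mc.simulate_time_tree(2, root_age=15.0, seed=5)
    aln = mc.simulate_alignment(tree, 10_770, 0.0115, seed=6)
    a, b = aln.values()
    t_closed = mc.rate_date(mc.jc69_distance(a, b)[0])
    res = mc.mcmc_date(aln, tree, clock=mc.ClockModel(rate=0.0115),
                       chain_length=50_000, n_runs=1, seed=7, root_max=200.0)
    assert res.posterior_mean("root") == pytest.approx(
        t_closed, abs=3 * res.trace["root"].std()
    )


def test_identical_seeds_give_identical_traces():
    tree = mc.simulate_time_tree(2, root_age=10.0, seed=8)
    aln = mc.simulate_alignment(tree, 2000, 0.0115, seed=9)
    runs = []
    for _ in range(2):
        res = mc.mcmc_date(aln, tree, clock=mc.ClockModel(rate=0.0115),
                           chain_length=10_000, n_runs=1, seed=11,
                           root_max=200.0)
        runs.append(res.runs[0])
    pd.testing.assert_frame_equal(runs[0], runs[1])


def test_multi_run_pooling_and_per_run_ess():
    tree = mc.simulate_time_tree(2, root_age=10.0, seed=12)
    aln = mc.simulate_alignment(tree, 2000, 0.0115, seed=13)
    res = mc.mcmc_date(aln, tree, clock=mc.ClockModel(rate=0.0115),
                       chain_length=20_000, n_runs=3, seed=14, root_max=200.0)
    n_per_run = 20_000 // 100
    assert len(res.trace) == 3 * int(n_per_run * 0.9)
    assert len(res.per_run_ess("root")) == 3
    assert all(e > 0 for e in res.per_run_ess("root"))


def test_free_rate_with_calibration_samples_rate():
    tree = mc.simulate_time_tree(3, root_age=260.0, seed=15)
    aln = mc.simulate_alignment(tree, 3000, 0.001, seed=16)
    res = mc.mcmc_date(aln, tree, clock=mc.ClockModel(rate=None),
                       calibration=mc.CalibrationPrior(),
                       chain_length=30_000, n_runs=1, seed=17)
    summary = res.summary()
    assert "rate" in set(summary["node"])
    rate_mean = res.posterior_mean("rate")
    assert rate_mean == pytest.approx(0.001, rel=0.5)


def test_free_rate_requires_calibration():
    tree = mc.simulate_time_tree(2, root_age=10.0, seed=18)
    with pytest.raises(ValueError):
        mc.ClockDatingModel({}, tree, clock=mc.ClockModel(rate=None),
                            likelihood_off=True)


def test_summary_table_format_and_ess_warning():
    tree = mc.simulate_time_tree(2, root_age=250.0, seed=19)
    res = mc.mcmc_date({}, tree, clock=mc.ClockModel(rate=None),
                       calibration=mc.CalibrationPrior(),
                       chain_length=50_000, n_runs=1, seed=20,
                       likelihood_off=True)
    table = res.summary()
    assert list(table.columns) == ["node", "mean", "ci_2.5%", "ci_97.5%", "ess"]
    row = table[table["node"] == "root"].iloc[0]
    assert row["ci_2.5%"] <= row["mean"] <= row["ci_97.5%"]

    # constant trace: degenerate interval and an ESS warning
    const = res.runs[0].copy()
    const["root"] = 42.0
    fake = DatingResults(res.model, [const], 0.1, 50_000, 100)
    with pytest.warns(UserWarning):
        t2 = fake.summary()
    r2 = t2[t2["node"] == "root"].iloc[0]
    assert r2["mean"] == 42.0 and r2["ci_2.5%"] == r2["ci_97.5%"] == 42.0


def test_summary_on_iid_normal_samples():
    rng = np.random.default_rng(21)
    samples = rng.normal(0.0, 1.0, 10_000)
    ess = effective_sample_size(samples)
    assert ess == pytest.approx(10_000, rel=0.15)
    lo, hi = np.quantile(samples, [0.025, 0.975])
    assert lo == pytest.approx(-1.96, abs=0.1)
    assert hi == pytest.approx(1.96, abs=0.1)


def test_zero_acceptance_raises_diagnostic_error():
    tree = mc.simulate_time_tree(2, root_age=260.0, seed=22)
    cal = mc.CalibrationPrior(truncated=True)
    model = mc.ClockDatingModel({}, tree, clock=mc.ClockModel(rate=0.0115),
                                calibration=cal, likelihood_off=True)
    with pytest.raises(RuntimeError, match="step"):
        # a hopeless step size: every proposal lands outside the truncation
        model.fit(chain_length=6000, n_runs=1, seed=23, root_step=1e7)


def test_posterior_plot_smoke():
    import matplotlib

    matplotlib.use("Agg")
    tree = mc.simulate_time_tree(2, root_age=250.0, seed=30)
    res = mc.mcmc_date({}, tree, clock=mc.ClockModel(rate=None),
                       calibration=mc.CalibrationPrior(),
                       chain_length=20_000, n_runs=1, seed=31,
                       likelihood_off=True)
    ax = res.plot_posterior("root")
    assert ax.get_xlabel().startswith("root")


def test_credible_interval_covers_truth_typically():
    hits = 0
    for i in range(10):
        rng = np.random.default_rng(400 + i)
        true_T = float(rng.uniform(5, 50))
        tree = mc.simulate_time_tree(2, root_age=true_T, seed=500 + i)
        aln = mc.simulate_alignment(tree, 10_770, 0.0115, seed=600 + i)
        res = mc.mcmc_date(aln, tree, clock=mc.ClockModel(rate=0.0115),
                           chain_length=20_000, n_runs=1, seed=700 + i,
                           root_max=200.0)
        lo, hi = res.credible_interval("root")
        hits += lo <= true_T <= hi
    assert hits >= 8
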