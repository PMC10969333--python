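"""Virtual-individual generation, measurement noise and whole experiments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import virtuallux as vl
from virtuallux.dose_response import _effective_dose_arrays


def _eds(df):
    a, b = df["a"].to_numpy(), df["b"].to_numpy()
    return (_effective_dose_arrays(0.25, a, b), _effective_dose_arrays(0.75, a, b))


def test_rejection_bounds_honoured(pop_model):
    df = vl.sample_individuals(pop_model, 10_000, rng=np.random.default_rng(0))
    ed25, ed75 = _eds(df)
    assert np.all(ed25 >= pop_model.ed25_floor)
    assert np.all(ed75 <= pop_model.ed75_ceiling)
    assert (df["sigma"] > 0).all()


def test_sample_cloud_covers_raw_estimate_scatter(pop_model, raw41):
    # a large sample of virtual (a, b) pairs should overlay the raw-estimate
    # scatter: its 2D ranges cover the raw ranges
    raw, _ = raw41
    df = vl.sample_individuals(pop_model, 25_000, rng=np.random.default_rng(20))
    for col in ("a", "b"):
        assert df[col].min() <= raw[col].min()
        assert df[col].max() >= raw[col].max()


def test_sampled_a_matches_kde_quartiles(pop_model):
    df = vl.sample_individuals(pop_model, 10_000, rng=np.random.default_rng(1))
    for q in (0.25, 0.5, 0.75):
        assert np.quantile(df["a"], q) == pytest.approx(
            pop_model.a_dist.quantile(q), abs=0.1
        )


def test_eta_zero_is_deterministic_median_individual(pop_model):
    i1 = vl.sample_individual_reduced(pop_model, 0.0, np.random.default_rng(2))
    i2 = vl.sample_individual_reduced(pop_model, 0.0, np.random.default_rng(99))
    assert i1.params.a == i2.params.a == pop_model.a_dist.a50
    assert i1.params.b == i2.params.b
    m = pop_model.regression.means()
    expected_b = np.exp(m["alpha"] + m["beta"] * pop_model.a_dist.a50)
    assert i1.params.b == pytest.approx(expected_b, rel=1e-9)


def test_eta_one_matches_unrestricted_distribution(pop_model):
    """The reduced-variance process at eta=1 must be distributionally
    indistinguishable (on a) from the unrestricted process."""
    s1 = vl.sample_individuals(pop_model, 2000, eta=None, rng=np.random.default_rng(3))
    s2 = vl.sample_individuals(pop_model, 2000, eta=1.0, rng=np.random.default_rng(4))
    assert stats.ks_2samp(s1["a"], s2["a"]).pvalue > 0.01


def test_eta_shrinks_variance(pop_model):
    v = {}
    for eta in (0.2, 1.0):
        df = vl.sample_individuals(pop_model, 10_000, eta=eta,
                                   rng=np.random.default_rng(5))
        v[eta] = df["a"].var()
    assert v[0.2] < v[1.0]


def test_eta_continuity_of_mean_and_spread(pop_model):
    etas = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    means, sds = [], []
    for eta in etas:
        df = vl.sample_individuals(pop_model, 8000, eta=eta,
                                   rng=np.random.default_rng(6))
        means.append(df["a"].mean())
        sds.append(df["a"].std())
    # spread grows monotonically with eta (Monte-Carlo slack via strictness
    # of the trend, not per-step tolerance)
    assert all(s2 > s1 for s1, s2 in zip(sds, sds[1:]))
    # mean moves continuously from a50 to the KDE mean
    assert means[0] == pytest.approx(pop_model.a_dist.a50, abs=1e-9)
    assert means[-1] == pytest.approx(pop_model.a_dist.mean, abs=0.05)
    assert max(abs(m2 - m1) for m1, m2 in zip(means, means[1:])) < 0.1


def test_eta_out_of_range(pop_model):
    with pytest.raises(ValueError):
        vl.sample_individuals(pop_model, 10, eta=1.5)


def test_measure_noiseless_limit_and_range(pop_model):
    p = vl.DoseResponseParams(2.0, 1.3)
    quiet = vl.VirtualIndividual(params=p, sigma=1e-12)
    x = 150.0
    assert vl.measure(quiet, x, np.random.default_rng(7)) == pytest.approx(
        vl.suppression(x, p), abs=1e-9
    )
    noisy = vl.VirtualIndividual(params=p, sigma=0.8)
    rng = np.random.default_rng(8)
    vals = np.array([vl.measure(noisy, x, rng) for _ in range(10_000)])
    assert np.all((vals > 0) & (vals < 1))
    # logit-normal noise: the median measurement equals the true value
    assert np.median(vals) == pytest.approx(vl.suppression(x, p), abs=0.01)


def test_measure_rejects_degenerate_truth():
    ind = vl.VirtualIndividual(params=vl.DoseResponseParams(2.0, 1.3), sigma=0.5)
    with pytest.raises(ValueError, match="above 1 lux"):
        vl.measure(ind, 1.0, np.random.default_rng(9))


def test_measurement_noise_stays_inside_unit_interval(pop_model):
    # bulk check across the population: a million noisy measurements
    rng = np.random.default_rng(10)
    df = vl.sample_individuals(pop_model, 1000, rng=rng)
    a, b, sg = (df[c].to_numpy()[:, None] for c in ("a", "b", "sigma"))
    x = np.geomspace(2.0, 2000.0, 10)[None, :]
    true = vl.dose_response._suppression_arrays(x, a, b)
    z = vl.logit(true)[..., None] + sg[..., None] * rng.standard_normal((1000, 10, 100))
    m = vl.inv_logit(z)
    assert m.size == 1_000_000
    assert np.all((m > 0) & (m < 1))


def test_virtual_experiment_shapes_and_determinism(pop_model):
    grid = vl.DEFAULT_MEASUREMENT_GRID
    e1 = vl.virtual_experiment(pop_model, 41, grid, rng=np.random.default_rng(11))
    assert e1.measured.shape == (41, len(grid))
    assert np.all((e1.measured > 0) & (e1.measured < 1))
    tidy = e1.to_frame(experiment_id=3)
    assert len(tidy) == 41 * len(grid)
    assert set(tidy.columns) == {
        "experiment_id", "individual_id", "a", "b", "sigma", "lux",
        "true_suppression", "measured_suppression",
    }
    e2 = vl.virtual_experiment(pop_model, 41, grid, rng=np.random.default_rng(11))
    np.testing.assert_array_equal(e1.measured, e2.measured)


def test_median_individual_experiment_traces_true_curve(pop_model):
    # eta=0 with the noise level forced to ~0: measurements reproduce the
    # median individual's true curve
    ind = vl.sample_individuals(pop_model, 1, eta=0.0, rng=np.random.default_rng(12))
    quiet = vl.VirtualIndividual(
        params=vl.DoseResponseParams(float(ind["a"][0]), float(ind["b"][0])),
        sigma=1e-12,
    )
    grid = np.array(vl.DEFAULT_MEASUREMENT_GRID)
    got = np.array([vl.measure(quiet, x, np.random.default_rng(13)) for x in grid])
    np.testing.assert_allclose(got, vl.suppression(grid, quiet.params), atol=1e-9)


def test_experiment_checks_constant_matrix():
    grid = np.array([10.0, 100.0])
    inds = pd.DataFrame({"a": [2.0], "b": [1.0], "sigma": [0.1]})
    exp = vl.VirtualExperiment(
        individuals=inds, grid=grid,
        true_suppression=np.full((1, 2), 0.5),
        measured=np.full((1, 2), 0.5), eta=None,
    )
    table = vl.experiment_checks([exp])
    assert (table["min"] == 0.5).all() and (table["max"] == 0.5).all()
    assert (table["frac_below_5pct"] == 0).all()
    assert (table["frac_above_95pct"] == 0).all()


def test_experiment_checks_saturation_pattern(pop_model):
    rng = np.random.default_rng(14)
    exps = [
        vl.virtual_experiment(pop_model, 41, vl.DEFAULT_MEASUREMENT_GRID, rng=rng)
        for _ in range(50)
    ]
    table = vl.experiment_checks(exps)
    assert ((table["frac_below_5pct"] + table["frac_above_95pct"]) <= 1).all()
    top = table[table["lux"] == 2000.0]
    # at the brightest level, saturation is overwhelmingly at the high end
    assert top["frac_above_95pct"].mean() > top["frac_below_5pct"].mean()


def test_experiment_checks_grid_mismatch(pop_model):
    rng = np.random.default_rng(15)
    e1 = vl.virtual_experiment(pop_model, 5, [10.0, 100.0], rng=rng)
    e2 = vl.virtual_experiment(pop_model, 5, [10.0, 200.0], rng=rng)
    with pytest.raises(ValueError, match="same measurement grid"):
        vl.experiment_checks([e1, e2])
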